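import numpy as np
import pytest

from dotslab import (
    OpticalProperties,
    make_slab_phantom,
    make_layout,
    RunConfig,
    run_pipeline,
)


@pytest.fixture
def phantom():
    """Default homogeneous compressed-breast slab."""
    return make_slab_phantom(seed=0)


@pytest.fixture
def het_phantom():
    """Slab with the default smooth absorption heterogeneity."""
    return make_slab_phantom(heterogeneity_amplitude=0.1, seed=1)


@pytest.fixture
def layout(phantom):
    """Full 48 x 54 transmission layout."""
    return make_layout(phantom)


@pytest.fixture
def small_layout(phantom):
    """Reduced 6 x 6 layout for fast forward-model checks."""
    return make_layout(phantom, n_sources=6, n_detectors=6)


def tiny_run_config(**overrides) -> RunConfig:
    """A seconds-scale pipeline configuration for smoke and determinism tests."""
    base = {
        "seed": 5,
        "layout": {"n_sources": 6, "n_detectors": 6},
        "dataset": {"n_samples": 24},
        "gbm": {"n_estimators": 30},
        "gp": {"scale": "desk", "population_size": 40, "generations": 3, "n_runs": 1},
        "eval": {"n_seeds": 1},
    }
    base.update(overrides)
    return RunConfig.model_validate(base)


@pytest.fixture(scope="session")
def desk_pipeline():
    """The reduced-scale reference experiment: 1000 samples, 2% noise,
    48 x 54 layout, desk GP budget, three pipeline seeds.

    Session-scoped because it takes several minutes; every end-to-end
    accuracy check reads from this single run.
    """
    return run_pipeline(RunConfig(seed=1))
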