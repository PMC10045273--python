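"""Config-driven end-to-end orchestration.

simulate -> train -> refine -> evaluate -> render, with every random
process seeded from the config and a config hash embedded in every output
so a rerun with the same config reproduces byte-identical reports.

Two scale presets are provided: ``desk`` (1000 samples, GP population 500,
30 generations, 3 runs — minutes on one CPU) and ``paper`` (5000 samples
and the full-scale GP budget — hours of CPU).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .geometry import OpticalProperties, make_slab_phantom, make_layout, DEFAULT_SLAB_SIZE_MM
from .dataset import (
    generate_dataset,
    split_dataset,
    LabeledDataset,
    LABEL_NAMES,
)
from .inverse import GBMHyperparams, train_inverse_model, predict
from .gp import GPConfig, desk_gp_config, evolve, refine_predictions, to_sexpr
from .metrics import (
    evaluate_stage,
    aggregate_reports,
    EvaluationReport,
    render_reconstruction,
    save_render_png,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# configuration blocks (pydantic: validated, JSON-schema exportable)


class PhantomBlock(BaseModel):
    size_x: float = DEFAULT_SLAB_SIZE_MM[0]
    size_y: float = DEFAULT_SLAB_SIZE_MM[1]
    size_z: float = DEFAULT_SLAB_SIZE_MM[2]
    mu_a: float = 0.005
    mu_s_prime: float = 1.0
    refractive_index: float = 1.4
    heterogeneity_amplitude: float = Field(0.1, ge=0.0, lt=0.5)
    contrast_min: float = 2.0
    contrast_max: float = 4.0


class LayoutBlock(BaseModel):
    n_sources: int = Field(48, ge=1)
    n_detectors: int = Field(54, ge=1)
    margin: float = Field(10.0, ge=0.0)


class DatasetBlock(BaseModel):
    n_samples: int = Field(1000, ge=8)
    noise_level: float = Field(0.02, ge=0.0)
    xgb_fraction: float = Field(0.5, gt=0.0, lt=1.0)
    train_fraction: float = Field(0.6, gt=0.0, lt=1.0)


class GBMBlock(BaseModel):
    n_estimators: int = 500
    max_depth: int = 6
    learning_rate: float = 0.05
    subsample: float = 0.8
    max_bin: int = 64

    def to_hyperparams(self) -> GBMHyperparams:
        return GBMHyperparams(**self.model_dump())


class GPBlock(BaseModel):
    scale: Literal["desk", "paper"] = "desk"
    population_size: int | None = None
    generations: int | None = None
    n_runs: int | None = None

    def to_config(self) -> GPConfig:
        overrides = {
            k: v
            for k, v in self.model_dump().items()
            if k != "scale" and v is not None
        }
        if self.scale == "desk":
            return desk_gp_config(**overrides)
        return GPConfig(**overrides)


class EvalBlock(BaseModel):
    n_seeds: int = Field(3, ge=1)
    render_z_slice: float | None = None


class RunConfig(BaseModel):
    """Full pipeline configuration; every stochastic stage derives its seed
    deterministically from ``seed``."""

    seed: int = Field(1, ge=0, lt=2**31)
    phantom: PhantomBlock = PhantomBlock()
    layout: LayoutBlock = LayoutBlock()
    dataset: DatasetBlock = DatasetBlock()
    gbm: GBMBlock = GBMBlock()
    gp: GPBlock = GPBlock()
    eval: EvalBlock = EvalBlock()

    @model_validator(mode="after")
    def _check(self):
        if self.phantom.contrast_max <= self.phantom.contrast_min:
            raise ValueError("contrast_max must exceed contrast_min")
        if self.phantom.contrast_min <= 1.0:
            raise ValueError("tumor contrast must exceed the background (> 1)")
        return self

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.model_dump(), f, sort_keys=True)


@dataclass
class SeedRunResult:
    """Artifacts of one pipeline seed."""

    seed: int
    dataset: LabeledDataset
    xgb_test_pred: np.ndarray
    xgb_test_true: np.ndarray
    gp_test_pred_stage1: np.ndarray
    gp_test_pred_refined: np.ndarray
    gp_test_true: np.ndarray
    gp_trees: list  # five best trees (s-expression-able), label order
    gp_histories: list  # per label: list of per-run histories
    n_nonfinite: int


@dataclass
class PipelineResult:
    """Aggregated outcome of the full multi-seed pipeline."""

    config: RunConfig
    report_xgb: EvaluationReport  # boosted-tree stage on its own test split
    report_gp: EvaluationReport  # refined predictions on the GP test split
    report_stage1_on_gp_test: EvaluationReport  # uncorrected, same split as report_gp
    per_seed: list  # list[SeedRunResult]

    def reports_dict(self) -> dict:
        return {
            "package_version": __version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "after_xgb": self.report_xgb.to_dict(),
            "after_gp": self.report_gp.to_dict(),
            "stage1_on_gp_test": self.report_stage1_on_gp_test.to_dict(),
        }

    def reports_json(self) -> str:
        return json.dumps(self.reports_dict(), sort_keys=True, indent=2)


def _run_one_seed(config: RunConfig, seed: int) -> SeedRunResult:
    ph = config.phantom
    phantom = make_slab_phantom(
        ph.size_x,
        ph.size_y,
        ph.size_z,
        OpticalProperties(ph.mu_a, ph.mu_s_prime, ph.refractive_index),
        ph.heterogeneity_amplitude,
        seed=config.seed,  # phantom structure is shared across seeds
    )
    layout = make_layout(
        phantom, config.layout.n_sources, config.layout.n_detectors, config.layout.margin
    )

    stage = "simulate"
    try:
        ds = generate_dataset(
            phantom,
            layout,
            config.dataset.n_samples,
            config.dataset.noise_level,
            seed=seed,
            contrast_range=(ph.contrast_min, ph.contrast_max),
        )
        ds.config_hash = config.config_hash()
        ds = split_dataset(
            ds, config.dataset.xgb_fraction, config.dataset.train_fraction, seed=seed
        )

        stage = "train"
        model = train_inverse_model(ds, config.gbm.to_hyperparams(), seed=seed)
        X_xt, Y_xt = ds.subset("xgb-test")
        xgb_test_pred = predict(model, X_xt)

        stage = "refine"
        gp_cfg = config.gp.to_config()
        X_gt, Y_gt = ds.subset("gp-train")
        X_ge, Y_ge = ds.subset("gp-test")
        pred_train = predict(model, X_gt)
        pred_test = predict(model, X_ge)
        trees = []
        histories = []
        n_nonfinite = 0
        label_seeds = np.random.SeedSequence(seed).spawn(len(LABEL_NAMES))
        for j in range(len(LABEL_NAMES)):
            res = evolve(
                pred_train[:, j],
                Y_gt[:, j],
                gp_cfg,
                seed=int(label_seeds[j].generate_state(1)[0] % (2**31)),
            )
            trees.append(res.best_tree)
            histories.append(res.fitness_history)
            n_nonfinite += res.n_nonfinite
        refined = refine_predictions(trees, pred_test)
        if n_nonfinite:
            logger.info(
                "seed %d: %d GP evaluations hit the non-finite sentinel",
                seed,
                n_nonfinite,
            )
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, e) from e

    return SeedRunResult(
        seed=seed,
        dataset=ds,
        xgb_test_pred=xgb_test_pred,
        xgb_test_true=Y_xt,
        gp_test_pred_stage1=pred_test,
        gp_test_pred_refined=refined,
        gp_test_true=Y_ge,
        gp_trees=trees,
        gp_histories=histories,
        n_nonfinite=n_nonfinite,
    )


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Execute the full pipeline over ``eval.n_seeds`` seeded repetitions.

    Returns the aggregated result; with ``out_dir`` set, also writes the
    dataset, fitted models, evolved programs, reports and a slice render.
    """
    seeds = [config.seed + k for k in range(config.eval.n_seeds)]
    per_seed = [_run_one_seed(config, s) for s in seeds]

    normalizer = per_seed[0].dataset.normalizer
    report_xgb = aggregate_reports(
        [
            evaluate_stage(r.xgb_test_pred, r.xgb_test_true, "after-xgb", normalizer, (r.seed,))
            for r in per_seed
        ]
    )
    report_gp = aggregate_reports(
        [
            evaluate_stage(
                r.gp_test_pred_refined, r.gp_test_true, "after-gp", normalizer, (r.seed,)
            )
            for r in per_seed
        ]
    )
    report_stage1 = aggregate_reports(
        [
            evaluate_stage(
                r.gp_test_pred_stage1, r.gp_test_true, "stage1-on-gp-test", normalizer, (r.seed,)
            )
            for r in per_seed
        ]
    )
    result = PipelineResult(
        config=config,
        report_xgb=report_xgb,
        report_gp=report_gp,
        report_stage1_on_gp_test=report_stage1,
        per_seed=per_seed,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "version": __version__}

    (out_dir / "config.json").write_text(
        json.dumps({**meta, "config": cfg.model_dump()}, sort_keys=True, indent=2)
    )
    (out_dir / "reports.json").write_text(result.reports_json())

    programs = {
        **meta,
        "programs": [
            {
                "seed": r.seed,
                "trees": {
                    name: to_sexpr(t) for name, t in zip(LABEL_NAMES, r.gp_trees)
                },
            }
            for r in result.per_seed
        ],
    }
    (out_dir / "gp_programs.json").write_text(
        json.dumps(programs, sort_keys=True, indent=2)
    )

    first = result.per_seed[0]
    first.dataset.save_hdf5(out_dir / f"dataset_seed{first.seed}.h5")
    first.dataset.labels_to_csv(out_dir / f"labels_seed{first.seed}.csv")

    # fitness histories of the first seed, long-form CSV
    import pandas as pd

    rows = []
    for name, runs in zip(LABEL_NAMES, first.gp_histories):
        for run_i, hist in enumerate(runs):
            for gen, fit in enumerate(hist):
                rows.append((name, run_i, gen, fit))
    pd.DataFrame(rows, columns=["label", "run", "generation", "best_fitness"]).to_csv(
        out_dir / "gp_fitness_history.csv", index=False
    )

    # render the first test sample of the first seed: truth vs refined
    ph = cfg.phantom
    phantom = make_slab_phantom(
        ph.size_x,
        ph.size_y,
        ph.size_z,
        OpticalProperties(ph.mu_a, ph.mu_s_prime, ph.refractive_index),
        heterogeneity_amplitude=0.0,
    )
    z_slice = cfg.eval.render_z_slice
    truth_phys = first.dataset.normalizer.denormalize(first.gp_test_true[0])
    pred_phys = first.dataset.normalizer.denormalize(first.gp_test_pred_refined[0])
    if z_slice is None:
        z_slice = float(truth_phys[2])
    for tag, row in (("truth", truth_phys), ("predicted", pred_phys)):
        img = render_reconstruction(row, phantom, z_slice)
        np.savez(out_dir / f"render_{tag}.npz", image=img, z_slice=z_slice, **meta)
        save_render_png(
            img, phantom, out_dir / f"render_{tag}.png", title=f"{tag} (z={z_slice:.1f} mm)"
        )
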