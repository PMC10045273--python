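"""Stage one of the inverse solver: per-label gradient-boosted trees.

One XGBoost regressor is fitted per label — x, y, z, tumor mu_a and radius
— mapping the log detector readings to the min-max normalized label, with a
squared-error objective.  Predictions are clipped to the normalized [0, 1]
range since every label is physically bounded.

Training is forced single-threaded with a fixed random state so the same
data, seed and hyperparameters reproduce bit-identical models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import xgboost as xgb

from .dataset import LabeledDataset, LabelNormalizer, LABEL_NAMES

__all__ = ["GBMHyperparams", "TrainedInverseModel", "train_inverse_model", "predict"]


@dataclass(frozen=True)
class GBMHyperparams:
    """Boosted-tree hyperparameters (library defaults for this problem)."""

    n_estimators: int = 500
    max_depth: int = 6
    learning_rate: float = 0.05
    subsample: float = 0.8
    # 64 histogram bins are ample for the smooth log-amplitude features and
    # keep single-threaded training fast on thousands of channels.
    max_bin: int = 64

    def to_xgb_kwargs(self, seed: int) -> dict:
        return dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            max_bin=self.max_bin,
            objective="reg:squarederror",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
        )


@dataclass
class TrainedInverseModel:
    """Five fitted regressors in fixed label order plus normalization state."""

    models: list  # list[xgb.XGBRegressor], one per LABEL_NAMES entry
    hyperparams: GBMHyperparams
    normalizer: LabelNormalizer
    seed: int
    n_features: int

    def __post_init__(self) -> None:
        if len(self.models) != len(LABEL_NAMES):
            raise ValueError(f"expected {len(LABEL_NAMES)} models, got {len(self.models)}")

    def save(self, directory) -> None:
        """Native-format model files plus a JSON sidecar of the metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, model in zip(LABEL_NAMES, self.models):
            booster = model.get_booster() if hasattr(model, "get_booster") else model
            booster.save_model(directory / f"model_{name}.ubj")
        sidecar = {
            "hyperparams": asdict(self.hyperparams),
            "bounds": [list(b) for b in self.normalizer.bounds],
            "seed": self.seed,
            "n_features": self.n_features,
            "label_order": list(LABEL_NAMES),
        }
        (directory / "model_meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedInverseModel":
        directory = Path(directory)
        meta = json.loads((directory / "model_meta.json").read_text())
        models = []
        for name in LABEL_NAMES:
            booster = xgb.Booster()
            booster.load_model(str(directory / f"model_{name}.ubj"))
            models.append(booster)
        return cls(
            models=models,
            hyperparams=GBMHyperparams(**meta["hyperparams"]),
            normalizer=LabelNormalizer(
                bounds=tuple(tuple(b) for b in meta["bounds"])
            ),
            seed=meta["seed"],
            n_features=meta["n_features"],
        )


def train_inverse_model(
    d: LabeledDataset,
    hyperparams: GBMHyperparams | None = None,
    seed: int = 0,
) -> TrainedInverseModel:
    """Fit the five per-label regressors on the xgb-train split."""
    hyperparams = hyperparams or GBMHyperparams()
    X, Y = d.subset("xgb-train")
    if len(X) == 0:
        raise ValueError("xgb-train split is empty")
    models = []
    for j, name in enumerate(LABEL_NAMES):
        model = xgb.XGBRegressor(**hyperparams.to_xgb_kwargs(seed))
        model.fit(X, Y[:, j])
        models.append(model)
    return TrainedInverseModel(
        models=models,
        hyperparams=hyperparams,
        normalizer=d.normalizer,
        seed=seed,
        n_features=X.shape[1],
    )


def predict(model: TrainedInverseModel, features: np.ndarray) -> np.ndarray:
    """Normalized-scale predictions [n, 5], clipped to [0, 1]."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {features.shape[1]} != training width {model.n_features}"
        )
    cols = []
    for m in model.models:
        if isinstance(m, xgb.Booster):  # loaded from disk
            cols.append(m.predict(xgb.DMatrix(features)))
        else:
            cols.append(m.predict(features))
    return np.clip(np.column_stack(cols), 0.0, 1.0)
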