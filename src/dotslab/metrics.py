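"""Evaluation metrics and reconstruction rendering.

Accuracy of the inverse solver is judged by two metrics on the normalized
label scale:

* RMSE per label, ``sqrt(mean((Y - X)^2))``;
* cosine similarity between the predicted and true label 5-vectors,
  ``dot(X, Y) / (|X| |Y|)``, computed per test sample and averaged.

Both are also reported in physical units (mm, mm^-1) by rescaling with the
per-label normalization spans.  Reports aggregate mean +- std across
repeated pipeline seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import LABEL_NAMES, LabelNormalizer
from .geometry import Phantom

__all__ = [
    "rmse",
    "cosine_similarity",
    "EvaluationReport",
    "evaluate_stage",
    "aggregate_reports",
    "render_reconstruction",
]


def rmse(predictions, truths) -> float:
    """Root mean squared error between two aligned vectors."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("inputs must have identical shape")
    if predictions.size == 0:
        raise ValueError("cannot compute RMSE of empty input")
    return float(np.sqrt(np.mean((predictions - truths) ** 2)))


def cosine_similarity(x_vec, y_vec) -> float:
    """dot(X, Y) / (|X| |Y|); raises on a zero vector."""
    x = np.asarray(x_vec, dtype=float)
    y = np.asarray(y_vec, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have identical shape")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


@dataclass
class EvaluationReport:
    """Per-label RMSE and mean cosine similarity for one pipeline stage."""

    stage: str  # 'after-xgb' or 'after-gp'
    label_names: tuple = LABEL_NAMES
    per_label_rmse: list = field(default_factory=list)  # normalized scale
    per_label_rmse_std: list = field(default_factory=list)
    per_label_rmse_physical: list = field(default_factory=list)  # mm / mm^-1
    mean_cosine_similarity: float = float("nan")
    std_cosine_similarity: float = float("nan")
    mean_rmse: float = float("nan")  # mean of the five per-label RMSEs
    n_test: int = 0
    seeds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["label_names"] = list(self.label_names)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_markdown(self) -> str:
        lines = [
            f"| Label | RMSE (normalized) | RMSE (physical) |",
            f"|---|---|---|",
        ]
        for name, r, s, p in zip(
            self.label_names,
            self.per_label_rmse,
            self.per_label_rmse_std,
            self.per_label_rmse_physical,
        ):
            unit = "mm^-1" if name == "mu_a" else "mm"
            lines.append(f"| {name} | {r:.4f} +- {s:.4f} | {p:.4f} {unit} |")
        lines.append(
            f"\nmean RMSE {self.mean_rmse:.4f}; mean cosine similarity "
            f"{self.mean_cosine_similarity:.4f} +- {self.std_cosine_similarity:.4f} "
            f"(stage {self.stage}, n_test {self.n_test})"
        )
        return "\n".join(lines)


def _stage_metrics(predictions: np.ndarray, truths: np.ndarray):
    """Per-label RMSE vector and mean per-sample 5-vector cosine similarity."""
    predictions = np.atleast_2d(predictions)
    truths = np.atleast_2d(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must be aligned")
    per_label = np.array(
        [rmse(predictions[:, j], truths[:, j]) for j in range(truths.shape[1])]
    )
    cs = np.array(
        [cosine_similarity(p, t) for p, t in zip(predictions, truths)]
    )
    return per_label, cs


def evaluate_stage(
    predictions,
    truths,
    stage_tag: str,
    normalizer: LabelNormalizer | None = None,
    seeds=(0,),
) -> EvaluationReport:
    """Evaluate one stage on one test split.

    ``predictions`` / ``truths`` may be single [n, 5] arrays (one run) or
    sequences of such arrays, one per repeated pipeline seed; the report
    carries the across-run mean +- std.
    """
    if isinstance(predictions, np.ndarray) and predictions.ndim == 2:
        predictions = [predictions]
        truths = [truths]
    if len(predictions) != len(truths) or len(predictions) == 0:
        raise ValueError("need >= 1 aligned (predictions, truths) pair")

    per_run_rmse = []
    per_run_cs = []
    n_test = 0
    for p, t in zip(predictions, truths):
        pl, cs = _stage_metrics(np.asarray(p), np.asarray(t))
        per_run_rmse.append(pl)
        per_run_cs.append(float(np.mean(cs)))
        n_test += len(np.atleast_2d(p))
    per_run_rmse = np.array(per_run_rmse)  # [runs, 5]
    rmse_mean = per_run_rmse.mean(axis=0)
    rmse_std = per_run_rmse.std(axis=0)
    spans = normalizer.spans if normalizer is not None else np.ones(len(LABEL_NAMES))
    return EvaluationReport(
        stage=stage_tag,
        per_label_rmse=[float(v) for v in rmse_mean],
        per_label_rmse_std=[float(v) for v in rmse_std],
        per_label_rmse_physical=[float(v) for v in rmse_mean * spans],
        mean_cosine_similarity=float(np.mean(per_run_cs)),
        std_cosine_similarity=float(np.std(per_run_cs)),
        mean_rmse=float(np.mean(rmse_mean)),
        n_test=n_test,
        seeds=[int(s) for s in seeds],
    )


def aggregate_reports(reports) -> EvaluationReport:
    """Merge per-seed single-run reports into one mean +- std report."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")
    stage = reports[0].stage
    rmses = np.array([r.per_label_rmse for r in reports])
    phys = np.array([r.per_label_rmse_physical for r in reports])
    cs = np.array([r.mean_cosine_similarity for r in reports])
    return EvaluationReport(
        stage=stage,
        per_label_rmse=[float(v) for v in rmses.mean(axis=0)],
        per_label_rmse_std=[float(v) for v in rmses.std(axis=0)],
        per_label_rmse_physical=[float(v) for v in phys.mean(axis=0)],
        mean_cosine_similarity=float(cs.mean()),
        std_cosine_similarity=float(cs.std()),
        mean_rmse=float(rmses.mean(axis=0).mean()),
        n_test=sum(r.n_test for r in reports),
        seeds=sorted({s for r in reports for s in r.seeds}),
    )


def render_reconstruction(
    labels_row,
    phantom: Phantom,
    z_slice: float,
    grid_resolution: float = 1.0,
) -> np.ndarray:
    """Rasterize the constant-z slice of a predicted (or true) tumor.

    Returns a 2-D absorption map (mu_a, mm^-1): the background value
    everywhere, the tumor value inside the disk where the sphere intersects
    the slice (radius ``sqrt(r^2 - d^2)`` at distance ``d < r`` from the
    center plane), uniform background if there is no intersection.
    """
    if not 0.0 <= z_slice <= phantom.size_z:
        raise ValueError(f"z_slice {z_slice} outside slab [0, {phantom.size_z}]")
    x0, y0, z0, mu_a_tumor, radius = np.asarray(labels_row, dtype=float)
    nx = max(2, int(round(phantom.size_x / grid_resolution)))
    ny = max(2, int(round(phantom.size_y / grid_resolution)))
    xs = (np.arange(nx) + 0.5) * phantom.size_x / nx
    ys = (np.arange(ny) + 0.5) * phantom.size_y / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    img = np.full((nx, ny), phantom.background.mu_a)
    d = abs(z_slice - z0)
    if d < radius:
        disk_r = np.sqrt(radius**2 - d**2)
        img[(gx - x0) ** 2 + (gy - y0) ** 2 <= disk_r**2] = mu_a_tumor
    return img


def save_render_png(img: np.ndarray, phantom: Phantom, path, title: str = "") -> None:
    """Write a slice render to PNG with a mu_a color bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(
        img.T,
        origin="lower",
        extent=(0, phantom.size_x, 0, phantom.size_y),
        aspect="equal",
    )
    fig.colorbar(im, ax=ax, label=r"$\mu_a$ (mm$^{-1}$)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
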