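"""Labeled training corpus: simulated measurements, features and labels.

Each sample is a random tumor in the phantom; features are the natural log
of the noisy detector readings (one column per source-detector channel) and
labels are the 5-vector (x, y, z, mu_a, radius).  Labels are min-max
normalized to [0, 1] using *physical* bounds (slab extents, the configured
tumor contrast range, the feasible radius range) so normalization is
dataset-independent and exactly invertible.

The corpus is split 50/50 between the boosted-tree stage and the GP stage,
each with a 60/40 train/test partition inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Phantom,
    SourceDetectorLayout,
    TumorSpec,
    sample_tumor,
    max_feasible_radius,
    TUMOR_RADIUS_RANGE_MM,
    DEFAULT_TUMOR_CONTRAST_RANGE,
)
from .forward import (
    MeasurementSet,
    simulate_measurement,
    add_noise,
    ForwardModelError,
)

__all__ = [
    "LABEL_NAMES",
    "LabelNormalizer",
    "LabeledDataset",
    "SPLIT_TAGS",
    "generate_dataset",
    "log_features",
    "normalize_labels",
    "physical_label_bounds",
    "split_dataset",
]

logger = logging.getLogger(__name__)

#: Fixed label order used throughout the package.
LABEL_NAMES = ("x", "y", "z", "mu_a", "radius")

#: The four split tags, in pipeline order.
SPLIT_TAGS = ("xgb-train", "xgb-test", "gp-train", "gp-test")

DEFAULT_MAX_RESAMPLE = 200


class DatasetError(RuntimeError):
    pass


@dataclass(frozen=True)
class LabelNormalizer:
    """Per-label min-max map to [0, 1] with recorded bounds for inversion."""

    bounds: tuple[tuple[float, float], ...]  # ((min, max),) * 5

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
                raise ValueError(f"degenerate normalization bounds ({lo}, {hi})")

    def normalize(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype=float)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return (labels - lo) / (hi - lo)

    def denormalize(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype=float)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return labels * (hi - lo) + lo

    @property
    def spans(self) -> np.ndarray:
        """Physical span of each label (for converting normalized RMSE)."""
        return np.array([hi - lo for lo, hi in self.bounds])


def physical_label_bounds(
    phantom: Phantom,
    contrast_range: tuple[float, float] = DEFAULT_TUMOR_CONTRAST_RANGE,
) -> LabelNormalizer:
    """Deterministic physical bounds: slab extents for x/y/z, the configured
    contrast range for mu_a and the drawn radius range for the radius."""
    mu = phantom.background.mu_a
    return LabelNormalizer(
        bounds=(
            (0.0, phantom.size_x),
            (0.0, phantom.size_y),
            (0.0, phantom.size_z),
            (contrast_range[0] * mu, contrast_range[1] * mu),
            (TUMOR_RADIUS_RANGE_MM[0], max_feasible_radius(phantom)),
        )
    )


def normalize_labels(labels: np.ndarray, normalizer: LabelNormalizer) -> np.ndarray:
    """Min-max map of raw [n, 5] labels to [0, 1] (thin functional wrapper)."""
    return normalizer.normalize(labels)


def log_features(m: MeasurementSet) -> np.ndarray:
    """Natural-log detector readings, the regression features log(d)."""
    if np.any(m.readings <= 0):
        raise ValueError("readings must be positive for the log transform")
    return np.log(m.readings)


@dataclass
class LabeledDataset:
    """Features, raw labels and split assignment for n samples."""

    features: np.ndarray  # [n, n_channels]
    labels: np.ndarray  # [n, 5], physical units
    split: np.ndarray  # [n] of SPLIT_TAGS strings ('' if unsplit)
    seed: int
    normalizer: LabelNormalizer
    noise_level: float = 0.0
    n_rejected: int = 0
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if self.labels.shape != (len(self.features), len(LABEL_NAMES)):
            raise ValueError("labels must be [n, 5]")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    def normalized_labels(self) -> np.ndarray:
        return self.normalizer.normalize(self.labels)

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        """(features, normalized labels) of one split."""
        if tag not in SPLIT_TAGS:
            raise ValueError(f"unknown split tag {tag!r}")
        mask = self.split == tag
        return self.features[mask], self.normalized_labels()[mask]

    # --- persistence -----------------------------------------------------

    def save_hdf5(self, path) -> None:
        import h5py

        # track_times=False keeps files byte-identical across reruns
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features, track_times=False)
            f.create_dataset("labels", data=self.labels, track_times=False)
            f.create_dataset(
                "split",
                data=np.array(self.split, dtype=h5py.string_dtype()),
                track_times=False,
            )
            f.attrs["seed"] = self.seed
            f.attrs["bounds"] = np.array(self.normalizer.bounds)
            f.attrs["noise_level"] = self.noise_level
            f.attrs["n_rejected"] = self.n_rejected
            f.attrs["config_hash"] = self.config_hash

    @classmethod
    def load_hdf5(cls, path) -> "LabeledDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                features=f["features"][...],
                labels=f["labels"][...],
                split=f["split"].asstr()[...],
                seed=int(f.attrs["seed"]),
                normalizer=LabelNormalizer(
                    bounds=tuple(tuple(b) for b in f.attrs["bounds"])
                ),
                noise_level=float(f.attrs["noise_level"]),
                n_rejected=int(f.attrs["n_rejected"]),
                config_hash=str(f.attrs["config_hash"]),
            )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            features=self.features,
            labels=self.labels,
            split=self.split.astype("U"),
            seed=self.seed,
            bounds=np.array(self.normalizer.bounds),
            noise_level=self.noise_level,
            n_rejected=self.n_rejected,
            config_hash=self.config_hash,
        )

    @classmethod
    def load_npz(cls, path) -> "LabeledDataset":
        with np.load(path) as f:
            return cls(
                features=f["features"],
                labels=f["labels"],
                split=f["split"],
                seed=int(f["seed"]),
                normalizer=LabelNormalizer(
                    bounds=tuple(tuple(b) for b in f["bounds"])
                ),
                noise_level=float(f["noise_level"]),
                n_rejected=int(f["n_rejected"]),
                config_hash=str(f["config_hash"]),
            )

    def labels_to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.labels, columns=list(LABEL_NAMES))
        df["split"] = self.split
        df.to_csv(path, index=False)


def generate_dataset(
    phantom: Phantom,
    layout: SourceDetectorLayout,
    n_samples: int,
    noise_level: float = 0.02,
    seed: int = 0,
    contrast_range: tuple[float, float] = DEFAULT_TUMOR_CONTRAST_RANGE,
    max_resample: int = DEFAULT_MAX_RESAMPLE,
) -> LabeledDataset:
    """Simulate ``n_samples`` labeled measurements.

    Each sample draws a fresh tumor; samples whose Born perturbation leaves
    the linear regime (a non-positive predicted reading) are rejected and
    redrawn, with the rejection count logged.  Noise is 2% multiplicative
    Gaussian by default.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    root = np.random.SeedSequence(seed)
    tumor_rng = np.random.default_rng(root.spawn(1)[0])
    noise_seed = int(root.generate_state(1)[0] % (2**31))

    readings = np.empty((n_samples, layout.n_channels))
    labels = np.empty((n_samples, len(LABEL_NAMES)))
    n_rejected = 0
    for i in range(n_samples):
        tumor: TumorSpec | None = None
        for _ in range(max_resample):
            cand = sample_tumor(phantom, tumor_rng, contrast_range)
            try:
                row = simulate_measurement(phantom, cand, layout)
            except ForwardModelError:
                n_rejected += 1
                continue
            tumor = cand
            break
        if tumor is None:
            raise DatasetError(
                f"sample {i}: no physical tumor found in {max_resample} draws"
            )
        readings[i] = row
        labels[i] = (
            tumor.center_x,
            tumor.center_y,
            tumor.center_z,
            tumor.mu_a_tumor,
            tumor.radius,
        )
    if n_rejected:
        logger.info(
            "generate_dataset: resampled %d non-physical tumors for %d samples",
            n_rejected,
            n_samples,
        )

    mset = MeasurementSet(
        readings=readings,
        source_xyz=layout.source_positions,
        detector_xyz=layout.detector_positions,
    )
    mset = add_noise(mset, noise_level, noise_seed)
    features = log_features(mset)
    return LabeledDataset(
        features=features,
        labels=labels,
        split=np.full(n_samples, "", dtype="U16"),
        seed=seed,
        normalizer=physical_label_bounds(phantom, contrast_range),
        noise_level=noise_level,
        n_rejected=n_rejected,
    )


def split_dataset(
    d: LabeledDataset,
    xgb_fraction: float = 0.5,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> LabeledDataset:
    """Seeded random partition into the four pipeline splits.

    Half the corpus feeds the boosted-tree stage and half the GP stage
    (``xgb_fraction``); within each stage ``train_fraction`` goes to
    training and the rest to testing.
    """
    for name, frac in (("xgb_fraction", xgb_fraction), ("train_fraction", train_fraction)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {frac}")
    n = d.n_samples
    perm = np.random.default_rng(seed).permutation(n)
    n_xgb = round(n * xgb_fraction)
    n_xgb_train = round(n_xgb * train_fraction)
    n_gp = n - n_xgb
    n_gp_train = round(n_gp * train_fraction)
    counts = [n_xgb_train, n_xgb - n_xgb_train, n_gp_train, n_gp - n_gp_train]
    if min(counts) < 1:
        raise ValueError(f"n={n} too small to populate all four splits {counts}")
    split = np.empty(n, dtype="U16")
    start = 0
    for tag, c in zip(SPLIT_TAGS, counts):
        split[perm[start : start + c]] = tag
        start += c
    d.split = split
    return d
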