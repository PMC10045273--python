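"""Compressed-breast slab phantom, tumor specification and optode layout.

The imaging geometry is a parallel-plate (transmission) arrangement: a
rectangular slab of turbid tissue of extents ``(size_x, size_y, size_z)`` in
mm, sources on the ``z = 0`` plate and detectors on the ``z = size_z`` plate.
A single spherical absorber (the tumor) sits fully inside the slab.  An
optional smooth multiplicative field on the background absorption emulates
the glandularity structure of a heterogeneous breast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "OpticalProperties",
    "Phantom",
    "TumorSpec",
    "SourceDetectorLayout",
    "make_slab_phantom",
    "sample_tumor",
    "make_layout",
    "DEFAULT_SLAB_SIZE_MM",
    "TUMOR_RADIUS_RANGE_MM",
    "DEFAULT_TUMOR_CONTRAST_RANGE",
]

#: Default slab extents (x, y, z) in mm of the compressed-breast geometry.
DEFAULT_SLAB_SIZE_MM = (220.8, 102.9, 23.7)

#: Tumor radii are drawn from this range (mm), truncated to fit the slab.
TUMOR_RADIUS_RANGE_MM = (2.0, 15.0)

#: Tumor absorption is drawn uniform in this multiple of background mu_a.
DEFAULT_TUMOR_CONTRAST_RANGE = (2.0, 4.0)

# Grid resolution of the heterogeneity field (coarse on purpose: the field
# stands in for smooth glandularity variation, not fine structure).
_HET_GRID_SHAPE = (24, 12, 6)
_HET_SMOOTH_SIGMA = 2.0


class GeometryError(ValueError):
    """Invalid phantom, tumor or layout geometry."""


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.
    refractive_index : float
        Refractive index of the medium (>= 1).
    """

    mu_a: float = 0.005
    mu_s_prime: float = 1.0
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a <= 0:
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValueError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if self.refractive_index < 1:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if self.mu_a / self.mu_s_prime > 0.1:
            warnings.warn(
                "mu_a/mu_s' > 0.1: diffusion approximation may be inaccurate",
                stacklevel=2,
            )


@dataclass
class Phantom:
    """Homogeneous slab with an optional smooth absorption heterogeneity.

    ``heterogeneity_amplitude`` is the maximum fractional modulation of the
    background ``mu_a``; the attached field (seeded, Gaussian-smoothed noise)
    takes values in ``[-amplitude, +amplitude]``.
    """

    size_x: float = DEFAULT_SLAB_SIZE_MM[0]
    size_y: float = DEFAULT_SLAB_SIZE_MM[1]
    size_z: float = DEFAULT_SLAB_SIZE_MM[2]
    background: OpticalProperties = field(default_factory=OpticalProperties)
    heterogeneity_amplitude: float = 0.0
    heterogeneity_seed: int = 0
    _het_field: np.ndarray | None = field(default=None, repr=False, compare=False)
    _het_interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for name in ("size_x", "size_y", "size_z"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0.0 <= self.heterogeneity_amplitude < 0.5):
            raise GeometryError(
                "heterogeneity_amplitude must be in [0, 0.5), got "
                f"{self.heterogeneity_amplitude}"
            )
        if self.heterogeneity_amplitude > 0 and self._het_field is None:
            self._build_heterogeneity()

    def _build_heterogeneity(self) -> None:
        rng = np.random.default_rng(self.heterogeneity_seed)
        raw = rng.standard_normal(_HET_GRID_SHAPE)
        smooth = gaussian_filter(raw, sigma=_HET_SMOOTH_SIGMA, mode="nearest")
        peak = np.max(np.abs(smooth))
        if peak == 0:  # pragma: no cover - degenerate constant field
            field_vals = np.zeros_like(smooth)
        else:
            field_vals = self.heterogeneity_amplitude * smooth / peak
        self._het_field = field_vals
        axes = (
            np.linspace(0.0, self.size_x, _HET_GRID_SHAPE[0]),
            np.linspace(0.0, self.size_y, _HET_GRID_SHAPE[1]),
            np.linspace(0.0, self.size_z, _HET_GRID_SHAPE[2]),
        )
        self._het_interp = RegularGridInterpolator(
            axes, field_vals, bounds_error=False, fill_value=None
        )

    def mu_a_modulation(self, points: np.ndarray) -> np.ndarray:
        """Fractional mu_a modulation at ``points`` [..., 3] (0 if homogeneous)."""
        points = np.asarray(points, dtype=float)
        if self.heterogeneity_amplitude == 0.0 or self._het_interp is None:
            return np.zeros(points.shape[:-1])
        return self._het_interp(points)

    @property
    def extents(self) -> tuple[float, float, float]:
        return (self.size_x, self.size_y, self.size_z)

    def to_dict(self) -> dict:
        return {
            "size_x": self.size_x,
            "size_y": self.size_y,
            "size_z": self.size_z,
            "background": asdict(self.background),
            "heterogeneity_amplitude": self.heterogeneity_amplitude,
            "heterogeneity_seed": self.heterogeneity_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        d = dict(d)
        d["background"] = OpticalProperties(**d["background"])
        return cls(**d)


@dataclass(frozen=True)
class TumorSpec:
    """A spherical absorber fully contained in the slab."""

    center_x: float
    center_y: float
    center_z: float
    radius: float
    mu_a_tumor: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y, self.center_z])

    def validate_inside(self, phantom: Phantom) -> None:
        """Raise :class:`GeometryError` unless the sphere fits in the slab."""
        r = self.radius
        c = (self.center_x, self.center_y, self.center_z)
        for ci, size in zip(c, phantom.extents):
            if ci - r < 0 or ci + r > size:
                raise GeometryError(
                    f"tumor (center {c}, radius {r}) extends outside the slab"
                )
        if self.mu_a_tumor <= phantom.background.mu_a:
            raise GeometryError("tumor mu_a must exceed background mu_a")


@dataclass(frozen=True)
class SourceDetectorLayout:
    """Sources on the z=0 plate, detectors on the z=size_z plate (mm)."""

    source_positions: np.ndarray  # [n_sources, 3]
    detector_positions: np.ndarray  # [n_detectors, 3]

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)

    @property
    def n_channels(self) -> int:
        return self.n_sources * self.n_detectors

    def channel_index(self) -> list[tuple[int, int]]:
        """Channel ordering: source-major, ``channel = s * n_detectors + d``."""
        return [
            (s, d) for s in range(self.n_sources) for d in range(self.n_detectors)
        ]

    def to_dict(self) -> dict:
        return {
            "source_positions": self.source_positions.tolist(),
            "detector_positions": self.detector_positions.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "SourceDetectorLayout":
        return cls(
            source_positions=np.asarray(d["source_positions"], dtype=float),
            detector_positions=np.asarray(d["detector_positions"], dtype=float),
        )


def make_slab_phantom(
    size_x: float = DEFAULT_SLAB_SIZE_MM[0],
    size_y: float = DEFAULT_SLAB_SIZE_MM[1],
    size_z: float = DEFAULT_SLAB_SIZE_MM[2],
    background: OpticalProperties | None = None,
    heterogeneity_amplitude: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Build a slab phantom; seeded smooth mu_a heterogeneity if amplitude > 0."""
    return Phantom(
        size_x=size_x,
        size_y=size_y,
        size_z=size_z,
        background=background or OpticalProperties(),
        heterogeneity_amplitude=heterogeneity_amplitude,
        heterogeneity_seed=seed,
    )


def max_feasible_radius(phantom: Phantom) -> float:
    """Largest sphere radius that fits in the slab, capped at the drawn range."""
    lo, hi = TUMOR_RADIUS_RANGE_MM
    return min(hi, phantom.size_x / 2, phantom.size_y / 2, phantom.size_z / 2)


def sample_tumor(
    phantom: Phantom,
    rng: np.random.Generator | int,
    contrast_range: tuple[float, float] = DEFAULT_TUMOR_CONTRAST_RANGE,
) -> TumorSpec:
    """Draw a random tumor: radius uniform on the feasible range, center
    uniform over the admissible interior, absorption uniform in
    ``contrast_range`` times the background mu_a.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo = TUMOR_RADIUS_RANGE_MM[0]
    hi = max_feasible_radius(phantom)
    if hi <= lo:
        raise GeometryError(
            f"slab too thin to contain a radius-{lo} mm sphere "
            f"(feasible max {hi:.2f} mm)"
        )
    radius = rng.uniform(lo, hi)
    center = np.array(
        [rng.uniform(radius, size - radius) for size in phantom.extents]
    )
    contrast = rng.uniform(*contrast_range)
    return TumorSpec(
        center_x=center[0],
        center_y=center[1],
        center_z=center[2],
        radius=radius,
        mu_a_tumor=contrast * phantom.background.mu_a,
    )


def _grid_factors(n: int) -> tuple[int, int]:
    """Factor n into the most nearly square (cols, rows) pair, cols >= rows."""
    best = None
    for rows in range(1, int(np.sqrt(n)) + 1):
        if n % rows == 0:
            best = (n // rows, rows)
    if best is None:  # pragma: no cover - every n >= 1 has rows=1
        raise GeometryError(f"cannot factor {n} into a grid")
    return best


def _face_grid(n: int, size_x: float, size_y: float, z: float, margin: float) -> np.ndarray:
    cols, rows = _grid_factors(n)
    if 2 * margin >= size_x or 2 * margin >= size_y:
        raise GeometryError(
            f"margin {margin} mm leaves no room on a {size_x}x{size_y} mm face"
        )
    # Longer face dimension carries more optodes.
    if size_x >= size_y:
        nx, ny = cols, rows
    else:
        nx, ny = rows, cols
    xs = np.linspace(margin, size_x - margin, nx) if nx > 1 else np.array([size_x / 2])
    ys = np.linspace(margin, size_y - margin, ny) if ny > 1 else np.array([size_y / 2])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    return pts


def make_layout(
    phantom: Phantom,
    n_sources: int = 48,
    n_detectors: int = 54,
    margin: float = 10.0,
) -> SourceDetectorLayout:
    """Regular optode grids: ``n_sources`` on z=0, ``n_detectors`` on z=size_z.

    Defaults give the 48 x 54 transmission arrangement (8x6 source grid,
    9x6 detector grid, 2592 channels).
    """
    if n_sources < 1 or n_detectors < 1:
        raise GeometryError("need at least one source and one detector")
    sources = _face_grid(n_sources, phantom.size_x, phantom.size_y, 0.0, margin)
    detectors = _face_grid(
        n_detectors, phantom.size_x, phantom.size_y, phantom.size_z, margin
    )
    return SourceDetectorLayout(source_positions=sources, detector_positions=detectors)
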