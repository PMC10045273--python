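"""Continuous-wave diffusion forward model for the parallel-plate slab.

Photon transport in the highly scattering breast is modeled with the
diffusion approximation.  The CW fluence due to an isotropic point source in
an infinite medium is the closed form

    phi(r) = exp(-mu_eff * r) / (4 * pi * D * r),

with diffusion coefficient ``D = 1/(3 (mu_a + mu_s'))`` and effective
attenuation ``mu_eff = sqrt(mu_a / D)``.  The slab solution is built from
mirror-image sources across the two extrapolated boundaries at ``z = -z_b``
and ``z = L + z_b`` (extrapolation length ``z_b = 2 A D``, with the
internal-reflection parameter ``A`` from the refractive-index mismatch).
A spherical absorber perturbs each source-detector channel through a
first-order Born term, and measurement error is multiplicative Gaussian
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Phantom, TumorSpec, SourceDetectorLayout, OpticalProperties

__all__ = [
    "DiffusionParams",
    "MeasurementSet",
    "ForwardModelError",
    "boundary_reflection_parameter",
    "diffusion_params",
    "infinite_medium_fluence",
    "slab_fluence",
    "born_perturbation",
    "simulate_measurement",
    "add_noise",
]

#: Default number of mirror-image source pairs in the slab Green's function.
DEFAULT_IMAGE_PAIRS = 7

#: Default number of quadrature nodes inside the tumor sphere.
DEFAULT_QUADRATURE_NODES = 500

#: Seed of the fixed quadrature point set (the forward model is deterministic).
QUADRATURE_SEED = 20230321

#: Number of sample points along the source-detector chord for the
#: heterogeneity attenuation correction.
CHORD_SAMPLES = 16


class ForwardModelError(RuntimeError):
    """Forward simulation produced a non-physical result."""


def boundary_reflection_parameter(n: float) -> float:
    """Internal-reflection parameter A(n) for the extrapolated boundary.

    Polynomial fit to the angle-integrated Fresnel reflection for a
    tissue-air refractive-index mismatch; A(1) = 1 (matched boundary),
    A(1.4) ~ 2.95.
    """
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    if n == 1.0:
        return 1.0
    return (
        504.332889
        - 2641.00214 * n
        + 5923.699064 * n**2
        - 7376.355093 * n**3
        + 5507.53041 * n**4
        - 2463.357945 * n**5
        + 610.956547 * n**6
        - 64.8047 * n**7
    )


@dataclass(frozen=True)
class DiffusionParams:
    """Derived diffusion quantities of a medium (all lengths in mm)."""

    D: float  # diffusion coefficient, mm
    mu_eff: float  # effective attenuation, mm^-1
    z_b: float  # extrapolated boundary distance, mm
    z_0: float  # isotropic source embedding depth (one transport mfp), mm


def diffusion_params(optics: OpticalProperties) -> DiffusionParams:
    D = 1.0 / (3.0 * (optics.mu_a + optics.mu_s_prime))
    mu_eff = np.sqrt(optics.mu_a / D)
    A = boundary_reflection_parameter(optics.refractive_index)
    return DiffusionParams(D=D, mu_eff=mu_eff, z_b=2.0 * A * D, z_0=1.0 / optics.mu_s_prime)


def infinite_medium_fluence(optics: OpticalProperties, r) -> np.ndarray | float:
    """CW fluence at distance ``r`` (mm) from a unit point source, mm^-2."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("source-field distance must be positive")
    p = diffusion_params(optics)
    out = np.exp(-p.mu_eff * r) / (4.0 * np.pi * p.D * r)
    return out if out.ndim else float(out)


def _image_z_positions(z_src: np.ndarray, thickness: float, z_b: float, n_pairs: int):
    """Yield (z_positive_image, z_negative_image) per mirror order m."""
    period = 2.0 * (thickness + 2.0 * z_b)
    for m in range(-n_pairs, n_pairs + 1):
        z_plus = m * period + z_src
        z_minus = m * period - z_src - 2.0 * z_b
        yield z_plus, z_minus


def slab_fluence(
    optics: OpticalProperties,
    slab_thickness: float,
    source_point,
    field_point,
    n_image_pairs: int = DEFAULT_IMAGE_PAIRS,
    convergence_tol: float = 1e-6,
    check_convergence: bool = False,
) -> np.ndarray | float:
    """Slab Green's function between point sets via mirror-image sources.

    ``source_point`` [N, 3] and ``field_point`` [M, 3] (or single points)
    must lie inside the slab ``0 <= z <= slab_thickness``.  Returns the
    [N, M] fluence matrix (scalar for single points).  The image expansion
    is truncated after ``n_image_pairs`` mirror orders on each side; with
    ``check_convergence`` a warning is emitted if the outermost order still
    contributes more than ``convergence_tol`` of the running sum.
    """
    src = np.atleast_2d(np.asarray(source_point, dtype=float))
    fld = np.atleast_2d(np.asarray(field_point, dtype=float))
    scalar = src.shape[0] == 1 and fld.shape[0] == 1 and np.ndim(source_point) == 1

    p = diffusion_params(optics)
    dx = src[:, 0][:, None] - fld[:, 0][None, :]
    dy = src[:, 1][:, None] - fld[:, 1][None, :]
    rho2 = dx**2 + dy**2
    zf = fld[:, 2][None, :]

    total = np.zeros_like(rho2)
    last = np.zeros_like(rho2)
    for z_plus, z_minus in _image_z_positions(
        src[:, 2], slab_thickness, p.z_b, n_image_pairs
    ):
        r_plus = np.sqrt(rho2 + (z_plus[:, None] - zf) ** 2)
        r_minus = np.sqrt(rho2 + (z_minus[:, None] - zf) ** 2)
        r_plus = np.maximum(r_plus, 1e-9)
        r_minus = np.maximum(r_minus, 1e-9)
        term = (
            np.exp(-p.mu_eff * r_plus) / r_plus
            - np.exp(-p.mu_eff * r_minus) / r_minus
        )
        total += term
        last = term
    total /= 4.0 * np.pi * p.D

    if check_convergence:
        rel = np.max(np.abs(last) / (4.0 * np.pi * p.D * np.maximum(np.abs(total), 1e-300)))
        if rel > convergence_tol:
            warnings.warn(
                f"image-source expansion not converged: outermost order "
                f"contributes {rel:.2e} of the sum",
                stacklevel=2,
            )
    return float(total[0, 0]) if scalar else total


def _sphere_quadrature(tumor: TumorSpec, n_nodes: int, seed: int) -> tuple[np.ndarray, float]:
    """Fixed seeded uniform nodes inside the sphere and the per-node volume."""
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    # Rejection sampling from the bounding cube; deterministic given the seed.
    while len(pts) < n_nodes:
        cand = rng.uniform(-1.0, 1.0, size=(2 * n_nodes, 3))
        cand = cand[np.sum(cand**2, axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    pts = pts[:n_nodes] * tumor.radius + tumor.center
    volume = 4.0 / 3.0 * np.pi * tumor.radius**3
    return pts, volume / n_nodes


def born_perturbation(
    optics: OpticalProperties,
    tumor: TumorSpec,
    source_point,
    detector_point,
    slab_thickness: float,
    n_image_pairs: int = DEFAULT_IMAGE_PAIRS,
    n_quadrature: int = DEFAULT_QUADRATURE_NODES,
    quadrature_seed: int = QUADRATURE_SEED,
) -> np.ndarray | float:
    """First-order Born fractional intensity change of each channel.

    Returns ``delta_phi / phi_0`` per (source, detector) pair:

        -delta_mu_a * sum_q w_q G(s, r_q) G(r_q, d) / G(s, d),

    with the sphere integral evaluated on a fixed seeded uniform node set.
    Non-positive for an absorber (``delta_mu_a >= 0``).
    """
    if tumor.center_z - tumor.radius < 0 or tumor.center_z + tumor.radius > slab_thickness:
        raise ForwardModelError("tumor overlaps a slab face")
    src = np.atleast_2d(np.asarray(source_point, dtype=float))
    det = np.atleast_2d(np.asarray(detector_point, dtype=float))
    scalar = np.ndim(source_point) == 1 and np.ndim(detector_point) == 1

    delta_mu_a = tumor.mu_a_tumor - optics.mu_a
    if delta_mu_a == 0:
        out = np.zeros((len(src), len(det)))
        return float(out[0, 0]) if scalar else out

    nodes, w = _sphere_quadrature(tumor, n_quadrature, quadrature_seed)
    g_sq = slab_fluence(optics, slab_thickness, src, nodes, n_image_pairs)  # [S,K]
    g_qd = slab_fluence(optics, slab_thickness, nodes, det, n_image_pairs)  # [K,D]
    g_sd = slab_fluence(optics, slab_thickness, src, det, n_image_pairs)  # [S,D]
    pert = -(delta_mu_a * w) * (g_sq @ g_qd) / g_sd
    return float(pert[0, 0]) if scalar else pert


def _heterogeneity_factor(
    phantom: Phantom, layout: SourceDetectorLayout
) -> np.ndarray:
    """Per-channel attenuation factor from the smooth mu_a heterogeneity.

    The fractional mu_a modulation is averaged along each source-detector
    chord and applied as an extra Beer-Lambert attenuation over the chord
    length (a Rytov-style correction adequate for small amplitudes).
    """
    if phantom.heterogeneity_amplitude == 0.0:
        return np.ones((layout.n_sources, layout.n_detectors))
    src = layout.source_positions[:, None, None, :]  # [S,1,1,3]
    det = layout.detector_positions[None, :, None, :]  # [1,D,1,3]
    t = np.linspace(0.0, 1.0, CHORD_SAMPLES)[None, None, :, None]
    pts = src + (det - src) * t  # [S,D,T,3]
    mod = phantom.mu_a_modulation(pts)  # [S,D,T]
    mean_mod = mod.mean(axis=-1)
    chord = np.linalg.norm(
        layout.detector_positions[None, :, :] - layout.source_positions[:, None, :],
        axis=-1,
    )
    return np.exp(-phantom.background.mu_a * mean_mod * chord)


def simulate_measurement(
    phantom: Phantom,
    tumor: TumorSpec | None,
    layout: SourceDetectorLayout,
    n_image_pairs: int = DEFAULT_IMAGE_PAIRS,
    n_quadrature: int = DEFAULT_QUADRATURE_NODES,
) -> np.ndarray:
    """Noiseless detector readings for one sample, flattened source-major.

    Per channel: background slab fluence times ``(1 + born)`` times the
    heterogeneity attenuation factor.  Raises :class:`ForwardModelError` if
    any channel would go non-positive (perturbation outside the linear
    regime); callers reject and resample such tumors.
    """
    optics = phantom.background
    p = diffusion_params(optics)
    src = layout.source_positions.copy()
    src[:, 2] = p.z_0  # isotropic source one transport mfp below the plate
    det = layout.detector_positions

    g0 = slab_fluence(optics, phantom.size_z, src, det, n_image_pairs)
    if tumor is not None:
        tumor.validate_inside(phantom)
        pert = born_perturbation(
            optics, tumor, src, det, phantom.size_z, n_image_pairs, n_quadrature
        )
    else:
        pert = 0.0
    readings = g0 * (1.0 + pert) * _heterogeneity_factor(phantom, layout)
    if np.any(readings <= 0):
        raise ForwardModelError(
            "non-positive reading: Born perturbation too large for linearization"
        )
    return readings.ravel()


@dataclass
class MeasurementSet:
    """Detector readings for a batch of samples.

    ``readings`` is [n_samples, n_channels] in source-major channel order
    (``channel = source_id * n_detectors + detector_id``); all values are
    positive CW intensities in arbitrary units.
    """

    readings: np.ndarray
    source_xyz: np.ndarray
    detector_xyz: np.ndarray
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        self.readings = np.atleast_2d(np.asarray(self.readings, dtype=float))
        expected = len(self.source_xyz) * len(self.detector_xyz)
        if self.readings.shape[1] != expected:
            raise ValueError(
                f"readings have {self.readings.shape[1]} channels, layout "
                f"implies {expected}"
            )

    @property
    def n_samples(self) -> int:
        return self.readings.shape[0]

    @property
    def n_channels(self) -> int:
        return self.readings.shape[1]

    def channel_index(self) -> list[tuple[int, int]]:
        nd = len(self.detector_xyz)
        return [(c // nd, c % nd) for c in range(self.n_channels)]

    def save_npz(self, path) -> None:
        np.savez(
            path,
            readings=self.readings,
            source_xyz=self.source_xyz,
            detector_xyz=self.detector_xyz,
            noise_level=self.noise_level,
        )

    @classmethod
    def load_npz(cls, path) -> "MeasurementSet":
        with np.load(path) as f:
            return cls(
                readings=f["readings"],
                source_xyz=f["source_xyz"],
                detector_xyz=f["detector_xyz"],
                noise_level=float(f["noise_level"]),
            )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("readings", data=self.readings, track_times=False)
            f.create_dataset("source_xyz", data=self.source_xyz, track_times=False)
            f.create_dataset("detector_xyz", data=self.detector_xyz, track_times=False)
            f.attrs["noise_level"] = self.noise_level

    @classmethod
    def load_hdf5(cls, path) -> "MeasurementSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                readings=f["readings"][...],
                source_xyz=f["source_xyz"][...],
                detector_xyz=f["detector_xyz"][...],
                noise_level=float(f.attrs["noise_level"]),
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = [f"s{s}_d{d}" for s, d in self.channel_index()]
        pd.DataFrame(self.readings, columns=cols).to_csv(path, index=False)


def add_noise(m: MeasurementSet, level: float, seed: int) -> MeasurementSet:
    """Multiplicative Gaussian measurement noise: reading * (1 + eps),
    eps ~ N(0, level); readings floored to stay positive."""
    if level < 0:
        raise ValueError(f"noise level must be >= 0, got {level}")
    if level == 0:
        return MeasurementSet(
            readings=m.readings.copy(),
            source_xyz=m.source_xyz,
            detector_xyz=m.detector_xyz,
            noise_level=0.0,
        )
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, level, size=m.readings.shape)
    noisy = m.readings * (1.0 + eps)
    noisy = np.maximum(noisy, m.readings * 1e-6)
    return MeasurementSet(
        readings=noisy,
        source_xyz=m.source_xyz,
        detector_xyz=m.detector_xyz,
        noise_level=level,
    )
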