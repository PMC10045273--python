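# Methods

`dotslab` is a desk-scale, fully synthetic test bed for a two-stage machine
learning solver of the continuous-wave diffuse optical tomography (CW-DOT)
inverse problem in a compressed-breast slab. Everything here — the forward
physics, the dataset, the two inverse stages, and the metrics — is computed
by the package itself; no external data are used.

## The imaging model

The tissue is a rectangular slab of extents 220.8 x 102.9 x 23.7 mm
(x, y, z), imaged in transmission between two parallel plates: 48 sources
in an 8 x 6 grid on the z = 0 face and 54 detectors in a 9 x 6 grid on the
z = 23.7 mm face (2592 channels, source-major order). One spherical
absorber (the "tumor") of radius r and absorption mu_a_tumor sits fully
inside the slab. The measurement is the CW intensity at each detector.

Photon transport is treated in the diffusion approximation. For background
optics (mu_a, mu_s', n) the diffusion coefficient is
`D = 1/(3 (mu_a + mu_s'))` (mm), the effective attenuation
`mu_eff = sqrt(mu_a / D)` (mm^-1), and the infinite-medium CW Green's
function is

    phi(r) = exp(-mu_eff r) / (4 pi D r).

The slab solution uses extrapolated-boundary image sources: fluence is
forced to zero on virtual planes at z = -z_b and z = L + z_b with
`z_b = 2 A D`, where A(n) is the internal-reflection parameter from a
standard polynomial fit (A = 1 at matched boundaries, A = 2.95 at n = 1.4).
The physical source is embedded one transport mean free path (1/mu_s')
below the source plate, and the image expansion is truncated at 7 mirror
orders per side — for this slab the outermost order contributes < 1e-6 of
the sum (checked by a 7-vs-15-order comparison in the tests). The image
construction is term-by-term symmetric, so source-detector reciprocity
holds to machine precision.

The tumor perturbs each channel through a first-order Born term,

    delta_phi / phi0 = -delta_mu_a * sum_q w_q G(s, r_q) G(r_q, d) / G(s, d),

with `delta_mu_a = mu_a_tumor - mu_a` and the sphere integral evaluated on
a fixed, seeded set of 500 uniform nodes (1% quadrature accuracy at desk
cost, verified against a 10x refinement). The per-channel reading is

    reading = G_slab(s, d) * (1 + born) * heterogeneity_factor.

Samples whose largest perturbation would drive a reading non-positive are
outside the linear regime of the Born approximation; they are rejected and
redrawn, with the count logged (roughly 15-20% of draws at the default
contrast range, almost all of them large-radius tumors).

Background heterogeneity — standing in for the glandularity structure of a
real breast — is a seeded Gaussian-smoothed random field multiplying the
background mu_a, with fractional amplitude 0.1 by default. It enters the
measurement as an extra Beer-Lambert attenuation using the field averaged
along each source-detector chord, a Rytov-style correction adequate at
this amplitude.

## Default parameters

| parameter | default | why |
|---|---|---|
| mu_a background | 0.005 mm^-1 | typical breast tissue near 800 nm |
| mu_s' background | 1.0 mm^-1 | typical breast tissue near 800 nm |
| refractive index | 1.4 | soft tissue |
| tumor radius | uniform [2, 11.85] mm | drawn from the nominal 2-15 mm range truncated to the largest sphere the 23.7 mm slab can contain (see below) |
| tumor mu_a | uniform [2x, 4x] background | elevated blood absorption |
| noise | 2% multiplicative Gaussian | proportional measurement error |
| samples | 1000 (desk) / 5000 (paper preset) | see scale presets |

The radius is drawn uniform on the feasible interval rather than drawn on
[2, 15] and clipped: clipping would place a point mass at 11.85 mm and the
empirical distribution is intended (and tested) to be uniform.

## Features, labels and splits

Features are the natural log of the noisy readings (one column per
channel). Labels are the 5-vector (x, y, z, mu_a, radius), min-max
normalized to [0, 1] using *physical* bounds — slab extents, the
configured contrast range, the feasible radius range — never data-derived
bounds, so normalization is deterministic and exactly invertible. All
errors are reported on this normalized scale (and also rescaled to
mm / mm^-1).

The corpus is split 50/50 between the two inverse stages, each half split
60/40 into train and test, by a seeded permutation (n = 1000 gives
300/200/300/200).

## Stage one: per-label gradient-boosted trees

One XGBoost regressor per label maps log-features to the normalized label
(squared-error objective). Hyperparameters (unstated upstream, exposed in
the config): 500 trees, depth 6, learning rate 0.05, row subsample 0.8,
64 histogram bins. 64 bins (rather than the library's 256) is a numerical
economy: the log-amplitude features are smooth, and it cuts
single-threaded fit time ~4x with no measurable accuracy change. Training
is forced single-threaded with fixed random state, so identical inputs
give bit-identical models. Predictions are clipped to [0, 1] since all
labels are physically bounded.

## Stage two: genetic-programming correction

Independently per label, a Koza-style tree GP evolves an R -> R program
that corrects the stage-one prediction. Function set: add, subtract,
multiply, protected divide (returns 1 when |denominator| < 1e-6 —
unprotected division destroys runs), unary negate. Terminals: the input
coordinate and integer ephemeral random constants in [-5, 5]. Depth is
bounded to [2, 6] at creation (ramped half-and-half) and re-enforced after
every crossover and mutation by reject-and-retry (bounded retries, then
the parents are returned as clones).

Fitness is the RMSE of the corrected predictions against the truths on a
random 10% subsample of the gp-train split, redrawn each generation
(shared by the whole generation for comparability; a fixed-subsample mode
is a config flag). Non-finite program output maps to a +inf sentinel.
Selection is tournament of size 4; each offspring event applies exactly
one of reproduction (p = 0.35), subtree crossover (p = 0.5) or mutation
(p = 0.15, including ERC perturbation) — the probabilities sum to 1, so an
exclusive-choice scheme is the natural reading. The generation best is
carried over unchanged (elitism), which makes the running-best fitness
history non-increasing by construction.

Each label runs several independent evolutions. The output program is the
across-run best judged by RMSE on the full training split, with the
identity-equivalent individual `add(x, 0)` — seeded into every initial
population — always among the candidates. Consequence: the correction can
never be worse than no correction on training data (test-split behavior is
checked separately and allowed 0.005 slack).

Scale presets: `desk` (population 500, 30 generations, 3 runs — seconds
per label) and `paper` (population 10,000, 100 generations, 30 runs —
hours of CPU). All headline numbers in this repository use the desk
preset.

## Metrics

* RMSE per label, `sqrt(mean((Y - X)^2))`, on the normalized scale.
* Cosine similarity between the predicted and true normalized 5-vectors,
  computed per test sample and averaged. The averaging axis is a
  documented convention of this package (per-sample vectors, then mean);
  spreads are across repeated full-pipeline seeds (default 3).

`render_reconstruction` rasterizes a constant-z slice: background mu_a
everywhere, the predicted mu_a inside the disk of radius
`sqrt(r^2 - d^2)` where the predicted sphere (distance d from the slice)
intersects the plane.

## What the generator does and does not emulate

It emulates: the transmission slab geometry and optode counts, a single
spherical absorber with the stated radius range, proportional 2% noise,
log-amplitude features, smooth background heterogeneity, and the exact
two-stage inverse pipeline and metrics.

It does not emulate: finite-element transport in a realistic anatomical
mesh, skin/chest-wall layers, nonlinear (beyond-Born) contrast, or
scattering perturbations. Two consequences show up in the numbers and are
worth understanding:

* **Radius is easier here.** The Born signal scales with the sphere
  volume, so radius dominates the measurement and is recovered better
  than in a full anatomical simulation.
* **Tumor mu_a is nearly unidentifiable here.** The same linearity means
  the signal amplitude is proportional to `delta_mu_a * volume`;
  delta_mu_a varies only 3x across the contrast range while volume varies
  ~200x across the radius range, so mu_a is confounded with radius almost
  everywhere. Stage-one mu_a error sits near the predict-the-mean level
  (1/sqrt(12) ~ 0.289 normalized), and a univariate correction of a
  near-constant prediction cannot add information. Passing pipeline tests
  therefore demonstrate localization and sizing, not absorption
  quantification.

## Numerical choices and degenerate inputs

* Image-sum distances are floored at 1e-9 mm to avoid the coincident-point
  singularity; `infinite_medium_fluence` rejects r = 0 outright.
* Noisy readings are floored at 1e-6 of their noiseless value (a 2% noise
  draw essentially never reaches the floor; it only guards the log).
* Tournament ties break to the first-drawn individual; best-of-run ties
  break to the lowest run index.
* Slabs thinner than 4 mm cannot contain the smallest tumor and are
  rejected; degenerate normalization bounds (max <= min) are rejected.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; reports are serialized with sorted keys and no
  timestamps, so a rerun with the same config is byte-identical.

## Known limitations

Single tumor per sample; CW amplitude only (no phase or time-of-flight);
absorption-only perturbation; the heterogeneity field perturbs chords, not
the Born kernel itself; desk-scale GP budgets are far below the
paper-preset budgets, so evolved programs are usually simple near-affine
corrections.
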