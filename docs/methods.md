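# Methods

This note documents the models and numerical choices behind veinforge: an
unsupervised retinal-vessel segmentation pipeline built around an ensemble
of speckle-adapted BM3D (S-BM3D) despeckling filters.

## Noise model

Fundus photographs carry multiplicative speckle from coherent scattering of
the illuminating light, plus a smaller additive sensor component.  We model
the observed amplitude as `z(k) = x(k) u(k)` where `x` is the clean
intensity and `u` is unit-mean amplitude speckle: `u^2 ~ Gamma(L, 1/L)`
rescaled by its mean `Gamma(L+1/2) / (Gamma(L) sqrt(L))` so `E[u] = 1`
exactly.  `L` is the number of looks; speckle variance
`Var[u] = L Gamma(L)^2 / Gamma(L+1/2)^2 - 1` falls roughly as `1/(4L)`.
`L = inf` is accepted and means "no speckle" — used to test the shrinkage
identities.  An optional additive Gaussian term (`additive_sigma`, default
0) is exposed but defaults off because no magnitude is established for
fundus hardware.

## Synthetic phantom

The phantom generator draws a branching vessel tree on a flat background
(level 0.4) inside a centered circular FOV (radius fraction 0.94 of the
half-side): two quadratic-Bezier arcades (cross-section sigma 2.6 px,
centerline amplitude ~0.42), three straight medium branches per arcade
(sigma 1.7, amplitude ~0.33) each with a thin twig (sigma 1.0, amplitude
~0.26).  Cross-sections are Gaussian; overlapping vessels combine by
per-pixel maximum.  Ground truth is the set of pixels within 2 sigma of any
centerline (≈95% of the profile mass), intersected with the FOV.
Dark-vessel phantoms are the inversion `1 - clean`, matching real fundus
polarity.  Geometry is drawn deterministically from the seed.

What the phantom does *not* emulate: optic disc, macula, exudates,
hemorrhages, illumination gradients, camera optics, or the inter-image
variability of real datasets.  Passing phantom-based tests therefore
demonstrates correctness of every stage and of their interaction under the
stated noise model — not clinical-grade accuracy on DRIVE/STARE/CHASE,
which requires those datasets (supported as user-supplied inputs through
the same CLI).

## S-BM3D

Amplitude-domain processing throughout; amplitudes are clamped at 1e-6
before any log or ratio.

**Block matching.** Patch similarity is the probabilistic distance

    D = sum_k [ (2L-1) log(a_s(k)/a_t(k) + a_t(k)/a_s(k))
              + gamma (x_s(k)-x_t(k))^2 / (x_s(k) x_t(k)) ]

whose first term is the speckle likelihood-ratio distance between amplitude
patches and whose second term compares clean-prior patches (`gamma = 4` by
default; active only in the second pass, because no prior exists before
stage 1).  For each reference patch (stride 3, last row/column always
included) every candidate in a centered search window is scanned at stride
1 and the `max_group = 16` smallest distances kept, reference first, stable
under ties in scan order.  The scan is a numba-compiled loop; a pure-NumPy
`patch_distance` is the reference implementation and the tests compare the
compiled path against an exhaustive scan built on it.

**Collaborative shrinkage.** Each group is transformed by an orthonormal
Haar matrix along the stacking axis (groups are truncated to the largest
power of two) and a stationary (undecimated) `db8` wavelet over the two
spatial axes, 2 levels, periodic extension.  Stage 1 applies an LLMMSE
shrink per coefficient, `x = mu + sx^2/(sx^2+sn^2) (y - mu)`, with `mu` and
the total variance estimated per (Haar plane, spatial subband) inside the
group, and `sn^2` predicted from `L`: pixel noise variance
`Var[u] mean(z^2) / (1+Var[u])` times an exact per-subband white-noise gain
computed once from the transform's impulse responses.  Stage 2 re-groups
with the full distance and applies the empirical Wiener filter
`X = X'^2/(X'^2 + <V^2>) Z` with the stage-1 coefficients `X'` as prior and
`<V^2>` the mean squared prior-vs-noisy coefficient difference per (group,
subband); `0/0` passes 0.

**Aggregation.** Overlapping per-group estimates are combined as a
normalized weighted mean with per-group weight `w = 1/(1 + r)` where `r` is
the group's mean squared change; this preserves constants exactly (a
constant image is a fixed point of the whole filter to 1e-6) and reduces to
uniform averaging when residuals are equal.  The image is symmetric-padded
by half the search window beforehand so every pixel is covered.

## Ensemble (ES-BM3D)

Patch-based filters leave periodic block-grid artifacts locked to their
block geometry.  The ensemble runs S-BM3D under the four parameterizations
block_size ∈ {8, 12} × search_window ∈ {24, 39} and averages the outputs
pixelwise with uniform weights (median optional).  Members with smaller
blocks carry finer detail and finer-grained artifacts, larger blocks the
reverse; their artifact patterns sit at different spatial frequencies and
cancel in the mean while the vessels, common to all members, survive.
Blocks below ~6 px are deliberately excluded from the default grid: at the
speckle levels this filter targets, a 16-pixel likelihood distance is too
noisy for reliable grouping, those members denoise measurably worse, and a
uniform average would inherit their error.
`checkerboard_energy` quantifies the artifact level as the fraction of AC
spectral power in bands of half-width `1/(4 period)` around frequencies
`1/period` and `2/period` along both axes (period defaults to the largest
member block size).

## Detectors

Both detectors assume bright ridges; the preprocessing inverts the green
channel for dark-vessel (real fundus) inputs.

**Hessian.** Gaussian-derivative second derivatives at scale `s`,
gamma-normalized by `s^2`.  The sampled, truncated kernels do not sum to
exactly zero, so each derivative response is corrected by subtracting
(kernel sum) × (Gaussian-smoothed image); a constant image then yields an
exactly zero Hessian.  Eigenvalues are closed-form for the 2×2 symmetric
matrix and ordered `|l1| <= |l2|`.

**Ratio-based ("improved") Frangi.** With `lam = -l2` (positive on bright
ridges) and the per-scale regularization
`lam_rho = lam if lam > tau * max(lam over FOV) else tau * max`, the
response is 0 for `lam <= 0`, 1 for `lam >= lam_rho/2`, else
`lam^2 (lam_rho - lam) (3/(lam + lam_rho))^3`; maximum over scales.  The
response depends on eigenvalue *ratios*, not magnitudes, so low-contrast
thin vessels are retained.  Defaults: scales {3, 4, 5, 6} px, `tau = 0.9`.
A cross-seed phantom study fixed these: scales at or below ~1.5 px amplify
residual post-CLAHE speckle texture (curvature noise at those scales is
comparable to thin-vessel curvature), and `tau` in the upper half of the
recommended [0.5, 1] range compresses weak background responses enough for
the downstream global threshold to separate the classes.

**Multiscale line detector.** Oriented second-derivative-of-anisotropic-
Gaussian kernels `g_uu` with width `sigma_v ∈ {4, 5}` px, elongation
`sigma_u = ratio * sigma_v`, ratio ∈ {0.5, 1, …, 3.5}, sampled on ±4 max
sigma and mean-subtracted to exact zero sum; 12 orientations (15° steps,
enough to resolve the thinnest phantom bars).  Responses are negated,
scale-normalized by `sigma_u^1 sigma_v^0.5`, maximized over the 168-kernel
grid, clipped at zero, normalized by the maximum, and finally compressed as
`v^0.5` (`response_gamma = 0.5`).  The compression is this package's
normalization convention: the raw response spans a wide dynamic range
(thick cores near 1, thin vessels near 0.1), which pushes a global
bimodal threshold above the thin-vessel responses; the square root
equalizes calibers before thresholding.  The image is reflect-padded by the
largest kernel radius before convolution so borders do not respond as
ridges.

## Pre/post-processing

**CLAHE** (8×8 tiles, clip limit 2.0 on 256 bins) is implemented with
FOV-masked tile histograms — the black border otherwise dominates rim
tiles — and bilinear interpolation between tile mappings; a constant image
is returned unchanged.  Outside-FOV pixels are first filled with the
inside median so the rim does not leak ridge responses.

**Anisotropic diffusion** (Perona–Malik, 10 iterations, kappa 0.1,
dt 0.2, exponential conduction) is applied to the vesselness map, between
detection and thresholding: it evens the response along a vessel while the
edge-stopping conduction preserves the vessel/background transition.  The
flux-form 4-neighbor update with reflective boundaries conserves the global
mean; dt ≤ 0.25 is enforced for stability.

**ISODATA threshold.** 256-bin histogram over the masked value range;
initialized at the Otsu level (shifted half a bin so the Otsu bin falls in
the lower class under the strict `< T` split); iterate `T = (mu0+mu1)/2`
until the move is below half a bin or 100 iterations.  Ties at `T` are
assigned to the vessel class.  Binarization restricts to the FOV; no
small-component removal by default (a `min_component` option exists).

## Evaluation

Confusion counts, Se = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total are
computed strictly over FOV pixels; any nonzero truth pixel counts as
vessel.  AUC is the trapezoidal ROC area of the continuous vesselness map
(tie-aware, via the Mann–Whitney identity).  Dice is used for
phantom-based checks.

## Problem sizes and determinism

Phantom studies run at 256×256 with the 4-member ensemble; unit tests use
32–128 px images and reduced member grids.  The entire pipeline is
deterministic: the only random draws are the phantom's seeded geometry and
noise, and repeated runs are bit-identical.

## Known limitations

- The denoiser's `L` must be supplied; real fundus hardware does not
  advertise one.  The default (4) was calibrated on phantoms; CLAHE applied
  before denoising additionally perturbs the speckle statistics the
  distance assumes, which the ensemble tolerates but a principled
  post-CLAHE noise model would improve.
- No exact numerical equivalence with released SAR-BM3D binaries is
  attempted (different wavelet, grouping and weighting conventions).
- Thresholding is global; vessels fainter than the ISODATA split are lost
  (no hysteresis by design).
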