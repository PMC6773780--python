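# Methods

This note documents the models, parameter choices and numerical
conventions behind holocyte, in the order the data flows.

## Phantom model

**Shape.** A discocyte is the radially symmetric thickness profile
t(ρ) = √(1−ρ²)·(c₀ + c₂ρ² + c₄ρ⁴) on the normalized radius ρ ∈ [0, 1],
clipped below at zero. The defaults c₀ = 0.81, c₂ = 7.83, c₄ = −4.39 µm
are the literature-standard biconcave parameterization. The optical path
difference is OPD = (n_cell − n_medium)·t with n_cell = 1.40,
n_medium = 1.34: the refractive contrast is chosen so that a cell of
PSA ≈ 50–60 µm² carries a mean OPD of order 100 nm and a dry mass of
≈ 30 pg, the physiological regime. Because the profile is analytic, PSA
(= πr²), mean OPD (1-D radial quadrature), MCH and sphericity
(k = t(0)/t(½)) are exact per-cell oracles.

**Scenario bases.** The two experimental scenarios start from phantoms
whose analytic scalars equal the single-cell values they emulate: the
sealed-chamber scenario from PSA 60 µm², k 0.65, MCH 32.3 pg; the open
chamber from PSA 49 µm², k 0.86, MCH 30.5 pg. The centre coefficient is
solved in closed form from the target sphericity
(c₀ = k·s·P/(1−k·s) with s = √¾, P = c₂/4 + c₄/16) and all coefficients
are rescaled together to hit the target mass (a uniform thickness scale
leaves PSA and k untouched).

**Temperature morphs.** Responses are phenomenological linear trends, not
biophysics: PSA(t) = PSA₀ + a·(t−t₀) (radius rescaling) and
k(t) = k₀ + b·(t−t₀) (re-solving c₀), with a final mass renormalization
so each cell's dry mass is exactly conserved across the sweep — purely
morphological change, the regime in which MCH is expected to stay flat.
Sealed defaults: a = (64−60)/24 µm²/°C, b = (0.45−0.65)/24 per °C over
17→41 °C; chamber: a = 0, b = (0.91−0.86)/24.

**Cohorts and the paired design.** A sweep samples one cohort and morphs
the *same* cells to every temperature, mirroring experiments that
re-image the same field while the stage heats. Between-cell variability
uses hematology-scale defaults: radius CV 4 % (red-cell size
distribution), dry-mass CV 6.5 % (an MCH SD of ≈ 2 pg on 30 pg), baseline
sphericity SD 0.02. Cells are placed on a jittered grid, non-overlapping
and clear of the image border. Because the design is paired, group-mean
differences across temperature are driven by the morph slopes rather than
by cohort sampling noise; slope tests are nevertheless run on per-cell
values with temperature as a numeric covariate, which is the conservative
(unpaired) analysis.

**Fluctuation stacks.** Frame t = base + u + b, with u zero-mean Gaussian
membrane flicker of per-pixel std A(x, y) — one amplitude on the central
"dimple" disc (default boundary 0.5·R, configurable; the anatomical
boundary is not sharply defined) and another on the surrounding ring — and
b white Gaussian background noise (default 2 nm) everywhere. Flicker is
temporally white by default because the estimator uses only the per-pixel
std, which is insensitive to temporal correlation; an AR(1) knob exists
for robustness studies (stationary variance preserved). Default cadence
is 100 frames at 10 Hz. Scenario amplitudes put the ring above the dimple
at all temperatures with the dimple rising faster, so the fluctuation
pattern migrates toward the dimple as temperature increases.

**What the generator does not emulate.** No microscope-objective pupil
(the rendered rim is sharp at the pixel scale, giving the OPD a long
spectral tail a real NA-limited system would not have), no speckle or
partially coherent illumination, no cell motion or drift, no echinocyte
shapes, and no biophysical water-efflux model. Passing tests therefore
demonstrate the correctness of the numerical chain under a controlled
image model, not performance on real microscope data.

## Hologram formation and reconstruction

**Recording.** The object is a unit-amplitude phase object
O = exp(i2π·OPD/λ) (red-cell absorption at 666 nm is negligible). The
plane reference is tilted so the real-image term R*O lands at positive
spatial frequency, by default at the (N/4, N/4) bins — the maximal
separation from DC that keeps the sideband's half-distance bandwidth
inside the Nyquist square. The recorded intensity is |R+O|² exactly; the
optional camera model adds Gaussian noise (σ = 2 % of the peak
intensity) or Poisson noise and quantizes to 12 bits. Gaussian noise is
clipped at zero and the clip count is recorded.

**Sideband search.** The Fourier-magnitude peak is sought in the
positive-frequency half-plane outside a DC-exclusion disc (N/16 bins);
restricting to a half-plane makes the argmax deterministic despite the
Hermitian twin peak. A peak below 1 % of the DC magnitude raises a
no-sideband error. The filter radius defaults to half the centre-to-DC
distance.

**Adaptive filter radius.** With a unit-modulus object the DC term is
spectrally a pure delta, so the only contamination is the twin image and
the sideband's own truncated tail; the half-distance radius is then
conservative. `reconstruct_hologram` extends the radius outward while the
azimuthal-mean spectral magnitude stays above 1.2× the noise floor (the
median magnitude far from all orders; a pure-noise annulus mean is
≈ 1.06× that median for Rayleigh magnitudes), capped at 97 % of the
sideband-to-twin bisector. Clean data thus harvests the rim's spectral
tail (sub-nanometre reconstruction error), while noisy data stays at the
half-distance default rather than admitting noise. The located radius is
never reduced below the default.

**Demodulation and propagation.** Demodulation multiplies by the digital
reference replica (the same plane wave used in recording), exactly
cancelling the carrier. The Fresnel transform is the single-FFT form with
pre- and post-chirps on centred coordinates and output pitch
Δξ = λd/(NΔx); it is normalized unitary (orthonormal FFT, unit-modulus
chirps), so energy checks are exact and the forward/inverse pair inverts
to machine precision. In-focus recording (d = 0) is the default; the
quadratic phase mask for objective curvature is off in synthetic mode
(the simulator introduces none) and available for real data.

**Phase handling.** Four-quadrant arctangent with output in (−π, π] and
the negative-real axis mapped to +π; zero-magnitude pixels get phase 0
and an `invalid` flag. 2-D unwrapping is reliability-guided
(scikit-image) and is a no-op for the default phantoms (max phase
≈ 1.2 rad < π). Background compensation fits a first- (default) or
second-order polynomial on cell-free pixels only — found by Otsu on the
absolute deviation from the median phase, dilated by a 5-px guard band —
and subtracts it everywhere; this also absorbs the arbitrary global phase
and the constant A of the Fresnel kernel. The real/twin sign ambiguity of
an automatically located sideband is resolved by requiring the cell phase
to be positive (valid whenever n_cell > n_medium).

**Known equivariance limit.** Whole-pixel translations of the scene that
are commensurate with the carrier period (multiples of 4 px at the ¼
cycle/px default) shift the reconstruction exactly; incommensurate shifts
rotate the reference phase and hence the (small) twin-leakage term, so
reconstructions agree only to that leakage scale.

## Segmentation and morphometrics

Binarization uses Otsu's threshold by default, or a fixed threshold
(20 nm in all synthetic work) for bit-reproducibility. The background
mask is the complement of the foreground dilated by 5 px, leaving a guard
annulus in neither mask. Components are 8-connected, filtered to
20–150 µm², border-touching components are dropped, and output order is
deterministic (centroid row, col). The discocyte QC accepts a cell iff
its Crofton-perimeter circularity 4πA/P² ≥ 0.8 and its sphericity lies in
[0.2, 1.2] — engineering proxies for a visual "biconcave" judgement.

MCH is computed by the dimensionally consistent dry-mass formula
mean_OPD·PSA/α_HB (α_HB = 0.00196 dl/g ≡ 0.196 cm³/g), which reproduces
the ≈ 30–32 pg scale; a verbatim variant with an explicit factor 10 and a
wavelength division is provided for comparison only, with its unit
caveats documented in the docstring. Sphericity samples OPD_c as the mean
over a disc of radius 0.1·R (floor 1.5 px) at the centroid and OPD_r over
the annulus [0.45, 0.55]·R, with R = √(PSA/π); small-region averages are
used instead of single pixels for noise robustness, at the cost of a
small positive bias (≤ 2 % for k ≥ 0.6, up to ≈ 4 % for very deep
dimples, where the profile curves strongly inside the centre disc).
Cells with R < 4 px are rejected as unreliable.

## Fluctuation estimation

The per-pixel temporal std uses divisor T−1. The noise floor is the mean
per-pixel std over background pixels; CMF is the quadrature difference,
clamped at zero where the variance falls below the floor (clamp counts
are reported as a data-quality signal). The whole-cell amplitude is the
mean of the map over the mask; ring and dimple means use the same 0.5·R
split as the generator. Frames are used as-is; an optional per-pixel
linear detrend exists for drifting real acquisitions. At the
experimental cadence (100 frames) the estimator's bias at amplitude ≥ 2×
noise is well below a percent; consistency is verified at 10,000 frames.

## Statistics

Group summaries report mean, sample SD (divisor n−1) and 2-SD error-bar
half-widths. The trend test is the OLS slope F-test,
F = SS_reg/(SS_res/(n−2)) with (1, n−2) df, run on per-cell values; an
exact fit reports p = 0, constant data F = 0, p = 1. The two-sample
Kolmogorov–Smirnov test uses the asymptotic Kolmogorov distribution with
the standard effective-n correction (exact mode available); the D
statistic is cross-checked in the tests against brute-force ECDF
enumeration. No multiple-testing correction is applied; raw p-values are
reported per test. Report JSON is written with sorted keys so reruns are
byte-identical.

## Problem sizes

Full-resolution checks (hologram round trip, 100-cell parameter
recovery) run at the native 1024² grid and 0.09 µm pitch (a 92 µm field).
The repeated temperature experiments (12 seeded sweeps per scenario, 36
cells per temperature) run at 512² and 0.18 µm — the same field of view
at half the sampling, which leaves per-cell discretization errors near
1 % while keeping dozens of full sweeps cheap. Fluctuation-estimator
studies use a single cell on a 128² patch at 0.2 µm, where a
10,000-frame stack is still a small array.

## Limitations

- No pupil/aperture model: reconstruction accuracy at the cell rim is
  limited by spectral truncation rather than by diffraction, and the
  adaptive filter radius is tuned to that regime.
- The temperature response is linear by construction; the package makes
  no claim about the functional form of real thermal responses.
- The two scenarios deliberately reproduce opposite sphericity trends
  (sealed: decreasing; chamber: increasing) as reported for the two
  mounting conditions; no attempt is made to reconcile them physically.
- Touching or overlapping cells are out of scope for segmentation
  (scenes are generated non-overlapping); real crowded fields would need
  watershed splitting.
- The verbatim MCH formula variant is not dimensionally meaningful and
  is retained only for comparison.
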