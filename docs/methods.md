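# Methods

`trialprep` implements a trial-based preprocessing chain for awake
non-human-primate fMRI acquired at high field, together with a seeded
simulator that provides ground truth for every stage. This note records
the models, the parameters that matter, and the numerical choices, in
enough detail to reason about what the tests do and do not demonstrate.

## The problem being modelled

Awake-monkey sessions are structured into short behavioural trials
during which the animal holds still; between trials it moves (jaw,
body, limbs) for reward. At high field these movements perturb the B0
field and, with segmented EPI, produce N/2 ghosts — a half-field-of-view
circularly shifted copy of the object along the phase-encode
(anterior–posterior) axis. Within trials, respiration causes small
apparent translations along the same axis; between trials, the animal's
repositioning changes both the position and the apparent shape of the
brain, so consecutive trials differ by (approximately) a small
12-parameter affine rather than a rigid motion. On top of this sit slow
scanner drifts, stepwise intensity offsets between runs, and a strong
receive-coil bias field from small custom RF coils.

The processing chain: (1) per-volume QC and whole-trial selection,
(2) concatenation of accepted trials, (3) 2-step realignment,
(4) gap-interpolated high-pass filtering, (5) adaptive brain extraction,
(6) per-run-session OLS GLM, plus a harness that compares five analysis
strategies by their suprathreshold voxel counts.

## Synthetic sessions

No public dataset of this kind exists, so all testing runs on the
simulator (`trialprep.synthetic`). The phantom is an ellipsoidal
"brain" (mean 1000, 10% smooth texture) with a partial posterior
"muscle" shell (mean 1030 before blurring, i.e. within the ±20%
window where intensity thresholding alone cannot separate the tissues),
a few-millimetre dark skull/CSF gap between them, and a dim noise-floor
background (80). The image is blurred with an anisotropic
point-spread kernel (0.8 voxel in-plane, 0.65 voxel through-plane):
sharp voxel edges are unphysical for EPI, and without the blur
interpolation error — not registration error — dominates every
resampling comparison. The muscle shell is confined to the slice slab
in z, as jaw musculature runs alongside, not above, the imaged volume.

The session model, per volume:

    data = baseline × bias × (1 + a·act·r(t) + drift(t) + step(run))
           → geometric corruption → white noise → N/2 ghosts

where `r(t)` is the HRF-convolved stimulation regressor
(peak-normalized, so the activation amplitude `a` reads as fractional
signal change at the regressor peak), `drift` is a linear trend plus a
cosine, and `step` is a per-run intensity offset. Geometric corruption
mirrors exactly what the 2-step realignment corrects: a sinusoidal
phase-axis translation within trials (zero at each trial's first
volume), an independent uniform 12-parameter affine per trial for every
trial after the first, and random phase-axis repositioning on
inter-trial volumes. B0-induced apparent shifts and true motion are not
distinguished — the correction is identical for both. Ghosts are added
to a seeded fraction of inter-trial volumes and to every volume of
designated "bad" trials (movement the motion sensors missed). Each
corrupted volume is produced by a single composed interpolation, so the
injected truth is recoverable to interpolation accuracy (verified:
inverting the recorded transforms restores the clean series to < 2% of
baseline at the default jitter).

Default conditions (`SimConfig.default()`): 64×64×11 grid at
1.5×1.5×2 mm, 2 runs × 150 volumes at 2 s inter-volume time, five
15-volume trials per run separated by 10-volume gaps; per trial a 6 s
fixation event followed by a 2 s visual-stimulation event; activation
3% in two 4 mm-radius blobs; drift 2% linear per run + 1.5% cosine at
180 s period; 3% run step; 1% white noise; 0.2 mm within-trial shifts
at 3 s period; ≤1 mm / ≤0.015 rad / ≤1% / ≤0.01 affine jitter; ±1 mm
gap repositioning; 10% of gap volumes ghosted at amplitude 0.3; bias
strength 1. The artefact amplitudes have no published values; they were
chosen once for discriminability at realistic orders of magnitude and
are not revisited. `SimConfig.small()` (32×32×8, 2×100 volumes, 4×12
trials) is the fixed condition for the optimization-heavy method
comparison; all other stages are exercised at the default scale.

What the simulator does **not** model: k-space/reconstruction physics,
physiological noise beyond white noise + drift, temporal
autocorrelation, eye movements, nonlinear (non-affine) distortion, and
spin-history effects. Passing tests therefore demonstrate correctness
of the algorithms under the stated generative model, not performance on
real data.

## QC and trial selection

Two per-volume statistics: the **ghost ratio** — mean intensity over a
brain region divided by mean intensity over the region where the N/2
ghost lands (the brain mask circularly shifted by half the FOV, minus
the brain; ε = 10⁻¹²·max guards empty backgrounds) — and the
**centre-of-mass shift** (intensity-weighted centroid in mm, relative
to a reference volume). A volume is flagged when its ghost ratio falls
below threshold or its CoM shift norm exceeds `com_threshold_mm`
(default 0.3 mm). The adaptive ratio threshold is median − 3·MAD of the
within-run ratios: robust and scale-free, standing in for the manually
tuned thresholds of an interactive workflow. Note its false-positive
floor: for Gaussian ratios, median − 3·MAD ≈ μ − 2σ, i.e. ~2% of clean
volumes flag, which whole-trial rejection amplifies — for guaranteed
bookkeeping an explicit threshold is preferable, and both paths are
exposed.

In pipeline flows the CoM reference is the first *trial* volume (the
session's first volume is inter-trial and may itself be corrupted), and
the orchestrated pipeline default for `com_threshold_mm` is 2 mm:
between-trial repositioning of ~1–2 mm is an expected condition that
realignment corrects, not an artefact.

Rejection is whole-trial — one flagged volume rejects the trial, since
movement that ghosts one volume also perturbs B0 for the rest of the
trial — and manual review enters as explicit per-trial overrides that
always win, keeping the subjective step auditable. Concatenation keeps
exactly the accepted trials' volumes in order, recording every removed
volume and its original acquisition time in a `ConcatIndex`.

## 2-step realignment

Step one registers every volume of a trial to the trial's first volume
with a single degree of freedom: translation along the phase-encode
axis. Restricting the fit encodes the physical prior that within-trial
motion is respiratory/B0-driven A–P shift only. Step two computes each
trial's mean image (after transiently applying the step-one shifts) and
registers it to the first accepted trial's mean with a full
12-parameter affine — translations (mm), intrinsic x-y-z rotations
(rad), scales, and unit-upper-triangular shears, composed as T·R·Z·S in
millimetre coordinates about the grid centre. The affine is stored as a
pull-back sampling map (output coordinates → moving-image
coordinates). Only parameters are kept from both steps; each data
volume is finally resampled once through the composed map (shift, then
its trial's affine) with cubic splines, zero outside the field of view.
Composing before reslicing measurably beats two sequential reslices
against the simulator's clean series.

Cost and optimization: mean squared intensity difference after Gaussian
pre-smoothing (FWHM 2 voxels), evaluated over an interior region that
excludes a 3-voxel rim (clamped on thin axes) — resampling pads
out-of-field voxels with zero while real background is not zero, and
the rim term otherwise swamps the cost. The 1-DOF fit uses bounded
scalar minimization (±5 voxels, 0.01-voxel tolerance). The affine fit
runs staged Gauss-Newton least squares (translations → +rotations →
full 12), each stage warm-started from the previous, with parameters
scaled so 1 mm of translation, 0.01 rad, 1% scale and 0.01 shear are
commensurate steps; the interior residual is sampled directly at mapped
coordinates, which is what makes the per-volume 6-DOF baseline
("standard realignment", used by the comparison harness) affordable.
If a stage hits its evaluation cap the best-so-far parameters are
returned flagged. Known limitation: with only 8–11 slices, z-scale and
z-shear are weakly constrained and individual trials can err by 2–4%
there; medians across trials stay well inside 0.01.

## Gap-interpolated high-pass filtering

Filtering a concatenated series directly would treat samples separated
by long real-time gaps as adjacent. Instead each run is reconstituted
on its original even grid: for every gap, the anchor on each side is
the voxelwise average of the two adjacent trial volumes, placed at the
midpoint of their acquisition times, and missing volumes are read off
the straight line between anchors (single-volume trials anchor
themselves; leading/trailing gaps extend the nearest anchor as a
constant). Runs are then filtered one by one and the interpolated
samples discarded.

The filter projects out the K non-constant discrete-cosine vectors with
period longer than the cutoff, K = ⌊2·N·TR/cutoff⌋ (default cutoff
96 s). DCT projection is zero-phase, exactly idempotent, exactly linear
and keeps the DC component; run-mean steps are deliberately left to the
per-run GLM intercepts. With cutoff ≤ 2·TR there is nothing to remove
and the input passes through with a warning.

## Adaptive brain extraction

The temporal-mean image is multiplied by a Gaussian radial weight
w(x) = exp(−(d(x, c)/σ)²) with σ = d_max/(1+strength), d in mm from the
crosshair c (in-plane only in 2D mode) and d_max the distance to the
farthest grid corner; then thresholded at `threshold_frac` × max. The
connected component at (or nearest) the crosshair is selected *before*
morphological closing — closing first would bridge the narrow skull gap
to the similar-intensity muscle — then closed (1-voxel ball) and
hole-filled (3D, or per-slice in 2D mode). The mask is applied to the
original, unweighted data, so neither the weight nor the coil bias
field enters further analysis. Defaults (strength 1.0, threshold 0.3,
crosshair at the intensity centroid, 3D mode) were calibrated on
phantoms across bias strengths 0.5–2 and both test grids (worst Dice
0.95, zero muscle leakage). The interactive slider workflow is replaced
by these parameters plus an optional grid search scored by mask
compactness (volume^{2/3}/boundary count) × mean boundary gradient,
with deterministic first-wins tie-breaking.

## GLM and the five-method comparison

Regressors are built per run on the original time grid: event boxcars
on a TR/16 grid, convolved with the canonical double-gamma HRF (peak
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio
1/6, 32 s support, peak-normalized), sampled at volume times, then
peak-normalized per condition. Any concatenation applied to the data is
applied to the regressor rows. The design adds one-hot columns for
artefact volumes (when requested) and one intercept per run ("runs as
sessions"). Fitting is voxelwise OLS with optional grand-mean scaling
of the whole dataset to 100 (which provably leaves t-maps unchanged);
t = cᵀβ/√(σ̂²·cᵀ(XᵀX)⁻c) with σ̂² = RSS/(n − rank X); voxels with
residual variance below 10⁻¹²·grand-mean are flagged degenerate with
t = 0. No AR(1) prewhitening is implemented: the simulated noise is
white, so OLS inference is exact here; on real, autocorrelated data the
t-values would be optimistic. Map quality is summarized as the count
and proportion of in-mask voxels with t above a threshold (default
3.11, p < 0.001 uncorrected at the reference degrees of freedom).

The harness compares, on identical sessions: (1) 6-DOF rigid
realignment of the full series; (2) method 1 plus artefact regressors
for every flagged volume and every volume of flagged trials; (3) trial
concatenation + rigid realignment; (4) concatenation + 2-step
realignment; (5) method 4 + the 96 s gap-interpolated filter. All five
share 2 mm FWHM smoothing, a 128 s model-side high-pass applied per run
to data and condition regressors (for the concatenated methods this
filter sees the compressed grid — deliberately, as a model-side filter
would), grand-mean scaling, and a per-method extraction mask from the
method's own realigned mean. The comparison conditions are
`SimConfig.small()` with one ghost-seeded trial, 10 seeds; expected and
observed outcome: method 5 strictly above method 1 (roughly 2× the
suprathreshold proportion) and at or above methods 2–4, while on
artefact-free sessions all five agree within ~5%.

## Numerical and engineering choices

- All internal storage is float64 regardless of on-disk dtype; NIfTI is
  written float32 with a JSON sidecar carrying inter-volume time,
  phase axis and run lengths (nibabel I/O).
- Volume indices 0-based; trial spans inclusive; times in seconds from
  run start. Transforms, concatenation indices and logs serialize to
  human-auditable JSON; every pipeline operation can append its full
  parameter set to an append-only JSON-lines step log.
- Interpolation: cubic spline for all reslicing and cost evaluation;
  geometric corruption in the simulator uses one composed resample per
  volume so double-interpolation error is bounded and measured.
- Degenerate inputs fail loudly: flat images cannot be registered,
  empty ROIs/masks raise, a run without an accepted trial cannot be
  gap-interpolated, rank-deficient designs fall back to the
  pseudo-inverse with a warning.
- Problem sizes used by the test suite and the acceptance script —
  detection and extraction at the 64×64×11 default scale (20 seeds
  each), registration recovery on 32×32×8 / 2×60-volume sessions (20
  seeds), the method comparison on `SimConfig.small()` (10 corrupted +
  3 artefact-free seeds) — are the package's fixed evaluation
  conditions, chosen so the full evaluation runs on a single CPU in
  minutes.
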