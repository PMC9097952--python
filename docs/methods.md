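# Methods

## Problem setting

Whole-body Patlak parametric FDG-PET produces two voxel-wise images beyond
the static SUV: the metabolic rate of FDG, MR_FDG = Ki × blood glucose,
where Ki is the net irreversible uptake rate (the Patlak slope), and the
apparent distribution volume DV of free (non-phosphorylated) tracer (the
Patlak intercept).  The standard acquisition keeps the patient on the bed
for ~75 minutes.  An abbreviated workflow acquires only two short dynamic
segments — 0–6 min (the input-function peak, single bed over the heart) and
60–75 min (equilibrium-phase whole-body passes) — and must reconstruct the
cumulative plasma integral across the unsampled 6–60 min interval.  This
package simulates both protocols end-to-end on a digital phantom and
quantifies how well the abbreviated protocol reproduces the standard one.

## Kinetic forward model

Tissue activity follows the irreversible two-tissue-compartment model

    dC1/dt = K1·Cp − (k2+k3)·C1,      dC2/dt = k3·C1,
    C_t(t) = C1(t) + C2(t) + vb·Cp(t),

with K1 (ml/min/ml) the plasma-to-tissue transport rate, k2 (1/min) the
efflux rate, k3 (1/min) the phosphorylation (trapping) rate, and vb the
fractional blood signal superimposed on the voxel.  k4 = 0 throughout: the
Patlak analysis assumes irreversible trapping over the scan duration.  The
Patlak macro-parameters are

    Ki = K1·k3/(k2+k3)            (slope),
    V  = vb + K1·k2/(k2+k3)²      (intercept, reported as DV = 100·V).

A deliberate modelling choice: the blood term vb·Cp rides *on top of* the
per-voxel tissue solution rather than diluting it by (1−vb).  With the
dilution convention the measured Patlak slope would be (1−vb)·Ki, i.e. the
slope and the nominal Ki would disagree by 4–10% at realistic vb; the
superposition convention makes the asymptotic slope exactly Ki, so that
simulated truth and Patlak estimate are directly comparable.  Rate
constants are therefore to be read as "per voxel volume".

No lumped constant is applied to MR_FDG (the product form Ki × glucose is
used as such), and activities are decay-corrected to injection time.
Units: minutes, kBq/ml, glucose in mmol/L, MR_FDG in µmol/min/ml, DV in
percent.

### Arterial input

The default input is a Feng-type model,

    Cp(u) = (A1·u − A2 − A3)·e^{λ1 u} + A2·e^{λ2 u} + A3·e^{λ3 u},
    u = t − t0,

with defaults A1 = 851.1 kBq/ml/min, A2 = 21.88, A3 = 20.81 kBq/ml,
λ = (−4.1339, −0.1191, −0.0104)/min and delay t0 = 0.5 min, giving an
aortic peak near 100 kBq/ml and a 60-min tail near 11 kBq/ml — typical of a
~260 MBq injection.  A pure multi-exponential bolus (`tri_exponential`) and
tabulated curves are also supported.  The clinical input function is
measured from images, so any realistic shape is admissible; the Feng form
was chosen because it admits closed-form convolution and integration.

### Closed-form evaluation

All exponential-family curves live in the function class
Σ c·tⁿ·e^{λt}, which is closed under antidifferentiation and convolution
with e^{−βt} (`wbpatlak.expsum`).  Tissue curves, cumulative plasma
integrals and per-frame averages are therefore evaluated *exactly* — no
quadrature, no ODE solver — and the test suite verifies them against
adaptive quadrature and stiff (LSODA) integration at 1e-8/1e-3 relative
tolerance.

## Acquisition simulation

**Frame schedule.** The standard protocol tiles 0–6 min with cardiac
list-mode sub-frames (12×5 s + 8×15 s + 6×30 s by default, configurable),
inserts a 4-min dead time while the scanner switches to whole-body mode,
then runs 5 passes of 2 min and 11 passes of 5 min; the last three frames
are exactly [60,65), [65,70), [70,75) min.  The published pass durations
sum to 71 min against a ~75-min session, so the 4-min dead time is a
reconciliation choice, configurable.  The two-short protocol is the exact
frame subset covering [0,6) ∪ [60,75).

**Phantom.** A 48³ grid at 4 mm isotropic voxels holds seven spherical
"organs" (brain, lung, liver, spleen, heart wall, bone, muscle), one to
three spherical lesions, and a 2×2×37-voxel descending-aorta column whose
voxels carry Cp itself.  Organ macro-parameters (Ki, V) are set so that
MR_FDG and DV means at 5.5 mmol/L glucose fall in the ranges typical of
normal organs (brain MR ≈ 0.17 µmol/min/ml, DV ≈ 59%; lung ≈ 0.01/4%;
etc.), then inverted to micro-parameters for a chosen efflux scale
β = k2+k3.  β is set to 0.25–0.35/min: with a decaying input tail
(λ_slow ≈ −0.0104/min) the finite-time Patlak intercept exceeds its
asymptote by ≈ β/(β+λ_slow), and β ≥ 0.25 keeps that inherent bias below
~4%.

**Noise.** Zero-mean Gaussian in image space with per-voxel
sd = σ0·sqrt(activity/Δt_frame), the standard frame-duration scaling of
reconstructed-image noise; σ0 defaults to 0.5 kBq/ml·min^½, giving ~2–4%
noise in organs on 5-min frames.  Noise streams are keyed by (seed, frame
start time), so frames shared by the two protocols carry bit-identical
noise — the two datasets really are subsets of one simulated session, as in
the clinical design.  What this generator does *not* emulate: Poisson
sinogram statistics and reconstruction correlations, attenuation/scatter
residuals, patient motion, peristalsis, and partial-volume blur.  Passing
tests therefore demonstrate correctness of the analysis chain under an
idealized noise model, not scanner-level robustness.

## Input-function workflow

The IDIF is the per-frame mean over the aorta VOI.  For the two-short
protocol the early and late segments are merged into a single TAC and
round-tripped through a fixed CSV dialect
(`frame_start_s,frame_end_s,activity_kBq_ml`, UTF-8, LF, `repr`-formatted
floats → bit-exact).  The 6–60 min gap is bridged by a fitted clearance
model:

- `tri_exponential` (default): Σ aᵢ·e^{−rᵢt}, aᵢ ≥ 0, fitted to post-peak
  samples by variable projection (rates by trust-region least squares from
  a grid of log-spaced starts; amplitudes by NNLS).  Samples within 1 min
  after the peak are excluded: there the bolus is still dispersing and is
  not yet multi-exponential, and including those samples pulled the
  extrapolated tail off by several percent.  Samples are weighted by
  sqrt(duration/activity), the inverse-variance weight under the noise
  model.
- `input_model_refit`: refit of the full Feng model (including its delay),
  appropriate when the measured curve carries a Feng-shaped peak.
- `loglinear_bridge`: a single exponential through the gap endpoints.

The cumulative plasma integral treats each frame value as an exact frame
average (so sampled stretches integrate exactly as Σ value·Δt), uses the
fitted model across the 6–60 min gap, and bridges gaps ≤ 5 min (the dead
time) by a trapezoid when no model is given.  Negative fitted values are
clamped at zero with a warning.

## Patlak mapping

For each voxel, the last three frames give points
x_k = ∫₀^{t_k}Cp/Cp(t_k), y_k = C_t(t_k)/Cp(t_k) at frame midpoints t_k;
ordinary least squares yields the slope (Ki) and intercept (V).  The
input-function coordinates are common to all voxels, so the whole volume is
fitted in one vectorized pass.  Voxels with non-positive plasma activity
become NaN (never zero-filled).  MR maps scale exactly linearly with
glucose; DV = 100·V; SUV is the mean of the same three frames scaled by
weight/dose.  Both protocol arms run through the identical fit code path —
only the input-function integral differs.

## VOI quantification

Lesions: iterated 41%-of-maximum isocontour — the connected component
(26-connectivity) containing the seed among voxels ≥ 0.41 × the component
maximum, with the maximum re-estimated to a fixed point (≤ 20 rounds).  The
threshold is referenced to the component maximum, not the global one.  In
the study pipeline the seed is the hottest MR voxel inside the lesion (the
voxel a reader would click), since the geometric centre can dip below zero
under noise.  Organs: fixed-diameter spheres (10 mm default, 25 mm liver).
"Peak" is the PERCIST-style value: the highest mean of a 1-cm³ sphere
(radius 6.2 mm) centred on any VOI voxel, computed NaN-aware by
convolution.  VOIs are defined on the standard maps and copied unchanged to
the two-short maps, so paired samples share voxel counts by construction.

## Agreement statistics

Implemented from scratch (`wbpatlak.agreement`):

- **Passing–Bablok regression**: slope B = shifted median of all pairwise
  slopes (slopes of exactly −1 excluded; median index offset by K, the
  count of slopes < −1; indices clamped at the boundaries in the degenerate
  case); intercept A = median(y − B·x); confidence intervals from the
  rank-based normal approximation (the analytic form, not bootstrap).
- **Cusum linearity test**: residual signs weighted to a zero-sum walk
  (+sqrt(L/l) / −sqrt(l/L)), accumulated in x-order; the statistic is the
  maximum excursion.  Its asymptotic reference is the Kolmogorov–Smirnov
  distribution (exposed as `cusum_statistic_ks_pvalue`), but that asymptote
  is noticeably conservative at method-comparison sample sizes (simulated
  type-I error ~0.014 at n = 20 under the randomized-ordering null), so the
  reported p-value is computed against the exact conditional null — random
  orderings of the observed scores, 2000 Monte-Carlo draws with a fixed
  internal seed, hence deterministic.  All-zero residuals give p = 1.
- **Bland–Altman**: differences d = two_short − standard; bias = mean(d);
  95% limits of agreement = bias ± 1.96·sd(d) (the literal 1.96 of printed
  reports).  These are *limits of agreement*, not a confidence interval of
  the bias; the bias CI (t-based) is computed separately to keep the two
  concepts distinct.
- **Spearman correlation**: midranks for ties, Fisher-z confidence interval
  (se = 1/sqrt(n−3)), two-sided p from the t approximation.

All p-values are two-sided; no multiple-testing correction is applied.

## Study design

The default study simulates 21 subjects.  Per subject: glucose ~ truncated
normal (5.5 ± 1.2 mmol/L, capped below 11 mmol/L ≈ the 198 mg/dl clinical
exclusion bound), organ Ki and V multipliers ~ truncated normal (cv 0.15),
1–3 lesions with Ki ~ U(0.02, 0.06)/min, V ~ U(0.3, 0.7), diameter
12–18 mm, and an input amplitude scale ~ U(0.8, 1.2).  Every random draw
descends from the config seed through a `SeedSequence` tree; reruns with
the same config are bit-identical.  Six metrics (max/mean/peak × MR/DV) are
pooled across subjects and regions, separately for organs and lesions and
pooled, and each runs through the full agreement battery.

## Numerical choices and degenerate inputs

- Frame midpoints are the Patlak/fitting time variable (frames are short
  relative to the late-curve dynamics).
- Rates with |λ| < 1e-12 are treated as exactly zero in the closed-form
  algebra (polynomial branch), avoiding catastrophic cancellation.
- Exponential fits falling to zero amplitudes, non-converging refits, or
  fewer than 3 post-peak samples raise `GapFitError` with diagnostics.
- Patlak fits with < 2 valid points return an invalid marker (NaN maps).
- Threshold segmentation refuses seeds on non-positive or NaN voxels.
- Subject-level failures inside `run_study` are logged and skipped, and
  surfaced in the run manifest.

## Problem sizes

Default problem sizes were chosen so a full study is a desk-scale
computation: 48³ voxels at 4 mm, 42 standard-protocol frames, 21 subjects
(a complete study runs in well under a minute on one core).  The
statistics oracles use 1000 random datasets (Passing–Bablok enumeration)
and 1000 null simulations (cusum calibration).

## Known limitations

- Image-space Gaussian noise stands in for the full reconstruction chain;
  direct (sinogram-space) Patlak reconstruction is out of scope.
- The phantom has no partial-volume blur, so VOI statistics are cleaner
  than clinical ones; between-protocol agreement is the target quantity,
  not absolute quantification accuracy.
- The aorta VOI is taken from the known phantom geometry; automatic vessel
  detection is not modelled.
- Micro-parameters (K1, k2, k3, vb) are representative values consistent
  with published macro-parameter ranges, not fits to patient data.
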