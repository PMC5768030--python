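# Methods

## Model

A CT slice with mean CT number ⟨CT⟩ (HU) over a region of area A_ROI has
water-equivalent area A_w = (⟨CT⟩/1000)·A_ROI + A_ROI, and the
water-equivalent diameter is D_w = 2√(A_w/π). The implementation uses the
whole reconstructed image as the ROI: air at −1000 HU contributes exactly
zero to A_w, so the result is insensitive to how much air surrounds the
body. This avoids body-contouring entirely; the cost is that anything else
in the field of view attenuates too, so the patient couch's
water-equivalent area A_w(table) — obtained once per scanner by contouring
the couch in a single image and applying the same formula — is subtracted
inside the square root. Validity assumptions: a linear, quantitative
reconstruction kernel (no edge enhancement), the patient contour inside
the FOV, and padding values outside the reconstruction circle already
masked to air (done at read time; vendor sentinels at or below −1500 HU
are replaced by −1000 HU).

Per-series scalar metrics:

- D_w_c: D_w at the slice whose z is nearest the midpoint of the scanned
  range. On an exact tie between two slices the lower-z slice is used (the
  convention had to be fixed somewhere; "middle of the scanned region" does
  not decide it).
- D_w_ave: unweighted arithmetic mean over reconstructed slices. No
  slice-spacing weighting: reconstructed spacing is uniform in practice,
  and no weighting scheme is standard.
- D_w range: max − min over the series.

SSDE = CTDI_vol × f(D_w), with f the 32-cm body-phantom conversion-factor
table shipped as package data (diameters 6–55 cm at 1-cm steps, tabulated
from the published exponential form f = 3.704369·exp(−0.03671937·D_w);
the tests verify table and fit agree to < 1%). Lookup is piecewise-linear
in diameter — simple and monotone-preserving; within the tabulated range
the difference from using the exponential directly is far below every
tolerance in this package. Outside 6–55 cm the factor clamps to the
nearest endpoint with a warning. The conventional argument is D_w_c; the
API accepts any D_w value so D_w_ave-based SSDE can be compared, and the
cohort records carry a field naming the metric used. Only
32-cm-referenced CTDI_vol is supported; 16-cm head-phantom factors are out
of scope.

## Raised-I_min simulation

A modulated acquisition records one tube current per slice. Raising the
protocol minimum is simulated as I'(z) = max(I(z), I_min); since CTDI_vol
is proportional to mean tube current at fixed kV, pitch and rotation time,
the simulated CTDI_vol is the recorded one scaled by mean(I')/mean(I).
This is a hard cutoff: real ATCM systems smooth their response near the
limits, but measured discrepancies are small (< 5% in the scanners this
model is patterned on). Only I_min values at or above the originally
applied floor are physically meaningful; smaller values reproduce the
original acquisition and trigger a warning. Scenario sweeps recompute
SSDE from the simulated CTDI_vol with each record's original D_w_c —
patient size does not change with the scenario.

## Cohort statistics

Fits are ordinary least squares with intercept; R² = 1 − SS_res/SS_tot
(equivalently the squared Pearson correlation). A constant response is
reported as R² = 0 with a warning; a constant predictor is an error; cells
with fewer than 3 usable records are marked unavailable. Strata follow
the tabulation conventions of dose-survey practice: scanner × exam type
for the R² grids, exam type × sex (plus "All") for the difference tables.
Differences are signed, with D_w_ave as the percentage denominator. All
SDs are population SDs (n denominator), stated in the output metadata —
with cohort sizes of ~100 the distinction from the n−1 convention is
cosmetic, but it must be fixed for byte-reproducible outputs. No
hypothesis testing or confidence intervals: the quantities are
descriptive, and the package asserts orderings, not significance.

The "common dose–size curve" check (are chest and CAP examinations on one
CTDI_vol-vs-D_w_ave line?) compares the pooled-fit R² with a stratified R²
computed on the same total-variance denominator (1 − Σ_strata SS_res /
SS_tot). Per-stratum R² values computed against each stratum's own
variance are not commensurable with a pooled R² and are not used for this
comparison.

## Synthetic data: what it emulates

The generator's defaults are the study conditions for every test; they
are fixed once, not tuning knobs.

**Phantoms.** Uniform disks and ellipses rendered by pixel-centre
inclusion on a −1000 HU background (default 512 px at 0.8 mm). For bodies
tens of cm across at sub-mm pixels, the area quantisation error is a few
hundredths of a cm² — orders of magnitude inside the 0.2-cm validation
bound — so no edge antialiasing is needed. Optional: per-pixel Gaussian
HU noise (default 10 HU where used; its effect on a whole-image mean is
negligible by averaging), and a synthetic couch (36 × 2 cm strip at
−400 HU, 0.5 cm below the body) whose analytic A_w = 43.2 cm² is the
ground truth for calibration tests.

**Anatomy profiles.** D_w(z) curves on a normalised anatomical coordinate
t ∈ [0,1]: chest is a cranio-caudal ramp with a Gaussian lung dip centred
mid-scan (so D_w_c < D_w_ave); chest–abdomen–pelvis (CAP) has a lung dip
in the upper third and a broad abdominal bulge peaking at t = 0.60 with
width 0.28, placing the mid-scan slice on the rising liver flank (so
D_w_c > D_w_ave). Curves are normalised so the discrete mean equals the
target D_w_ave exactly and max − min = 23% of it (the range fraction
reported for adult torsos). The shape constants were chosen analytically
so that, with the default scan-window jitter, the signed D_w_c − D_w_ave
differences land near −4% (chest) and +6% (CAP) and the jitter-induced
D_w_c scatter is ≈ 0.5–1 cm — the regime in which mid-scan metrics
visibly underperform scan means without becoming useless.

**Scan-window jitter** (sd 8% of scan length) slides the scan window over
the fixed anatomy. This is the generator's explicit model of scan-length
and positioning variation: it moves the anatomical location of the
mid-scan slice — injecting noise into D_w_c — while leaving the scan mean
nearly unchanged. It is the sole mechanism behind the R² gap between
D_w_c and D_w_ave; localized-anatomy effects (abdominal obesity, breast
tissue) that also perturb real D_w_c are not modelled.

**ATCM emulator.** Noise-constant response I(z) = clamp(I_ref·exp(k·(D_w(z)
− D_w_ref)), I_min, I_max), CTDI_vol = c·mean(I). Defaults: k = ln2/6 cm⁻¹
(a 6-cm D_w_ave increase — about 24% of a 25-cm adult — doubles dose),
I_ref = 170 mA at D_w_ref = 26 cm, clamps 80/500 mA, c = 0.055 mGy/mA.
These put a mid-size adult near 10 mGy with roughly a factor-two dose
range across the cohort, and leave most default-cohort records unclamped
(so the exponential constant is recoverable by log-linear fit) while
letting a raised I_min of 140–180 mA bite visibly.

**Cohort.** Per patient: sex (1:1), weight from a truncated lognormal
(medians 63 kg F / 71 kg M, log-sd 0.20, truncated to 43–117 kg), height
from truncated normals per sex, D_w_ave = 0.162·weight + 14.0 cm plus a
normal residual (sd 1.2 cm) — spanning ≈ 21–33 cm over the weight range —
then profile, jitter, currents and dose (multiplicative lognormal dose
noise, log-sd 0.08), with all D_w metrics recomputed from the realised
profile rather than copied from the regression. Default strata: 120 CAP +
80 chest. Randomness: one root seed with per-patient spawned substreams,
so early cohort members are unchanged when a stratum grows.

**What passing tests do and do not show.** The generator reproduces the
*mechanisms* (size-dose coupling, clamp flattening, mid-scan decoupling)
and therefore supports ordering- and sign-level claims: R²(D_w_ave) >
R²(D_w_c) > R²(weight), chest negative / CAP positive mid-scan bias, SD
compression under a raised floor. Numeric R² values, cohort means and
difference magnitudes are properties of a synthetic population and carry
no clinical meaning; real anatomy, helical geometry, vendor modulation
smoothing and truncated-FOV effects are absent.

## Numerical conventions and edge cases

- Areas are carried in mm² and converted to cm² at operation boundaries;
  D_w is reported in cm (display rounding 2 decimals in the CLI, full
  precision in CSV).
- HU conversion happens once, at read time; downstream code never sees
  stored raw values. The writer stores int16 with slope 1 / intercept
  −1024, so round-trips agree within 1 HU.
- A negative radicand in the table-corrected D_w (calibration exceeding
  slice content, e.g. an air-only end slice) clamps to 0 with a warning
  instead of raising, so one empty slice cannot abort a series.
- Truncation screening is report-and-flag only: the fraction of the
  outermost 2-pixel border ring above −600 HU, compared by the caller to
  a cutoff (default 0.05). No attenuation correction for truncated
  contours is attempted — such cases are rare enough in torso imaging
  that exclusion is the appropriate handling.
- Tube-current metadata: the integer DICOM element is written alongside
  its floating-point companion; series lacking per-slice currents read
  back with currents unset and are refused by the I_min sweep (skipped
  with a warning and counted).

## Problem sizes used in the test suite

Phantom tests render 512-px slices (0.8-mm pixels); end-to-end rendering
tests use 320-px slices at 1.5 mm and a handful of examinations; cohort
tests run the full default cohort (200 records, profile-level only, no
image rendering). The full suite runs in a few seconds on one CPU.

## Known limitations

- Whole-image ROI assumes nothing but patient, couch and air in the FOV
  (no arms-down positioning artefacts, lines, or blankets).
- The couch model is a homogeneous strip; real couches are curved
  composites. Calibration-by-contour absorbs this in practice.
- The simulation of raised I_min is a hard threshold; it cannot simulate
  lowered I_min, I_max changes, or noise-index changes.
- Multi-frame enhanced CT objects and compressed transfer syntaxes beyond
  the I/O backend's native support are out of scope; CTDI_vol may be
  injected explicitly when absent from metadata.
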