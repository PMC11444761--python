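# Methods

`nestescape` analyses tri-axial accelerometer recordings of sea-turtle
hatchlings during the cryptic digging-out period between hatching and
emergence at the sand surface. This note documents the models and
procedures, the parameters that matter, the synthetic-data generator used
for verification, and the design choices made where conventions were open.

## Signal model

A carapace-mounted logger samples acceleration in g at 1 Hz on three body
axes: surge (x, longitudinal), sway (y, lateral) and heave (z,
dorsoventral), calibrated to ±2 g. The raw signal decomposes as

    raw = SA + DBA + noise

where **SA** (static acceleration) is the gravity-dominated low-frequency
component, estimated per axis by a centred running mean over `window_s = 3 s`
(an odd number of samples, so the window is symmetric; the first and last
`floor(w/2)` samples of each contiguous segment are dropped rather than
shrunk, keeping SA unbiased at the edges), and **DBA** (dynamic body
acceleration) is the movement-generated residual `raw − SA` per axis.
The scalar movement-intensity proxy is the vectorial DBA,

    VeDBA = sqrt(XDBA² + YDBA² + ZDBA²),

the Euclidean norm of the three DBA components. Consequences used as test
invariants: VeDBA is non-negative; it satisfies the Pythagorean identity
with the per-axis DBA; it is invariant to constant per-axis offsets (any
fixed reorientation of gravity) and to rigid rotations of the DBA vector.

## Body orientation

With the logger flat on the carapace, six cardinal postures map onto signed
gravity axes: head-up (x = +1 g), head-down (x = −1 g), right-side-up
(y = +1 g), right-side-down (y = −1 g), carapace-up (z = +1 g),
carapace-down (z = −1 g). A sample earns a canonical label when at least one
axis reaches `|0.70| g`; below that it is an *intermediate* posture, which is
why canonical proportions sum to less than 1. When more than one axis
exceeds 0.70 g (possible during vigorous movement), the axis with the
largest magnitude wins; exact ties break by the fixed priority x > y > z.
For a unit static vector this rule coincides with nearest-pole (smallest
angle) assignment wherever it assigns a canonical label, which the tests
check against a brute-force angular oracle.

The orientation time budget is computed over the whole recording, including
the initial reorientation phase. The **head-up onset** — the anchor for all
activity analyses — is the first time x ≥ 0.7 g holds for at least 10
consecutive seconds; runs are broken by sub-threshold samples and by
recording gaps. Classification uses raw values (not SA): at 1 Hz with 3-s
smoothing the two differ negligibly in static postures, and raw values are
the convention for threshold-style posture filters.

## Activity segmentation

Working on the VeDBA series between head-up onset and emergence:

* **Pulse** — one sample with VeDBA strictly above the noise threshold
  (default 0.035 g; a sample exactly at threshold is inactive).
* **Inter-pulse interval (IPI)** — the elapsed time between consecutive
  pulses whenever it exceeds one sample period; consecutive supra-threshold
  seconds belong to one activity run and produce no IPI. IPI durations are
  the raw gap (not gap minus one sample); the alternative is a flag.
* **IPI histogram** — nine fixed duration bins with left-open/right-closed
  edges (1–60 s, 61 s–10 min, 10–30 min, 30 min–1 h, then five half-hour
  bins to 3 h, and 3 h+). The edge convention makes the printed labels a
  partition: an IPI of exactly 600 s falls in 61 s–10 min. Bin shares are
  fractions of total IPI time by default; normalisation by total analysis
  time is available.
* **Bout** — a maximal run of pulses whose successive gaps are at most the
  merge threshold (1, 5 or 10 min; a gap exactly at threshold merges). Bout
  duration spans first to last pulse plus one sample period, so a lone
  pulse forms a 1-s bout.

Recording gaps (from trimming handling periods, or logger dropouts) are
unobserved time: no IPI or bout spans one; each contiguous segment is
processed independently. Medians use the midpoint convention for even
counts. A sensitivity sweep re-runs the segmentation at 0.025 / 0.035 /
0.045 / 0.055 g and reports pulse counts (necessarily non-increasing in the
threshold) and histogram shifts.

## Diel analysis

Mean VeDBA (unfiltered — the noise floor is not zeroed; filtered averaging
is a flag) is averaged within six fixed 4-h local-clock blocks (12–16,
16–20, 20–24, 00–04, 04–08, 08–12) for two windows per nest: the first 24 h
after head-up onset and the last 24 h before emergence. Local clock time is
carried as a seconds-past-midnight offset of the trace epoch. Nests whose
two windows overlap (emergence − onset < 48 h) are flagged and excluded
from the cohort model. Windows not aligned to block boundaries contribute
split block occurrences pooled by label.

The cohort model is a fixed-effects two-way ANOVA of cell means,
`mean_vedba ~ period * block`, with sequential (type I) sums of squares —
identical to marginal SS on the balanced design — followed by one-way
per-period ANOVAs across blocks. Cells are treated as independent
observations (no nest random effect, matching the small-cohort convention
of the analysis this reproduces); p-values come from the F distribution
with the model's degrees of freedom, uncorrected. Degenerate inputs with a
zero-variance term report F = 0, p = 1 for that term rather than 0/0. The
implementation is statsmodels OLS + `anova_lm`; tests verify it against a
hand-rolled closed-form SS oracle to 1e-9 and check the period term's
type-I error (0.05 ± 0.02 over 2000 null tables).

## Synthetic-data generator

The simulator produces seeded, ground-truth-annotated traces with the
structure the analysis assumes. Defaults (units, rationale):

| parameter | default | meaning |
|---|---|---|
| `duration_h` | 72 | recording length; study recordings ran ~31–92 h |
| `sample_rate` | 1 Hz | study rate |
| schedule fractions | CU .10, RU .08, INT .10, RD .04, CD .01, HU .67 | posture budget; carapace-up first (placement posture), head-up last and sustained |
| `transition_s` | 30 | slerp reorientation between postures; generates realistic DBA artefacts |
| `ipi_law` | lognormal, median 420 s, σ = 1.3 | skewed inactivity: ~7% of IPIs < 60 s, ~0.6% > 3 h |
| `bout_law` | lognormal, median 8.5 s, σ = 0.8 | brief activity bouts |
| `pulse_dba_magnitude` | 0.12 g (σ = 0.4, lognormal) | per-second stroke magnitude; no quantitative field distribution exists, chosen to sit well clear of both the noise floor and the posture filter |
| `axis_mix` | (0.08, 0.35, 1.0) | z-dominant digging with secondary yaw, minimal surge |
| `noise_sd` | 0.005 g/axis | buried-logger floor; VeDBA 99th percentile ≈ 0.014 < 0.02 |
| `diel_night_gain` | 1 (off) | optional ×k activity rate, 20:00–04:00 of the final 24 h |

Within a bout the dynamic vector alternates sign each second (a 1 Hz
pitching stroke). This matters numerically: the 3-point running mean maps
an alternating stroke to DBA of magnitude `(2·m_t + m_{t−1} + m_{t+1})/3` —
it never cancels, so every injected pulse is detectable. Had strokes been
drawn i.i.d., sign cancellations inside the smoothing window would
randomly erase true pulses and no generator magnitude could guarantee
recoverability.

An intermediate-posture phase uses the oblique unit vector (1,1,1)/√3, each
component 0.577 < 0.70, so it classifies as intermediate by construction.

The default IPI law is unimodal. A bimodal mixture (44% short lognormal,
median 15 s; 56% long, median 1300 s) mirroring the short-burst/long-rest
time budget is provided as `IPI_MIXTURE_LAW`, but it is not the default:
its overall median falls in the density trough between the components, and
the asymptotic standard error of a sample median, `1/(2 f(m) √n)`, is then
~12% at cohort-scale IPI counts — the median of such a law is not a
recoverable parameter at these sample sizes, while the unimodal law's
median recovers to within a few percent.

Ground truth records the noiseless static-field posture per sample, the
head-up onset implied by the schedule, and every injected pulse, IPI and
bout. Pulse recovery is scored with a ±1-sample matching tolerance: the
centred running mean leaks ~1/3 of a bout-edge stroke into the adjacent
second, an artefact of the gravity filter rather than a detection error.

**What the generator does not emulate** — intra-pulse autocorrelation
(strokes are independent across seconds), biomechanics (no limb model, no
sand physics), temperature, logger drift or clipping saturation, and
cooperative digging by clutch-mates. Passing recovery tests therefore show
the *pipeline* is correct under the assumed statistical structure, not that
the structure is a complete model of real nests.

## Numerical choices and degenerate inputs

* Sample spacing must be an integer multiple of the sample period within
  1e-6 s; larger multiples are recorded as gaps, anything else is rejected.
* Out-of-range samples (|a| > 2 g) are clipped and flagged, preserving
  timing structure, rather than dropped.
* Trimming that splits a trace keeps the longest contiguous piece and
  reports the discarded ones; removing everything is an error.
* Strict/inclusive boundaries: pulse comparison is strict (>); the posture
  filter and onset rule are inclusive (≥); bout merging is inclusive (≤).
* Gap and threshold comparisons carry a 1e-9 s guard against float jitter.
* Written CSVs round-trip exactly (full-precision floats; reads use
  round-trip float parsing).

## Problem sizes used in verification

The test suite verifies segmentation against a brute-force loop oracle on
1000 random series of 200–1200 samples across all threshold combinations,
ANOVA against the closed-form oracle on 200 random balanced 8×2×6 tables
plus 2000 null tables for calibration, and parameter recovery on ten
seeded 72-h nests (2.6 M samples); `scripts/acceptance.py` reruns the full
chain on a ten-nest cohort (eight 72-h nests with night gain 3, two 40-h
nests that trigger the overlap exclusion) plus three 1-h buried-logger
calibrations.

## Known limitations

* One fixed clock offset per run; no timezone database or DST handling.
* Emergence time is a config input, not inferred from the signal.
* No mixed-effects alternative to the independence assumption in the diel
  ANOVA.
* No continuous pitch/roll estimation; the six-pole scheme only.
* The binary logger export format is out of scope; ingestion is CSV with a
  configurable column map.
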