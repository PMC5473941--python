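# Methods

This note documents the models, defaults and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Single-molecule binding kinetics

**Acquisition model.** TIRF movies are discrete frames: 100 ms exposure +
25 ms readout delay, i.e. a 125 ms frame cycle (8 fps). All event times are
multiples of the cycle. The scoreable minimum is 2 frames (0.25 s),
implemented as `duration ≥ 2 × cycle` — the threshold phrasing "greater
than 2 frames (0.25 s)" equates the two readings, so the inclusive
comparator is the default and a strict mode is available
(`include_boundary=False`). Events still bound at movie end are flagged
right-censored and excluded from dwell analysis by default, since their
dwell is unknown.

**Binding rate.** Each microtubule is one independent observation:
`rate = n_events / (length_um × duration_s × conc_nM)`, summarized as mean
± SEM over microtubules. SEM is always sample sd (n−1 denominator) / √n.

**Dwell survival fit.** The survival curve is the percentage of molecules
still attached at each multiple of the 0.125 s bin:
`S(t) = 100 × #(dwell ≥ t)/n`, fitted with
`S(t) = 100 [w e^(−t/τ_f) + (1−w) e^(−t/τ_s)]`, constraints 0 < w ≤ 1,
0 < τ_f ≤ τ_s (the fast phase is by definition the smaller time constant;
if the optimizer converges with the labels swapped they are relabelled and
w ↦ 1−w). The fit target is the survival curve, not a density histogram,
and the least squares are unweighted. No plateau term is included — a bound
motor eventually unbinds — and the nested single-exponential case is
handled naturally (w → 1 or τ_f ≈ τ_s). Initialization: τ_f = 0.5×, τ_s =
2× the curve's trapezoidal mean dwell, w = 0.8, plus 4 jittered restarts
from a fixed internal seed; the lowest residual sum of squares wins.

**Left truncation.** Discarding events shorter than the scoring threshold
left-truncates the dwell sample; a plain two-phase fit to such data returns
a badly distorted fast-phase weight (the curve is pinned at 100% out to the
threshold). `TwoPhaseDecayModel.fit(left_truncation_s=…)` therefore fits
the conditional survival `S(t) = 100 N(t)/N(t₀)` over grid points at or
beyond the threshold, where N is the untruncated mixture survival, and
recovers the untruncated parameters. Because dwells are rounded to the
nearest whole frame, a recorded dwell of k frames corresponds to a true
dwell ≥ (k − ½) frames; the pipeline passes `time_offset_s = cycle/2` to
account for this.

**Detection-corrected kon.** The raw event rate counts only scoreable
events. `analyze_binding_assay` (default `correct_detection=True`) divides
it by the detection probability `P(dwell ≥ threshold − cycle/2)` evaluated
under the fitted mixture, giving the total arrival rate. With the default
dwell mixture (w = 0.8, τ_f = 0.3 s, τ_s = 3 s) roughly 40% of binding
events are too short to score, so the correction matters; without it the
derived Kd would be overestimated by the same factor. The raw rate is
reported alongside (`kon_raw`).

**Kd.** `koff = 1/τ_fast`; `Kd(nM) = (koff/kon) × N_sites` with
`N_sites = protofilaments × (1000/repeat_nm) × accessible_fraction`;
defaults 13, 8.1 nm, ½ give 802.47, rounded to 802. The per-repeat versus
pooled question (average of per-repeat τ_fast values vs one pooled fit) is
left to the caller: `analyze_binding_assay` fits one pooled curve per call,
and per-repeat averaging is done by calling it per repeat and averaging —
both routes use the same fit.

## Motility

A track is processive iff duration **>** 0.625 s, |net displacement|
**>** 500 nm (both strict, matching "longer than"/"greater than"), and the
excursion against the net direction never exceeds 2 pixels (0.32 µm).
"Unidirectional" has no published numeric definition; the bounded
counter-excursion, computed from the running extremum, is this package's
operationalization and the tolerance is a parameter. Displacement is 1-D,
along the microtubule-axis coordinate carried by the track.

The processive-event rate is reported in two conventions —
`n/(length × time × conc_pM)` and, without the time term,
`n/(length × conc_pM)` — because published figure legends and methods
sections disagree on whether the per-second normalization is included;
both are emitted rather than guessing.

Gliding velocity: per-track mean of |Δx|/Δt over consecutive samples of
the filament's leading edge (3 s sampling, 0.16 µm pixels), then mean ±
SEM over tracks. Pixel quantization bounds the per-track error by one
pixel per interval (±0.053 µm/s at those settings).

## EM population statistics

Class proportions use the micrograph-resampling scheme: shuffle the
micrograph list with the plan's seed, take 25 per round for 9 rounds, each
micrograph used at most once (the plan is rejected if fewer than 225
micrographs exist); per round the class proportion is class count / total
count, and the summary is mean ± SEM over the 9 rounds. Ambiguous
particles stay in the denominator (the published phi + open percentages
sum below 100%, implying a third category in the total). The SEM is over
rounds, not micrographs. Orientation summaries are pooled proportions
over all labelled particles, with the same resampling scheme reused for an
SEM when a plan is supplied.

Distance histograms are particle-count-weighted with 2.5 nm bins,
left-closed right-open starting at 0 (the binning origin is a convention
choice; a distance exactly on an edge goes to the upper bin).

`classify_pair_orientation` is a geometric surrogate for what is a visual
assignment in practice: inverted if both stalk vectors point at the
opposite motor within an angular tolerance (default 20°), parallel if
their mutual angle is within tolerance, else ambiguous; inverted is tested
first.

## SEC quantification

Traces are normalized by subtracting the (linearly interpolated) A280 at
5 mL — a pre-void volume where only buffer absorbs — which makes the
result invariant to constant offsets. AUC fractions use trapezoidal
quadrature on the native grid with interpolated window endpoints; no
resampling. Negative post-normalization values are clipped to zero before
integration (they would otherwise represent negative protein); a no-clip
mode exists. Peak windows are explicit inputs: identifying which fractions
contain the complex is a gel-based decision outside this package. Group
comparison is an unpaired two-tailed Student's t-test (equal variance by
default, Welch switchable); identical zero-variance groups return p = 1
with a warning instead of NaN.

## Cell-image quantification

Fixed-cell: SUM projection of the 11 slices around the structure (window
must lie inside the stack; no silent truncation), 12×12 pixel ROI at the
structure and three 12×12 cytoplasmic ROIs. Centrosome signal subtracts
the **mean** of the three backgrounds; spindle-pole signal divides by
their **median** — the two conventions are deliberately not unified, as
both are in use. ROI statistic is the per-pixel **mean** by default
(subtraction and division are only dimensionally coherent if signal and
background use the same statistic); `statistic="sum"` is available. Even
ROI sizes anchor the named center at index (size/2, size/2) of the window.
Negative background-subtracted values pass through.

Live-cell: per-timepoint MAX z-projections; 3×3 ROIs placed on foci at the
final frame and tracked backward by moving each ROI to the brightest pixel
within a 1-pixel radius (manual ROI dragging, made deterministic); when a
focus's corrected intensity reaches zero it is considered disappeared and
its ROI freezes for all earlier timepoints. Summary is mean ± SD across
foci per timepoint.

Group comparison: per experiment, Shapiro–Wilk per condition and Bartlett
across conditions (diagnostics), Kruskal–Wallis omnibus, then pairwise
paired Wilcoxon with pairing by within-experiment measurement order
(pairing is the caller's responsibility; unequal-length groups are skipped
with a warning). The reported p per comparison is the maximum across
experiments — the most conservative replicate.

## Synthetic generators

The generators produce data with the distributional structure each
analysis assumes, not realistic images or micrographs: dwells are drawn by
Bernoulli(fast fraction) then an exponential of that phase's τ; arrivals
are Poisson and uniform in time; event starts snap to the next frame
boundary and dwells round to the nearest whole frame (sub-frame events are
discarded and logged, movie-end events flagged censored); tracks are ideal
static/diffusive/constant-velocity-with-exponential-run motions plus
optional Gaussian localization noise and pixel quantization; particle
counts are Poisson per micrograph with iid multinomial labels (no
per-micrograph clustering of conformations); inter-motor distances are
uniform in their range (10–45 nm open, 15–25 nm DDB) with one center pair
per 2D class; chromatograms are exact Gaussians on a flat baseline; cell
images are 2-D Gaussian foci on a uniform background with Poisson or
Gaussian noise, clipped to the 16-bit range. Defaults are the study
conditions where stated (0.29/0.58 nM motor, 8 fps, 300 micrographs ×
~40 particles, class probabilities 75/22/3, orientation 52/15/33,
DDB fractions 11.5%/27.3%) and zero noise elsewhere so analytic oracles
apply. Passing tests on these data therefore validates the estimators
under their own model assumptions — they say nothing about kymograph
scoring errors, drift, uneven illumination, or class-assignment ambiguity
in real data.

Every generator takes a seed and is byte-reproducible; every generator
returns a ground-truth sidecar sufficient for parameter-recovery tests
(including a closed-form per-window Gaussian-mass callable for
chromatograms).

## Pipeline and problem sizes

The driver fans a single global seed out to per-stage seeds by CRC-32
hashing of the stage name, so stages are independently reproducible, and
writes a deterministic report bundle (resolved config, metrics JSON, CSV
tables, checksummed run log — no wall-clock timestamps, so fixed-seed runs
are byte-identical). The default demo sizes — 50 microtubules × 360 s
(≈2000 binding events), 300 micrographs × ~40 particles, 4 SEC replicates
per group, 60 motility tracks — are chosen to match the scale of the
corresponding real datasets while keeping a full run in seconds.

## Known limitations

- No maximum-likelihood dwell fitting with censoring; censored events are
  simply excluded (their information is lost).
- The truncation-aware fit assumes the two-phase model is correct below
  the threshold, where it is unobserved by construction.
- No spot detection, kymograph tracing, or 2D classification: event
  tables, tracks and class labels are inputs, produced upstream or by the
  generators.
- The live-cell backward tracker follows the brightest nearby pixel; it
  will follow a brighter neighbour that drifts within one pixel of a
  dimmer focus.
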