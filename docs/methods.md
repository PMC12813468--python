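# Methods

## Scope

The package implements a complete desk-scale pipeline for longitudinal
structural-MRI scalar features: a synthetic five-group cohort
generator, a canonical session-level feature table, a quantized
time-heatmap encoder, small CNN/FCN classifiers, Grad-CAM temporal
attribution, and a nonparametric group-comparison protocol.  MRI
preprocessing (segmentation, lesion filling, spatial normalization)
and voxel-wise inference are upstream of the feature tables and are
out of scope: the pipeline starts where a table of per-session scalar
features exists.

## Synthetic cohort generator

### What it emulates

Five diagnostic strata (AD=0, CN=1, MCI=2, EMCI=3, LMCI=4) with
published participant counts (22/22/25/20/25 = 114), per-group session
counts, and per-group feature statistics: cross-sectional baseline
mean/SD for CSF, GM, WM volumes (ml), mean cortical thickness (mm) and
WMH volume (ml); annual-change median/IQR and the fraction of subjects
increasing; and plausible raw-measurement ranges.

### Trajectory model

Per subject and feature: `value(t) = baseline + slope·t/12 + ε`, with
`baseline ~ N(μ, σ)`, `ε ~ N(0, (f·σ)²)` per visit, and values clipped
to the plausible range (WMH floored at 0).  TIV is constant per
subject, `~ N(1500, 140)` ml; the source tables print no TIV moments,
so these are field-typical values consistent with the printed %TIV
ranges against the absolute volumes.

**Slope law.** The published change statistics give three quantiles and
a sign count.  The per-subject annual slope is drawn by inverse
transform from a piecewise-linear quantile function anchored at
(0.25, q25), (0.5, median), (0.75, q75) and (1 − frac_increasing, 0),
with linear tail extrapolation.  This honors the median, the IQR and
P(slope > 0) exactly and simultaneously; a two-piece parametric scale
mixture could only approximate the joint constraint.  Inconsistent
parameter combinations (sign fraction contradicting the quantiles) are
rejected at construction.

**Measurement noise.** The per-visit residual SD defaults to 1% of the
feature's between-subject baseline SD (configurable).  Scan–rescan
error of automated volumetry is small relative to between-subject
spread, and the default keeps the median of per-subject OLS slope
estimates an essentially unbiased estimate of the generative median
even for the shortest follow-up group (3–4 sessions): with a large
residual SD, the noise on each subject's fitted slope convolves with
the strongly asymmetric slope distribution and visibly biases the
sample median, which would defeat parameter-recovery checks.

**Schedules.** Session count uniform over the group's observed range;
inter-visit gaps uniform on [3, 12] months (3 months = one encoder
bin, the minimum resolvable spacing); visits truncated at the group's
maximum follow-up.  This reproduces the irregular-visit structure but
not the printed follow-up medians — a group with 4–5 sessions cannot
span 78 months at ≤12-month gaps — which is acceptable because every
downstream stage conditions on the realized schedule.

**GM/WM/CT slopes.** Numeric change statistics are published only for
CSF and WMH; the GM/WM/CT longitudinal rows are qualitative.  Their
slope parameters are package constants encoding the reported direction
and severity gradient (fastest decline in AD, minimal change in CN;
e.g. CT: −0.045 mm/yr in AD down to −0.005 in CN).  The sign
conventions are explicit per-group profile fields, so a user who reads
the trends differently can override them without touching code.

**Determinism.** Each subject's randomness comes from a generator
keyed on (cohort seed, group code, subject index); a cohort is
byte-identical under a fixed seed and independent of generation order.

### What it does not emulate

Within-subject correlation between features (channels are independent),
non-linear trajectories, informative dropout, site/scanner effects, and
the full multivariate shape of real data.  Consequently, passing tests
show the pipeline is correct and well-calibrated — not that the
headline classification accuracies reported on real restricted cohorts
are reproducible.  On cohorts generated from the published group
moments, test accuracies land well above chance (~0.3–0.75 depending
on feature and architecture) but far below 99%: the published moments
overlap heavily, and part of the separability in the simulation comes
from group-specific session counts rather than feature values.

## Feature table

One row per scan session with hierarchical label `group.subject.scan`
(e.g. `0.1.1` = first scan of the first AD subject), months from the
subject's first scan (baseline = 0, sessions sorted by time before
assignment), TIV, absolute volumes, and %TIV columns stored
redundantly and validated on read (tolerance 1e−9).  Cortical
thickness is kept in mm: a thickness is not a volume fraction, even
where source tables list it under %TIV headings.  CSV is UTF-8,
comma-separated, '.'-decimal, floats in shortest round-trip form.

## Heatmap encoding

* Grid: 28 half-open 3-month bins [3k, 3k+3) over 0–84 months; t = 84
  joins bin 27.  Sessions outside the window are dropped by callers.
* Multiple sessions in one bin are averaged.
* C1 (value): min–max scaled to [0, 255]
  (`(f − f_min)/(f_max − f_min) × 255`, clipped; degenerate range maps
  to 0), then snapped to 2^b uniform levels,
  `round(x/255·(L−1))·255/(L−1)` — idempotent, max error 255/(2(L−1)).
  Supported b: 2, 3, 4, 8, 16.
* C2 (rate): slope between consecutive occupied bins at bin-center
  times, units per month; first occupied bin 0.  Scaled like C1 but
  left unquantized.  An optional mode additionally divides by the
  total study duration (180 months); it is off by default because that
  normalization only rescales C2 uniformly before min–max scaling and
  the printed formula for it is ambiguous.
* C3 (mask): binary availability; C1/C2 forced to 0 where C3 = 0 so
  the models can distinguish missing bins from true zeros.
* Normalization statistics (f_min/f_max for values and rates) are
  computed on the training split only and frozen for test-time
  encoding, avoiding leakage through the scaling.

## Classifiers

Implemented on numpy (inputs are 1 × 28 × 3; no GPU framework is
warranted at this size), with analytically verified backpropagation
(gradient checks against central differences are part of the test
suite) and Adam.  The nominal 3×3 kernels of the printed architecture
act on height-1 inputs where the off-row taps only see zero padding,
so convolutions are width-3 along time — the exact same computation —
and 2×2 pooling degenerates to 1×2 along time.  The FCN input has 3
channels (value, rate, mask), consistent with the encoder; its per-bin
softmax output is reduced to a subject-level prediction by averaging
per-bin probabilities (mean rather than majority keeps the reduction
differentiable and tie-free).  The FCN loss broadcasts the subject
label to all 28 bins; a mask-weighted variant (ignoring empty bins) is
available but off by default.  Heatmap intensities are divided by 255
at the network boundary.

Training is invariant to dataset assembly order: samples are brought
into a canonical lexicographic order before seeded epoch shuffling.
A NaN loss aborts with a diagnostic rather than training through it.

Splits are stratified 80:20 at subject level (one heatmap per subject
per feature, so subject = sample) via scikit-learn, seeded; classes
with fewer than 2 subjects are rejected.

## Evaluation

Confusion-matrix metrics computed from first principles: per-class
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), accuracy =
trace/total.  Headline aggregates are support-weighted; micro averages
(identically equal to accuracy for single-label data — asserted as an
algebraic property test) are emitted alongside.  Empty classes are
reported as 0 and flagged rather than silently dropped.  Test loss is
final cross-entropy on the held-out subjects.

## Grad-CAM

Target layer: the last convolution's post-ReLU activation, excluding
the logits head.  Per-filter weights are the class-logit gradients
averaged over time; the map is ReLU(weighted activation sum), min–max
normalized to [0, 1], linearly interpolated from the pooled width (7
bins for the CNN) back to 28.  Maps default to the predicted class;
group averages use true-class membership.  All-zero gradients yield a
flagged degenerate map instead of NaNs.  The weight-randomization
check re-initializes a copy of the model, computes per-sample Spearman
correlations between trained and randomized maps, and reports the mean
with a bin-permutation p-value; informative maps decorrelate (the
trained-vs-trained reference is 1.0).

## Group statistics

Shapiro–Wilk (scipy's Royston implementation) per group × measure;
tie-corrected Kruskal–Wallis H referred to χ² with k−1 df (undefined
for all-identical data, reported as an error); natural log(1+x) on WMH
before testing — a strictly monotone transform, so H is provably
unchanged (property-tested), and the transform matters only for
descriptives and normality screening; Benjamini–Hochberg FDR via
statsmodels; Dunn z-tests on pooled mean ranks with tie correction as
the pairwise post-hoc (the conventional follow-up to Kruskal–Wallis;
the choice is an assumption, flagged as such).  Observations are scan
sessions by default; a subject-mean sensitivity mode is provided
because repeated measures violate the independence assumption and
inflate session-level type-I error.

## Problem sizes and tolerances

Parameter-recovery checks use 300–500 simulated subjects and compare
within 3 Monte-Carlo standard errors (bootstrap SE for the median,
analytic SEs for moments, plus a small allowance for the 1%
measurement noise).  Null-calibration checks use 2,000 replicates and
test the 5% rejection rate within 3 binomial SEs.  The end-to-end
sanity cohort has 150 subjects with group means 5 within-group SDs
apart and dense schedules (10–14 sessions), so that the heatmaps carry
signal in many bins; the nearest-centroid oracle for that cohort uses
the mask-aware per-subject mean of C1 (missingness there is
uninformative by construction).  These sizes keep the full test suite
under a minute of CPU while leaving comfortable statistical margins.

## Known limitations

* The generator's independence assumptions (features, visits) understate
  the structure of real cohorts; accuracies on simulated data are not
  comparable to values reported on real data.
* The piecewise-linear slope law has linear tails; extreme slopes
  beyond the printed quantiles are extrapolations.
* Session-level statistics ignore within-subject clustering (mitigated
  by the subject-level mode).
* The CNN/FCN are faithful to the printed small architectures; no
  regularization, early stopping or augmentation is applied, so on
  small noisy cohorts the models can overfit within their epoch budget.
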