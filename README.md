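# trajheat

Longitudinal structural-MRI scalar features — gray-matter, white-matter
and CSF volume, mean cortical thickness, and white-matter-hyperintensity
(WMH) load — encoded as small multi-channel "time heatmaps", classified
into five diagnostic groups (AD, CN, MCI, EMCI, LMCI) with compact
CNN/FCN models, and interpreted with Grad-CAM.  Because the MRI-derived
feature tables such studies use come from access-restricted cohorts, the
package includes a synthetic-cohort generator parameterized by published
group-level statistics, so the entire pipeline is runnable and testable
end to end.

## Who this is for

Researchers studying longitudinal neuroimaging biomarkers of Alzheimer's
progression who want (a) a reproducible reference implementation of the
tabular-to-image heatmap encoding and its classification/attribution
protocol, and (b) a principled simulator for irregularly-sampled
five-group volumetric trajectories.

## The model

**Cohort simulator.** Each subject in group *g* follows, per feature,

```
value(t) = baseline + slope · t/12 + ε,   ε ~ N(0, σ²)
```

with `baseline ~ N(μ_g, σ_g)` from the group's cross-sectional moments
and the annual `slope` drawn from a quantile-anchored law that honors
the group's published median, IQR and fraction-of-subjects-increasing
exactly (e.g. AD CSF: median +14.61 ml/yr, IQR +9.57 to +16.42, 14/15
increasing).  Visit schedules are irregular: session counts uniform over
each group's observed range, gaps uniform on [3, 12] months.

**Heatmap encoding.** The follow-up axis 0–84 months is split into 28
three-month bins.  Channel C1 holds the TIV-normalized feature value,
min–max scaled to [0, 255] and snapped to 2^b quantization levels
(b ∈ {2, 3, 4, 8, 16}); C2 holds the inter-visit slope ΔS/Δt, min–max
scaled; C3 is the binary availability mask separating missing bins from
true zeros.

**Classifiers.** A CNN (conv 32 → pool → conv 64 → pool → dense 128 →
softmax over 5 classes) and an FCN encoder–decoder (32/64 → 128
bottleneck → 64/32 → 1×1 conv) giving a per-bin class distribution,
trained per feature with Adam (lr 0.001), batch 32, sparse categorical
cross-entropy, subject-level stratified 80:20 split, 70 (CNN) / 50 (FCN)
epochs.  The networks are implemented on numpy directly (the inputs are
1 × 28 × 3), which keeps training deterministic and exposes the
gradients Grad-CAM needs.

**Interpretation and statistics.** Grad-CAM weights the last conv
layer's activations by time-averaged class-score gradients, giving a
[0, 1] importance profile over the 28 bins; group-averaged profiles
localize *when* each feature separates the groups.  Group comparisons
follow a nonparametric protocol: Shapiro–Wilk screening per group,
Kruskal–Wallis omnibus tests (χ², df = 4), log(1+WMH) transform, and
Benjamini–Hochberg FDR on Dunn pairwise contrasts.

## Worked example

```
python analysis/01_simulate_cohort.py      # -> results/cohort.csv
python analysis/02_group_statistics.py     # -> results/stats/
python analysis/03_encode_heatmaps.py      # -> results/heatmaps/
python analysis/04_train_classifiers.py    # -> results/classification_metrics.csv
python analysis/05_gradcam_attribution.py  # -> results/gradcam/
```

With the default seed, step 01 prints a cohort of **114 subjects / 628
sessions** (22/22/25/20/25 subjects in AD/CN/MCI/EMCI/LMCI).  Step 02
reports that all five measures separate the groups at the session level,
e.g.

```
measure         H  df            p
 csf_ml 26.647109   4 2.342635e-05
 wmh_ml 84.387694   4 2.045818e-17
```

(df = 4 because there are five groups; small p means the measure's
distribution differs across diagnostic strata).  Step 04 trains both
networks per feature; on this synthetic cohort the best cell is
`wmh_pct / FCN` with test accuracy 0.739 on 23 held-out subjects —
well above the 0.2 chance level but far below accuracies reported on
real restricted data, because the generator reproduces only the
published group *moments*, not the full multivariate structure of real
trajectories (see docs/methods.md).  Step 05 writes group-averaged
Grad-CAM profiles and prints the weight-randomization check, e.g.
`wmh_pct: randomized-weights map correlation -0.509` — far from the
trained-vs-trained correlation of 1.0, as expected for maps that carry
learned signal.

The same pipeline is available as a CLI: `trajheat simulate|stats|
encode|train|evaluate|gradcam` (see `trajheat --help`).

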