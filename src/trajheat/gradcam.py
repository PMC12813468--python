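"""Grad-CAM temporal attribution for the heatmap classifiers.

For a target class c, the gradient of the class logit with respect to
the last convolutional feature map is averaged over the time axis to
give one weight per filter; the ReLU of the weight-activation sum is
the importance profile, min-max normalized to [0, 1] and linearly
upsampled back to the 28 input bins.  Group-level profiles average the
per-subject maps over a diagnostic group.  A randomization sanity
check verifies that maps from a weight-reinitialized model decorrelate
from the trained maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from trajheat.classifiers import TrainedModel, prepare_inputs
from trajheat.nn import Conv1D, ReLU, Sequential, softmax

__all__ = ["AttributionMap", "gradcam_map", "group_average_map", "sanity_check"]


@dataclass
class AttributionMap:
    """Per-time-bin importance in [0, 1] for one (input, class) pair."""

    values: np.ndarray  # shape (n_bins,)
    class_code: int
    feature_name: str = ""
    degenerate: bool = False  # all-zero gradient; map carries no signal


def _target_conv_index(model: Sequential) -> int:
    """Index of the last conv layer's ReLU (its post-activation map).

    The final logits layer (Dense head or 1x1 conv head) is excluded:
    Grad-CAM attributes through it, not at it.
    """
    idx = None
    for i, layer in enumerate(model.layers[:-1]):
        if isinstance(layer, Conv1D) and i + 1 < len(model.layers) \
                and isinstance(model.layers[i + 1], ReLU):
            idx = i + 1
    if idx is None:
        raise ValueError("model has no convolutional layer")
    return idx


def _upsample_linear(profile: np.ndarray, width: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, num=len(profile))
    dst = np.linspace(0.0, 1.0, num=width)
    return np.interp(dst, src, profile)


def gradcam_map(trained: TrainedModel, heatmap_data: np.ndarray,
                target_class: int | None = None, *,
                output_width: int | None = None) -> AttributionMap:
    """Grad-CAM importance profile for one input heatmap.

    Parameters
    ----------
    heatmap_data
        One encoded heatmap, shape (n_bins, 3), on the [0, 255] scale.
    target_class
        Class whose logit is attributed; defaults to the model's
        predicted class.
    output_width
        Width to upsample the profile to (defaults to the input width).
    """
    model = trained.model
    x = prepare_inputs(heatmap_data[None, :, :])
    width = x.shape[1] if output_width is None else output_width
    tgt = _target_conv_index(model)

    outs = model.forward_collect(x)
    logits = outs[-1]
    subject_logits = logits.mean(axis=1) if logits.ndim == 3 else logits
    if target_class is None:
        target_class = int(subject_logits[0].argmax())

    # d(logit_c)/d(output): one-hot on the class, spread over positions
    # for per-bin heads
    seed = np.zeros_like(logits)
    if logits.ndim == 3:
        seed[0, :, target_class] = 1.0 / logits.shape[1]
    else:
        seed[0, target_class] = 1.0
    model.zero_grad()
    grad_act = model.backward_to(seed, tgt)  # (1, W', F)
    act = outs[tgt]

    weights = grad_act.mean(axis=1)  # (1, F): time-averaged gradients
    cam = np.maximum((act * weights[:, None, :]).sum(axis=2), 0.0)[0]
    degenerate = not np.any(grad_act) or cam.max() == cam.min()
    if cam.max() > cam.min():
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    else:
        cam = np.zeros_like(cam)
    return AttributionMap(_upsample_linear(cam, width), int(target_class),
                          trained.feature_name, degenerate)


def group_average_map(maps: list[AttributionMap]) -> AttributionMap:
    """Element-wise mean of same-shaped maps, re-normalized to [0, 1]."""
    if not maps:
        raise ValueError("need at least one map")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched shapes: {shapes}")
    mean = np.mean([m.values for m in maps], axis=0)
    if mean.max() > mean.min():
        mean = (mean - mean.min()) / (mean.max() - mean.min())
    return AttributionMap(mean, maps[0].class_code, maps[0].feature_name,
                          degenerate=all(m.degenerate for m in maps))


def _map_correlations(trained: TrainedModel, other: TrainedModel,
                      X: np.ndarray) -> np.ndarray:
    """Per-sample Spearman correlation between two models' maps.

    Samples whose map is constant under either model are skipped
    (correlation undefined)."""
    cors = []
    for i in range(len(X)):
        a = gradcam_map(trained, X[i])
        b = gradcam_map(other, X[i], target_class=a.class_code)
        if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
            continue
        rho = spearmanr(a.values, b.values).statistic
        if np.isfinite(rho):
            cors.append(rho)
    return np.array(cors)


@dataclass
class SanityCheckResult:
    mean_correlation: float
    p_value: float
    n_maps: int
    degenerate: bool = False


def sanity_check(trained: TrainedModel, X: np.ndarray, seed: int = 0,
                 n_permutations: int = 500) -> SanityCheckResult:
    """Weight-randomization test: trained vs re-initialized model maps.

    Re-initializes a copy of the model, computes Grad-CAM maps for both
    on the same inputs, and reports the mean per-sample rank correlation
    with a permutation p-value (bin-shuffling null).  Meaningful
    attributions should decorrelate (mean correlation near 0 relative
    to a trained-vs-trained comparison).
    """
    if len(X) < 2:
        raise ValueError("need at least 2 inputs")
    rng = np.random.default_rng(seed)
    randomized = TrainedModel(trained.model.reinitialize(rng), {}, trained.config,
                              trained.arch, trained.feature_name)
    cors = _map_correlations(trained, randomized, X)
    if cors.size == 0:
        return SanityCheckResult(float("nan"), float("nan"), 0, degenerate=True)
    observed = float(np.mean(cors))

    # permutation null: shuffle one map's bins within each pair
    null = np.empty(n_permutations)
    maps_a, maps_b = [], []
    for i in range(len(X)):
        a = gradcam_map(trained, X[i])
        b = gradcam_map(randomized, X[i], target_class=a.class_code)
        if np.ptp(a.values) > 0 and np.ptp(b.values) > 0:
            maps_a.append(a.values)
            maps_b.append(b.values)
    for p in range(n_permutations):
        vals = []
        for a, b in zip(maps_a, maps_b):
            rho = spearmanr(a, rng.permutation(b)).statistic
            if np.isfinite(rho):
                vals.append(rho)
        null[p] = np.mean(vals)
    p_value = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_permutations + 1))
    return SanityCheckResult(observed, p_value, len(cors))
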