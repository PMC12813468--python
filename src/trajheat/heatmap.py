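"""Encode one subject's longitudinal feature series as a time heatmap.

The time axis is divided into 28 half-open 3-month bins spanning 0-84
months.  Each heatmap row carries three channels:

* **C1** — the feature value, min-max scaled to [0, 255] and snapped to
  2^b quantization levels (b in {2, 3, 4, 8, 16});
* **C2** — the rate of change: the finite-difference slope between
  consecutive occupied bins (value units per month), min-max scaled to
  [0, 255] but left unquantized;
* **C3** — the availability mask, 1 where at least one scan falls in
  the bin, else 0, so the model can tell missing data from a true zero.

Normalization statistics (f_min/f_max per channel) are computed on the
training split only and frozen for test-time encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "QuantizationSpec",
    "NormStats",
    "Heatmap",
    "bin_index",
    "aggregate_bins",
    "rate_channel",
    "minmax_scale",
    "quantize",
    "compute_norm_stats",
    "encode_heatmap",
    "encode_dataset",
]

#: Total study duration (months) used by the optional rate
#: normalization mode; exceeds the 84-month encoding axis.
TOTAL_STUDY_MONTHS = 180.0

_SUPPORTED_BITS = (2, 3, 4, 8, 16)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform binning of the follow-up axis (defaults: 0-84 mo, 3-mo bins)."""

    bin_width_months: float = 3.0
    t_min: float = 0.0
    t_max: float = 84.0

    def __post_init__(self) -> None:
        n = (self.t_max - self.t_min) / self.bin_width_months
        if self.bin_width_months <= 0 or abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("grid span must be a positive multiple of bin width")

    @property
    def n_bins(self) -> int:
        return int(round((self.t_max - self.t_min) / self.bin_width_months))

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times in months, used for slope computation."""
        return self.t_min + (np.arange(self.n_bins) + 0.5) * self.bin_width_months


@dataclass(frozen=True)
class QuantizationSpec:
    """Bit depth of the value channel; n_levels = 2^bit_depth."""

    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.bit_depth not in _SUPPORTED_BITS:
            raise ValueError(
                f"unsupported bit depth {self.bit_depth}; supported: {_SUPPORTED_BITS}"
            )

    @property
    def n_levels(self) -> int:
        return 2 ** self.bit_depth


@dataclass(frozen=True)
class NormStats:
    """Frozen min-max normalization ranges for the value and rate channels."""

    value_min: float
    value_max: float
    rate_min: float
    rate_max: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        return cls(**json.loads(s))


@dataclass
class Heatmap:
    """A 3-channel encoded trajectory; ``data`` has shape (n_bins, 3)."""

    data: np.ndarray
    grid: TimeGrid
    spec: QuantizationSpec
    feature_name: str = ""
    label: str = ""

    @property
    def c1(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def c2(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def mask(self) -> np.ndarray:
        return self.data[:, 2]


def bin_index(t_months: float, grid: TimeGrid = TimeGrid()) -> int:
    """Map a time to its half-open bin [3k, 3k+3); t = t_max joins the last bin."""
    if t_months < grid.t_min or t_months > grid.t_max:
        raise ValueError(
            f"time {t_months} outside encoding window [{grid.t_min}, {grid.t_max}]"
        )
    idx = int(np.floor((t_months - grid.t_min) / grid.bin_width_months))
    return min(idx, grid.n_bins - 1)


def aggregate_bins(delta_t_months, values, grid: TimeGrid = TimeGrid()):
    """Per-bin mean value and availability mask.

    Multiple sessions falling in one bin are averaged.  Returns
    ``(binned_values, mask)`` with zeros wherever the mask is 0.
    """
    t = np.asarray(delta_t_months, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("delta_t and value lists must be aligned")
    out = np.zeros(grid.n_bins)
    mask = np.zeros(grid.n_bins)
    counts = np.zeros(grid.n_bins)
    for ti, vi in zip(t, v):
        b = bin_index(ti, grid)
        out[b] += vi
        counts[b] += 1
    occupied = counts > 0
    out[occupied] /= counts[occupied]
    mask[occupied] = 1.0
    return out, mask


def rate_channel(binned_values, mask, grid: TimeGrid = TimeGrid(), *,
                 normalize_by_total: bool = False,
                 total_months: float = TOTAL_STUDY_MONTHS) -> np.ndarray:
    """Raw rate-of-change channel from binned values.

    For each occupied bin after the first occupied bin, the slope
    ``(S(t2) - S(t1)) / (t2 - t1)`` between it and the previous
    occupied bin, evaluated at bin-center times (value units per
    month).  The first occupied bin and all empty bins are 0.  With
    ``normalize_by_total`` the slope is additionally divided by the
    total study duration (180 months).
    """
    v = np.asarray(binned_values, dtype=float)
    m = np.asarray(mask, dtype=float)
    rate = np.zeros(grid.n_bins)
    occ = np.flatnonzero(m > 0)
    centers = grid.bin_centers
    for prev, cur in zip(occ[:-1], occ[1:]):
        dt = centers[cur] - centers[prev]
        rate[cur] = (v[cur] - v[prev]) / dt
    if normalize_by_total:
        rate = rate / total_months
    return rate


def minmax_scale(values, f_min: float, f_max: float) -> np.ndarray:
    """Scale to [0, 255]: ``(f - f_min) / (f_max - f_min) * 255``.

    Out-of-range inputs are clipped; a degenerate range (f_max == f_min)
    maps everything to 0.
    """
    if f_max < f_min:
        raise ValueError("f_max must be >= f_min")
    v = np.asarray(values, dtype=float)
    if f_max == f_min:
        return np.zeros_like(v)
    return np.clip((v - f_min) / (f_max - f_min) * 255.0, 0.0, 255.0)


def quantize(scaled_values, spec: QuantizationSpec) -> np.ndarray:
    """Snap [0, 255] values onto 2^b uniform levels (kept on the 0-255 scale).

    ``x -> round(x / 255 * (L - 1)) * 255 / (L - 1)``; idempotent, with at
    most L distinct outputs and per-entry error <= 255 / (2 (L - 1)).
    """
    v = np.asarray(scaled_values, dtype=float)
    if np.any(v < 0) or np.any(v > 255):
        raise ValueError("quantize expects values in [0, 255]")
    L = spec.n_levels
    return np.round(v / 255.0 * (L - 1)) * (255.0 / (L - 1))


def compute_norm_stats(times_list, values_list, grid: TimeGrid = TimeGrid(), *,
                       normalize_by_total: bool = False) -> NormStats:
    """Min-max ranges over a collection of subjects (the training split).

    Value range is taken over occupied-bin values, rate range over
    occupied-bin raw rates, so test-time encoding reuses frozen
    statistics instead of leaking its own extremes.
    """
    all_vals, all_rates = [], []
    for t, v in zip(times_list, values_list):
        bv, m = aggregate_bins(t, v, grid)
        r = rate_channel(bv, m, grid, normalize_by_total=normalize_by_total)
        occ = m > 0
        all_vals.append(bv[occ])
        all_rates.append(r[occ])
    av = np.concatenate(all_vals) if all_vals else np.zeros(1)
    ar = np.concatenate(all_rates) if all_rates else np.zeros(1)
    return NormStats(float(av.min()), float(av.max()), float(ar.min()), float(ar.max()))


def encode_heatmap(delta_t_months, values, norm_stats: NormStats,
                   spec: QuantizationSpec = QuantizationSpec(),
                   grid: TimeGrid = TimeGrid(), *,
                   normalize_by_total: bool = False,
                   feature_name: str = "", label: str = "") -> Heatmap:
    """Encode one subject's series into a (n_bins, 3) heatmap.

    C1 = quantize(minmax(binned values)); C2 = minmax(raw rates),
    unquantized; C3 = binary mask.  C1 and C2 are forced to 0 wherever
    C3 = 0.  Sessions outside the grid window must be dropped by the
    caller; an input with no in-window session raises.
    """
    t = np.asarray(delta_t_months, dtype=float)
    if t.size == 0:
        raise ValueError("no sessions inside the encoding window")
    binned, mask = aggregate_bins(t, values, grid)
    rate = rate_channel(binned, mask, grid, normalize_by_total=normalize_by_total)
    c1 = quantize(minmax_scale(binned, norm_stats.value_min, norm_stats.value_max), spec)
    c2 = minmax_scale(rate, norm_stats.rate_min, norm_stats.rate_max)
    c1[mask == 0] = 0.0
    c2[mask == 0] = 0.0
    data = np.stack([c1, c2, mask], axis=1)
    return Heatmap(data, grid, spec, feature_name=feature_name, label=label)


def encode_dataset(table: pd.DataFrame, feature_col: str,
                   spec: QuantizationSpec = QuantizationSpec(),
                   grid: TimeGrid = TimeGrid(), *,
                   norm_stats: NormStats | None = None,
                   norm_subjects: set[tuple[int, int]] | None = None,
                   normalize_by_total: bool = False):
    """Encode every subject in a feature table for one feature column.

    Sessions beyond the grid window are dropped.  ``norm_stats`` may be
    supplied (frozen from a training split); otherwise it is computed
    from ``norm_subjects`` (or, failing that, all subjects).

    Returns
    -------
    X : ndarray, shape (n_subjects, n_bins, 3)
    y : ndarray of group codes
    subjects : list of (group_code, subject_num)
    norm_stats : NormStats actually used
    """
    groups = []
    for (g, s), sub in table.groupby(["group_code", "subject_num"]):
        keep = (sub["delta_t_months"] >= grid.t_min) & (sub["delta_t_months"] <= grid.t_max)
        sub = sub[keep]
        if len(sub) == 0:
            continue
        groups.append(((int(g), int(s)),
                       sub["delta_t_months"].to_numpy(dtype=float),
                       sub[feature_col].to_numpy(dtype=float)))
    if not groups:
        raise ValueError("no subject has sessions inside the encoding window")
    if norm_stats is None:
        sel = groups
        if norm_subjects is not None:
            sel = [g for g in groups if g[0] in norm_subjects]
            if not sel:
                raise ValueError("norm_subjects selects no subject")
        norm_stats = compute_norm_stats([g[1] for g in sel], [g[2] for g in sel],
                                        grid, normalize_by_total=normalize_by_total)
    X, y, subjects = [], [], []
    for (g, s), t, v in groups:
        hm = encode_heatmap(t, v, norm_stats, spec, grid,
                            normalize_by_total=normalize_by_total,
                            feature_name=feature_col, label=f"{g}.{s}")
        X.append(hm.data)
        y.append(g)
        subjects.append((g, s))
    return np.stack(X), np.array(y, dtype=int), subjects, norm_stats


def save_heatmap_png(hm: Heatmap, path) -> None:
    """Export a heatmap as a grayscale PNG (one channel per image row).

    8-bit depths and below export as 8-bit PNG; 16-bit as 16-bit PNG.
    """
    from PIL import Image

    arr = hm.data.T  # (3, n_bins): rows C1, C2, C3(x255)
    img = arr.copy()
    img[2] *= 255.0
    if hm.spec.bit_depth <= 8:
        Image.fromarray(np.round(img).astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(np.round(img / 255.0 * 65535.0).astype(np.uint16)).save(path)
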