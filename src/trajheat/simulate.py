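"""Synthetic longitudinal cohort generator.

Subjects follow noisy linear trajectories: for each feature,
``value(t) = baseline + slope * t/12 + eps``, with the baseline drawn
from the group's cross-sectional distribution, the annual slope drawn
from a quantile-anchored slope law that honors the group's published
median, IQR and fraction-of-subjects-increasing exactly, and ``eps`` a
small per-visit measurement error.  Visit schedules are irregular:
session count uniform over the group's observed range, inter-visit gaps
uniform on [3, 12] months, truncated at the group's maximum follow-up.

Everything is deterministic given (profile, subject index, seed): each
subject draws from a ``numpy`` generator keyed on
``(seed, group_code, subject_num)``, so a cohort is reproducible
regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajheat.profiles import FEATURES, FeatureProfile, GroupProfile, make_default_profiles
from trajheat import feature_table

__all__ = [
    "SlopeSampler",
    "SubjectTrajectory",
    "CohortConfig",
    "sample_subject",
    "generate_cohort",
]

#: Default per-visit measurement-error SD, as a fraction of the group's
#: cross-sectional baseline SD.  Scan-rescan error of automated
#: volumetry is far smaller than between-subject spread; see
#: docs/methods.md for the calibration argument.
DEFAULT_NOISE_FRAC = 0.01

#: Default inter-visit gap bounds in months (min gap 3 = one time bin).
DEFAULT_GAP_RANGE = (3.0, 12.0)


class SlopeSampler:
    """Piecewise-linear quantile sampler for per-subject annual slopes.

    The published change statistics give three quantiles (q25, median,
    q75) plus the sign fraction P(slope > 0).  A distribution matching
    all four exactly is built by anchoring the quantile function
    Q(p) at ``(0.25, q25), (0.5, median), (0.75, q75)`` and at
    ``(1 - frac_increasing, 0)``, interpolating linearly between
    anchors and extrapolating the tails with the slope of the adjacent
    segment.  Sampling is inverse-transform: ``Q(U)``, U ~ Uniform(0,1).
    """

    def __init__(self, median: float, iqr: tuple[float, float], frac_increasing: float):
        q25, q75 = iqr
        anchors = {0.25: q25, 0.5: median, 0.75: q75}
        p0 = 1.0 - frac_increasing
        # The sign anchor pins Q(p0) = 0: anchors left of p0 must be
        # negative, anchors right of p0 positive, otherwise the stated
        # quantiles contradict the stated sign fraction.
        consistent = all(
            (q <= 0) if p < p0 else (q >= 0) if p > p0 else (q == 0)
            for p, q in anchors.items()
        )
        if not consistent:
            raise ValueError(
                "inconsistent slope parameters: sign fraction contradicts quantiles "
                f"(median={median}, iqr={iqr}, frac_increasing={frac_increasing})"
            )
        anchors.setdefault(p0, 0.0)
        ps = np.array(sorted(anchors))
        qs = np.array([anchors[p] for p in ps])
        if np.any(np.diff(qs) < 0):
            raise ValueError(
                "inconsistent slope parameters: quantile anchors are not monotone "
                f"(median={median}, iqr={iqr}, frac_increasing={frac_increasing})"
            )
        self._ps, self._qs = ps, qs

    def quantile(self, p):
        """Evaluate the quantile function (vectorized)."""
        p = np.asarray(p, dtype=float)
        q = np.interp(p, self._ps, self._qs)
        ps, qs = self._ps, self._qs
        if len(ps) > 1:
            lo_slope = (qs[1] - qs[0]) / (ps[1] - ps[0])
            hi_slope = (qs[-1] - qs[-2]) / (ps[-1] - ps[-2])
            q = np.where(p < ps[0], qs[0] + (p - ps[0]) * lo_slope, q)
            q = np.where(p > ps[-1], qs[-1] + (p - ps[-1]) * hi_slope, q)
        return q if q.ndim else float(q)

    def sample(self, rng: np.random.Generator, size=None):
        return self.quantile(rng.uniform(size=size))


@dataclass
class SubjectTrajectory:
    """One simulated subject: visit times and aligned feature series."""

    group_code: int
    subject_num: int
    visit_months: np.ndarray  # ascending, first element 0
    values: dict[str, np.ndarray]  # feature -> series aligned to visits
    tiv_ml: float

    def __post_init__(self) -> None:
        t = np.asarray(self.visit_months, dtype=float)
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("visit_months must be strictly increasing and start at 0")
        for name, v in self.values.items():
            if len(v) != t.size:
                raise ValueError(f"feature '{name}' length differs from visit count")
        if self.tiv_ml <= 0:
            raise ValueError("tiv_ml must be positive")
        self.visit_months = t

    @property
    def n_visits(self) -> int:
        return int(self.visit_months.size)


def _draw_schedule(profile: GroupProfile, rng: np.random.Generator,
                   gap_range: tuple[float, float]) -> np.ndarray:
    lo, hi = profile.sessions_range
    fu_max = profile.followup_months_range[1]
    if lo < 2:
        raise ValueError("sessions_range.min must be >= 2 for estimable slopes")
    if (lo - 1) * gap_range[0] > fu_max:
        raise ValueError(
            f"sessions_range {profile.sessions_range} infeasible for follow-up "
            f"window of {fu_max} months at minimum gap {gap_range[0]}"
        )
    n = int(rng.integers(lo, hi + 1))
    gaps = rng.uniform(gap_range[0], gap_range[1], size=n - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    # truncate at the follow-up window, but never below the minimum
    # feasible session count
    keep = t <= fu_max
    keep[: lo] = True
    return t[keep]


def sample_subject(
    profile: GroupProfile,
    subject_num: int,
    seed: int,
    *,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    gap_range: tuple[float, float] = DEFAULT_GAP_RANGE,
    fixed_slopes: dict[str, float] | None = None,
) -> SubjectTrajectory:
    """Simulate one subject's longitudinal trajectory.

    Parameters
    ----------
    profile
        Group-level generative parameters.
    subject_num
        1-based subject index within the group; part of the RNG key.
    seed
        Cohort seed; identical (profile, subject_num, seed) gives an
        identical trajectory.
    noise_frac
        Per-visit Gaussian measurement-error SD as a fraction of the
        feature's baseline SD.
    gap_range
        (min, max) inter-visit gap in months.
    fixed_slopes
        Optional per-feature slope overrides (units per year), bypassing
        the stochastic slope law — useful for controlled experiments.
    """
    if subject_num < 1:
        raise ValueError("subject_num is 1-based")
    rng = np.random.default_rng([int(seed), profile.group_code, int(subject_num)])
    t = _draw_schedule(profile, rng, gap_range)
    tiv = float(rng.normal(profile.tiv_mean, profile.tiv_sd))
    tiv = max(tiv, profile.tiv_mean - 4.0 * profile.tiv_sd, 1.0)

    values: dict[str, np.ndarray] = {}
    for name in FEATURES:
        fp: FeatureProfile = profile.features[name]
        baseline = rng.normal(fp.baseline_mean, fp.baseline_sd)
        if fixed_slopes is not None and name in fixed_slopes:
            slope = float(fixed_slopes[name])
        else:
            sampler = SlopeSampler(fp.annual_change_median, fp.annual_change_iqr,
                                   fp.frac_increasing)
            slope = float(sampler.sample(rng))
        noise = rng.normal(0.0, noise_frac * fp.baseline_sd, size=t.size)
        series = baseline + slope * t / 12.0 + noise
        values[name] = np.clip(series, *fp.plausible_range)
    return SubjectTrajectory(profile.group_code, subject_num, t, values, tiv)


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`.

    ``n_per_group`` maps group code -> subject count; ``None`` uses each
    default profile's published count (114 subjects in total).
    """

    n_per_group: dict[int, int] | None = None
    noise_frac: float = DEFAULT_NOISE_FRAC
    gap_range: tuple[float, float] = DEFAULT_GAP_RANGE
    profiles: list[GroupProfile] = field(default_factory=make_default_profiles)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls()
        if "n_per_group" in d and d["n_per_group"] is not None:
            cfg.n_per_group = {int(k): int(v) for k, v in d["n_per_group"].items()}
        if "noise_frac" in d:
            cfg.noise_frac = float(d["noise_frac"])
        if "gap_range" in d:
            cfg.gap_range = tuple(float(x) for x in d["gap_range"])
        return cfg


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a full feature table: one row per scan session.

    Returns a validated table in the canonical schema of
    :mod:`trajheat.feature_table` (hierarchical ``g.s.k`` labels,
    months-from-baseline, absolute volumes plus %TIV columns).
    """
    config = config or CohortConfig()
    rows = []
    for profile in config.profiles:
        n = profile.n_subjects
        if config.n_per_group is not None:
            n = config.n_per_group.get(profile.group_code, 0)
        if n <= 0:
            raise ValueError(f"empty group request for group {profile.group_code}")
        for s in range(1, n + 1):
            traj = sample_subject(
                profile, s, seed,
                noise_frac=config.noise_frac, gap_range=config.gap_range,
            )
            for k, t in enumerate(traj.visit_months, start=1):
                i = k - 1
                rows.append({
                    "group_code": profile.group_code,
                    "subject_num": s,
                    "scan_num": k,
                    "delta_t_months": float(t),
                    "tiv_ml": traj.tiv_ml,
                    "gm_ml": float(traj.values["gm"][i]),
                    "wm_ml": float(traj.values["wm"][i]),
                    "csf_ml": float(traj.values["csf"][i]),
                    "ct_mm": float(traj.values["ct"][i]),
                    "wmh_ml": float(traj.values["wmh"][i]),
                })
    return feature_table.build_table(pd.DataFrame(rows))


def fit_subject_slopes(table: pd.DataFrame, feature_col: str) -> pd.DataFrame:
    """Per-subject ordinary least-squares annual slopes for one feature.

    Serves as the independent parameter-recovery oracle: regress the
    feature on time-in-years within each subject and return one row per
    subject with the fitted slope (units per year).  Subjects with fewer
    than two visits are dropped.
    """
    out = []
    for (g, s), sub in table.groupby(["group_code", "subject_num"]):
        if len(sub) < 2:
            continue
        x = sub["delta_t_months"].to_numpy(dtype=float) / 12.0
        y = sub[feature_col].to_numpy(dtype=float)
        slope = np.polyfit(x, y, 1)[0]
        out.append({"group_code": g, "subject_num": s, "slope_per_year": float(slope)})
    return pd.DataFrame(out)
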