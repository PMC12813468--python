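"""Per-group generative parameters for the synthetic longitudinal cohort.

Each diagnostic stratum (AD, CN, MCI, EMCI, LMCI) is described by a
:class:`GroupProfile`: cross-sectional baseline moments, annual-change
quantiles with the fraction of subjects whose measure increases over
follow-up, plausible physical ranges, head-size (TIV) moments, and the
visit-schedule envelope (participant count, sessions per participant,
follow-up window).

Baseline means/SDs, annual-change medians/IQRs and sign fractions for
CSF and WMH, raw-measurement ranges, and the schedule envelope are the
published descriptive statistics of the ADNI-derived study cohort the
generator emulates.  The study reports only qualitative longitudinal
trends for GM, WM and CT ("significant decrease", "stable over time"),
so their slope parameters are package constants chosen to match the
reported direction and severity gradient; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "FeatureProfile",
    "GroupProfile",
    "FEATURES",
    "GROUP_NAMES",
    "GROUP_CODES",
    "make_default_profiles",
]

#: Scalar features carried by every profile, in canonical order.
#: Volumes (gm, wm, csf, wmh) are in ml; cortical thickness (ct) in mm.
FEATURES = ("gm", "wm", "csf", "ct", "wmh")

#: Diagnostic group coding used throughout (hierarchical labels, model
#: targets): AD=0, CN=1, MCI=2, EMCI=3, LMCI=4.
GROUP_NAMES = {0: "AD", 1: "CN", 2: "MCI", 3: "EMCI", 4: "LMCI"}
GROUP_CODES = {v: k for k, v in GROUP_NAMES.items()}


@dataclass(frozen=True)
class FeatureProfile:
    """Generative parameters for one scalar feature within one group.

    Parameters
    ----------
    baseline_mean, baseline_sd
        Moments of the cross-sectional baseline distribution (ml or mm).
    annual_change_median
        Median per-subject slope, units per year.
    annual_change_iqr
        (25th, 75th) percentile of the per-subject slope distribution.
    frac_increasing
        Proportion of subjects whose measure increases over follow-up.
    plausible_range
        Hard physical bounds; generated values are clipped here.
    """

    baseline_mean: float
    baseline_sd: float
    annual_change_median: float
    annual_change_iqr: tuple[float, float]
    frac_increasing: float
    plausible_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if not 0.0 <= self.frac_increasing <= 1.0:
            raise ValueError("frac_increasing must be in [0, 1]")
        lo, hi = self.annual_change_iqr
        if lo > hi:
            raise ValueError("annual_change_iqr must be ordered (q25 <= q75)")
        if not lo <= self.annual_change_median <= hi:
            raise ValueError("annual_change_median must lie inside its IQR")
        rlo, rhi = self.plausible_range
        if not rlo <= self.baseline_mean <= rhi:
            raise ValueError(
                f"baseline_mean {self.baseline_mean} outside plausible_range {self.plausible_range}"
            )


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one diagnostic stratum."""

    group_code: int
    name: str
    features: dict[str, FeatureProfile]
    tiv_mean: float
    tiv_sd: float
    n_subjects: int
    sessions_range: tuple[int, int]
    followup_months_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.group_code not in GROUP_NAMES:
            raise ValueError(f"unknown group_code {self.group_code}")
        if set(self.features) != set(FEATURES):
            raise ValueError(f"features must cover exactly {FEATURES}")
        if self.tiv_mean <= 0 or self.tiv_sd < 0:
            raise ValueError("TIV moments must be positive / non-negative")
        lo, hi = self.sessions_range
        if not (2 <= lo <= hi):
            raise ValueError("sessions_range must satisfy 2 <= min <= max")
        flo, fhi = self.followup_months_range
        if not (0 <= flo <= fhi):
            raise ValueError("followup_months_range must be ordered and non-negative")


def _rng(mean: float, sd: float, printed: tuple[float, float] | None,
         floor_zero: bool = False) -> tuple[float, float]:
    """Plausible range: union of the printed raw range and mean +/- 3 SD.

    The published raw ranges are occasionally inconsistent with the
    published means (e.g. a group mean just outside its printed range),
    so the union guarantees the range always contains the mean.
    """
    lo, hi = mean - 3.0 * sd, mean + 3.0 * sd
    if printed is not None:
        lo, hi = min(lo, printed[0]), max(hi, printed[1])
    if floor_zero:
        lo = max(lo, 0.0)
    return (lo, hi)


def make_default_profiles() -> list[GroupProfile]:
    """Build the five default group profiles, ordered by group code.

    Returns
    -------
    list of GroupProfile
        AD, CN, MCI, EMCI, LMCI — one per code 0..4.
    """
    # fmt: off
    ad = GroupProfile(
        group_code=0, name="AD",
        features={
            "csf": FeatureProfile(455.0, 79.6, 14.61, (9.57, 16.42), 14 / 15,
                                  _rng(455.0, 79.6, (245.5, 603.8))),
            "gm":  FeatureProfile(558.0, 50.1, -8.0, (-12.0, -4.0), 1 / 15,
                                  _rng(558.0, 50.1, (452.0, 755.0))),
            "wm":  FeatureProfile(461.0, 66.5, -4.0, (-6.5, -1.5), 2 / 15,
                                  _rng(461.0, 66.5, None)),
            "ct":  FeatureProfile(2.22, 0.150, -0.045, (-0.070, -0.020), 1 / 15,
                                  _rng(2.22, 0.150, (1.99, 2.52))),
            "wmh": FeatureProfile(8.22, 12.8, 0.725, (0.104, 3.204), 14 / 15,
                                  _rng(8.22, 12.8, (0.86, 71.27), floor_zero=True)),
        },
        tiv_mean=1500.0, tiv_sd=140.0, n_subjects=22,
        sessions_range=(3, 4), followup_months_range=(12.3, 95.8),
    )
    cn = GroupProfile(
        group_code=1, name="CN",
        features={
            "csf": FeatureProfile(443.0, 83.8, 7.16, (4.87, 8.29), 21 / 22,
                                  _rng(443.0, 83.8, (247.7, 712.3))),
            "gm":  FeatureProfile(593.0, 58.1, -1.0, (-2.5, 0.5), 8 / 22,
                                  _rng(593.0, 58.1, (517.0, 642.0))),
            "wm":  FeatureProfile(464.0, 80.7, -0.5, (-1.8, 0.8), 9 / 22,
                                  _rng(464.0, 80.7, None)),
            "ct":  FeatureProfile(2.33, 0.177, -0.005, (-0.015, 0.005), 8 / 22,
                                  _rng(2.33, 0.177, (2.22, 2.51))),
            "wmh": FeatureProfile(3.55, 3.69, 0.122, (0.050, 0.266), 19 / 22,
                                  _rng(3.55, 3.69, (0.0, 22.04), floor_zero=True)),
        },
        tiv_mean=1500.0, tiv_sd=140.0, n_subjects=22,
        sessions_range=(4, 5), followup_months_range=(25.3, 138.7),
    )
    mci = GroupProfile(
        group_code=2, name="MCI",
        features={
            "csf": FeatureProfile(397.0, 111.0, 6.39, (4.21, 10.93), 22 / 25,
                                  _rng(397.0, 111.0, (58.8, 896.5))),
            "gm":  FeatureProfile(573.0, 94.4, -4.5, (-7.5, -1.5), 3 / 25,
                                  _rng(573.0, 94.4, (573.0, 667.4))),
            "wm":  FeatureProfile(465.0, 96.6, -2.5, (-4.5, -0.5), 4 / 25,
                                  _rng(465.0, 96.6, None)),
            "ct":  FeatureProfile(2.28, 0.404, -0.020, (-0.038, -0.005), 4 / 25,
                                  _rng(2.28, 0.404, (2.28, 2.684))),
            "wmh": FeatureProfile(4.68, 14.0, 0.189, (0.071, 0.484), 23 / 25,
                                  _rng(4.68, 14.0, (0.0, 125.40), floor_zero=True)),
        },
        tiv_mean=1500.0, tiv_sd=140.0, n_subjects=25,
        sessions_range=(3, 9), followup_months_range=(11.3, 171.0),
    )
    emci = GroupProfile(
        group_code=3, name="EMCI",
        features={
            "csf": FeatureProfile(392.0, 63.8, 5.98, (4.05, 7.84), 19 / 20,
                                  _rng(392.0, 63.8, (232.3, 526.6))),
            "gm":  FeatureProfile(615.0, 51.2, -4.0, (-6.5, -1.5), 2 / 20,
                                  _rng(615.0, 51.2, (571.0, 755.0))),
            "wm":  FeatureProfile(481.0, 65.2, -1.5, (-3.5, 0.5), 6 / 20,
                                  _rng(481.0, 65.2, None)),
            "ct":  FeatureProfile(2.40, 0.101, -0.015, (-0.030, -0.004), 3 / 20,
                                  _rng(2.40, 0.101, (2.33, 2.52))),
            "wmh": FeatureProfile(4.48, 6.53, 0.361, (0.122, 0.724), 20 / 20,
                                  _rng(4.48, 6.53, (0.30, 35.28), floor_zero=True)),
        },
        tiv_mean=1500.0, tiv_sd=140.0, n_subjects=20,
        sessions_range=(3, 7), followup_months_range=(3.0, 141.7),
    )
    lmci = GroupProfile(
        group_code=4, name="LMCI",
        features={
            "csf": FeatureProfile(400.0, 82.8, 7.98, (4.62, 15.43), 23 / 25,
                                  _rng(400.0, 82.8, (248.0, 713.4))),
            "gm":  FeatureProfile(575.0, 86.6, -5.0, (-8.5, -2.0), 2 / 25,
                                  _rng(575.0, 86.6, (452.0, 566.0))),
            "wm":  FeatureProfile(479.0, 76.8, -3.0, (-5.0, -1.0), 3 / 25,
                                  _rng(479.0, 76.8, None)),
            "ct":  FeatureProfile(2.30, 0.249, -0.030, (-0.050, -0.012), 2 / 25,
                                  _rng(2.30, 0.249, (1.95, 2.32))),
            "wmh": FeatureProfile(3.13, 3.38, 0.118, (0.059, 0.256), 21 / 25,
                                  _rng(3.13, 3.38, (0.0, 16.73), floor_zero=True)),
        },
        tiv_mean=1500.0, tiv_sd=140.0, n_subjects=25,
        sessions_range=(6, 9), followup_months_range=(12.2, 132.9),
    )
    # fmt: on
    return [ad, cn, mci, emci, lmci]
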