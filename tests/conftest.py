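import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trajheat.profiles import FeatureProfile, GroupProfile, make_default_profiles
from trajheat.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_profiles():
    return make_default_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """Small deterministic cohort: 4 subjects per group."""
    cfg = CohortConfig(n_per_group={g: 4 for g in range(5)})
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def full_cohort():
    """Default cohort at the published group sizes (114 subjects)."""
    return generate_cohort(seed=7)


def make_separable_profiles(spacing_sds: float = 5.0, sd: float = 10.0):
    """Five profiles whose feature means sit ``spacing_sds`` within-group
    SDs apart — trivially separable groups for end-to-end sanity runs.
    Schedules are dense (10-14 sessions) so the heatmaps carry the
    signal in many bins rather than being dominated by missingness."""
    profiles = []
    for g in range(5):
        mean = 400.0 + g * spacing_sds * sd
        feats = {}
        for name in ("gm", "wm", "csf"):
            feats[name] = FeatureProfile(
                baseline_mean=mean, baseline_sd=sd,
                annual_change_median=1.0, annual_change_iqr=(0.5, 1.5),
                frac_increasing=1.0, plausible_range=(0.0, 2000.0))
        feats["ct"] = FeatureProfile(
            baseline_mean=2.0 + g * 0.25, baseline_sd=0.05,
            annual_change_median=0.01, annual_change_iqr=(0.005, 0.015),
            frac_increasing=1.0, plausible_range=(0.1, 10.0))
        feats["wmh"] = FeatureProfile(
            baseline_mean=5.0 + g * 5.0, baseline_sd=1.0,
            annual_change_median=0.1, annual_change_iqr=(0.05, 0.15),
            frac_increasing=1.0, plausible_range=(0.0, 100.0))
        profiles.append(GroupProfile(
            group_code=g, name=f"G{g}", features=feats,
            tiv_mean=1500.0, tiv_sd=50.0, n_subjects=30,
            sessions_range=(10, 14), followup_months_range=(12.0, 84.0)))
    return profiles


def separable_config() -> CohortConfig:
    return CohortConfig(profiles=make_separable_profiles(), gap_range=(3.0, 9.0))


@pytest.fixture(scope="session")
def separable_cohort():
    """~150 subjects, 5 groups, means 5 within-group SDs apart."""
    return generate_cohort(separable_config(), seed=11)
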