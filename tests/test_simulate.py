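import numpy as np
import pandas as pd
import pytest

from trajheat.profiles import make_default_profiles
from trajheat.simulate import (
    CohortConfig,
    SlopeSampler,
    fit_subject_slopes,
    generate_cohort,
    sample_subject,
)


@pytest.fixture(scope="module")
def ad_profile():
    return make_default_profiles()[0]


class TestSlopeSampler:
    def test_honors_median_iqr_and_sign_fraction(self):
        s = SlopeSampler(14.61, (9.57, 16.42), 14 / 15)
        draws = s.sample(np.random.default_rng(0), 100_000)
        assert np.median(draws) == pytest.approx(14.61, abs=0.05)
        q25, q75 = np.percentile(draws, [25, 75])
        assert q25 == pytest.approx(9.57, abs=0.1)
        assert q75 == pytest.approx(16.42, abs=0.1)
        assert (draws > 0).mean() == pytest.approx(14 / 15, abs=0.01)

    def test_negative_median_with_minority_increasing(self):
        s = SlopeSampler(-1.0, (-2.5, 0.5), 8 / 22)
        draws = s.sample(np.random.default_rng(1), 100_000)
        assert np.median(draws) == pytest.approx(-1.0, abs=0.05)
        assert (draws > 0).mean() == pytest.approx(8 / 22, abs=0.01)

    def test_all_increasing_gives_no_negative_draws(self):
        s = SlopeSampler(0.361, (0.122, 0.724), 1.0)
        draws = s.sample(np.random.default_rng(2), 50_000)
        assert (draws >= 0).all()

    def test_contradictory_parameters_rejected(self):
        # median below zero but 95% of subjects said to increase
        with pytest.raises(ValueError):
            SlopeSampler(-1.0, (-2.0, -0.5), 0.95)


class TestSampleSubject:
    def test_determinism(self, ad_profile):
        a = sample_subject(ad_profile, 3, seed=5)
        b = sample_subject(ad_profile, 3, seed=5)
        assert np.array_equal(a.visit_months, b.visit_months)
        for f in a.values:
            assert np.array_equal(a.values[f], b.values[f])
        assert a.tiv_ml == b.tiv_ml

    def test_different_seed_differs(self, ad_profile):
        a = sample_subject(ad_profile, 3, seed=5)
        b = sample_subject(ad_profile, 3, seed=6)
        assert not np.array_equal(a.values["csf"], b.values["csf"])

    def test_noiseless_fixed_slope_is_exactly_linear(self, ad_profile):
        from dataclasses import replace

        quiet = replace(
            ad_profile,
            features={k: replace(v, baseline_sd=0.0) for k, v in ad_profile.features.items()},
        )
        traj = sample_subject(quiet, 1, seed=0, noise_frac=0.0,
                              fixed_slopes={"csf": 12.0})
        expected = quiet.features["csf"].baseline_mean + 12.0 * traj.visit_months / 12.0
        assert traj.values["csf"] == pytest.approx(expected, abs=1e-9)

    def test_schedule_envelope(self, ad_profile):
        for i in range(1, 60):
            traj = sample_subject(ad_profile, i, seed=9)
            t = traj.visit_months
            assert t[0] == 0.0
            assert np.all(np.diff(t) >= 3.0)
            assert np.all(np.diff(t) <= 12.0)
            lo, hi = ad_profile.sessions_range
            assert lo <= traj.n_visits <= hi
            assert t[-1] <= ad_profile.followup_months_range[1] or traj.n_visits == lo

    def test_values_respect_plausible_range(self, ad_profile):
        for i in range(1, 40):
            traj = sample_subject(ad_profile, i, seed=3)
            for name, fp in ad_profile.features.items():
                lo, hi = fp.plausible_range
                assert np.all(traj.values[name] >= lo)
                assert np.all(traj.values[name] <= hi)
            assert traj.tiv_ml > 0


class TestGenerateCohort:
    def test_published_cohort_size(self, full_cohort):
        subjects = full_cohort.groupby(["group_code", "subject_num"]).ngroups
        assert subjects == 114
        counts = full_cohort.groupby("group_code")["subject_num"].nunique()
        assert counts.to_dict() == {0: 22, 1: 22, 2: 25, 3: 20, 4: 25}

    def test_every_subject_starts_at_month_zero(self, full_cohort):
        first = full_cohort[full_cohort.scan_num == 1]
        assert (first.delta_t_months == 0).all()
        assert len(first) == 114

    def test_row_count_equals_total_sessions(self, full_cohort):
        per_subject = full_cohort.groupby(["group_code", "subject_num"]).size()
        assert per_subject.sum() == len(full_cohort)
        assert (per_subject >= 3).all()

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = CohortConfig(n_per_group={g: 3 for g in range(5)})
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_cohort(cfg, seed=1).to_csv(p1, index=False)
        generate_cohort(cfg, seed=1).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_group_request_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            generate_cohort(CohortConfig(n_per_group={0: 0, 1: 2, 2: 2, 3: 2, 4: 2}), seed=0)


class TestParameterRecovery:
    """Moderate-n recovery of the generative constants from the data."""

    @pytest.fixture(scope="class")
    @staticmethod
    def ad_heavy():
        cfg = CohortConfig(n_per_group={0: 300, 1: 2, 2: 2, 3: 2, 4: 2})
        t = generate_cohort(cfg, seed=13)
        return t[t.group_code == 0]

    def test_baseline_moments_recovered(self, ad_heavy):
        base = ad_heavy[ad_heavy.scan_num == 1]
        n = len(base)
        se_mean = 0.150 / np.sqrt(n)
        se_sd = 0.150 / np.sqrt(2 * n)
        assert abs(base.ct_mm.mean() - 2.22) < 3 * se_mean + 0.002
        assert abs(base.ct_mm.std(ddof=1) - 0.150) < 3 * se_sd + 0.002

    def test_fraction_increasing_within_binomial_error(self, ad_heavy):
        slopes = fit_subject_slopes(ad_heavy, "csf_ml")
        frac = (slopes.slope_per_year > 0).mean()
        p = 14 / 15
        se = np.sqrt(p * (1 - p) / len(slopes))
        assert abs(frac - p) < 3 * se + 0.02  # slack for slope-estimation noise

    def test_median_slope_recovered(self, ad_heavy):
        slopes = fit_subject_slopes(ad_heavy, "csf_ml")["slope_per_year"].to_numpy()
        med = np.median(slopes)
        rng = np.random.default_rng(0)
        boot = np.array([
            np.median(rng.choice(slopes, size=len(slopes))) for _ in range(500)
        ])
        assert abs(med - 14.61) < 3 * boot.std()
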