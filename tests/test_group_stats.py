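import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from trajheat import group_stats as gs


class TestDescriptives:
    def test_five_groups_in_five_rows_out(self, small_cohort):
        out = gs.descriptives(small_cohort, "ct_mm")
        assert len(out) == 5
        assert set(out.group) == {"AD", "CN", "MCI", "EMCI", "LMCI"}

    def test_mean_and_sample_sd(self, small_cohort):
        out = gs.descriptives(small_cohort, "csf_ml")
        sub = small_cohort[small_cohort.group_code == 0]["csf_ml"]
        row = out[out.group_code == 0].iloc[0]
        assert row["mean"] == pytest.approx(sub.mean())
        assert row["sd"] == pytest.approx(sub.std(ddof=1))

    def test_constant_group_sd_zero(self):
        import pandas as pd

        t = pd.DataFrame({"group_code": [0, 0, 1, 1], "x": [5.0, 5.0, 1.0, 2.0]})
        out = gs.descriptives(t, "x")
        assert out[out.group_code == 0]["sd"].iloc[0] == 0.0

    def test_recovers_generative_moments(self):
        """AD cortical thickness generated at mean 2.22, SD 0.150 is
        recovered from baseline rows within 3 standard errors."""
        from trajheat.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(n_per_group={0: 300, 1: 2, 2: 2, 3: 2, 4: 2})
        t = generate_cohort(cfg, seed=21)
        base = t[(t.group_code == 0) & (t.scan_num == 1)]
        n = len(base)
        assert abs(base.ct_mm.mean() - 2.22) < 3 * 0.150 / np.sqrt(n) + 0.002
        assert abs(base.ct_mm.std(ddof=1) - 0.150) < 3 * 0.150 / np.sqrt(2 * n) + 0.002


class TestShapiroWilk:
    def test_gaussian_sample_rarely_rejected(self):
        rng = np.random.default_rng(0)
        p = gs.shapiro_wilk(rng.normal(size=200))
        assert 0 <= p <= 1

    def test_lognormal_sample_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            gs.shapiro_wilk(rng.lognormal(0, 1, size=100)) < 0.05 for _ in range(50)
        )
        assert rejections >= 48  # heavy skew: near-certain detection

    def test_small_or_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            gs.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            gs.shapiro_wilk([3.0] * 10)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, df, p = gs.kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert df == 2
        assert 0 < p < 0.05

    def test_df_is_k_minus_one(self):
        groups = [np.random.default_rng(i).normal(size=10) for i in range(6)]
        _, df, _ = gs.kruskal_wallis(*groups)
        assert df == 5

    def test_identical_observations_flagged(self):
        with pytest.raises(ValueError, match="identical"):
            gs.kruskal_wallis([1.0, 1.0], [1.0, 1.0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gs.kruskal_wallis([1.0, 2.0], [])

    @given(seed=stn.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        """H is rank-based: exp (strictly monotone) cannot change it —
        hence log(1+x) cannot alter the WMH omnibus result."""
        rng = np.random.default_rng(seed)
        groups = [rng.uniform(0, 5, size=rng.integers(5, 15)) for _ in range(3)]
        h1, _, _ = gs.kruskal_wallis(*groups)
        h2, _, _ = gs.kruskal_wallis(*[np.expm1(g) for g in groups])
        assert h1 == pytest.approx(h2)


class TestLog1pWmh:
    def test_zero_maps_to_zero(self):
        assert gs.log1p_wmh([0.0])[0] == 0.0

    def test_round_trip(self):
        x = np.array([0.0, 0.5, 3.2, 125.4])
        assert np.expm1(gs.log1p_wmh(x)) == pytest.approx(x, abs=1e-12)

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 50)
        y = gs.log1p_wmh(x)
        assert np.array_equal(np.argsort(x), np.argsort(y))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gs.log1p_wmh([-0.1])


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert gs.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        adj = gs.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = gs.fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.fdr_adjust([0.5, 1.2])


class TestDunnPosthoc:
    def test_pair_count_and_fdr_monotone(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(g, 1.0, size=20) for g in range(5)}
        out = gs.dunn_posthoc(groups)
        assert len(out) == 10
        assert np.all(out.p_fdr >= out.p_raw - 1e-12)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        groups = {0: rng.normal(0, 1, 30), 1: rng.normal(5, 1, 30)}
        out = gs.dunn_posthoc(groups)
        assert out.p_fdr.iloc[0] < 0.001


class TestComputeReport:
    def test_full_protocol_shapes(self, full_cohort):
        rep = gs.compute_report(full_cohort)
        assert set(rep.descriptives) == set(gs.DEFAULT_MEASURES)
        assert len(rep.kruskal) == 5
        assert (rep.kruskal.df == 4).all()
        assert len(rep.shapiro) == 25
        for df in rep.pairwise.values():
            assert len(df) == 10

    def test_group_separation_detected(self, full_cohort):
        """On a cohort generated from the published group moments at the
        published sizes, CSF, GM, CT and WMH omnibus tests reject."""
        rep = gs.compute_report(full_cohort)
        kw = rep.kruskal.set_index("measure")
        for m in ("csf_ml", "gm_ml", "ct_mm", "wmh_ml"):
            assert kw.loc[m, "p"] < 0.05

    def test_subject_level_mode(self, full_cohort):
        rep = gs.compute_report(full_cohort, unit="subject")
        assert rep.unit == "subject"
        assert (rep.descriptives["csf_ml"]["n"].sum()) == 114

    def test_invalid_unit_rejected(self, full_cohort):
        with pytest.raises(ValueError):
            gs.compute_report(full_cohort, unit="scan")
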