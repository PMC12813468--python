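import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from trajheat import heatmap as hm


GRID = hm.TimeGrid()


class TestTimeGrid:
    def test_default_is_28_bins(self):
        assert GRID.n_bins == 28
        assert GRID.bin_width_months == 3.0
        assert (GRID.t_min, GRID.t_max) == (0.0, 84.0)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            hm.TimeGrid(bin_width_months=5.0, t_max=84.0)


class TestBinIndex:
    @pytest.mark.parametrize("t,expected", [(0.0, 0), (2.99, 0), (3.0, 1),
                                            (10.5, 3), (83.9, 27), (84.0, 27)])
    def test_half_open_bins_with_right_edge_clamp(self, t, expected):
        assert hm.bin_index(t, GRID) == expected

    @pytest.mark.parametrize("t", [-0.1, 84.1, 200.0])
    def test_out_of_window_rejected(self, t):
        with pytest.raises(ValueError):
            hm.bin_index(t, GRID)


class TestAggregateBins:
    def test_mask_marks_occupied_bins(self):
        vals, mask = hm.aggregate_bins([0.0, 6.0], [10.0, 20.0], GRID)
        assert mask.sum() == 2
        assert mask[0] == 1 and mask[2] == 1

    def test_same_bin_sessions_averaged(self):
        vals, mask = hm.aggregate_bins([0.0, 1.0], [10.0, 14.0], GRID)
        assert vals[0] == pytest.approx(12.0)
        assert mask.sum() == 1

    def test_empty_input_all_zero(self):
        vals, mask = hm.aggregate_bins([], [], GRID)
        assert not mask.any() and not vals.any()


class TestRateChannel:
    def test_hand_computed_slope(self):
        vals, mask = hm.aggregate_bins([0.0, 12.0], [10.0, 16.0], GRID)
        rate = hm.rate_channel(vals, mask, GRID)
        # occupied bins 0 and 4; bin centers 1.5 and 13.5 months
        assert rate[0] == 0.0
        assert rate[4] == pytest.approx((16.0 - 10.0) / 12.0)

    def test_total_duration_mode(self):
        vals, mask = hm.aggregate_bins([0.0, 12.0], [10.0, 16.0], GRID)
        rate = hm.rate_channel(vals, mask, GRID, normalize_by_total=True)
        assert rate[4] == pytest.approx(0.5 / 180.0)

    def test_constant_series_all_zero(self):
        vals, mask = hm.aggregate_bins([0.0, 6.0, 12.0], [5.0, 5.0, 5.0], GRID)
        assert not hm.rate_channel(vals, mask, GRID).any()

    def test_single_visit_all_zero(self):
        vals, mask = hm.aggregate_bins([6.0], [5.0], GRID)
        assert not hm.rate_channel(vals, mask, GRID).any()

    def test_matches_independent_finite_differences(self):
        """Oracle equivalence on random subjects: slopes between
        consecutive occupied bins equal a direct finite-difference
        computation over the binned series."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 9)
            t = np.sort(rng.uniform(0, 84, size=n))
            v = rng.normal(100, 20, size=n)
            vals, mask = hm.aggregate_bins(t, v, GRID)
            rate = hm.rate_channel(vals, mask, GRID)
            occ = np.flatnonzero(mask)
            expected = np.zeros(28)
            centers = GRID.bin_centers
            for a, b in zip(occ[:-1], occ[1:]):
                expected[b] = (vals[b] - vals[a]) / (centers[b] - centers[a])
            assert rate == pytest.approx(expected)


class TestMinMaxScale:
    def test_endpoints(self):
        out = hm.minmax_scale([0.0, 5.0, 10.0], 0.0, 10.0)
        assert out[0] == 0.0 and out[2] == 255.0
        assert out[1] == pytest.approx(127.5)

    def test_out_of_range_clipped(self):
        out = hm.minmax_scale([-5.0, 15.0], 0.0, 10.0)
        assert out.tolist() == [0.0, 255.0]

    def test_degenerate_range_maps_to_zero(self):
        assert not hm.minmax_scale([3.0, 3.0], 3.0, 3.0).any()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            hm.minmax_scale([1.0], 2.0, 1.0)


class TestQuantize:
    @pytest.mark.parametrize("bits,levels", [(2, 4), (3, 8), (4, 16), (8, 256), (16, 65536)])
    def test_level_count_bound(self, bits, levels):
        spec = hm.QuantizationSpec(bits)
        assert spec.n_levels == levels
        x = np.linspace(0, 255, 1000)
        assert len(np.unique(hm.quantize(x, spec))) <= levels

    def test_two_bit_mapping_by_hand(self):
        spec = hm.QuantizationSpec(2)
        # levels are 0, 85, 170, 255; x=100 -> round(100/255*3)=1 -> 85
        assert hm.quantize(np.array([100.0]), spec)[0] == pytest.approx(85.0)
        assert set(np.unique(hm.quantize(np.linspace(0, 255, 500), spec))) == {0.0, 85.0, 170.0, 255.0}

    def test_unsupported_bit_depth_rejected(self):
        with pytest.raises(ValueError):
            hm.QuantizationSpec(5)

    @given(x=stn.lists(stn.floats(0, 255), min_size=1, max_size=50),
           bits=stn.sampled_from([2, 3, 4, 8, 16]))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_bounded_error_and_monotone(self, x, bits):
        spec = hm.QuantizationSpec(bits)
        x = np.array(x)
        q = hm.quantize(x, spec)
        assert hm.quantize(q, spec) == pytest.approx(q)
        assert np.max(np.abs(q - x)) <= 255.0 / (2 * (spec.n_levels - 1)) + 1e-9
        order = np.argsort(x)
        assert np.all(np.diff(q[order]) >= -1e-9)


class TestEncodeHeatmap:
    def _stats(self):
        return hm.NormStats(0.0, 100.0, -1.0, 1.0)

    def test_shape_and_channel_contract(self):
        out = hm.encode_heatmap([0.0, 6.0, 12.0], [10.0, 50.0, 100.0], self._stats())
        assert out.data.shape == (28, 3)
        assert set(np.unique(out.mask)) <= {0.0, 1.0}
        assert out.c1.min() >= 0 and out.c1.max() <= 255
        assert out.c2.min() >= 0 and out.c2.max() <= 255

    def test_channels_zero_where_mask_zero(self):
        out = hm.encode_heatmap([0.0, 6.0], [50.0, 60.0], self._stats())
        off = out.mask == 0
        assert not out.c1[off].any()
        assert not out.c2[off].any()

    def test_c1_quantized_to_level_count(self):
        out = hm.encode_heatmap(np.linspace(0, 84, 28), np.linspace(0, 100, 28),
                                self._stats(), hm.QuantizationSpec(2))
        assert len(np.unique(out.c1)) <= 4

    def test_mask_sum_bounded_by_sessions(self):
        t = [0.0, 1.0, 2.0, 40.0]
        out = hm.encode_heatmap(t, [1.0, 2.0, 3.0, 4.0], self._stats())
        assert out.mask.sum() <= len(t)

    def test_no_sessions_rejected(self):
        with pytest.raises(ValueError):
            hm.encode_heatmap([], [], self._stats())


class TestPngExport:
    @pytest.mark.parametrize("bits,mode", [(8, "L"), (16, "I;16")])
    def test_png_round_trip_dimensions(self, tmp_path, bits, mode):
        from PIL import Image

        stats = hm.NormStats(0.0, 100.0, -1.0, 1.0)
        out = hm.encode_heatmap([0.0, 6.0, 15.0], [10.0, 50.0, 90.0], stats,
                                hm.QuantizationSpec(bits))
        path = tmp_path / "h.png"
        hm.save_heatmap_png(out, path)
        img = Image.open(path)
        assert img.size == (28, 3)  # (width=time bins, height=channels)


class TestEncodeDataset:
    def test_shapes_and_labels(self, small_cohort):
        X, y, subjects, stats = hm.encode_dataset(small_cohort, "gm_pct")
        assert X.shape == (len(subjects), 28, 3)
        assert set(y) <= set(range(5))
        assert len(subjects) == small_cohort.groupby(["group_code", "subject_num"]).ngroups

    def test_frozen_norm_stats_reused(self, small_cohort):
        _, _, _, stats = hm.encode_dataset(small_cohort, "gm_pct")
        X2, _, _, stats2 = hm.encode_dataset(small_cohort, "gm_pct", norm_stats=stats)
        assert stats2 == stats

    def test_out_of_window_sessions_dropped(self, small_cohort):
        t = small_cohort.copy()
        t.loc[t.index[-1], "delta_t_months"] = 300.0  # beyond 84 months
        X, y, subjects, _ = hm.encode_dataset(t, "gm_pct")
        assert X.shape[1:] == (28, 3)
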