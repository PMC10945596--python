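"""IOI extraction, filtering, ratio computation, bands, KDE peaks, tempi."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import longcall as lc
from longcall.errors import InsufficientDataError
from conftest import onsets_to_table

positive_iois = st.lists(
    st.floats(0.03, 4.9, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=40)


class TestComputeIois:
    def test_direct_subtraction(self):
        t = onsets_to_table([0.0, 1.7, 3.4])
        s = lc.compute_iois(t, "full_pulse")
        assert np.allclose(s.t_k, [1.7, 1.7])

    def test_within_parent_never_crosses_pulses(self, tiny_events):
        s = lc.compute_iois(tiny_events, "bubble_sub_pulse",
                            within_parent=True)
        # two bubbles in p1 and two in p2: one IOI per pulse
        assert len(s) == 2
        assert np.allclose(sorted(s.t_k), [0.2, 0.2])
        assert s.data["sequence_id"].nunique() == 2

    def test_without_parent_constraint_bridges_pulses(self, tiny_events):
        s = lc.compute_iois(tiny_events, "bubble_sub_pulse",
                            within_parent=False)
        assert len(s) == 3  # s1-s2, s2-s3, s3-s4

    def test_unknown_type_raises(self, tiny_events):
        with pytest.raises(ValueError, match="unknown element_type"):
            lc.compute_iois(tiny_events, "chirp")

    def test_absent_type_gives_empty_series(self, tiny_events):
        assert len(lc.compute_iois(tiny_events, "pulse_body")) == 0

    def test_sequences_do_not_cross_calls(self, tiny_events):
        s = lc.compute_iois(tiny_events, "full_pulse")
        assert len(s) == 3  # 2 IOIs in callA + 1 in callB
        assert s.data.groupby("sequence_id").size().to_dict() == \
            {"callA/full_pulse": 2, "callB/full_pulse": 1}


class TestFilterIois:
    def test_strict_bounds(self):
        s = lc.IOISeries.from_values([0.02, 1.0, 6.0])
        assert np.allclose(lc.filter_iois(s).t_k, [1.0])

    def test_boundary_value_excluded(self):
        s = lc.IOISeries.from_values([0.025])
        assert len(lc.filter_iois(s)) == 0

    def test_interior_removal_splits_sequence(self):
        s = lc.IOISeries.from_values([1.0, 6.0, 1.2, 1.3])
        out = lc.filter_iois(s)
        assert np.allclose(out.t_k, [1.0, 1.2, 1.3])
        seqs = out.data["sequence_id"].tolist()
        assert seqs[0] != seqs[1] and seqs[1] == seqs[2]
        # and no ratio is ever formed across the split
        r = lc.compute_ratios(out)
        assert len(r) == 1 and np.isclose(r.r_k[0], 1.2 / 2.5)

    def test_intact_sequence_keeps_id(self):
        s = lc.IOISeries.from_values([1.0, 1.1], sequence_id="orig")
        assert set(lc.filter_iois(s).data["sequence_id"]) == {"orig"}

    @given(positive_iois, st.floats(0.001, 0.1), st.floats(1.0, 10.0))
    def test_widening_bounds_is_monotone(self, t_k, lo, hi):
        s = lc.IOISeries.from_values(t_k)
        narrow = lc.filter_iois(s, lo, hi)
        wide = lc.filter_iois(s, lo / 2, hi * 2)
        assert len(wide) >= len(narrow)


class TestComputeRatios:
    @pytest.mark.parametrize("t_k, expected_r, expected_band", [
        ([1.0, 1.0], 0.5, "on"),
        ([1.0, 3.0], 0.25, "outside"),
        ([1.0, 1.2], 1.0 / 2.2, "on"),     # 0.4545… inside (0.440, 0.555)
        ([1.2, 1.0], 1.2 / 2.2, "on"),
        ([1.0, 1.35], 1.0 / 2.35, "off"),  # 0.4255… inside (0.400, 0.440)
    ])
    def test_formula_and_band(self, t_k, expected_r, expected_band):
        r = lc.compute_ratios(lc.IOISeries.from_values(t_k))
        assert np.isclose(r.r_k[0], expected_r)
        assert r.data["band"].iloc[0] == expected_band

    def test_empty_series_gives_empty_ratios(self):
        assert len(lc.compute_ratios(lc.IOISeries.from_values([]))) == 0

    def test_boundary_value_in_no_band(self):
        bands = lc.IsochronyBands()
        assert list(bands.classify([0.440, 0.555, 0.400, 0.600])) == \
            ["outside"] * 4

    @given(positive_iois, st.floats(0.01, 100.0))
    def test_scale_invariance(self, t_k, c):
        base = lc.compute_ratios(lc.IOISeries.from_values(t_k)).r_k
        scaled = lc.compute_ratios(
            lc.IOISeries.from_values(np.asarray(t_k) * c)).r_k
        assert np.allclose(base, scaled, rtol=1e-9, atol=1e-12)

    @given(positive_iois)
    def test_reversal_maps_ratios_to_one_minus(self, t_k):
        forward = lc.compute_ratios(lc.IOISeries.from_values(t_k)).r_k
        backward = lc.compute_ratios(
            lc.IOISeries.from_values(list(reversed(t_k)))).r_k
        assert np.allclose(np.sort(forward), np.sort(1.0 - backward),
                           atol=1e-12)

    @given(st.floats(0.03, 4.9), st.integers(3, 30))
    def test_perfect_isochrony_is_all_on_band(self, t, n):
        r = lc.compute_ratios(lc.IOISeries.from_values([t] * n))
        assert np.allclose(r.r_k, 0.5)
        assert (r.data["band"] == "on").all()


class TestBandCounts:
    def test_membership_counts(self):
        r = lc.RatioSeries(pd.DataFrame({
            "r_k": [0.5, 0.5, 0.42, 0.3],
            "band": lc.DEFAULT_BANDS.classify([0.5, 0.5, 0.42, 0.3]),
            "element_type": "full_pulse", "long_call_id": "c",
            "individual_id": "i", "sequence_id": "s"}))
        out = lc.band_counts(r)
        by_band = dict(zip(out["band"], out["count"]))
        assert by_band == {"on": 2, "off": 1, "outside": 1}
        widths = dict(zip(out["band"], out["band_width"]))
        assert np.isclose(widths["on"], 0.115)
        assert np.isclose(widths["off"], 0.085)

    def test_empty_input(self):
        empty = lc.RatioSeries(pd.DataFrame(
            columns=["r_k", "band", "element_type", "long_call_id",
                     "individual_id", "sequence_id"]))
        assert len(lc.band_counts(empty)) == 0

    def test_uniform_ratios_split_proportionally_to_width(self):
        # closed form: uniform on (0.400, 0.600) puts 0.115/0.200 = 57.5%
        # of mass in the on band
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.4, 0.6, 1000)
        r = lc.RatioSeries(pd.DataFrame({
            "r_k": vals, "band": lc.DEFAULT_BANDS.classify(vals),
            "element_type": "full_pulse", "long_call_id": "c",
            "individual_id": "i", "sequence_id": "s"}))
        out = lc.band_counts(r)
        by_band = dict(zip(out["band"], out["count"]))
        # binomial(1000, 0.575): 3 sigma ~ 47
        assert abs(by_band["on"] - 575) < 50
        assert by_band["on"] + by_band["off"] + by_band["outside"] == 1000

    def test_count_conservation_on_synthetic(self, filtered_series):
        s = filtered_series["full_pulse"]
        r = lc.compute_ratios(s)
        out = lc.band_counts(r, group_by=("element_type", "individual_id"))
        assert out["count"].sum() == len(r)

    def test_brute_force_interval_scan_oracle(self, filtered_series):
        r = lc.compute_ratios(filtered_series["bubble_sub_pulse"])
        out = lc.band_counts(r, group_by=("element_type",))
        by_band = dict(zip(out["band"], out["count"]))
        on = sum(1 for v in r.r_k if 0.440 < v < 0.555)
        off = sum(1 for v in r.r_k
                  if 0.400 < v < 0.440 or 0.555 < v < 0.600)
        assert by_band["on"] == on and by_band["off"] == off


class TestRatioDensity:
    def test_normal_sample_peak_near_mean(self):
        rng = np.random.default_rng(11)
        vals = np.clip(rng.normal(0.5, 0.01, 500), 0.001, 0.999)
        peak = lc.ratio_density(vals)
        assert abs(peak.peak_location - 0.5) < 0.01
        assert abs(peak.restricted_peak_location - 0.5) < 0.01

    def test_alternating_iois_bimodal_no_on_peak(self):
        t_k = [1.0, 2.0] * 40
        r = lc.compute_ratios(lc.IOISeries.from_values(t_k))
        assert set(np.round(r.r_k, 12)) == {round(1 / 3, 12), round(2 / 3, 12)}
        peak = lc.ratio_density(r)
        maxima = peak.local_maxima()
        assert any(abs(m - 1 / 3) < 0.05 for m in maxima)
        assert any(abs(m - 2 / 3) < 0.05 for m in maxima)
        assert not any(0.44 < m < 0.555 for m in maxima)

    def test_density_integrates_to_one(self, filtered_series):
        r = lc.compute_ratios(filtered_series["full_pulse"])
        peak = lc.ratio_density(r)
        mass = np.trapezoid(peak.density, peak.grid)
        assert abs(mass - 1.0) < 1e-3

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            lc.ratio_density(np.full(9, 0.5))

    def test_jittered_isochrony_peak_recovery(self):
        # multiplicative jitter <= 10%: restricted peak stays in (0.48, 0.52)
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(20):
            t = 1.7 * rng.lognormal(0.0, 0.0998, 400)  # cv ~ 10%
            r = lc.compute_ratios(lc.IOISeries.from_values(t))
            pk = lc.ratio_density(r)
            hits += 0.48 < pk.restricted_peak_location < 0.52
        assert hits >= 19


class TestTempoSummary:
    def test_constant_train(self):
        ts = lc.tempo_summary(lc.IOISeries.from_values([2.0, 2.0, 2.0]))
        assert (ts.n, ts.mean_t, ts.sd_t, ts.mean_rate) == (3, 2.0, 0.0, 0.5)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            lc.tempo_summary(lc.IOISeries.from_values([]))

    def test_mean_rate_is_per_interval_not_inverse_mean(self):
        ts = lc.tempo_summary(lc.IOISeries.from_values([0.1, 1.0]))
        assert np.isclose(ts.mean_rate, (10.0 + 1.0) / 2)
        assert not np.isclose(ts.mean_rate, 1.0 / ts.mean_t)
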