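"""Linear discriminant core and the crossed permuted DFA."""

import numpy as np
import pandas as pd
import pytest

import longcall as lc
from longcall.errors import DesignError, InsufficientDataError, ModelError
from longcall.pdfa import permute_within_blocks


def _two_clusters(rng, n=100, distance=6.0):
    X = np.vstack([rng.normal(0, 1, (n, 2)),
                   rng.normal(0, 1, (n, 2)) + [distance, 0.0]])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


def _acoustic_table(rng, n_indiv=8, per_cell=12, separation=0.0,
                    n_vars=7, indiv_sd=0.5):
    """Gaussian features; class means separated along the first axis.

    Cell sizes vary around ``per_cell`` so the balanced selection always
    leaves a cross-classification holdout.
    """
    labels = ("grumble_sub_pulse", "sub_pulse_transitory", "bubble_sub_pulse")
    rows = []
    for i in range(n_indiv):
        offset = rng.normal(0, indiv_sd, n_vars)
        for k, lab in enumerate(labels):
            mu = np.zeros(n_vars)
            mu[0] = k * separation
            n_cell = int(rng.integers(max(2, per_cell - 4), per_cell + 5))
            for _ in range(n_cell):
                x = mu + offset + rng.normal(0, 1, n_vars)
                row = {"individual_id": f"i{i}", "sub_type": lab}
                row.update({v: x[j] for j, v in
                            enumerate(lc.ACOUSTIC_MEASURES)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestFitLda:
    def test_separated_clusters_high_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _two_clusters(rng)
        model = lc.fit_lda(X, y)
        assert np.mean(model.predict(X) == y) >= 0.99

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(1)
        X, y = _two_clusters(rng, n=300)
        y_shuf = rng.permutation(y)
        model = lc.fit_lda(X, y_shuf)
        acc = np.mean(model.predict(X) == y_shuf)
        assert abs(acc - 0.5) < 0.1  # max prior = 0.5 for balanced labels

    def test_one_class_raises(self):
        X = np.random.default_rng(2).normal(size=(10, 3))
        with pytest.raises(InsufficientDataError):
            lc.fit_lda(X, np.array(["a"] * 10))

    def test_singular_covariance_advises_ridge(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        X = np.hstack([X, X[:, :1]])  # exact collinearity
        y = np.array(["a", "b"] * 10)
        with pytest.raises(ModelError, match="ridge"):
            lc.fit_lda(X, y)
        lc.fit_lda(X, y, ridge=0.1)  # regularized path works


class TestPermutation:
    def test_labels_never_cross_blocks(self):
        rng = np.random.default_rng(4)
        labels = np.array(list("aabbccaabbcc"))
        blocks = np.repeat(["b1", "b2"], 6)
        for _ in range(200):
            perm = permute_within_blocks(rng, labels, blocks)
            for b in ("b1", "b2"):
                assert sorted(perm[blocks == b]) == \
                    sorted(labels[blocks == b])

    def test_permutation_actually_shuffles(self):
        rng = np.random.default_rng(5)
        labels = np.array(list("abcdef"))
        blocks = np.zeros(6)
        assert any(not np.array_equal(
            permute_within_blocks(rng, labels, blocks), labels)
            for _ in range(10))


class TestPdfaCrossed:
    def test_strong_separation_floor_p_value(self):
        rng = np.random.default_rng(6)
        data = _acoustic_table(rng, separation=4.0)
        res = lc.pdfa_crossed(data, lc.PDFAConfig(n_sel=20, n_perm=100,
                                                  seed=10))
        assert res.p_value == pytest.approx(1.0 / 101.0)
        assert res.observed_pct_selected >= 95.0
        assert res.observed_pct_cross >= 90.0

    def test_null_world_not_significant(self):
        rng = np.random.default_rng(7)
        data = _acoustic_table(rng, separation=0.0)
        res = lc.pdfa_crossed(data, lc.PDFAConfig(n_sel=20, n_perm=100,
                                                  seed=11))
        assert res.p_value >= 0.05
        assert abs(res.observed_pct_selected - res.expected_pct) < 10.0

    def test_seeded_run_is_bit_reproducible(self):
        rng = np.random.default_rng(8)
        data = _acoustic_table(rng, separation=1.0)
        cfg = lc.PDFAConfig(n_sel=5, n_perm=100, seed=42)
        a = lc.pdfa_crossed(data, cfg)
        b = lc.pdfa_crossed(data, cfg)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_distribution, b.null_distribution)
        assert a.observed_pct_selected == b.observed_pct_selected

    def test_affine_rescaling_of_a_feature_is_irrelevant(self):
        rng = np.random.default_rng(9)
        data = _acoustic_table(rng, separation=1.5)
        cfg = lc.PDFAConfig(n_sel=5, n_perm=100, seed=13)
        base = lc.pdfa_crossed(data, cfg)
        scaled = data.copy()
        scaled["peak_frequency"] = scaled["peak_frequency"] * 120.0 + 600.0
        res = lc.pdfa_crossed(scaled, cfg)
        assert res.p_value == base.p_value
        assert res.observed_pct_selected == \
            pytest.approx(base.observed_pct_selected, abs=1e-9)

    def test_small_cells_dropped_with_record(self):
        rng = np.random.default_rng(10)
        data = _acoustic_table(rng, n_indiv=4, per_cell=6)
        # leave a 1-case cell for one individual/type
        drop = data[(data["individual_id"] == "i0")
                    & (data["sub_type"] == "bubble_sub_pulse")].index[1:]
        data = data.drop(index=drop)
        res = lc.pdfa_crossed(data, lc.PDFAConfig(n_sel=5, n_perm=100,
                                                  seed=14))
        assert ("i0", "bubble_sub_pulse", 1) in res.dropped_cells

    def test_design_without_two_test_levels_errors(self):
        rng = np.random.default_rng(11)
        data = _acoustic_table(rng, n_indiv=3)
        data = data[data["sub_type"] == "bubble_sub_pulse"]
        with pytest.raises(DesignError):
            lc.pdfa_crossed(data, lc.PDFAConfig(n_sel=5, n_perm=100, seed=1))

    def test_missing_variable_column_named(self):
        rng = np.random.default_rng(12)
        data = _acoustic_table(rng).drop(columns=["avg_entropy"])
        with pytest.raises(DesignError, match="avg_entropy"):
            lc.pdfa_crossed(data, lc.PDFAConfig(n_sel=5, n_perm=100, seed=1))

    def test_raven_style_variable_names_accepted(self):
        rng = np.random.default_rng(13)
        data = _acoustic_table(rng, separation=1.0)
        renamed = data.rename(columns={
            "duration": "Delta.Time", "peak_frequency": "Peak.Freq",
            "peak_time": "Peak.Time", "pfc_avg_slope": "PFC.Avg.Slope",
            "pfc_max_slope": "PFC.Max.Slope", "avg_entropy": "Avg.Entropy",
            "snr_nist_quick": "SNR.NIST.Quick"})
        cfg = lc.PDFAConfig(n_sel=5, n_perm=100, seed=3)
        assert lc.pdfa_crossed(renamed, cfg).p_value == \
            lc.pdfa_crossed(data, cfg).p_value
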