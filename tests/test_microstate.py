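"""Microstate clustering, back-fitting, temporal parameters, transitions.

Arithmetic operations are checked against brute-force oracles written here,
independently of the implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msalpha.core import EEGRecording, EpochSet, UNASSIGNED
from msalpha.microstate import (
    MicrostateModel,
    backfit,
    compute_cv,
    compute_gev,
    compute_gfp,
    match_templates,
    microstate_metrics,
    modified_kmeans,
    select_gfp_peaks,
    select_k,
    spatial_correlation,
    transition_matrix,
)
from msalpha.synth import make_templates, simulate_label_sequence
from conftest import uniform_tp


class TestGFP:
    def test_equal_channels_zero(self):
        assert compute_gfp(np.array([[5.0, 5.0, 5.0]]))[0] == 0.0

    def test_antisymmetric_pair(self):
        assert compute_gfp(np.array([[1.0, -1.0]]))[0] == pytest.approx(1.0)

    def test_matches_per_sample_sd_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(200, 62))
        got = compute_gfp(data)
        # brute force: per-sample population SD
        want = np.array([np.sqrt(np.mean((row - row.mean()) ** 2)) for row in data])
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestPeakSelection:
    def test_regular_maxima_all_retained(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        gfp = 40.0 * np.abs(np.sin(2 * np.pi * 10.0 * t))  # maxima every 50 ms
        idx = select_gfp_peaks(gfp, fs, min_peak_uv=20.0, sd_band=10.0)
        assert len(idx) == 40  # maxima of |sin| every 50 ms over 2 s
        assert np.all(np.diff(idx) >= 10)

    def test_close_peaks_keep_larger(self):
        gfp = np.zeros(100)
        gfp[50] = 30.0
        gfp[53] = 40.0  # 3 ms later at 1 kHz
        idx = select_gfp_peaks(gfp, 1000.0, min_interval_ms=10.0, sd_band=None)
        assert list(idx) == [53]

    def test_amplitude_floor(self):
        gfp = np.zeros(300)
        gfp[50], gfp[150], gfp[250] = 10.0, 25.0, 30.0
        idx = select_gfp_peaks(gfp, 1000.0, min_peak_uv=20.0, sd_band=None)
        assert list(idx) == [150, 250]

    def test_subsample_to_cap(self):
        fs = 1000.0
        t = np.arange(75000) / fs
        gfp = 40.0 * np.abs(np.sin(2 * np.pi * 10.0 * t))  # ~1500 maxima
        idx = select_gfp_peaks(gfp, fs, sd_band=10.0, max_peaks=1000, seed=1)
        assert len(idx) == 1000
        assert np.all(np.diff(idx) > 0)
        idx2 = select_gfp_peaks(gfp, fs, sd_band=10.0, max_peaks=1000, seed=1)
        np.testing.assert_array_equal(idx, idx2)

    def test_sd_band_excludes_outlying_peaks(self):
        gfp = np.zeros(2200)
        peaks = [30.0] * 20 + [31.0] * 20 + [300.0]  # one huge outlier
        for i, v in enumerate(peaks):
            gfp[20 + i * 50] = v
        idx = select_gfp_peaks(gfp, 1000.0, min_peak_uv=20.0, sd_band=1.0)
        assert len(idx) == 40  # outlier excluded
        assert np.all(gfp[idx] < 100)


class TestSpatialCorrelation:
    def test_self_and_negation(self):
        m = np.array([1.0, -2.0, 0.5, 0.5])
        assert spatial_correlation(m, m) == pytest.approx(1.0)
        assert spatial_correlation(m, -m, ignore_polarity=True) == pytest.approx(1.0)
        assert spatial_correlation(m, -m, ignore_polarity=False) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        ac, bc = a - a.mean(), b - b.mean()
        want = float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))
        assert spatial_correlation(a, b, ignore_polarity=False) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestModifiedKmeans:
    def test_exact_polarity_mixed_copies_recovered(self):
        T = make_templates(2, 8, seed=3)
        signs = np.resize([1.0, -1.0], 40)
        maps = 30.0 * signs[:, None] * T[np.resize([0, 1], 40)]
        model = modified_kmeans(maps, 2, n_init=5, seed=0)
        assert model.gev == pytest.approx(1.0, abs=1e-10)
        _, mean_corr = match_templates(model, T)
        assert mean_corr == pytest.approx(1.0, abs=1e-10)

    def test_global_negation_invariant(self):
        rng = np.random.default_rng(4)
        T = make_templates(3, 10, seed=4)
        maps = T[rng.integers(0, 3, 100)] * 25.0 + rng.normal(0, 2.0, (100, 10))
        a = modified_kmeans(maps, 3, n_init=10, seed=1)
        b = modified_kmeans(-maps, 3, n_init=10, seed=1)
        np.testing.assert_allclose(a.templates, b.templates, atol=1e-10)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)

    def test_noisy_five_state_recovery(self):
        rng = np.random.default_rng(5)
        T = make_templates(5, 32, seed=5)
        labels = rng.integers(0, 5, 1000)
        signs = rng.choice([-1.0, 1.0], 1000)
        maps = 40.0 * signs[:, None] * T[labels] + rng.normal(0, 40.0 / np.sqrt(4 * 32), (1000, 32))
        model = modified_kmeans(maps, 5, n_init=20, seed=2)
        _, mean_corr = match_templates(model, T)
        assert mean_corr >= 0.95

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        maps = rng.normal(size=(80, 12))
        a = modified_kmeans(maps, 3, n_init=5, seed=9)
        b = modified_kmeans(maps, 3, n_init=5, seed=9)
        np.testing.assert_array_equal(a.templates, b.templates)


class TestGEV:
    def test_perfect_assignment_is_one(self):
        T = make_templates(2, 6, seed=1)
        labels = np.array([0, 1, 0, 1])
        maps = 20.0 * T[labels]
        total, per_state = compute_gev(T, maps, labels)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert per_state.sum() == pytest.approx(total, abs=1e-12)

    def test_orthogonal_template_contributes_zero(self):
        T = make_templates(2, 6, seed=2)
        maps = 20.0 * T[[0, 0]]
        # assign both samples to the *other* (orthogonal) template
        total, per_state = compute_gev(T, maps, np.array([1, 1]))
        assert per_state[1] == pytest.approx(0.0, abs=1e-20)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(20, 4))
        T = make_templates(2, 4, seed=7)
        labels = rng.integers(0, 2, 20)
        total, per_state = compute_gev(T, maps, labels)
        # oracle: direct evaluation of the GFP-weighted squared correlation sum
        X = maps - maps.mean(axis=1, keepdims=True)
        gfp = X.std(axis=1)
        num = 0.0
        for t in range(20):
            tm = T[labels[t]] - T[labels[t]].mean()
            c = X[t] @ tm / (np.linalg.norm(X[t]) * np.linalg.norm(tm))
            num += (gfp[t] * c) ** 2
        assert total == pytest.approx(num / np.sum(gfp**2), abs=1e-12)


class TestCV:
    def test_perfect_fit_zero(self):
        T = make_templates(2, 6, seed=3)
        maps = 15.0 * np.vstack([T, -T])
        assert compute_cv(T, maps) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_instance(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(6, 4))
        T = make_templates(2, 4, seed=8)
        got = compute_cv(T, maps)
        # oracle: residual variance orthogonal to assigned template, penalized
        X = maps - maps.mean(axis=1, keepdims=True)
        best = np.argmax((X @ T.T) ** 2, axis=1)
        sigma2 = np.mean([
            (X[i] @ X[i] - (X[i] @ T[best[i]]) ** 2) / 3.0 for i in range(6)
        ]) * 3.0 / 3.0  # n_ch-1 = 3
        sigma2 = np.sum([X[i] @ X[i] - (X[i] @ T[best[i]]) ** 2 for i in range(6)]) / (6 * 3)
        want = sigma2 * (3.0 / (3.0 - 2.0)) ** 2
        assert got == pytest.approx(want, abs=1e-12)

    def test_too_few_channels_rejected(self):
        T = make_templates(3, 4, seed=0)
        with pytest.raises(ValueError):
            compute_cv(T, np.random.default_rng(0).normal(size=(10, 4)))

    def test_residual_variance_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        T = make_templates(4, 16, seed=9)
        maps = 30.0 * T[rng.integers(0, 4, 400)] + rng.normal(0, 3.0, (400, 16))
        sigmas = []
        for k in (2, 3, 4):
            m = modified_kmeans(maps, k, n_init=10, seed=3)
            X = maps - maps.mean(axis=1, keepdims=True)
            a = np.max(np.abs(X @ m.templates.T), axis=1)
            sigmas.append(float(np.sum(np.einsum("ij,ij->i", X, X) - a**2)))
        assert sigmas[0] >= sigmas[1] >= sigmas[2]


class TestSelectK:
    def _model(self, gev, cv):
        return MicrostateModel(templates=make_templates(2, 6, seed=0), gev=gev, cv=cv)

    def test_normalization_endpoints(self):
        models = {k: self._model(gev, cv) for k, gev, cv in
                  [(2, 0.4, 10.0), (3, 0.75, 4.0), (4, 0.8, 6.0)]}
        chosen, table = select_k(models)
        assert table.loc[table["cv"].idxmin(), "norm_cv"] == 0.0
        assert table.loc[table["gev"].idxmax(), "norm_gev"] == 1.0
        assert chosen == 3

    def test_tie_broken_toward_smaller_k(self):
        models = {k: self._model(0.1 * k, 1.0 * k) for k in (2, 3, 4)}
        with pytest.warns(UserWarning):
            chosen, _ = select_k(models)
        assert chosen == 2


class TestBackfit:
    def _setup(self):
        T = make_templates(3, 8, seed=10)
        labels = np.repeat([0, 1, 2, 1, 0, 2], 50)
        rec = EEGRecording(data=35.0 * T[labels], fs=250.0)
        model = MicrostateModel(templates=T, gev=1.0, cv=0.0)
        return model, rec, labels

    def test_noiseless_labels_exact(self):
        model, rec, labels = self._setup()
        got = backfit(model, rec)[0]
        np.testing.assert_array_equal(got, labels)

    def test_gain_and_polarity_invariance(self):
        model, rec, labels = self._setup()
        for factor in (2.0, -1.0, -0.3):
            got = backfit(model, rec.copy_with(factor * rec.data))[0]
            np.testing.assert_array_equal(got, labels)

    def test_zero_variance_sample_unassigned(self):
        model, rec, _ = self._setup()
        data = rec.data.copy()
        data[10] = 0.0
        got = backfit(model, rec.copy_with(data))[0]
        assert got[10] == UNASSIGNED


class TestMetrics:
    def test_known_coverage_occurrence_duration(self):
        fs = 1000.0
        labels = np.full(4000, 1)
        # 8 maximal runs of state 0, each 125 samples
        for i in range(8):
            labels[i * 500 : i * 500 + 125] = 0
        gfp = np.ones(4000)
        m = microstate_metrics([labels], [gfp], fs, 2)
        assert m.loc["A", "coverage"] == pytest.approx(0.25)
        assert m.loc["A", "occurrence"] == pytest.approx(2.0)
        assert m.loc["A", "duration"] == pytest.approx(125.0)

    def test_absent_state_reported_missing(self):
        m = microstate_metrics([np.zeros(100, dtype=int)], [np.ones(100)], 250.0, 2)
        assert m.loc["B", "coverage"] == 0.0
        assert m.loc["B", "occurrence"] == 0.0
        assert np.isnan(m.loc["B", "duration"])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(min_value=-1, max_value=3), min_size=20, max_size=300),
           st.sampled_from([100.0, 250.0, 1000.0]))
    def test_conservation_identities_fuzz(self, label_list, fs):
        """Coverage sums to 1 and coverage = occurrence x duration / 1000."""
        labels = np.array(label_list)
        if np.all(labels == UNASSIGNED):
            return
        gfp = np.abs(np.sin(np.arange(len(labels)))) + 0.1
        m = microstate_metrics([labels], [gfp], fs, 4)
        assert m["coverage"].sum() == pytest.approx(1.0, abs=1e-12)
        present = m["occurrence"] > 0
        np.testing.assert_allclose(
            m.loc[present, "coverage"],
            m.loc[present, "occurrence"] * m.loc[present, "duration"] / 1000.0,
            atol=1e-12,
        )


class TestTransitionMatrix:
    def test_alternating_sequence(self):
        labels = np.repeat([0, 1, 0, 1], 10)
        tp, counts = transition_matrix([labels], 2)
        assert tp[0, 1] == 1.0 and tp[1, 0] == 1.0
        assert counts.sum() == 3

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix([np.zeros(50, dtype=int)], 2)

    def test_rows_sum_to_one(self):
        labels = simulate_label_sequence(uniform_tp(4), np.full(4, 50.0), 20000, 1000.0, 3)
        tp, counts = transition_matrix([labels], 4)
        defined = counts.sum(axis=1) > 0
        np.testing.assert_allclose(tp[defined].sum(axis=1), 1.0, atol=1e-12)

    def test_recovers_generating_matrix(self):
        rng = np.random.default_rng(12)
        tp_true = np.zeros((5, 5))
        for i in range(5):
            tp_true[i, np.arange(5) != i] = rng.dirichlet(np.full(4, 6.0))
        # ~2e4 transitions at 50 ms dwells / 1 kHz
        labels = simulate_label_sequence(tp_true, np.full(5, 50.0), 10**6, 1000.0, 13)
        tp_est, counts = transition_matrix([labels], 5)
        assert counts.sum() >= 2e4
        assert np.max(np.abs(tp_est - tp_true)) <= 0.03

    def test_epoch_boundaries_not_bridged(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([2, 2, 0, 0])
        tp, counts = transition_matrix([a, b], 3)
        assert counts[1, 2] == 0  # boundary 1->2 not counted
        assert counts.sum() == 2
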