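"""Attribution algebra: rollout identities, closed forms, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import frostgrip as fg
from frostgrip.attribution import (AttributionConfig, average_heads,
                                   fuse_profiles, minmax_normalize, peak_time,
                                   peak_interval_histogram, residual_adjust,
                                   rollout, temporal_score)
from frostgrip.models import build_model

WORKED_A_BAR = np.array([[0.5, 0.3, 0.2],
                         [0.2, 0.6, 0.2],
                         [0.1, 0.1, 0.8]])
WORKED_A_TILDE = np.array([[0.75, 0.15, 0.10],
                           [0.10, 0.80, 0.10],
                           [0.05, 0.05, 0.90]])


def random_row_stochastic(rng, T):
    m = rng.random((T, T)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)


def brute_force_scores(maps):
    """Independent oracle: explicit loops over Eqs. head-mean ->
    residual row-norm -> product -> column means."""
    H = len(maps)
    T = maps[0].shape[0]
    A_bar = np.zeros((T, T))
    for h in range(H):
        for i in range(T):
            for j in range(T):
                A_bar[i, j] += maps[h][i, j] / H
    adj = np.zeros((T, T))
    for i in range(T):
        row = [A_bar[i, j] + (1.0 if i == j else 0.0) for j in range(T)]
        s = sum(row)
        for j in range(T):
            adj[i, j] = row[j] / s
    s = np.zeros(T)
    for t in range(T):
        s[t] = sum(adj[q, t] for q in range(T)) / T
    return adj, s


class TestAlgebra:
    def test_average_heads_single(self):
        assert np.array_equal(average_heads([WORKED_A_BAR]), WORKED_A_BAR)

    def test_average_identity_and_uniform(self):
        T = 4
        avg = average_heads([np.eye(T), np.full((T, T), 1.0 / T)])
        assert np.allclose(np.diag(avg), (1 + 1.0 / T) / 2)
        off = avg[~np.eye(T, dtype=bool)]
        assert np.allclose(off, 1.0 / (2 * T))
        assert np.allclose(avg.sum(axis=1), 1.0)

    def test_average_empty_rejected(self):
        with pytest.raises(ValueError):
            average_heads([])

    def test_residual_adjust_identity_fixed_point(self):
        assert np.allclose(residual_adjust(np.eye(2)), np.eye(2))

    def test_residual_adjust_worked_example(self):
        assert np.allclose(residual_adjust(WORKED_A_BAR), WORKED_A_TILDE)

    def test_residual_adjust_uniform(self):
        T = 50
        adj = residual_adjust(np.full((T, T), 1.0 / T))
        assert np.allclose(np.diag(adj), 0.51)
        assert np.allclose(adj[~np.eye(T, dtype=bool)], 0.01)

    def test_rollout_single_layer_is_identity_operation(self):
        R = rollout([WORKED_A_TILDE])
        assert R is WORKED_A_TILDE

    def test_rollout_of_identities(self):
        assert np.array_equal(rollout([np.eye(5), np.eye(5)]), np.eye(5))

    def test_rollout_preserves_row_stochasticity(self):
        rng = np.random.default_rng(0)
        maps = [random_row_stochastic(rng, 6) for _ in range(3)]
        assert np.allclose(rollout(maps).sum(axis=1), 1.0, atol=1e-9)

    def test_rollout_shape_mismatch(self):
        with pytest.raises(ValueError):
            rollout([np.eye(3), np.eye(4)])

    def test_temporal_score_uniform_and_identity(self):
        for T in (3, 50):
            assert np.allclose(temporal_score(np.full((T, T), 1.0 / T)),
                               1.0 / T)
            assert np.allclose(temporal_score(np.eye(T)), 1.0 / T)

    def test_temporal_score_worked_example(self):
        s = temporal_score(WORKED_A_TILDE)
        assert np.allclose(s, [0.3000, 0.3333, 0.3667], atol=1e-4)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_pipeline_matches_brute_force(self, T, seed):
        rng = np.random.default_rng(seed)
        maps = [random_row_stochastic(rng, T) for _ in range(2)]
        A_tilde = residual_adjust(average_heads(maps))
        s = temporal_score(rollout([A_tilde]))
        oracle_adj, oracle_s = brute_force_scores(maps)
        assert np.allclose(A_tilde, oracle_adj, atol=1e-9)
        assert np.allclose(s, oracle_s, atol=1e-9)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)


class TestNormalizationAndPeaks:
    def test_minmax_constant_to_zero(self):
        assert np.allclose(minmax_normalize(np.full(50, 0.02)), 0.0)

    def test_minmax_worked_example(self):
        # exact column means of the worked 3x3 residual-adjusted map
        s_hat = minmax_normalize(np.array([0.3, 1 / 3, 11 / 30]))
        assert np.allclose(s_hat, [0.0, 0.5, 1.0], atol=1e-4)

    def test_minmax_min_is_zero(self):
        rng = np.random.default_rng(1)
        assert minmax_normalize(rng.random(50)).min() == 0.0

    def test_fuse_profiles(self):
        assert np.allclose(fuse_profiles(np.array([1.0, 0]),
                                         np.array([0.0, 1])), [0.5, 0.5])
        p = np.array([0.0, 0.5, 1.0])
        assert np.array_equal(fuse_profiles(p, p), p)
        assert np.allclose(fuse_profiles(p, p[::-1]), 0.5)

    def test_fuse_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse_profiles(np.zeros(3), np.zeros(4))

    def test_peak_time_and_tie_rule(self):
        assert peak_time(np.array([0.1, 0.9, 0.3])) == 1
        assert peak_time(np.array([0.5, 0.5, 0.5])) == 0
        assert peak_time(np.array([0.0, 0.5, 1.0])) == 2

    def test_histogram_first_bin(self):
        cfg = AttributionConfig(interval_width=5)
        h = peak_interval_histogram([0, 1, 2, 3, 4], cfg, T=50)
        assert h.counts[0] == 5 and h.counts[1:].sum() == 0

    def test_histogram_extremes(self):
        cfg = AttributionConfig(interval_width=5)
        h = peak_interval_histogram([0, 49], cfg, T=50)
        assert h.counts[0] == 1 and h.counts[9] == 1

    def test_histogram_partition_property(self):
        cfg = AttributionConfig(interval_width=7)
        rng = np.random.default_rng(2)
        t_stars = rng.integers(0, 50, 200)
        h = peak_interval_histogram(t_stars, cfg, T=50)
        assert h.counts.sum() == 200

    def test_histogram_errors(self):
        cfg = AttributionConfig()
        with pytest.raises(ValueError):
            peak_interval_histogram([], cfg, T=50)
        with pytest.raises(ValueError):
            peak_interval_histogram([50], cfg, T=50)


class TestEndToEnd:
    def test_profiles_conserve_mass(self, small_inputs):
        model = build_model("fusion", seed=4)
        profiles, hist = fg.attribute_dataset(model, small_inputs)
        assert len(profiles) == len(small_inputs)
        for p in profiles:
            assert p.s_p.sum() == pytest.approx(1.0, abs=1e-6)
            assert p.s_v.sum() == pytest.approx(1.0, abs=1e-6)
            assert 0 <= p.t_star <= 49
        assert hist.counts.sum() == len(small_inputs)

    def test_zero_projection_model_uniform_profiles(self, small_inputs):
        model = build_model("fusion", seed=4)
        for br in (model.branch_p, model.branch_v):
            for w in (br.Wq, br.bq, br.Wk, br.bk):
                w.data = np.zeros_like(w.data)
        profiles, hist = fg.attribute_dataset(model, small_inputs)
        for p in profiles:
            assert np.allclose(p.s_p, 1.0 / 50)
            assert np.allclose(p.s_hat_fused, 0.0, atol=1e-9)
            assert p.t_star == 0  # tie rule: earliest index
        assert hist.counts[0] == len(small_inputs)

    def test_single_modality_attribution(self, small_inputs):
        model = build_model("pressure_only", seed=4)
        profile = fg.attribute_sample(model, small_inputs[0])
        assert profile.s_v is None
        assert np.array_equal(profile.s_hat_fused, profile.s_hat_p)

    def test_save_attributions(self, small_inputs, tmp_path):
        model = build_model("fusion", seed=4)
        profiles, hist = fg.attribute_dataset(model, small_inputs)
        out = fg.save_attributions(profiles, hist, tmp_path)
        assert (out / "profiles.csv").exists()
        assert (out / "histogram.json").exists()
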