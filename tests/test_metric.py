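"""Log-ratio loss algebra, triplet-sampler contract, and the gamma penalty."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metricvae.metric import (
    MetricConfig,
    Triplet,
    gamma_penalty,
    log_ratio_loss,
    metric_vae_loss,
    neighborhood_size,
    sample_triplets,
)
from metricvae.tcvae import AlphaSchedule, KLDecomposition


class TestLogRatioLoss:
    def test_matched_ratios_zero(self):
        f = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array([0.0, 1.0, 2.0])
        assert log_ratio_loss([Triplet(0, 1, 2)], f, y, epsilon=0.0) == 0.0

    def test_hand_evaluated_mismatch(self):
        f = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        y = np.array([0.0, 1.0, 2.0])
        expected = (math.log(9) - math.log(4)) ** 2  # ~0.6576
        assert log_ratio_loss([Triplet(0, 1, 2)], f, y, epsilon=0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_swap_symmetry(self, rng):
        f = rng.normal(size=(3, 4))
        y = rng.normal(size=3)
        a = log_ratio_loss([Triplet(0, 1, 2)], f, y, epsilon=0.0)
        b = log_ratio_loss([Triplet(0, 2, 1)], f, y, epsilon=0.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_label_rescaling_invariance(self, rng):
        f = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        trip = [Triplet(0, 1, 2), Triplet(3, 4, 5), Triplet(6, 7, 0)]
        base = log_ratio_loss(trip, f, y, epsilon=0.0)
        scaled = log_ratio_loss(trip, f, 37.5 * y, epsilon=0.0)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_latent_rescaling_invariance(self, rng):
        f = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        trip = [Triplet(1, 2, 3), Triplet(4, 5, 6)]
        base = log_ratio_loss(trip, f, y, epsilon=0.0)
        scaled = log_ratio_loss(trip, 0.013 * f, y, epsilon=0.0)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_nonnegative(self, rng):
        f = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        trip = [Triplet(0, 1, 2), Triplet(5, 6, 7)]
        assert log_ratio_loss(trip, f, y) >= 0.0

    def test_empty_triplets_rejected(self, rng):
        with pytest.raises(ValueError, match="no triplets"):
            log_ratio_loss([], rng.normal(size=(4, 2)), rng.normal(size=4))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        trip = [Triplet(0, 1, 2), Triplet(3, 4, 5)]
        eps = 1e-8
        expected = 0.0
        for t in trip:
            dan = sum((f[t.anchor] - f[t.negative]) ** 2)
            dap = sum((f[t.anchor] - f[t.positive]) ** 2)
            yan = (y[t.anchor] - y[t.negative]) ** 2
            yap = (y[t.anchor] - y[t.positive]) ** 2
            expected += (
                math.log((dan + eps) / (dap + eps)) - math.log((yan + eps) / (yap + eps))
            ) ** 2
        expected /= len(trip)
        assert log_ratio_loss(trip, f, y, eps) == pytest.approx(expected, abs=1e-9)


class TestSampleTriplets:
    def test_hand_enumerated_batch_of_four(self):
        # fraction 1.0, anchor 0: neighborhood = {1,2,3}; property distances
        # 1,2,3 -> ranked [1,2,3]; pair (1,2) -> triplet, 3 left unpaired
        latents = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        cfg = MetricConfig(neighborhood_fraction=1.0)
        trip = sample_triplets(latents, y, cfg, anchor_order=[0])
        assert trip == [Triplet(anchor=0, positive=1, negative=2)]

    def test_neighborhood_fraction_arithmetic(self):
        assert neighborhood_size(16, 0.25) == int(np.ceil(0.25 * 15)) == 4
        assert neighborhood_size(4, 0.25) == 2  # padded to the minimum pair

    def test_postconditions_random_batches(self, rng):
        cfg = MetricConfig(neighborhood_fraction=0.25)
        for _ in range(200):
            B = int(rng.integers(4, 33))
            latents = rng.normal(size=(B, 3))
            y = rng.normal(size=B)
            m = neighborhood_size(B, cfg.neighborhood_fraction)
            for t in sample_triplets(latents, y, cfg):
                d = np.linalg.norm(latents - latents[t.anchor], axis=1)
                d[t.anchor] = np.inf
                kept = set(np.argsort(d, kind="stable")[:m])
                assert {t.positive, t.negative} <= kept
                assert abs(y[t.positive] - y[t.anchor]) <= abs(y[t.negative] - y[t.anchor])

    def test_every_anchor_used_once(self, rng):
        latents = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        trip = sample_triplets(latents, y, MetricConfig(neighborhood_fraction=0.5))
        anchors = [t.anchor for t in trip]
        # fraction 0.5 of 11 -> 6 kept -> 3 pairs per anchor
        assert sorted(set(anchors)) == list(range(12))
        assert all(anchors.count(a) == 3 for a in range(12))

    def test_small_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            sample_triplets(rng.normal(size=(3, 2)), rng.normal(size=3), MetricConfig())


class TestGammaPenalty:
    def test_exact_linear_dimension_gives_zero(self, rng):
        y = rng.normal(size=20)
        z = rng.normal(size=(20, 4))
        z[:, 2] = 3.0 * y - 1.0
        assert gamma_penalty(z, y, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_latents_give_full_coefficient(self):
        # constructed zero-correlation case
        y = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([[1.0, 2.0], [1.0, 2.0], [-1.0, 0.0], [-1.0, 0.0]])
        assert gamma_penalty(z, y, 0.1) == pytest.approx(0.1, abs=1e-12)

    def test_matches_independent_correlation_routine(self, rng):
        from scipy.stats import pearsonr

        z = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        best = max(abs(pearsonr(z[:, j], y)[0]) for j in range(5))
        assert gamma_penalty(z, y, 0.1) == pytest.approx(0.1 * (1 - best), abs=1e-9)

    def test_degenerate_variance_treated_as_zero_correlation(self):
        z = np.ones((5, 3))
        y = np.arange(5.0)
        assert gamma_penalty(z, y, 0.1) == 0.1
        # constant y: correlation undefined -> treated as 0
        assert gamma_penalty(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5), 0.1) == 0.1

    def test_bounded_on_random_batches(self, rng):
        for _ in range(300):
            z = rng.normal(size=(int(rng.integers(3, 40)), 6))
            y = rng.normal(size=z.shape[0])
            g = gamma_penalty(z, y, 0.1)
            assert 0.0 <= g <= 0.1


class TestMetricVAELoss:
    def test_zero_metric_term_reduces_to_tcvae(self):
        decomp = KLDecomposition(mi=0.5, tc=0.2, dwkl=0.1)
        bd = metric_vae_loss(1.0, decomp, AlphaSchedule(), 10, 0.0, 0.1)
        from metricvae.tcvae import weighted_kl

        assert bd.total == pytest.approx(1.0 + weighted_kl(decomp, AlphaSchedule(), 10))

    def test_component_arithmetic(self):
        decomp = KLDecomposition(mi=0.0, tc=0.0, dwkl=0.0)
        bd = metric_vae_loss(1.0, decomp, AlphaSchedule(), 0, 2.0, 0.1)
        assert bd.total == pytest.approx(1.2)
        assert set(bd.components) == {"recon", "mi", "tc", "dwkl", "metric", "gamma", "total"}

    def test_zero_gamma_annihilates_metric(self):
        decomp = KLDecomposition(mi=0.0, tc=0.0, dwkl=0.0)
        bd = metric_vae_loss(1.0, decomp, AlphaSchedule(), 0, 123.0, 0.0)
        assert bd.total == pytest.approx(1.0)
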