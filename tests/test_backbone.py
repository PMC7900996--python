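"""Encoder/decoder contracts, loss closed forms, and a small training oracle."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import softmax

from metricvae.backbone import (
    ModelConfig,
    decode_logits,
    encode,
    greedy_decode,
    init_params,
    kl_standard_normal,
    reconstruction_loss,
    sequence_reconstruction_loss,
)
from metricvae.data import TokenSequence, build_vocabulary, encode_batch
from metricvae.config import RunConfig
from metricvae.tcvae import AlphaSchedule
from metricvae.synthetic import SyntheticSpec, generate_encoded_dataset
from metricvae.training import train
from tests.conftest import TINY_MODEL


class TestEncode:
    def test_shapes(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs[:2], max_len=6, vocab=vocab)
        lat = encode(params, config, batch, lengths)
        assert lat.mu.shape == lat.logvar.shape == lat.z.shape == (2, config.latent_dim)

    def test_identical_rows_identical_mu(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch([seqs[0], seqs[0]], max_len=6, vocab=vocab)
        lat = encode(params, config, batch, lengths)
        assert np.array_equal(lat.mu[0], lat.mu[1])

    def test_zero_noise_gives_mu(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs, max_len=6, vocab=vocab)
        lat = encode(params, config, batch, lengths, eps=None)
        assert np.array_equal(lat.z, lat.mu)

    def test_reparameterization_identity(self, tiny_model, tiny_corpus, rng):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs, max_len=6, vocab=vocab)
        eps = rng.standard_normal((len(seqs), config.latent_dim))
        lat = encode(params, config, batch, lengths, eps=eps)
        assert np.allclose(lat.z, lat.mu + np.exp(lat.logvar / 2) * eps)

    def test_out_of_range_token_rejected(self, tiny_model):
        params, config, vocab = tiny_model
        bad = np.array([[vocab.size + 3, 0]])
        with pytest.raises(ValueError, match="out of range"):
            encode(params, config, bad, np.array([1]))


class TestDecode:
    def test_logits_normalize_per_step(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs, max_len=6, vocab=vocab)
        lat = encode(params, config, batch, lengths)
        logits = decode_logits(params, config, lat.z, batch[:, :-1], lengths)
        probs = softmax(logits, axis=2)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-9)

    def test_zero_latent_valid_logits(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs, max_len=6, vocab=vocab)
        z = np.zeros((len(seqs), config.latent_dim))
        logits = decode_logits(params, config, z, batch[:, :-1], lengths)
        assert np.all(np.isfinite(logits))

    def test_latent_dim_mismatch(self, tiny_model, tiny_corpus):
        params, config, vocab = tiny_model
        _, seqs, _ = tiny_corpus
        batch, lengths = encode_batch(seqs, max_len=6, vocab=vocab)
        with pytest.raises(ValueError, match="latent"):
            decode_logits(params, config, np.zeros((len(seqs), 7)), batch[:, :-1], lengths)


class TestReconstructionLoss:
    def test_uniform_logits_log_vocab(self):
        V = 7
        logits = np.zeros((3, 5, V))
        targets = np.random.default_rng(0).integers(0, V - 1, size=(3, 5))
        assert reconstruction_loss(logits, targets, pad_index=V - 1) == pytest.approx(
            np.log(V), abs=1e-12
        )

    def test_confident_correct_logits_near_zero(self):
        targets = np.array([[0, 1, 2]])
        logits = np.full((1, 3, 4), -50.0)
        for t, tok in enumerate(targets[0]):
            logits[0, t, tok] = 50.0
        assert reconstruction_loss(logits, targets, pad_index=3) < 1e-8

    def test_matches_per_position_cross_entropy(self, rng):
        # brute-force oracle: independent per-position NLL sum / count
        B, T, V, pad = 4, 6, 5, 4
        logits = rng.standard_normal((B, T, V))
        targets = rng.integers(0, V, size=(B, T))
        expected, count = 0.0, 0
        for b in range(B):
            for t in range(T):
                if targets[b, t] == pad:
                    continue
                p = softmax(logits[b, t])
                expected += -np.log(p[targets[b, t]])
                count += 1
        assert reconstruction_loss(logits, targets, pad) == pytest.approx(
            expected / count, abs=1e-6
        )

    def test_sequence_sum_variant_scales_by_tokens(self, rng):
        B, T, V, pad = 3, 5, 4, 3
        logits = rng.standard_normal((B, T, V))
        targets = rng.integers(0, V - 1, size=(B, T))
        mean_loss = reconstruction_loss(logits, targets, pad)
        n_tokens = (targets != pad).sum()
        assert sequence_reconstruction_loss(logits, targets, pad) == pytest.approx(
            mean_loss * n_tokens / B, rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruction_loss(np.zeros((2, 3, 4)), np.zeros((2, 4), dtype=int), 0)


class TestKL:
    def test_standard_normal_zero(self):
        assert kl_standard_normal(np.zeros((2, 3)), np.zeros((2, 3))) == 0.0

    def test_unit_mean_half(self):
        mu = np.array([[1.0, 0.0, 0.0]])
        assert kl_standard_normal(mu, np.zeros_like(mu)) == pytest.approx(0.5, abs=1e-12)

    def test_nonnegative_random(self, rng):
        mu = rng.standard_normal((20, 6))
        logvar = rng.standard_normal((20, 6))
        assert kl_standard_normal(mu, logvar) >= 0.0

    def test_quadrature_oracle(self, rng):
        # 1-D KL integrals per dimension, summed, vs the closed form
        mu = rng.normal(0, 1, size=(3, 2))
        logvar = rng.normal(0, 0.5, size=(3, 2))
        total = 0.0
        for b in range(3):
            for d in range(2):
                s = np.exp(logvar[b, d] / 2)

                def integrand(x):
                    q = np.exp(-0.5 * ((x - mu[b, d]) / s) ** 2) / (s * np.sqrt(2 * np.pi))
                    logq = -0.5 * ((x - mu[b, d]) / s) ** 2 - np.log(s * np.sqrt(2 * np.pi))
                    logp = -0.5 * x**2 - 0.5 * np.log(2 * np.pi)
                    return q * (logq - logp)

                total += quad(integrand, -30, 30, limit=200)[0]
        assert kl_standard_normal(mu, logvar) == pytest.approx(total / 3, abs=1e-6)


class TestTrainingOracles:
    def test_overfit_reproduces_training_tokens(self):
        """A small autoencoding run memorizes its corpus: greedy rollout
        from the posterior mean reproduces >= 99% of training tokens."""
        seqs, props, vocab = generate_encoded_dataset(
            SyntheticSpec(n_molecules=25, alphabet_size=4, length_range=(2, 5), seed=3)
        )
        cfg = RunConfig(
            mode="vae",
            model=ModelConfig(
                latent_dim=4, rnn_layers=1, hidden_size=32, embed_dim=12,
                bidirectional_encoder=True, learning_rate=5e-3,
            ),
            schedule=AlphaSchedule(alpha1=0.0, alpha3=0.0, alpha2_start=0.0, alpha2_end=0.0),
            epochs=250,
            batch_size=20,
            seed=0,
            max_len=5,
            tokenizer="whitespace",
        )
        result = train(cfg, seqs, props, vocab)
        train_rows = result.split.train
        batch, lengths = encode_batch([seqs[i] for i in train_rows], 5, vocab)
        lat = encode(result.params, cfg.model, batch, lengths, eps=None)
        rolled = greedy_decode(result.params, cfg.model, lat.mu, vocab, max_steps=8)
        total = correct = 0
        for row, out in zip(train_rows, rolled):
            ref = list(seqs[row].indices)
            total += len(ref)
            correct += sum(a == b for a, b in zip(ref, out))
        assert correct / total >= 0.99

    def test_loss_decreases_on_overfit_task(self):
        seqs, props, vocab = generate_encoded_dataset(
            SyntheticSpec(n_molecules=63, alphabet_size=4, length_range=(2, 6), seed=1)
        )
        cfg = RunConfig(
            mode="vae", model=TINY_MODEL, epochs=40, batch_size=50, seed=0,
            max_len=6, tokenizer="whitespace",
        )
        result = train(cfg, seqs, props, vocab)  # 40 epochs x 1 batch = 200 steps
        assert result.log[-1]["total"] < result.log[0]["total"]
        assert all(np.isfinite(row["total"]) for row in result.log)
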