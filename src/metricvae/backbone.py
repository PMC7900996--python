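"""Recurrent sequence VAE: bidirectional GRU encoder to a diagonal-Gaussian
posterior, reparameterized sampling, autoregressive GRU decoder.

The model is written functionally over a flat parameter dict of numpy
arrays so the whole training objective can be differentiated with
``autograd``. All forward functions accept either plain arrays or autograd
boxes; outside training they run as ordinary numpy.

Architecture (defaults follow the grammar-VAE setup this reuses): token
embedding, 3-layer bidirectional GRU encoder with 384 hidden units, a
linear map from the final recurrent state to the mean and log-variance of
a 50-dimensional Gaussian, and a 3-layer unidirectional GRU decoder whose
initial state is a learned map of z; z is additionally concatenated to
every decoder input step to strengthen the conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .data import Vocabulary


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimizer constants.

    Defaults are the reference values for the grammar-sequence model:
    z in R^50, three GRU layers of 384 units (encoder bidirectional),
    900-dim token embedding, Adam with learning rate 0.001.
    """

    latent_dim: int = 50
    rnn_layers: int = 3
    hidden_size: int = 384
    embed_dim: int = 900
    bidirectional_encoder: bool = True
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("latent_dim", "rnn_layers", "hidden_size", "embed_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class LatentBatch:
    """Posterior parameters and a reparameterized sample for one minibatch.

    ``z = mu + exp(logvar/2) * eps`` with the noise ``eps`` recorded;
    ``eps = 0`` gives the deterministic embedding ``z == mu`` used for
    evaluation.
    """

    def __init__(self, mu, logvar, z, eps) -> None:
        self.mu = mu
        self.logvar = logvar
        self.z = z
        self.eps = eps

    @property
    def batch_size(self) -> int:
        return self.mu.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(config: ModelConfig, vocab_size: int, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights, zero biases, for every model matrix."""
    H, E, L = config.hidden_size, config.embed_dim, config.latent_dim
    dirs = 2 if config.bidirectional_encoder else 1
    p: dict[str, np.ndarray] = {}
    p["embed"] = rng.normal(0.0, 0.1, size=(vocab_size, E))
    for layer in range(config.rnn_layers):
        in_dim = E if layer == 0 else H * dirs
        for d in range(dirs):
            tag = f"enc_{layer}_{d}"
            p[f"{tag}_Wx"] = _glorot(rng, in_dim, 3 * H)
            p[f"{tag}_Wh"] = _glorot(rng, H, 3 * H)
            p[f"{tag}_bx"] = np.zeros(3 * H)
            p[f"{tag}_bh"] = np.zeros(3 * H)
    p["enc_out_W"] = _glorot(rng, H * dirs, 2 * L)
    p["enc_out_b"] = np.zeros(2 * L)
    for layer in range(config.rnn_layers):
        in_dim = (E + L) if layer == 0 else H
        tag = f"dec_{layer}"
        p[f"{tag}_Wx"] = _glorot(rng, in_dim, 3 * H)
        p[f"{tag}_Wh"] = _glorot(rng, H, 3 * H)
        p[f"{tag}_bx"] = np.zeros(3 * H)
        p[f"{tag}_bh"] = np.zeros(3 * H)
        p[f"dec_init_W_{layer}"] = _glorot(rng, L, H)
        p[f"dec_init_b_{layer}"] = np.zeros(H)
    p["out_W"] = _glorot(rng, H, vocab_size)
    p["out_b"] = np.zeros(vocab_size)
    return p


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _gru_step(gx_t, h, Wh, bh, mask_t):
    """One fused-gate GRU step with a (batch, 1) validity mask."""
    Hn = h.shape[1]
    gh = anp.dot(h, Wh) + bh
    r = _sigmoid(gx_t[:, :Hn] + gh[:, :Hn])
    u = _sigmoid(gx_t[:, Hn : 2 * Hn] + gh[:, Hn : 2 * Hn])
    n = anp.tanh(gx_t[:, 2 * Hn :] + r * gh[:, 2 * Hn :])
    h_new = (1.0 - u) * n + u * h
    return mask_t * h_new + (1.0 - mask_t) * h


def _run_gru_layer(params, tag, inputs, mask, reverse: bool, collect: bool = True):
    """inputs: (B, T, in_dim) -> hidden sequence (B, T, H) and final state.

    ``collect=False`` skips assembling the per-step output sequence (only
    the final state is needed by a top encoder layer).
    """
    B, T, _ = inputs.shape
    Wh = params[f"{tag}_Wh"]
    H = Wh.shape[0]
    gx = anp.dot(inputs, params[f"{tag}_Wx"]) + params[f"{tag}_bx"]
    h = anp.zeros((B, H))
    steps = range(T - 1, -1, -1) if reverse else range(T)
    outs = [None] * T
    for t in steps:
        h = _gru_step(gx[:, t, :], h, Wh, params[f"{tag}_bh"], mask[:, t : t + 1])
        if collect:
            outs[t] = h
    return (anp.stack(outs, axis=1) if collect else None), h


def _validity_mask(batch: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    # START + tokens + END occupy the first lengths+2 positions
    T = batch.shape[1]
    return (np.arange(T)[None, :] < (np.asarray(lengths)[:, None] + 2)).astype(np.float64)


def encode(params, config: ModelConfig, batch: np.ndarray, lengths: np.ndarray, eps=None) -> LatentBatch:
    """Map an index batch to its posterior; deterministic given ``eps``.

    ``eps`` is the reparameterization noise, shape (batch, latent_dim);
    ``None`` means zero noise, i.e. z == mu.
    """
    batch = np.asarray(batch)
    vocab_size = params["embed"].shape[0]
    if batch.max() >= vocab_size:
        raise ValueError(
            f"token index {int(batch.max())} out of range for vocabulary of size {vocab_size}"
        )
    mask = _validity_mask(batch, lengths)
    dirs = 2 if config.bidirectional_encoder else 1
    inputs = params["embed"][batch]
    finals = None
    for layer in range(config.rnn_layers):
        last = layer == config.rnn_layers - 1
        seq_f, h_f = _run_gru_layer(
            params, f"enc_{layer}_0", inputs, mask, reverse=False, collect=not last
        )
        if dirs == 2:
            seq_b, h_b = _run_gru_layer(
                params, f"enc_{layer}_1", inputs, mask, reverse=True, collect=not last
            )
            if not last:
                inputs = anp.concatenate([seq_f, seq_b], axis=2)
            finals = anp.concatenate([h_f, h_b], axis=1)
        else:
            inputs = seq_f
            finals = h_f
    stats = anp.dot(finals, params["enc_out_W"]) + params["enc_out_b"]
    L = config.latent_dim
    mu, logvar = stats[:, :L], stats[:, L:]
    if eps is None:
        eps = np.zeros((batch.shape[0], L))
    z = mu + anp.exp(0.5 * logvar) * eps
    return LatentBatch(mu=mu, logvar=logvar, z=z, eps=eps)


def decode_logits(params, config: ModelConfig, z, teacher: np.ndarray, lengths: np.ndarray):
    """Teacher-forced decoder logits, one categorical per step.

    ``teacher`` is the START-shifted input (the encoded batch minus its
    last column); returns (batch, steps, vocab) logits.
    """
    teacher = np.asarray(teacher)
    if z.shape[1] != config.latent_dim:
        raise ValueError(f"latent dim {z.shape[1]} != config.latent_dim {config.latent_dim}")
    B, T = teacher.shape
    # decoder consumes START..END-1, predicts positions 1..END
    mask = (np.arange(T)[None, :] < (np.asarray(lengths)[:, None] + 1)).astype(np.float64)
    emb = params["embed"][teacher]
    ztile = anp.repeat(z[:, None, :], T, axis=1)
    inputs = anp.concatenate([emb, ztile], axis=2)
    for layer in range(config.rnn_layers):
        h0 = anp.tanh(anp.dot(z, params[f"dec_init_W_{layer}"]) + params[f"dec_init_b_{layer}"])
        inputs = _run_gru_layer_with_init(params, f"dec_{layer}", inputs, mask, h0)
    return anp.dot(inputs, params["out_W"]) + params["out_b"]


def _run_gru_layer_with_init(params, tag, inputs, mask, h0):
    B, T, _ = inputs.shape
    Wh = params[f"{tag}_Wh"]
    gx = anp.dot(inputs, params[f"{tag}_Wx"]) + params[f"{tag}_bx"]
    h = h0
    outs = []
    for t in range(T):
        h = _gru_step(gx[:, t, :], h, Wh, params[f"{tag}_bh"], mask[:, t : t + 1])
        outs.append(h)
    return anp.stack(outs, axis=1)


def reconstruction_loss(logits, targets: np.ndarray, pad_index: int):
    """Mean negative log-likelihood of the target token over non-PAD steps."""
    targets = np.asarray(targets)
    if logits.shape[:2] != targets.shape:
        raise ValueError(f"logits {logits.shape} vs targets {targets.shape} mismatch")
    V = logits.shape[2]
    logz = anp.log(anp.sum(anp.exp(logits - anp.max(logits, axis=2, keepdims=True)), axis=2))
    logz = logz + anp.max(logits, axis=2)
    onehot = np.eye(V)[targets]
    picked = anp.sum(logits * onehot, axis=2)
    nll = logz - picked
    mask = (targets != pad_index).astype(np.float64)
    return anp.sum(nll * mask) / np.sum(mask)


def sequence_reconstruction_loss(logits, targets: np.ndarray, pad_index: int):
    """Per-molecule summed cross-entropy, averaged over the batch.

    This is the reconstruction term of the training objective: summing
    over sequence positions keeps it on the same per-molecule scale as
    the KL terms. :func:`reconstruction_loss` is the per-token mean of
    the same masked NLL.
    """
    targets = np.asarray(targets)
    mask = (targets != pad_index).astype(np.float64)
    per_token = reconstruction_loss(logits, targets, pad_index)
    return per_token * (np.sum(mask) / targets.shape[0])


def kl_standard_normal(mu, logvar):
    """Batch-mean KL( N(mu, diag e^logvar) || N(0, I) ), closed form."""
    per = 0.5 * anp.sum(anp.exp(logvar) + mu ** 2 - 1.0 - logvar, axis=1)
    return anp.mean(per)


def greedy_decode(
    params, config: ModelConfig, z: np.ndarray, vocab: Vocabulary, max_steps: int
) -> list[list[int]]:
    """Argmax rollout from latent vectors; stops each row at END."""
    z = np.asarray(z)
    B = z.shape[0]
    hs = [
        np.tanh(z @ params[f"dec_init_W_{layer}"] + params[f"dec_init_b_{layer}"])
        for layer in range(config.rnn_layers)
    ]
    tok = np.full(B, vocab.start_index, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    out: list[list[int]] = [[] for _ in range(B)]
    ones = np.ones((B, 1))
    for _ in range(max_steps):
        x = np.concatenate([params["embed"][tok], z], axis=1)
        for layer in range(config.rnn_layers):
            tag = f"dec_{layer}"
            gx = x @ params[f"{tag}_Wx"] + params[f"{tag}_bx"]
            hs[layer] = _gru_step(gx, hs[layer], params[f"{tag}_Wh"], params[f"{tag}_bh"], ones)
            x = hs[layer]
        logits = x @ params["out_W"] + params["out_b"]
        tok = np.argmax(logits, axis=1)
        hit_end = tok == vocab.end_index
        for b in range(B):
            if not done[b] and not hit_end[b]:
                out[b].append(int(tok[b]))
        done |= hit_end
        if done.all():
            break
    return out
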