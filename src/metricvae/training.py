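"""Training orchestration: mode-selected objectives, Adam, logging,
checkpoints, and seeded reproducibility.

One scalar ``seed`` drives everything through fixed offsets: the
train/val/test split, parameter initialization, the regression head's own
stream (so adding the head never perturbs backbone initialization),
epoch shuffling together with reparameterization noise, and evaluation
center sampling. Two runs with the same config and seed on one device
produce bitwise-identical trajectories; metric mode with a zero metric
coefficient, and joint mode with a zero regression weight, reduce exactly
to plain VAE training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten
from autograd.tracer import getval

from . import joint as joint_mod
from .backbone import (
    ModelConfig,
    encode,
    decode_logits,
    init_params,
    kl_standard_normal,
    reconstruction_loss,
    sequence_reconstruction_loss,
)
from .config import RunConfig
from .data import (
    PropertyTable,
    Split,
    TokenSequence,
    Vocabulary,
    build_vocabulary,
    encode_batch,
    read_dataset,
    sequences_from_token_lists,
    split_dataset,
)
from .metric import (
    LossBreakdown,
    gamma_penalty,
    log_ratio_loss,
    metric_vae_loss,
    sample_triplets,
)
from .tcvae import decomposed_kl
from .evaluation import NeighborEvalReport, embed_dataset, local_regression_mae

# sub-seed offsets off the run seed (kept < 2^31 by masking)
_SPLIT, _INIT, _HEAD, _EPOCH, _CENTERS = 0, 1, 2, 3, 4
GRAD_CLIP_NORM = 5.0


def _subseed(seed: int, offset: int) -> int:
    return (seed + offset) & 0x7FFFFFFF


@dataclass
class TrainResult:
    params: dict
    config: RunConfig
    vocab: Vocabulary
    sequences: list[TokenSequence]
    properties: PropertyTable
    split: Split
    log: list[dict]

    @property
    def final_total(self) -> float:
        return self.log[-1]["total"]


class AdamState:
    """Plain Adam over the flattened parameter pytree, with norm clipping."""

    def __init__(self, params: dict, lr: float, clip: float = GRAD_CLIP_NORM) -> None:
        flat, self._unflatten = flatten(params)
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0
        self.lr = lr
        self.clip = clip
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def update(self, params: dict, grads: dict) -> dict:
        flat_p, _ = flatten(params)
        flat_g, _ = flatten(grads)
        gnorm = np.linalg.norm(flat_g)
        if gnorm > self.clip:
            flat_g = flat_g * (self.clip / gnorm)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * flat_g
        self.v = self.beta2 * self.v + (1 - self.beta2) * flat_g ** 2
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return self._unflatten(flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _batch_loss(
    params: dict,
    cfg: RunConfig,
    batch: np.ndarray,
    lengths: np.ndarray,
    eps: np.ndarray,
    y: np.ndarray | None,
    epoch: int,
    dataset_size: int,
    pad_index: int,
) -> LossBreakdown:
    """Mode-dispatched minibatch objective; differentiable in ``params``."""
    latents = encode(params, cfg.model, batch, lengths, eps=eps)
    teacher, targets = batch[:, :-1], batch[:, 1:]
    logits = decode_logits(params, cfg.model, latents.z, teacher, lengths)
    recon = sequence_reconstruction_loss(logits, targets, pad_index)
    decomp = decomposed_kl(latents, dataset_size)

    if cfg.mode == "metric" and cfg.metric.gamma_coefficient > 0.0:
        # the metric term shapes the deterministic embedding f(x) = mu;
        # triplet choice and the adaptive weight are detached batch values
        mu_det = getval(latents.mu)
        gamma = gamma_penalty(mu_det, y, cfg.metric.gamma_coefficient)
        triplets = sample_triplets(mu_det, y, cfg.metric)
        term = log_ratio_loss(triplets, latents.mu, y, cfg.metric.distance_epsilon)
        return metric_vae_loss(recon, decomp, cfg.schedule, epoch, term, gamma)
    if cfg.mode == "joint" and cfg.joint_gamma_weight > 0.0:
        regloss = joint_mod.regression_loss(latents.z, y, params)
        return joint_mod.joint_vae_loss(
            recon, decomp, cfg.schedule, epoch, regloss, cfg.joint_gamma_weight
        )
    # plain VAE (and the exact reduction of the other modes at weight 0)
    return metric_vae_loss(recon, decomp, cfg.schedule, epoch, 0.0, 0.0)


def load_training_data(
    cfg: RunConfig,
) -> tuple[list[TokenSequence], PropertyTable, Vocabulary]:
    if cfg.sequence_file is None or cfg.property_file is None:
        raise ValueError("config must point at a sequence file and a property file")
    token_lists, props = read_dataset(cfg.sequence_file, cfg.property_file, cfg.tokenizer)
    vocab = build_vocabulary(token_lists)
    return sequences_from_token_lists(token_lists, vocab), props, vocab


def train(
    cfg: RunConfig,
    sequences: list[TokenSequence] | None = None,
    properties: PropertyTable | None = None,
    vocab: Vocabulary | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Run one training job; data may be passed in memory or read from the
    files named in the config."""
    if sequences is None:
        sequences, properties, vocab = load_training_data(cfg)
    assert properties is not None and vocab is not None
    if cfg.mode in ("joint", "metric"):
        y_all = properties.column(cfg.metric.target_property)
    else:
        y_all = None

    split = split_dataset(
        len(sequences), _subseed(cfg.seed, _SPLIT), cfg.test_fraction, cfg.val_fraction
    )
    train_idx = split.train
    n_train = len(train_idx)
    if n_train < cfg.batch_size:
        raise ValueError(f"training split of {n_train} smaller than batch_size {cfg.batch_size}")

    params = init_params(cfg.model, vocab.size, np.random.default_rng(_subseed(cfg.seed, _INIT)))
    if cfg.mode == "joint":
        params.update(
            joint_mod.init_head_params(
                cfg.model.latent_dim, np.random.default_rng(_subseed(cfg.seed, _HEAD))
            )
        )

    all_batch, all_lengths = encode_batch(sequences, cfg.max_len, vocab)

    comps: dict[str, float] = {}

    def objective(p, *args):
        bd = _batch_loss(p, cfg, *args)
        comps.clear()
        comps.update({k: float(getval(v)) for k, v in bd.components.items()})
        return bd.total

    loss_and_grad = value_and_grad(objective)
    adam = AdamState(params, cfg.model.learning_rate)
    rng = np.random.default_rng(_subseed(cfg.seed, _EPOCH))
    log: list[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n_train - cfg.batch_size + 1, cfg.batch_size):
            rows = train_idx[order[start : start + cfg.batch_size]]
            batch = all_batch[rows]
            lengths = all_lengths[rows]
            eps = rng.standard_normal((len(rows), cfg.model.latent_dim))
            y = None if y_all is None else y_all[rows]
            total, grads = loss_and_grad(
                params, batch, lengths, eps, y, epoch, n_train, vocab.pad_index
            )
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss {total} at epoch {epoch}, batch {n_batches}; "
                    "check learning rate / data scaling"
                )
            params = adam.update(params, grads)
            n_batches += 1
            for key, value in comps.items():
                sums[key] = sums.get(key, 0.0) + value
        row = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        log.append(row)
        if verbose:
            print(f"epoch {epoch}: total {row['total']:.4f}")
    return TrainResult(
        params=params,
        config=cfg,
        vocab=vocab,
        sequences=sequences,
        properties=properties,
        split=split,
        log=log,
    )


def write_log_csv(log: list[dict], path: str | Path) -> None:
    keys = list(log[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(keys) + "\n")
        for row in log:
            fh.write(",".join(f"{row.get(k, '')}" for k in keys) + "\n")


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Single-file checkpoint: weights plus config and vocabulary metadata."""
    from .config import config_to_dict

    meta = {
        "config": config_to_dict(result.config),
        "vocab_tokens": list(result.vocab.tokens),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        **result.params,
    )


def load_checkpoint(path: str | Path) -> tuple[dict, RunConfig, Vocabulary]:
    from .config import config_from_dict

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        params = {k: data[k] for k in data.files if k != "__meta__"}
    tokens = meta["vocab_tokens"]
    vocab = Vocabulary(tokens=tuple(tokens), index_of={t: i for i, t in enumerate(tokens)})
    return params, config_from_dict(meta["config"]), vocab


def neighbor_evaluation(
    result: TrainResult,
    k: int | None = None,
    n_centers: int | None = None,
    ridge: float = 1e-3,
) -> NeighborEvalReport:
    """Run the k-neighbor local-regression protocol on a trained model.

    Centers are sampled (seeded, without replacement) from the validation
    split; the neighbor pool is the training split's embeddings.
    """
    cfg = result.config
    k = cfg.eval_k if k is None else k
    n_centers = cfg.eval_centers if n_centers is None else n_centers
    if len(result.split.val) == 0:
        raise ValueError("config reserved no validation split; set val_fraction > 0")
    rng = np.random.default_rng(_subseed(cfg.seed, _CENTERS))
    n_centers = min(n_centers, len(result.split.val))
    centers = rng.choice(result.split.val, size=n_centers, replace=False)

    latents = embed_dataset(
        result.params, cfg.model, result.vocab, result.sequences, cfg.max_len
    )
    sub = lambda idx: PropertyTable(
        names=result.properties.names, values=result.properties.values[idx]
    )
    return local_regression_mae(
        latents[centers],
        sub(centers),
        latents[result.split.train],
        sub(result.split.train),
        k=k,
        ridge=ridge,
        target_property=cfg.metric.target_property if cfg.mode != "vae" else None,
    )
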