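"""Total-correlation decomposition of the KL term (beta-TCVAE objective).

Instead of a single KL-to-prior penalty, the KL is split into three
separately weighted terms estimated on each minibatch:

* ``mi``    — index-code mutual information, E[log q(z|x) - log q(z)]
* ``tc``    — total correlation,            E[log q(z) - sum_j log q(z_j)]
* ``dwkl``  — dimension-wise KL,            E[sum_j log q(z_j) - log p(z_j)]

The aggregate densities q(z) and q(z_j) are estimated by minibatch
stratified sampling (MSS): each batch element's density is a weighted
mixture of every batch element's posterior, with importance weights that
account for the minibatch being a size-M sample of an N-point dataset.

The three weights follow the schedule used for training: alpha1 and
alpha3 fixed at 0.75, alpha2 annealed from 1.25 down to 0.75 by 0.1 per
epoch (a high early total-correlation weight encourages independent
latent dimensions before the metric term shapes them).
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .backbone import LatentBatch

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class AlphaSchedule:
    alpha1: float = 0.75
    alpha3: float = 0.75
    alpha2_start: float = 1.25
    alpha2_end: float = 0.75
    alpha2_step: float = 0.1

    def alpha2(self, epoch: int) -> float:
        """Linear decay per epoch, floored at ``alpha2_end``; epoch 0 is the start."""
        if epoch < 0:
            raise ValueError("epoch must be >= 0")
        return max(self.alpha2_end, self.alpha2_start - self.alpha2_step * epoch)


class KLDecomposition:
    """Named minibatch estimates (nats); mi + tc + dwkl estimates the mean KL."""

    def __init__(self, mi, tc, dwkl) -> None:
        self.mi = mi
        self.tc = tc
        self.dwkl = dwkl

    @property
    def total(self):
        return self.mi + self.tc + self.dwkl


def mss_log_weights(batch_size: int, dataset_size: int) -> np.ndarray:
    """Log importance weights for the stratified aggregate-posterior estimate.

    Row i weights the mixture components q(z_i | x_j): the element's own
    posterior gets 1/N; one designated off-diagonal slot (cyclically the
    next batch element) carries the stratified remainder
    (N - M + 1)/(N (M - 1)); every other slot gets 1/(M - 1). Rows of the
    exponentiated matrix sum to one.
    """
    M, N = batch_size, dataset_size
    if M < 2:
        raise ValueError("batch_size must be >= 2 for a minibatch density estimate")
    if M > N:
        raise ValueError(f"batch_size {M} exceeds dataset_size {N}")
    W = np.full((M, M), 1.0 / (M - 1))
    strat = (N - M + 1.0) / (N * (M - 1.0))
    idx = np.arange(M)
    W[idx, idx] = 1.0 / N
    W[idx, (idx + 1) % M] = strat
    return np.log(W)


def _logsumexp(a, axis):
    m = anp.max(a, axis=axis, keepdims=True)
    return anp.squeeze(m, axis=axis) + anp.log(anp.sum(anp.exp(a - m), axis=axis))


def gaussian_log_density(z, mu, logvar):
    """Elementwise log N(z; mu, e^logvar); broadcasts over leading axes."""
    return -0.5 * (_LOG2PI + logvar + (z - mu) ** 2 * anp.exp(-logvar))


def decomposed_kl(latents: LatentBatch, dataset_size: int) -> KLDecomposition:
    """MSS estimates of mi/tc/dwkl on the sampled z of a minibatch."""
    B = latents.batch_size
    if B < 2:
        raise ValueError("decomposed_kl needs a minibatch of at least 2")
    if dataset_size < B:
        raise ValueError(f"dataset_size {dataset_size} < batch_size {B}")
    z, mu, logvar = latents.z, latents.mu, latents.logvar
    # cross-density cube: entry [i, j, d] = log N(z_i,d ; mu_j,d, var_j,d)
    cube = gaussian_log_density(z[:, None, :], mu[None, :, :], logvar[None, :, :])
    log_qz_given_x = anp.sum(cube[np.arange(B), np.arange(B), :], axis=1)
    logw = mss_log_weights(B, dataset_size)
    log_qz = _logsumexp(logw + anp.sum(cube, axis=2), axis=1)
    log_qz_marginals = _logsumexp(logw[:, :, None] + cube, axis=1)  # (B, D)
    sum_log_qzj = anp.sum(log_qz_marginals, axis=1)
    log_pz = anp.sum(-0.5 * (_LOG2PI + z ** 2), axis=1)
    mi = anp.mean(log_qz_given_x - log_qz)
    tc = anp.mean(log_qz - sum_log_qzj)
    dwkl = anp.mean(sum_log_qzj - log_pz)
    return KLDecomposition(mi=mi, tc=tc, dwkl=dwkl)


def weighted_kl(decomp: KLDecomposition, sched: AlphaSchedule, epoch: int):
    """alpha1*mi + alpha2(epoch)*tc + alpha3*dwkl — the beta of the total loss."""
    return sched.alpha1 * decomp.mi + sched.alpha2(epoch) * decomp.tc + sched.alpha3 * decomp.dwkl
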