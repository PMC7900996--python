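"""Joint-VAE baseline: a small regression head on z trained with the VAE.

The established alternative to metric learning: a 2-layer perceptron
f: R^latent -> R (affine, tanh, affine) predicts the target property from
the latent vector and its squared error is added to the VAE loss. The
regression pressure organizes the latent space around the property, but
can collapse the property onto few latent axes — the behaviour the metric
objective is designed to avoid.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .metric import LossBreakdown
from .tcvae import AlphaSchedule, KLDecomposition, weighted_kl

HEAD_HIDDEN = 64


def init_head_params(latent_dim: int, rng: np.random.Generator, hidden: int = HEAD_HIDDEN) -> dict:
    s1 = np.sqrt(6.0 / (latent_dim + hidden))
    s2 = np.sqrt(6.0 / (hidden + 1))
    return {
        "head_W1": rng.uniform(-s1, s1, size=(latent_dim, hidden)),
        "head_b1": np.zeros(hidden),
        "head_W2": rng.uniform(-s2, s2, size=(hidden, 1)),
        "head_b2": np.zeros(1),
    }


def head_predict(params: dict, z):
    """One property value per molecule."""
    h = anp.tanh(anp.dot(z, params["head_W1"]) + params["head_b1"])
    return anp.reshape(anp.dot(h, params["head_W2"]) + params["head_b2"], (-1,))


def regression_loss(z_batch, y_batch, params: dict):
    """Mean squared error of the head's prediction against the target property."""
    pred = head_predict(params, z_batch)
    y = anp.reshape(y_batch, (-1,))
    return anp.mean((pred - y) ** 2)


def joint_vae_loss(
    recon,
    decomp: KLDecomposition,
    sched: AlphaSchedule,
    epoch: int,
    regloss,
    gamma_weight: float,
) -> LossBreakdown:
    """Total = reconstruction + weighted KL decomposition + gamma * regloss.

    Components are logged under the same names as metric mode (the
    property term under "metric") so training logs are comparable.
    """
    wkl = weighted_kl(decomp, sched, epoch)
    total = recon + wkl + gamma_weight * regloss
    return LossBreakdown(
        total=total,
        components={
            "recon": recon,
            "mi": decomp.mi,
            "tc": decomp.tc,
            "dwkl": decomp.dwkl,
            "metric": regloss,
            "gamma": gamma_weight,
            "total": total,
        },
    )
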