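"""Log-ratio metric learning over the VAE latent space.

The metric term ties *ratios* of latent distances to ratios of property
distances for (anchor, positive, negative) triplets:

    L = mean_t ( log[(D(z_a,z_n)+e)/(D(z_a,z_p)+e)]
               - log[(D(y_a,y_n)+e)/(D(y_a,y_p)+e)] )^2

with D the squared Euclidean distance in both spaces and ``e`` a small
guard for duplicate molecules. Using ratios makes the loss invariant to
rescaling the property and to rescaling the latent space, so any
continuous property works without normalization.

Triplets are constrained to the anchor's latent neighborhood: candidates
are ranked by latent (Euclidean) distance to the anchor, only the nearest
fraction (default 25%) is kept, that neighborhood is re-ranked by property
distance, and consecutive non-overlapping pairs of the property ranking
become (positive, negative) with the property-nearer member as positive.
Structurally distant molecules therefore never serve as metric targets —
the latent geometry stays driven by structure, the metric term only
re-orders each local patch by property.

The metric weight is adaptive: gamma = c * (1 - max_i |corr(z_i, y)|)
over latent dimensions i. If one dimension already encodes the property
linearly, the metric pressure vanishes, preventing the property from
collapsing onto a single latent axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import autograd.numpy as anp
import numpy as np

from .tcvae import AlphaSchedule, KLDecomposition, weighted_kl


@dataclass(frozen=True)
class Triplet:
    anchor: int
    positive: int
    negative: int

    def __post_init__(self) -> None:
        if len({self.anchor, self.positive, self.negative}) != 3:
            raise ValueError("triplet indices must be distinct")


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the metric objective.

    neighborhood_fraction: share of the batch (excluding the anchor) kept
    as triplet candidates, ranked by latent distance. gamma_coefficient is
    the ceiling of the adaptive metric weight. distance_epsilon guards the
    log against zero distances (duplicate molecules).
    """

    neighborhood_fraction: float = 0.25
    gamma_coefficient: float = 0.1
    distance_epsilon: float = 1e-8
    target_property: str = "target"

    def __post_init__(self) -> None:
        if not 0.0 < self.neighborhood_fraction <= 1.0:
            raise ValueError("neighborhood_fraction must be in (0, 1]")
        if self.gamma_coefficient < 0:
            raise ValueError("gamma_coefficient must be >= 0")
        if self.distance_epsilon <= 0:
            raise ValueError("distance_epsilon must be positive")


class LossBreakdown:
    """Named scalar loss components and their weighted total."""

    def __init__(self, total, components: dict) -> None:
        self.total = total
        self.components = components

    def scalar_components(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.components.items()}


def neighborhood_size(batch_size: int, fraction: float) -> int:
    """ceil(fraction * (batch - 1)), floored at 2 so a pair always exists."""
    return max(2, int(np.ceil(fraction * (batch_size - 1))))


def sample_triplets(
    latents: np.ndarray,
    properties: np.ndarray,
    cfg: MetricConfig,
    anchor_order: Sequence[int] | None = None,
) -> list[Triplet]:
    """Latent-proximity-constrained triplet sampling.

    For each anchor (every batch element once, in ``anchor_order``):
    rank the other batch members by Euclidean latent distance, keep the
    nearest ``neighborhood_size`` of them, rank the kept members by
    property distance |y - y_a| (ties broken by batch index), and emit
    consecutive non-overlapping pairs of that ranking as triplets, the
    property-nearer member of each pair as positive. An incomplete last
    pair is dropped.
    """
    latents = np.asarray(latents, dtype=np.float64)
    properties = np.asarray(properties, dtype=np.float64).ravel()
    B = latents.shape[0]
    if B < 4:
        raise ValueError(f"batch of {B} too small for triplet sampling (need >= 4)")
    if properties.shape[0] != B:
        raise ValueError("properties length must match batch")
    if anchor_order is None:
        anchor_order = range(B)
    m = neighborhood_size(B, cfg.neighborhood_fraction)
    triplets: list[Triplet] = []
    for a in anchor_order:
        others = np.concatenate([np.arange(a), np.arange(a + 1, B)])
        d_lat = np.linalg.norm(latents[others] - latents[a], axis=1)
        kept = others[np.lexsort((others, d_lat))[:m]]
        d_prop = np.abs(properties[kept] - properties[a])
        ranked = kept[np.lexsort((kept, d_prop))]
        for i in range(0, len(ranked) - 1, 2):
            p, n = int(ranked[i]), int(ranked[i + 1])
            triplets.append(Triplet(anchor=int(a), positive=p, negative=n))
    return triplets


def log_ratio_loss(
    triplets: Sequence[Triplet],
    latents,
    properties,
    epsilon: float = 1e-8,
):
    """Mean squared difference of latent and property log-distance-ratios."""
    if len(triplets) == 0:
        raise ValueError("no triplets")
    a = np.array([t.anchor for t in triplets])
    p = np.array([t.positive for t in triplets])
    n = np.array([t.negative for t in triplets])
    y = anp.reshape(properties, (-1,))
    d_an = anp.sum((latents[a] - latents[n]) ** 2, axis=1)
    d_ap = anp.sum((latents[a] - latents[p]) ** 2, axis=1)
    y_an = (y[a] - y[n]) ** 2
    y_ap = (y[a] - y[p]) ** 2
    diff = anp.log((d_an + epsilon) / (d_ap + epsilon)) - anp.log((y_an + epsilon) / (y_ap + epsilon))
    return anp.mean(diff ** 2)


def gamma_penalty(z_batch: np.ndarray, y_batch: np.ndarray, coefficient: float = 0.1) -> float:
    """Adaptive metric weight c * (1 - max_i |Pearson(z_i, y)|), in [0, c].

    Degenerate batches (zero variance in y, or in a latent dimension)
    contribute correlation 0 for the affected dimensions.
    """
    z = np.asarray(z_batch, dtype=np.float64)
    y = np.asarray(y_batch, dtype=np.float64).ravel()
    if z.shape[0] < 3:
        raise ValueError("gamma_penalty needs a batch of at least 3")
    zc = z - z.mean(axis=0)
    yc = y - y.mean()
    z_sd = np.sqrt(np.sum(zc ** 2, axis=0))
    y_sd = np.sqrt(np.sum(yc ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (zc.T @ yc) / (z_sd * y_sd)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return coefficient * (1.0 - float(np.max(np.abs(corr))))


def metric_vae_loss(
    recon,
    decomp: KLDecomposition,
    sched: AlphaSchedule,
    epoch: int,
    metric_term,
    gamma: float,
) -> LossBreakdown:
    """Total = reconstruction + weighted KL decomposition + gamma * metric."""
    wkl = weighted_kl(decomp, sched, epoch)
    total = recon + wkl + gamma * metric_term
    return LossBreakdown(
        total=total,
        components={
            "recon": recon,
            "mi": decomp.mi,
            "tc": decomp.tc,
            "dwkl": decomp.dwkl,
            "metric": metric_term,
            "gamma": gamma,
            "total": total,
        },
    )
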