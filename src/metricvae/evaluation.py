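"""Neighbor-point evaluation of embedding quality.

An embedding is good for molecular design if property values vary
smoothly over it. The protocol quantifies that locally: for each of a set
of held-out center molecules, take the k (default 10) nearest *training*
embeddings, fit a per-property local linear (ridge) regression on those k
points, predict the center's property, and report the mean absolute error
over centers. A low MAE — including for properties the embedding was not
trained on — means structure and properties are embedded locally and
continuously.

The local fit centers the neighborhood (intercept unpenalized) and solves
(Xc'Xc + ridge I) w = Xc'yc; with latent dimension above k the problem is
underdetermined and ridge supplies the standard minimum-norm resolution.
At k=1 the fit degenerates to nearest-neighbor regression by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import ModelConfig, encode
from .data import PropertyTable, TokenSequence, Vocabulary, encode_batch


@dataclass(frozen=True)
class NeighborEvalReport:
    """Per-property MAE of the k-neighbor local regression protocol."""

    mae: dict[str, float]
    n_centers: int
    k: int
    target_property: str | None = None

    def __post_init__(self) -> None:
        for name, value in self.mae.items():
            if value < 0:
                raise ValueError(f"negative MAE for {name!r}")


def embed_dataset(
    params: dict,
    config: ModelConfig,
    vocab: Vocabulary,
    sequences: list[TokenSequence],
    max_len: int,
    batch_size: int = 512,
) -> np.ndarray:
    """Posterior-mean embedding of each sequence, order preserved."""
    rows = []
    for start in range(0, len(sequences), batch_size):
        chunk = sequences[start : start + batch_size]
        batch, lengths = encode_batch(chunk, max_len, vocab)
        rows.append(np.asarray(encode(params, config, batch, lengths, eps=None).mu))
    return np.concatenate(rows, axis=0)


def embed_token_lists(
    params: dict,
    config: ModelConfig,
    vocab: Vocabulary,
    token_lists: list[list[str]],
    max_len: int,
) -> np.ndarray:
    """Embed raw token lists; out-of-vocabulary tokens are a located error."""
    sequences = []
    for row, tokens in enumerate(token_lists):
        for tok in tokens:
            if tok not in vocab.index_of:
                raise ValueError(f"token {tok!r} at row {row} not in checkpoint vocabulary")
        sequences.append(TokenSequence(indices=tuple(vocab.encode_tokens(tokens))))
    return embed_dataset(params, config, vocab, sequences, max_len)


def report_to_csv(report: NeighborEvalReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("property,mae,n_centers,k,target_property\n")
        for name, value in report.mae.items():
            fh.write(
                f"{name},{value:.12g},{report.n_centers},{report.k},"
                f"{report.target_property or ''}\n"
            )


def report_from_csv(path) -> NeighborEvalReport:
    import pandas as pd

    df = pd.read_csv(path)
    target = df["target_property"].iloc[0]
    return NeighborEvalReport(
        mae={str(r["property"]): float(r["mae"]) for _, r in df.iterrows()},
        n_centers=int(df["n_centers"].iloc[0]),
        k=int(df["k"].iloc[0]),
        target_property=None if pd.isna(target) else str(target),
    )


def _local_fit_predict(
    neigh_x: np.ndarray, neigh_y: np.ndarray, center: np.ndarray, ridge: float
) -> np.ndarray:
    """Centered ridge fit on one neighborhood; neigh_y is (k, n_properties)."""
    xm = neigh_x.mean(axis=0)
    ym = neigh_y.mean(axis=0)
    Xc = neigh_x - xm
    A = Xc.T @ Xc + ridge * np.eye(neigh_x.shape[1])
    try:
        W = np.linalg.solve(A, Xc.T @ (neigh_y - ym))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular local fit; use a nonzero ridge regularizer"
        ) from None
    return ym + (center - xm) @ W


def local_regression_mae(
    center_latents: np.ndarray,
    center_properties: PropertyTable,
    train_latents: np.ndarray,
    train_properties: PropertyTable,
    k: int = 10,
    ridge: float = 1e-3,
    target_property: str | None = None,
) -> NeighborEvalReport:
    """MAE of predicting each center from its k nearest training embeddings."""
    center_latents = np.asarray(center_latents, dtype=np.float64)
    train_latents = np.asarray(train_latents, dtype=np.float64)
    if center_properties.names != train_properties.names:
        raise ValueError("center and training property tables must share columns")
    n_train = train_latents.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds training size {n_train}")
    if k < 1:
        raise ValueError("k must be >= 1")
    abs_err = np.zeros((center_latents.shape[0], len(train_properties.names)))
    for c in range(center_latents.shape[0]):
        d2 = np.sum((train_latents - center_latents[c]) ** 2, axis=1)
        neigh = np.argpartition(d2, k - 1)[:k]
        pred = _local_fit_predict(
            train_latents[neigh], train_properties.values[neigh], center_latents[c], ridge
        )
        abs_err[c] = np.abs(pred - center_properties.values[c])
    mae = {name: float(abs_err[:, j].mean()) for j, name in enumerate(train_properties.names)}
    return NeighborEvalReport(
        mae=mae, n_centers=center_latents.shape[0], k=k, target_property=target_property
    )


def compare_embeddings(
    report_a: NeighborEvalReport, report_b: NeighborEvalReport
) -> dict[str, object]:
    """Per-property wins (strictly smaller MAE) of a over b, and the fractions.

    Ties count to neither side. Mirrors the scatter-plot comparison of two
    embedding models over a panel of descriptors.
    """
    if set(report_a.mae) != set(report_b.mae):
        raise ValueError("reports evaluate different property lists")
    a_wins = {name: report_a.mae[name] < report_b.mae[name] for name in report_a.mae}
    b_wins = {name: report_b.mae[name] < report_a.mae[name] for name in report_a.mae}
    n = len(a_wins)
    return {
        "a_wins": sum(a_wins.values()),
        "b_wins": sum(b_wins.values()),
        "n_properties": n,
        "a_win_fraction": sum(a_wins.values()) / n,
        "per_property": {
            name: ("a" if a_wins[name] else "b" if b_wins[name] else "tie")
            for name in report_a.mae
        },
    }
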