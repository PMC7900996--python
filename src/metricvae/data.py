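"""Molecule/property table IO, token vocabularies, and fixed-length index batches.

Molecules arrive as token sequences: either SMILES strings tokenized at the
character level (with a fixed digraph list so ``Cl``/``Br`` stay single
tokens), or pre-tokenized whitespace-separated files such as grammar
production-rule sequences. Properties arrive as a CSV with a header row,
aligned to the sequence file by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PAD = "<pad>"
START = "<start>"
END = "<end>"

#: two-character SMILES atoms kept as single tokens in character mode
SMILES_DIGRAPHS = ("Cl", "Br", "Si", "Se")


class DataError(ValueError):
    """Malformed input data (bad rows are reported with line numbers)."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token alphabet with reserved PAD/START/END entries.

    Token order is first-seen order over the corpus, with the reserved
    tokens appended at the end, so indices are contiguous from 0 and two
    builds over the same corpus produce identical maps.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        for tok in (PAD, START, END):
            if tok not in self.index_of:
                raise ValueError(f"reserved token {tok!r} missing from vocabulary")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index_of[PAD]

    @property
    def start_index(self) -> int:
        return self.index_of[START]

    @property
    def end_index(self) -> int:
        return self.index_of[END]

    def encode_tokens(self, tokens: Sequence[str]) -> list[int]:
        try:
            return [self.index_of[t] for t in tokens]
        except KeyError as exc:
            raise DataError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode_indices(self, indices: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in indices]


@dataclass(frozen=True)
class TokenSequence:
    """One molecule as vocabulary indices; ``length`` is the pre-padding length."""

    indices: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PropertyTable:
    """Continuous per-molecule property values, one row per molecule."""

    names: tuple[str, ...]
    values: np.ndarray  # (n_molecules, n_properties), float64

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("property matrix shape does not match names")
        if not np.all(np.isfinite(self.values)):
            raise DataError("property table contains missing/non-finite values")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown property {name!r}; have {self.names}") from None
        return self.values[:, j]

    def __len__(self) -> int:
        return self.values.shape[0]


def tokenize_smiles(line: str) -> list[str]:
    """Character-level SMILES tokens; digraph atoms (Cl, Br, ...) stay whole."""
    tokens: list[str] = []
    i = 0
    while i < len(line):
        pair = line[i : i + 2]
        if pair in SMILES_DIGRAPHS:
            tokens.append(pair)
            i += 2
        else:
            tokens.append(line[i])
            i += 1
    return tokens


def tokenize_line(line: str, mode: str) -> list[str]:
    if mode == "smiles":
        return tokenize_smiles(line.strip())
    if mode == "whitespace":
        return line.split()
    raise ValueError(f"unknown tokenizer mode {mode!r} (use 'smiles' or 'whitespace')")


def build_vocabulary(sequences: Sequence[Sequence[str]]) -> Vocabulary:
    """First-seen token enumeration over the corpus, reserved tokens appended."""
    if len(sequences) == 0:
        raise DataError("no sequences")
    seen: dict[str, int] = {}
    for seq in sequences:
        for tok in seq:
            if tok not in seen:
                seen[tok] = len(seen)
    tokens = list(seen)
    for reserved in (PAD, START, END):
        if reserved in seen:
            raise DataError(f"input uses reserved token {reserved!r}")
        seen[reserved] = len(seen)
        tokens.append(reserved)
    return Vocabulary(tokens=tuple(tokens), index_of=seen)


def encode_batch(
    sequences: Sequence[TokenSequence], max_len: int, vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Pack sequences into an index matrix of shape (batch, max_len + 2).

    Each row is START, the sequence tokens, END, then PAD to full width.
    Returns the matrix and the pre-padding lengths.
    """
    batch = np.full((len(sequences), max_len + 2), vocab.pad_index, dtype=np.int64)
    lengths = np.empty(len(sequences), dtype=np.int64)
    for r, seq in enumerate(sequences):
        if seq.length > max_len:
            raise DataError(f"sequence at row {r} has length {seq.length} > max_len {max_len}")
        if seq.length < 1:
            raise DataError(f"sequence at row {r} is empty")
        batch[r, 0] = vocab.start_index
        batch[r, 1 : 1 + seq.length] = seq.indices
        batch[r, 1 + seq.length] = vocab.end_index
        lengths[r] = seq.length
    return batch, lengths


def decode_batch(batch: np.ndarray, vocab: Vocabulary) -> list[TokenSequence]:
    """Invert :func:`encode_batch`: strip START, stop at END/PAD."""
    out: list[TokenSequence] = []
    for row in np.asarray(batch):
        indices: list[int] = []
        for idx in row:
            if idx == vocab.start_index:
                continue
            if idx in (vocab.end_index, vocab.pad_index):
                break
            indices.append(int(idx))
        out.append(TokenSequence(indices=tuple(indices)))
    return out


def sequences_from_token_lists(
    token_lists: Sequence[Sequence[str]], vocab: Vocabulary
) -> list[TokenSequence]:
    return [TokenSequence(indices=tuple(vocab.encode_tokens(t))) for t in token_lists]


def read_sequence_file(path: str | Path, mode: str) -> list[list[str]]:
    """One molecule per line; empty lines are a located error, never dropped."""
    token_lists: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            tokens = tokenize_line(line, mode)
            if not tokens:
                raise DataError(f"{path}:{lineno}: empty sequence line")
            token_lists.append(tokens)
    if not token_lists:
        raise DataError(f"{path}: no sequences")
    return token_lists


def read_property_csv(path: str | Path) -> PropertyTable:
    df = pd.read_csv(path)
    names = tuple(str(c) for c in df.columns)
    values = df.to_numpy()
    try:
        values = values.astype(np.float64)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = int(bad.isna().idxmax())
                raise DataError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                    f"{col!r} at data row {row + 1}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataError(f"{path}: missing value in column {names[j]!r} at data row {i + 1}")
    return PropertyTable(names=names, values=values)


def read_dataset(
    sequence_file: str | Path,
    property_file: str | Path,
    mode: str = "smiles",
) -> tuple[list[list[str]], PropertyTable]:
    """Read aligned sequence + property files, preserving input order."""
    token_lists = read_sequence_file(sequence_file, mode)
    props = read_property_csv(property_file)
    if len(token_lists) != len(props):
        raise DataError(
            f"row-count mismatch: {sequence_file} has {len(token_lists)} sequences, "
            f"{property_file} has {len(props)} property rows"
        )
    return token_lists, props


@dataclass(frozen=True)
class Split:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_dataset(
    n: int, seed: int = 0, test_fraction: float = 0.2, val_fraction: float = 0.0
) -> Split:
    """Seeded-shuffle split. Defaults to 80/20 train/test; a validation
    slice (carved out of the training share) is reserved when the neighbor
    evaluation protocol needs held-out centers disjoint from both."""
    if not 0.0 < test_fraction < 1.0 or val_fraction < 0.0 or test_fraction + val_fraction >= 1.0:
        raise ValueError("invalid split fractions")
    order = np.random.default_rng(seed).permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    n_val = int(round(val_fraction * n))
    test = order[:n_test]
    val = order[n_test : n_test + n_val]
    train = order[n_test + n_val :]
    if len(train) == 0 or (val_fraction > 0 and len(val) == 0):
        raise ValueError(f"split of {n} rows leaves an empty part")
    return Split(train=np.sort(train), val=np.sort(val), test=np.sort(test))
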