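"""One-hot (sparse) encoding of N-terminal sequence windows.

A k-mer window becomes a binary vector of length 20*k: feature
``(p - 1) * 20 + rank(r)`` indicates residue ``r`` at window position ``p``
(1-based).  The unknown symbol 'X' and the padding gap '-' encode to an
all-zero block, so the feature space stays at 20 dimensions per position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import DataError, SequenceDataset, POSITIVE

#: Fixed residue ordering defining feature ranks; feature indices and split
#: tie-breaking depend on it, so it is part of the model contract.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
RANK = {r: i for i, r in enumerate(ALPHABET)}
N_RESIDUES = 20


@dataclass(frozen=True)
class WindowSpec:
    """k-mer window: `k` residues starting at 1-based position `start`.

    Positions are counted after the removed iMet (position 1 = first mature
    residue); the default is the 10-residue window used for curation.
    """

    k: int = 10
    start: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("window length k must be >= 1")
        if self.start < 1:
            raise ValueError("window start must be >= 1")

    @property
    def n_features(self) -> int:
        return N_RESIDUES * self.k


def extract_window(seq: str, spec: WindowSpec) -> str:
    """Slice seq[start .. start+k-1] (1-based), right-padded with '-'."""
    w = seq[spec.start - 1: spec.start - 1 + spec.k]
    return w.ljust(spec.k, "-")


def encode_residue(r: str) -> np.ndarray:
    """20-dim indicator for one residue; 'X' and '-' give all zeros."""
    v = np.zeros(N_RESIDUES, dtype=np.uint8)
    if r in RANK:
        v[RANK[r]] = 1
    elif r not in ("X", "-"):
        raise DataError(f"cannot encode residue {r!r}")
    return v


def encode_window(window: str) -> np.ndarray:
    """Concatenated per-residue one-hot blocks; length 20 * len(window)."""
    return np.concatenate([encode_residue(r) for r in window])


def decode_vector(v: np.ndarray) -> str:
    """Inverse of :func:`encode_window` up to 'X'/'-' indistinguishability.

    All-zero blocks decode to '-'.
    """
    if v.size % N_RESIDUES:
        raise ValueError("vector length is not a multiple of 20")
    out = []
    for p in range(v.size // N_RESIDUES):
        block = v[p * N_RESIDUES:(p + 1) * N_RESIDUES]
        hits = np.flatnonzero(block)
        if hits.size == 0:
            out.append("-")
        elif hits.size == 1:
            out.append(ALPHABET[hits[0]])
        else:
            raise ValueError(f"block {p} has {hits.size} ones; not one-hot")
    return "".join(out)


def feature_name(f: int) -> str:
    """Human-readable "pos:residue" name of feature index f."""
    return f"{f // N_RESIDUES + 1}:{ALPHABET[f % N_RESIDUES]}"


def feature_index(pos: int, residue: str) -> int:
    """Feature index of (1-based position, residue)."""
    if residue not in RANK:
        raise DataError(f"not a standard residue: {residue!r}")
    if pos < 1:
        raise ValueError("position must be >= 1")
    return (pos - 1) * N_RESIDUES + RANK[residue]


def encode_dataset(ds: SequenceDataset, spec: WindowSpec,
                   include_unknown: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Encode a dataset into (X, y) with y = 1 for acetylated.

    Records containing 'X' are excluded by default (their all-zero blocks
    would silently behave like gaps during training).
    """
    recs = ds.records if include_unknown else [r for r in ds.records if not r.has_unknown]
    if not recs:
        return np.zeros((0, spec.n_features), dtype=np.uint8), np.zeros(0, dtype=np.int8)
    X = np.stack([encode_window(extract_window(r.nterm, spec)) for r in recs])
    y = np.array([1 if r.label == POSITIVE else 0 for r in recs], dtype=np.int8)
    return X, y
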