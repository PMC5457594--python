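"""Labeled N-terminal sequence datasets: parsing, curation, dedup, splitting.

Position numbering throughout the package: position 1 is the first residue
*after* the removed initiator methionine (iMet).  Labels are binary:
``"positive"`` = N-terminally acetylated, ``"negative"`` = unacetylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: 20 standard residues; 'X' is the accepted unknown symbol, '-' the
#: window-padding gap (never present in stored sequences, only in windows).
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
UNKNOWN = "X"

#: Residues after which methionine aminopeptidase cleaves iMet
#: (side-chain radius of gyration <= 1.29 A).
IMET_CLEAVABLE_SET = frozenset("GASCTPV")

_LABEL_ALIASES = {
    "positive": POSITIVE, "negative": NEGATIVE,
    "ac": POSITIVE, "unac": NEGATIVE,
    "pos": POSITIVE, "neg": NEGATIVE,
    "1": POSITIVE, "0": NEGATIVE,
}


class DataError(ValueError):
    """Malformed input data (bad label token, illegal residue, bad row)."""


def parse_label(token: str) -> str:
    key = token.strip().lower()
    if key not in _LABEL_ALIASES:
        raise DataError(f"unknown label token {token!r}")
    return _LABEL_ALIASES[key]


def validate_residues(seq: str) -> None:
    bad = set(seq) - STANDARD_RESIDUES - {UNKNOWN}
    if bad:
        raise DataError(f"illegal residue(s) {sorted(bad)} in sequence {seq!r}")
    if not seq:
        raise DataError("empty sequence")


@dataclass(frozen=True)
class LabeledSequence:
    """One protein's post-iMet N-terminal sequence and acetylation label."""

    id: str
    nterm: str
    label: str

    def __post_init__(self) -> None:
        validate_residues(self.nterm)
        if self.label not in (POSITIVE, NEGATIVE):
            raise DataError(f"label must be positive/negative, got {self.label!r}")

    @property
    def has_unknown(self) -> bool:
        """True if the sequence contains the unknown residue symbol 'X'."""
        return UNKNOWN in self.nterm

    def window(self, length: int) -> str:
        """First `length` residues, right-padded with '-' when short."""
        return self.nterm[:length].ljust(length, "-")


@dataclass
class SequenceDataset:
    """A curated collection of labeled N-terminal sequences.

    `window_length` is the dedup/analysis window (the first 10 residues by
    default, mirroring the curation rule the dataset construction uses).
    """

    records: list[LabeledSequence] = field(default_factory=list)
    window_length: int = 10
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> LabeledSequence:
        return self.records[i]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)

    def by_label(self, label: str) -> list[LabeledSequence]:
        return [r for r in self.records if r.label == label]

    def without_unknown(self) -> "SequenceDataset":
        """Drop records containing 'X' (excluded from training by default)."""
        kept = [r for r in self.records if not r.has_unknown]
        n_dropped = len(self.records) - len(kept)
        if n_dropped:
            logger.info("excluded %d record(s) containing unknown residue 'X'", n_dropped)
        return SequenceDataset(kept, self.window_length,
                               self.provenance + f" | dropped {n_dropped} X-records" if n_dropped else self.provenance)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": [r.id for r in self.records],
             "sequence": [r.nterm for r in self.records],
             "label": [r.label for r in self.records]}
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tsequence\tlabel\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.nterm}\t{r.label}\n")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(f">{r.id}|{r.label}\n{r.nterm}\n")


@dataclass(frozen=True)
class SplitSpec:
    """Per-class training-set sizes and the RNG seed for a random split."""

    n_train_pos: int
    n_train_neg: int
    seed: int = 0


def load_dataset(path: str | Path, format: str | None = None,
                 window_length: int = 10) -> SequenceDataset:
    """Read a labeled dataset from TSV (id, sequence, label) or FASTA.

    FASTA headers carry the label after a pipe: ``>id|label``.  Format is
    inferred from the extension when not given.  All malformed rows/records
    are collected and reported together with their line numbers.
    Deduplication is NOT applied here; see :func:`deduplicate`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "tsv"
    if format == "tsv":
        records, errors = _parse_tsv(path)
    elif format == "fasta":
        records, errors = _parse_fasta(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'fasta')")
    if errors:
        raise DataError(
            f"{len(errors)} malformed record(s) in {path.name}:\n  " + "\n  ".join(errors)
        )
    return SequenceDataset(records, window_length, provenance=f"loaded from {path}")


def _parse_tsv(path: Path) -> tuple[list[LabeledSequence], list[str]]:
    records: list[LabeledSequence] = []
    errors: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.strip().lower() for p in parts[:3]] == ["id", "sequence", "label"]:
                continue
            if len(parts) != 3:
                errors.append(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
                continue
            ident, seq, label = (p.strip() for p in parts)
            try:
                records.append(LabeledSequence(ident, seq.upper(), parse_label(label)))
            except DataError as e:
                errors.append(f"line {lineno}: {e}")
    return records, errors


def _parse_fasta(path: Path) -> tuple[list[LabeledSequence], list[str]]:
    records: list[LabeledSequence] = []
    errors: list[str] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if "|" not in header:
            errors.append(f"line {header_line}: header {header!r} lacks '|label' suffix")
            return
        ident, _, label = header.rpartition("|")
        try:
            records.append(LabeledSequence(ident, seq.upper(), parse_label(label)))
        except DataError as e:
            errors.append(f"line {header_line}: {e}")

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, header_line, chunks = line[1:], lineno, []
            else:
                chunks.append(line)
    flush()
    return records, errors


def imet_cleavable(protein_seq: str) -> bool:
    """Is the initiator Met of this full-length sequence cleaved?

    Methionine aminopeptidase removes iMet when residue 2 has a side-chain
    radius of gyration no greater than 1.29 A, i.e. is one of
    Gly, Ala, Ser, Cys, Thr, Pro or Val.
    """
    if len(protein_seq) < 2:
        raise DataError("sequence must have at least 2 residues")
    if protein_seq[0] != "M":
        raise DataError("sequence does not start with Met")
    return protein_seq[1].upper() in IMET_CLEAVABLE_SET


def deduplicate(ds: SequenceDataset, return_report: bool = False):
    """Remove duplicate (window, label) records; drop label-conflicting windows.

    Records whose first `window_length` residues AND label match an earlier
    record are dropped (first occurrence kept, order preserved).  Windows that
    occur with BOTH labels are removed entirely — keeping either side would
    inject label noise — and reported.

    With ``return_report=True`` returns ``(dataset, report)`` where report is
    a dict with ``n_duplicates_removed`` and ``conflicts`` (the offending
    window strings).
    """
    wl = ds.window_length
    labels_by_window: dict[str, set[str]] = {}
    for r in ds.records:
        labels_by_window.setdefault(r.window(wl), set()).add(r.label)
    conflicts = {w for w, labs in labels_by_window.items() if len(labs) > 1}

    seen: set[tuple[str, str]] = set()
    survivors: list[LabeledSequence] = []
    n_dup = 0
    for r in ds.records:
        w = r.window(wl)
        if w in conflicts:
            continue
        key = (w, r.label)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        survivors.append(r)
    if conflicts:
        logger.warning("removed %d window(s) with conflicting labels", len(conflicts))
    out = SequenceDataset(survivors, wl, ds.provenance + " | deduplicated")
    if return_report:
        return out, {"n_duplicates_removed": n_dup, "conflicts": sorted(conflicts)}
    return out


def random_split(ds: SequenceDataset, spec: SplitSpec) -> tuple[SequenceDataset, SequenceDataset]:
    """Seeded per-class random split into (train, test).

    Samples `spec.n_train_pos` positives and `spec.n_train_neg` negatives
    without replacement; the complement forms the test set.  Original record
    order is preserved within each part, and identical seeds reproduce
    identical splits.
    """
    pos_idx = [i for i, r in enumerate(ds.records) if r.label == POSITIVE]
    neg_idx = [i for i, r in enumerate(ds.records) if r.label == NEGATIVE]
    if spec.n_train_pos > len(pos_idx):
        raise ValueError(f"requested {spec.n_train_pos} training positives, only {len(pos_idx)} available")
    if spec.n_train_neg > len(neg_idx):
        raise ValueError(f"requested {spec.n_train_neg} training negatives, only {len(neg_idx)} available")
    rng = np.random.default_rng(spec.seed)
    train_set = set(rng.choice(pos_idx, size=spec.n_train_pos, replace=False).tolist())
    train_set |= set(rng.choice(neg_idx, size=spec.n_train_neg, replace=False).tolist())
    train = [r for i, r in enumerate(ds.records) if i in train_set]
    test = [r for i, r in enumerate(ds.records) if i not in train_set]
    prov = f"{ds.provenance} | split seed={spec.seed} ({spec.n_train_pos}+,{spec.n_train_neg}-)"
    return (SequenceDataset(train, ds.window_length, prov + " [train]"),
            SequenceDataset(test, ds.window_length, prov + " [test]"))
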