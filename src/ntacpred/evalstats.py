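"""Performance metrics, window scans, composition tables and charge tests.

The six confusion-matrix indicators (TPR, SPC, PPV, ACC, MCC, F1) follow
the standard binary-classification definitions with "acetylated" as the
positive class.  The N-terminal net-charge statistic counts +1 per Lys/Arg
and -1 per Asp/Glu over the first 10 mature residues — the only residues
charged at physiological pH — and the two classes are compared with a
Wilcoxon–Mann–Whitney rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .encoding import ALPHABET, WindowSpec
from .seqdata import (DataError, NEGATIVE, POSITIVE, SequenceDataset,
                      STANDARD_RESIDUES)

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

#: largest group size for which the rank-sum null is enumerated exactly
EXACT_ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six indicators; None marks an undefined (0/0) ratio.

    MCC follows the zero-denominator -> 0 convention.
    """

    tpr: Optional[float]
    spc: Optional[float]
    ppv: Optional[float]
    acc: Optional[float]
    mcc: float
    f1: Optional[float]
    counts: Optional[ConfusionCounts] = None

    _ORDER = ("TPR", "SPC", "PPV", "ACC", "MCC", "F1")

    def __getitem__(self, name: str) -> Optional[float]:
        return getattr(self, name.lower())

    def as_series(self, decimals: int | None = 3) -> pd.Series:
        vals = [self[k] for k in self._ORDER]
        s = pd.Series(vals, index=list(self._ORDER), dtype=float)
        return s.round(decimals) if decimals is not None else s

    def to_text(self) -> str:
        cells = ["  n/a" if self[k] is None else f"{self[k]:.3f}" for k in self._ORDER]
        head = "".join(f"{k:>8}" for k in self._ORDER)
        body = "".join(f"{c:>8}" for c in cells)
        return head + "\n" + body


def confusion_counts(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the acetylated class positive."""
    if len(predictions) != len(truth):
        raise ValueError(f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths")
    if not predictions:
        raise ValueError("need at least one prediction")
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truth):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """TPR, SPC, PPV, ACC, MCC and F1 from confusion counts.

    TPR = TP/(TP+FN); SPC = TN/(TN+FP); PPV = TP/(TP+FP);
    ACC = (TP+TN)/total; MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    F1 = 2TP/(2TP+FP+FN).  Ratios with a zero denominator are None, except
    MCC which returns 0 by convention.
    """
    if c.total < 1:
        raise ValueError("metrics need at least one case")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    tpr = ratio(c.tp, c.tp + c.fn)
    spc = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    acc = ratio(c.tp + c.tn, c.total)
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return MetricsReport(tpr=tpr, spc=spc, ppv=ppv, acc=acc, mcc=mcc, f1=f1, counts=c)


def evaluate_tree(tree, test: SequenceDataset) -> MetricsReport:
    """Predict a labeled test set and compute the six indicators."""
    usable = [r for r in test if not r.has_unknown]
    preds = tree.predict([r.nterm for r in usable])
    return compute_metrics(confusion_counts(preds, [r.label for r in usable]))


# ---------------------------------------------------------------------------
# window performance scans
# ---------------------------------------------------------------------------

def _scan_metric(train: SequenceDataset, spec: WindowSpec, cfg, mode: str) -> float:
    from .cart import TrainConfig, cross_validate_depth, grow_tree

    cfg = cfg or TrainConfig()
    best_depth, table = cross_validate_depth(train, cfg, spec)
    if mode == "cv":
        return float(table.loc[best_depth, "mean"])
    if mode == "resubstitution":
        tree = grow_tree(train, best_depth, spec)
        rep = evaluate_tree(tree, train)
        v = rep[cfg.selection_metric]
        return float("nan") if v is None else float(v)
    raise ValueError(f"unknown scan mode {mode!r}")


def kmer_length_scan(train: SequenceDataset, grid: Iterable[int], cfg=None,
                     mode: str = "cv") -> pd.DataFrame:
    """Selection-metric value of a predictor refit at each k-mer length.

    For each k the depth is re-selected by CV on windows (start 1, length
    k); ``mode="cv"`` records the best mean CV metric, ``"resubstitution"``
    the training-set metric of the final tree.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty k grid")
    rows = [{"k": k, "metric": _scan_metric(train, WindowSpec(k=k, start=1), cfg, mode)}
            for k in grid]
    return pd.DataFrame(rows).set_index("k")


def window_start_scan(train: SequenceDataset, starts: Iterable[int], k: int = 5,
                      cfg=None, mode: str = "cv") -> pd.DataFrame:
    """Selection metric of a k-mer predictor as the window start slides."""
    starts = list(starts)
    if not starts:
        raise ValueError("empty start grid")
    rows = [{"start": s, "metric": _scan_metric(train, WindowSpec(k=k, start=s), cfg, mode)}
            for s in starts]
    return pd.DataFrame(rows).set_index("start")


# ---------------------------------------------------------------------------
# charge statistics
# ---------------------------------------------------------------------------

def net_charge(seq: str, window: int = 10) -> int:
    """Sum of residue charges (+1 K/R, -1 D/E) over the first `window` positions."""
    if not seq:
        raise DataError("empty sequence")
    head = seq[:window]
    bad = set(head) - STANDARD_RESIDUES - {"X", "-"}
    if bad:
        raise DataError(f"illegal residue(s) {sorted(bad)} in {seq!r}")
    return sum(CHARGE.get(r, 0) for r in head)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Returns ``(W, p)`` where W is the sum of midranks of `group_a` in the
    pooled sample.  For group sizes both <= 8 the null distribution is
    enumerated exactly over all C(n1+n2, n1) assignments of the pooled
    midranks (which handles ties correctly); larger samples use the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())

    if max(n1, n2) <= EXACT_ENUMERATION_MAX_N:
        n = n1 + n2
        dist = np.array([sum(ranks[list(c)]) for c in combinations(range(n), n1)])
        mean = dist.mean()
        dev = abs(w - mean)
        p = float(np.mean(np.abs(dist - mean) >= dev - 1e-12))
        return w, min(p, 1.0)

    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    dev = abs(w - mean)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    from scipy.stats import norm

    p = 2.0 * float(norm.sf(z))
    return w, min(p, 1.0)


@dataclass
class ChargeReport:
    """Per-class N-terminal charge summary and rank-sum comparison."""

    charges_pos: np.ndarray
    charges_neg: np.ndarray
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    statistic: float
    p_value: float
    ddof: int = 1

    def to_text(self) -> str:
        return (f"acetylated   mean {self.mean_pos:+.2f} (SD = {self.sd_pos:.2f}, n = {self.charges_pos.size})\n"
                f"unacetylated mean {self.mean_neg:+.2f} (SD = {self.sd_neg:.2f}, n = {self.charges_neg.size})\n"
                f"Wilcoxon rank-sum W = {self.statistic:.1f}, two-sided p = {self.p_value:.2g}")


def charge_group_compare(ds: SequenceDataset, window: int = 10, ddof: int = 1) -> ChargeReport:
    """Compare net N-terminal charges of acetylated vs unacetylated proteins.

    `ddof=1` gives the sample SD (default); pass 0 for population SD.
    The charge window is 10 residues regardless of any model's k.
    """
    pos = np.array([net_charge(r.nterm, window) for r in ds if r.label == POSITIVE], dtype=float)
    neg = np.array([net_charge(r.nterm, window) for r in ds if r.label == NEGATIVE], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for the charge comparison")
    w, p = rank_sum_test(pos, neg)
    return ChargeReport(
        charges_pos=pos, charges_neg=neg,
        mean_pos=float(pos.mean()), mean_neg=float(neg.mean()),
        sd_pos=float(pos.std(ddof=ddof)), sd_neg=float(neg.std(ddof=ddof)),
        statistic=w, p_value=p, ddof=ddof,
    )


# ---------------------------------------------------------------------------
# residue composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Percentage residue frequencies per class and position.

    `frequencies[label]` is a DataFrame (rows = positions 1..L, columns =
    the 20 residues) of percentages; each row sums to 100 over sequences
    with a standard residue at that position.
    """

    frequencies: dict[str, pd.DataFrame]

    def top_ranked(self, n: int = 5, decimals: int = 1) -> pd.DataFrame:
        """Top-n residues per class and position, "R (pct)" style."""
        blocks = {}
        for label, freq in self.frequencies.items():
            cols = {}
            for pos in freq.index:
                row = freq.loc[pos].sort_values(ascending=False)
                cols[pos] = [f"{r} ({v:.{decimals}f})" for r, v in row.head(n).items()]
            blocks[label] = pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="rank"))
        return pd.concat(blocks, names=["class", "rank"])

    def percentage(self, label: str, pos: int, residue: str) -> float:
        return float(self.frequencies[label].loc[pos, residue])


def composition_table(ds: SequenceDataset, length: int = 10) -> CompositionTable:
    """Per-class, per-position residue percentage frequencies.

    Positions run 1..length; the denominator at each position is the number
    of class sequences carrying a standard residue there (padding and 'X'
    are ignored).
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    freqs: dict[str, pd.DataFrame] = {}
    for label in (POSITIVE, NEGATIVE):
        recs = [r for r in ds if r.label == label]
        if not recs:
            continue
        mat = np.zeros((length, len(ALPHABET)))
        for r in recs:
            w = r.window(length)
            for p, res in enumerate(w):
                if res in STANDARD_RESIDUES:
                    mat[p, ALPHABET.index(res)] += 1
        totals = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pct = np.where(totals > 0, 100.0 * mat / totals, 0.0)
        freqs[label] = pd.DataFrame(pct, index=pd.RangeIndex(1, length + 1, name="position"),
                                    columns=list(ALPHABET))
    return CompositionTable(frequencies=freqs)
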