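"""Seeded generator of labeled N-terminal sequence datasets.

Sequences are drawn position-independently from class-conditional
categorical distributions over the 20 residues — the same feature geometry
the decision tree assumes.  The shipped preset emulates the statistical
structure of the curated 811-protein N-terminome study set: the printed
top-5 position-specific residue frequencies per class, class sizes 411
acetylated / 400 unacetylated, and the class-dependent net-charge bias
(mean -0.28 for acetylated, +0.61 for unacetylated N-termini).  Planted
motif rules with adjustable penetrance provide ground truth for end-to-end
recovery tests.  Positional dependence and sequence homology between
records are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .encoding import ALPHABET
from .evalstats import CHARGE
from .rules import SequenceMotif, match_motif
from .seqdata import LabeledSequence, NEGATIVE, POSITIVE, SequenceDataset

_CHARGE_VEC = np.array([CHARGE.get(r, 0) for r in ALPHABET], dtype=float)


@dataclass
class PlantedRule:
    """A motif that (with given penetrance) dictates the label."""

    motif: SequenceMotif
    label: str
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass
class PositionModel:
    """Class-conditional per-position residue distributions.

    `probs[label]` is an (L, 20) row-stochastic matrix in ALPHABET order.
    When `rules` is nonempty, sampled labels are overwritten by the first
    matching rule (or `default_label` if none matches), each applied with
    its penetrance (the complementary probability flips the label).
    """

    probs: dict[str, np.ndarray]
    rules: list[PlantedRule] = field(default_factory=list)
    default_label: str = NEGATIVE
    seed: int = 0

    def __post_init__(self) -> None:
        for label, mat in self.probs.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != len(ALPHABET):
                raise ValueError(f"probs[{label!r}] must be (L, 20)")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"probs[{label!r}] rows must sum to 1")
            self.probs[label] = mat

    @property
    def length(self) -> int:
        return next(iter(self.probs.values())).shape[0]

    def expected_charge(self, label: str) -> float:
        """Mean net charge (+1 K/R, -1 D/E) implied by the categoricals."""
        return float((self.probs[label][: min(self.length, 10)] @ _CHARGE_VEC).sum())

    # -- plain-text persistence -----------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("class\tposition\tresidue\tprobability\n")
            for label, mat in self.probs.items():
                for p in range(mat.shape[0]):
                    for j, r in enumerate(ALPHABET):
                        fh.write(f"{label}\t{p + 1}\t{r}\t{mat[p, j]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionModel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        probs = {}
        for label, grp in df.groupby("class"):
            L = int(grp["position"].max())
            mat = np.zeros((L, len(ALPHABET)))
            for _, row in grp.iterrows():
                mat[int(row["position"]) - 1, ALPHABET.index(row["residue"])] = row["probability"]
            probs[label] = mat
        return cls(probs=probs)


def fit_position_model(ds: SequenceDataset, length: int = 10) -> PositionModel:
    """Maximum-likelihood (count-based) categoricals per class and position.

    No smoothing is applied: unseen residues get probability 0.
    """
    probs = {}
    for label in (POSITIVE, NEGATIVE):
        recs = [r for r in ds if r.label == label]
        if not recs:
            raise ValueError(f"class {label!r} is empty")
        counts = np.zeros((length, len(ALPHABET)))
        for r in recs:
            for p, res in enumerate(r.window(length)):
                if res in ALPHABET:
                    counts[p, ALPHABET.index(res)] += 1
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError(f"class {label!r} has a position with no standard residues")
        probs[label] = counts / totals
    return PositionModel(probs=probs)


def sample_dataset(model: PositionModel, n_pos: int, n_neg: int,
                   seed: Optional[int] = None,
                   id_prefix: str = "syn") -> SequenceDataset:
    """Draw a labeled dataset from the model; identical seeds reproduce it.

    `n_pos`/`n_neg` are the numbers of sequences drawn from the positive and
    negative categoricals.  Without planted rules the drawn class is the
    label; with rules the final label is determined by the first matching
    rule (or `default_label`), so final class counts may differ.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    records: list[LabeledSequence] = []
    counter = 0
    for label, n in ((POSITIVE, n_pos), (NEGATIVE, n_neg)):
        if n == 0:
            continue
        mat = model.probs[label]
        L = mat.shape[0]
        draws = np.stack([rng.choice(len(ALPHABET), size=n, p=mat[p]) for p in range(L)], axis=1)
        for row in draws:
            seq = "".join(ALPHABET[j] for j in row)
            final = label
            if model.rules:
                final = model.default_label
                pen = 1.0
                for rule in model.rules:
                    if match_motif(rule.motif, seq):
                        final, pen = rule.label, rule.penetrance
                        break
                if pen < 1.0 and rng.random() >= pen:
                    final = POSITIVE if final == NEGATIVE else NEGATIVE
            counter += 1
            records.append(LabeledSequence(f"{id_prefix}{counter:05d}", seq, final))
    return SequenceDataset(records, window_length=min(model.length, 10),
                           provenance=f"synthetic seed={model.seed if seed is None else seed}")


# ---------------------------------------------------------------------------
# the N-terminome emulation preset
# ---------------------------------------------------------------------------

#: Printed top-5 residue percentage frequencies per class and position
#: (positions 1..10 after the removed iMet).
TOP5_FREQUENCIES: dict[str, list[list[tuple[str, float]]]] = {
    POSITIVE: [
        [("S", 44.0), ("A", 43.3), ("T", 5.4), ("G", 4.4), ("V", 1.5)],
        [("D", 17.3), ("E", 14.1), ("S", 11.2), ("A", 10.5), ("G", 7.8)],
        [("T", 10.9), ("A", 9.0), ("K", 9.0), ("P", 8.5), ("S", 8.5)],
        [("A", 13.6), ("G", 9.5), ("E", 9.0), ("V", 8.5), ("S", 7.8)],
        [("A", 12.9), ("K", 9.5), ("T", 9.2), ("V", 8.0), ("S", 7.3)],
        [("K", 9.7), ("L", 9.5), ("A", 8.8), ("V", 8.3), ("G", 8.0)],
        [("A", 11.2), ("K", 10.5), ("V", 8.8), ("S", 8.5), ("L", 7.1)],
        [("A", 14.8), ("K", 9.2), ("E", 8.8), ("V", 8.8), ("L", 8.0)],
        [("A", 12.7), ("K", 9.7), ("E", 7.5), ("G", 7.3), ("I", 7.1)],
        [("A", 12.9), ("G", 9.2), ("L", 9.0), ("K", 7.3), ("E", 6.8)],
    ],
    NEGATIVE: [
        [("G", 24.3), ("A", 21.5), ("P", 20.8), ("V", 18.8), ("S", 7.8)],
        [("K", 13.3), ("L", 12.8), ("R", 9.0), ("A", 8.5), ("P", 7.0)],
        [("S", 16.3), ("K", 9.3), ("E", 6.8), ("A", 6.3), ("G", 6.0)],
        [("K", 13.8), ("L", 8.8), ("T", 7.8), ("A", 7.3), ("R", 7.0)],
        [("S", 11.5), ("A", 11.3), ("K", 8.8), ("D", 7.5), ("V", 7.0)],
        [("K", 10.3), ("L", 9.5), ("A", 8.3), ("E", 8.0), ("T", 7.3)],
        [("K", 11.0), ("L", 8.5), ("E", 8.5), ("A", 8.3), ("G", 7.5)],
        [("K", 10.8), ("R", 9.5), ("S", 9.3), ("E", 7.3), ("V", 6.8)],
        [("K", 10.8), ("L", 10.5), ("R", 8.5), ("G", 8.3), ("A", 7.8)],
        [("V", 9.8), ("A", 9.3), ("G", 7.8), ("S", 7.8), ("L", 7.3)],
    ],
}

#: Target per-class mean net N-terminal charges of the emulated study set.
CHARGE_BIAS_DEFAULT = {POSITIVE: -0.28, NEGATIVE: +0.61}

#: Emulated class sizes (acetylated, unacetylated).
CLASS_SIZES = (411, 400)


def _class_matrix(top5: list[list[tuple[str, float]]], target_charge: Optional[float]) -> np.ndarray:
    """Build an (L, 20) matrix from top-5 percentages.

    The listed residues keep their printed frequencies exactly; the
    remaining mass at each position is spread over the other residues with
    exponential tilting ``w_r ∝ exp(t * charge_r)``, the single scalar t
    solved so the matrix's expected net charge over positions 1..10 equals
    `target_charge`.  With ``target_charge=None`` the remainder is uniform.
    """
    L = len(top5)
    fixed = np.zeros((L, len(ALPHABET)))
    free = np.ones((L, len(ALPHABET)), dtype=bool)
    for p, entries in enumerate(top5):
        for r, pct in entries:
            fixed[p, ALPHABET.index(r)] = pct / 100.0
            free[p, ALPHABET.index(r)] = False

    def matrix_for(t: float) -> np.ndarray:
        mat = fixed.copy()
        for p in range(L):
            m = 1.0 - fixed[p].sum()
            w = np.where(free[p], np.exp(t * _CHARGE_VEC), 0.0)
            mat[p] += m * w / w.sum()
        return mat

    if target_charge is None:
        return matrix_for(0.0)

    def charge_at(t: float) -> float:
        return float((matrix_for(t)[: min(L, 10)] @ _CHARGE_VEC).sum())

    lo, hi = -8.0, 8.0
    if not (charge_at(lo) <= target_charge <= charge_at(hi)):
        raise ValueError(f"target charge {target_charge} unreachable by tilting the remainder mass")
    t_star = brentq(lambda t: charge_at(t) - target_charge, lo, hi, xtol=1e-12)
    return matrix_for(t_star)


def table1_preset(charge_bias: Optional[dict[str, float]] = None,
                  seed: int = 0) -> PositionModel:
    """The default N-terminome emulation model.

    Each class's categoricals reproduce the printed top-5 position-specific
    frequencies exactly; the unlisted remainder mass is charge-tilted so the
    expected mean net charge per class hits `charge_bias` (default -0.28
    acetylated / +0.61 unacetylated).
    """
    if charge_bias is None:
        charge_bias = CHARGE_BIAS_DEFAULT
    probs = {label: _class_matrix(TOP5_FREQUENCIES[label], charge_bias.get(label))
             for label in (POSITIVE, NEGATIVE)}
    return PositionModel(probs=probs, seed=seed)


def emulated_study_dataset(seed: int = 0) -> SequenceDataset:
    """A full emulated study set: 411 acetylated + 400 unacetylated draws."""
    return sample_dataset(table1_preset(), *CLASS_SIZES, seed=seed)


def motif_rule_preset(penetrance: float = 1.0, seed: int = 0) -> PositionModel:
    """Preset with labels planted by NatA-style motif rules.

    Sequences are drawn from the class-averaged study categoricals (so the
    residue marginals are realistic but carry no class signal on their own)
    and labels are assigned by the known position-specific rules, all
    confined to the first five residues: ``SXX[^R][^P]`` -> acetylated,
    ``A[^PR]`` -> acetylated, Asp at position 2 -> acetylated; anything
    else unacetylated.  Because two of the rules hinge on position >= 2,
    a 1-mer predictor cannot resolve them — the ground truth for the
    k-mer-scan jump — while all signal sits within positions 1..5.
    """
    base = table1_preset(seed=seed)
    avg = 0.5 * (base.probs[POSITIVE] + base.probs[NEGATIVE])
    rules = [
        PlantedRule(SequenceMotif(required={1: "S"}, excluded={4: {"R"}, 5: {"P"}}),
                    POSITIVE, penetrance),
        PlantedRule(SequenceMotif(required={1: "A"}, excluded={2: {"P", "R"}}),
                    POSITIVE, penetrance),
        PlantedRule(SequenceMotif(required={2: "D"}), POSITIVE, penetrance),
    ]
    return PositionModel(probs={POSITIVE: avg, NEGATIVE: avg.copy()},
                         rules=rules, default_label=NEGATIVE, seed=seed)


def signal_truncated_preset(n_signal_positions: int = 5, seed: int = 0) -> PositionModel:
    """Preset variant with class signal confined to the first positions.

    Positions beyond `n_signal_positions` use the two classes' averaged
    categorical, removing any discriminative information there — the ground
    truth for window-scan behaviour tests.
    """
    base = table1_preset(seed=seed)
    avg = 0.5 * (base.probs[POSITIVE] + base.probs[NEGATIVE])
    probs = {}
    for label in (POSITIVE, NEGATIVE):
        mat = base.probs[label].copy()
        mat[n_signal_positions:] = avg[n_signal_positions:]
        probs[label] = mat
    return PositionModel(probs=probs, seed=seed)
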