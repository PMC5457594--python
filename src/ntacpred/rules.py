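"""Root-to-leaf tree paths as position-wise sequence motifs.

Each leaf of a trained tree corresponds to a motif: a "yes" edge on the
indicator (position p, residue r) requires r at p, a "no" edge adds r to
the excluded set at p.  The motif set of one tree therefore partitions
sequence space — every window satisfies exactly one leaf's constraints and
that motif's label equals the tree's prediction.  Motifs render in the
regular-expression style used for NatA substrate rules, e.g. ``A[^PR]``
(Ala at 1, neither Pro nor Arg at 2) or ``SXX[^R][^P]XX[^P]`` with ``X``
standing for any residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cart import DecisionTree, TreeNode
from .encoding import ALPHABET, N_RESIDUES
from .seqdata import DataError, SequenceDataset, STANDARD_RESIDUES

logger = logging.getLogger(__name__)


@dataclass
class SequenceMotif:
    """Per-position constraints of one root-to-leaf path.

    `required`: position -> the single residue demanded there.
    `excluded`: position -> set of residues forbidden there.
    A position never appears in both maps.
    """

    required: dict[int, str] = field(default_factory=dict)
    excluded: dict[int, set[str]] = field(default_factory=dict)
    predicted_label: str = ""
    n_covered: int = 0

    def constrained_positions(self) -> list[int]:
        return sorted(set(self.required) | set(self.excluded))


def extract_motifs(tree: DecisionTree) -> list[SequenceMotif]:
    """One motif per leaf, in leaf traversal order (yes branch first)."""
    motifs: list[SequenceMotif] = []

    def walk(node: TreeNode, required: dict[int, str], excluded: dict[int, set[str]]) -> None:
        if node.is_leaf:
            motifs.append(SequenceMotif(
                required={p: r for p, r in required.items()},
                excluded={p: set(s) for p, s in excluded.items()},
                predicted_label=node.predicted_label,
                n_covered=node.n,
            ))
            return
        pos, rank = divmod(node.feature, N_RESIDUES)
        pos += 1
        res = ALPHABET[rank]
        req_yes = dict(required)
        req_yes[pos] = res
        # on the yes branch any exclusions at this position are subsumed
        exc_yes = {p: set(s) for p, s in excluded.items() if p != pos}
        walk(node.yes, req_yes, exc_yes)
        exc_no = {p: set(s) for p, s in excluded.items()}
        exc_no.setdefault(pos, set()).add(res)
        walk(node.no, dict(required), exc_no)

    walk(tree.root, {}, {})
    return motifs


def render_regex(m: SequenceMotif, any_symbol: str = "X") -> str:
    """Anchored pattern text for a motif.

    Required residues render literally, excluded sets as ``[^...]`` in
    alphabet order, interior unconstrained positions as `any_symbol`
    (the domain's ``X`` convention by default; pass ``"."`` for a strict
    regex dialect).  Trailing unconstrained positions are omitted; a fully
    unconstrained motif renders as the empty string (matches everything).
    """
    positions = m.constrained_positions()
    if not positions:
        return ""
    out = []
    for p in range(1, positions[-1] + 1):
        if p in m.required:
            out.append(m.required[p])
        elif p in m.excluded:
            members = "".join(sorted(m.excluded[p], key=ALPHABET.index))
            out.append(f"[^{members}]")
        else:
            out.append(any_symbol)
    return "".join(out)


def match_motif(m: SequenceMotif, seq: str) -> bool:
    """Does the sequence satisfy every positional constraint?

    Mirrors tree traversal exactly: an unknown ('X') or padded ('-')
    position answers "no" to any residue test, so it fails a requirement
    and passes an exclusion.
    """
    bad = set(seq) - STANDARD_RESIDUES - {"X", "-"}
    if bad:
        raise DataError(f"illegal residue(s) {sorted(bad)} in {seq!r}")
    for p, r in m.required.items():
        if p > len(seq) or seq[p - 1] != r:
            return False
    for p, forbidden in m.excluded.items():
        if p <= len(seq) and seq[p - 1] in forbidden:
            return False
    return True


def coverage_counts(motifs: list[SequenceMotif], ds: SequenceDataset):
    """Per-motif coverage of a dataset.

    Each sequence is assigned to the first motif (in leaf order) it
    satisfies.  Returns a pandas DataFrame with pattern, predicted label,
    leaf training count, matched count, dataset fraction, and the fraction
    of matched sequences whose true label agrees with the motif's.  For a
    complete motif set from one tree the fractions sum to 1; otherwise a
    warning is logged.
    """
    import pandas as pd

    n = len(ds)
    rows = []
    assigned = 0
    for m in motifs:
        matched = [r for r in ds if match_motif(m, r.nterm)]
        agree = sum(1 for r in matched if r.label == m.predicted_label)
        rows.append({
            "pattern": render_regex(m),
            "predicted_label": m.predicted_label,
            "n_covered_train": m.n_covered,
            "n_matched": len(matched),
            "fraction": len(matched) / n if n else 0.0,
            "label_agreement": agree / len(matched) if matched else float("nan"),
        })
    # first-match assignment: recount exclusively for the partition check
    for r in ds:
        for m in motifs:
            if match_motif(m, r.nterm):
                assigned += 1
                break
    table = pd.DataFrame(rows)
    if n and not abs(table["fraction"].sum() - 1.0) < 1e-9:
        logger.warning("motif fractions sum to %.4f (motifs do not partition the dataset)",
                       table["fraction"].sum())
    return table


def motif_table_tsv(motifs: list[SequenceMotif], ds: SequenceDataset, path: str | Path) -> None:
    coverage_counts(motifs, ds).to_csv(path, sep="\t", index=False)
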