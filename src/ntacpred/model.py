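"""statsmodels-style modelling interface.

`AcetylationPredictor` is built from a labeled sequence dataset; `fit()`
selects the tree depth by cross-validation, grows the final CART tree and
returns an `AcetylationResults` carrying the tree, the CV table, the
extracted motifs and evaluation helpers with a `summary()` view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .cart import DecisionTree, TrainConfig, cross_validate_depth, grow_tree
from .encoding import WindowSpec
from .evalstats import MetricsReport, evaluate_tree
from .rules import SequenceMotif, coverage_counts, extract_motifs, render_regex
from .seqdata import (LabeledSequence, SequenceDataset, deduplicate,
                      load_dataset, parse_label)


class AcetylationPredictor:
    """N-terminal acetylation predictor model.

    Parameters
    ----------
    data : SequenceDataset
        Labeled post-iMet N-terminal sequences (the training data).
    window : WindowSpec, optional
        Sequence window to encode; defaults to the first 10 residues.
    config : TrainConfig, optional
        Depth grid, fold count, selection metric and seed.
    dedup : bool
        Apply window/label deduplication before fitting (default True).
    """

    def __init__(self, data: SequenceDataset, window: WindowSpec | None = None,
                 config: TrainConfig | None = None, dedup: bool = True):
        self.data = deduplicate(data) if dedup else data
        self.window = window or WindowSpec(k=self.data.window_length)
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AcetylationPredictor":
        """Build from a DataFrame with columns id, sequence, label."""
        records = [LabeledSequence(str(r.id), str(r.sequence).upper(), parse_label(str(r.label)))
                   for r in df.itertuples(index=False)]
        return cls(SequenceDataset(records, provenance="from_dataframe"), **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "AcetylationPredictor":
        return cls(load_dataset(path, "tsv"), **kwargs)

    def fit(self) -> "AcetylationResults":
        """Select depth by stratified CV, grow the final tree, extract motifs."""
        best_depth, cv_table = cross_validate_depth(self.data, self.config, self.window)
        tree = grow_tree(self.data, best_depth, self.window)
        return AcetylationResults(model=self, tree=tree, best_depth=best_depth,
                                  cv_table=cv_table)


@dataclass
class AcetylationResults:
    """Fit results: the trained tree and its interpretable read-outs."""

    model: AcetylationPredictor
    tree: DecisionTree
    best_depth: int
    cv_table: pd.DataFrame
    _motifs: Optional[list[SequenceMotif]] = field(default=None, repr=False)

    @property
    def motifs(self) -> list[SequenceMotif]:
        if self._motifs is None:
            self._motifs = extract_motifs(self.tree)
        return self._motifs

    def predict(self, seqs: Iterable[str] | SequenceDataset) -> list[str]:
        if isinstance(seqs, SequenceDataset):
            seqs = [r.nterm for r in seqs]
        return self.tree.predict(seqs)

    def evaluate(self, test: SequenceDataset) -> MetricsReport:
        return evaluate_tree(self.tree, test)

    def motif_coverage(self, ds: SequenceDataset | None = None) -> pd.DataFrame:
        return coverage_counts(self.motifs, ds or self.model.data)

    def summary(self) -> str:
        """Human-readable fit summary: CV table, tree shape, motif table."""
        lines = [
            "N-terminal acetylation CART predictor",
            "=" * 53,
            f"training cases: {len(self.model.data)} "
            f"({self.model.data.n_positive} acetylated, {self.model.data.n_negative} unacetylated)",
            f"window: k={self.model.window.k} start={self.model.window.start}   "
            f"selection metric: {self.model.config.selection_metric}   seed: {self.model.config.seed}",
            f"selected max depth: {self.best_depth}   "
            f"tree depth: {self.tree.depth()}   leaves: {self.tree.n_leaves()}",
            "",
            "cross-validated depth grid (mean %s per depth):" % self.model.config.selection_metric,
            self.cv_table["mean"].round(3).to_string(),
            "",
            "leaf motifs (pattern, label, training cases):",
        ]
        for m in self.motifs:
            pat = render_regex(m) or "(unconstrained)"
            lines.append(f"  {pat:<24} {m.predicted_label:<9} {m.n_covered}")
        resub = self.evaluate(self.model.data)
        lines += ["", "training-set (resubstitution) performance:", resub.to_text()]
        return "\n".join(lines)
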