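# Methods

## Problem and scope

`ntacpred` models the N-terminal (Nα) acetylation status of proteins whose
initiator methionine has been cleaved by methionine aminopeptidase.  iMet
cleavage occurs when residue 2 of the nascent chain is small (Gly, Ala,
Ser, Cys, Thr, Pro, Val — side-chain radius of gyration ≤ 1.29 Å), and the
resulting mature N-termini are acetylated almost exclusively by NatA, whose
substrate specificity is broad and position-specific rather than motif-exact.
The package therefore treats prediction and rule discovery as one problem:
the classifier is a decision tree whose paths are themselves the
position-specific rules.

Throughout, position 1 is the first residue *after* the removed iMet, the
positive class is "acetylated", and labels are attached to each N-terminal
sequence record (TSV `id/sequence/label` or FASTA `>id|label`).

## Data curation

* **Deduplication** keys on (first 10 residues, label).  Windows occurring
  with *both* labels are removed entirely rather than arbitrarily keeping
  one side: such conflicts are irreducible label noise at the resolution the
  model sees.  Dedup is idempotent and order-preserving.
* **Unknown residues**: `X` is accepted on input, flagged, and excluded from
  training and composition/charge analyses by default (it encodes to an
  all-zero block, which would silently behave as "none of the 20 residues").
* **Short sequences** are right-padded with `-` for windowing; the pad also
  encodes to zeros, so a padded position answers "no" to every residue test.
* **Splitting** is per-class sampling without replacement from a single
  integer seed (`SplitSpec(n_train_pos, n_train_neg, seed)`), reproducing
  the 200 + 200 training / remainder test design used for the curated
  811-protein study set.

## Encoding

A window of `k` residues starting at 1-based `start` maps to a binary
vector of length 20·k: feature `(p−1)·20 + rank(r)` indicates residue `r`
at window position `p`, with the alphabet fixed as `ACDEFGHIKLMNPQRSTVWY`.
The ordering is arbitrary but load-bearing: feature indices and split
tie-breaking depend on it, so it is part of the serialized model contract.
Gap and unknown encode to all-zero blocks, keeping the space at 20
dimensions per position.  Encoding is exactly invertible up to the
`X`/`-` distinction.

## The CART classifier

Growth is standard greedy binary recursive partitioning:

* **Criterion**: Gini impurity, `1 − p₊² − p₋²`.  The best split maximizes
  the size-weighted impurity decrease over every (position, residue)
  indicator.  Internally the comparison `T = (pos_y²+neg_y²)/n_y +
  (pos_n²+neg_n²)/n_n` is used (monotone in the decrease); near-ties are
  re-resolved with exact integer cross-products so float rounding can never
  decide between mathematically equal gains, and exact ties go to the
  lowest feature index (position-major, alphabet-rank-minor).  Positivity
  of the winning gain is also confirmed in integer arithmetic.
* **Stopping**: a node becomes a leaf when pure, at the depth bound, below
  the minimum split size (2), or when no strictly positive decrease exists.
* **Leaf label**: majority class; an exact tie predicts *unacetylated*, the
  conservative call for claiming a modification.
* **Depth selection**: stratified seeded 5-fold cross-validation over the
  depth grid (default 2–10); folds are built per class by seeded shuffle
  dealt round-robin.  The selection metric is MCC by default (robust to the
  mild class imbalance); ACC and F1 are selectable.  Ties in the mean CV
  metric go to the smallest depth.  A fold whose metric is undefined
  contributes NaN and is excluded from the mean.

Training is exactly reproducible: identical data, configuration and seed
produce a byte-identical serialized tree (a documented JSON text format
with features written as `"pos:residue"` and per-node case counts).

## Motifs

Each root-to-leaf path is rendered as a motif: a "yes" edge on (p, r)
requires `r` at `p`; a "no" edge adds `r` to the excluded set at `p`
(multiple exclusions at one position merge, e.g. `[^AS]`).  Rendering uses
the domain's `X`-for-any convention (`SXX[^R][^P]XX[^P]`), with a strict
regex dialect (`.` wildcard) available.  Motif matching mirrors tree
traversal exactly — unknown/padded positions fail requirements and pass
exclusions — so the motif set of one tree partitions sequence space and
agrees with `predict_one` everywhere; leaf training counts sum to the
training-set size.

## Evaluation statistics

* Six indicators (TPR, SPC, PPV, ACC, MCC, F1) from TP/TN/FP/FN with the
  acetylated class positive.  Undefined (0/0) ratios are reported as
  missing, except MCC where the conventional zero-denominator → 0 is used.
  Display rounding is 3 decimals for metrics and 1 decimal for composition
  percentages; internal values keep full precision.
* **Net N-terminal charge**: Σ over positions 1–10 of +1 (Lys, Arg) and −1
  (Asp, Glu) — the residues charged at physiological pH.  The charge window
  is always 10 residues regardless of the model's k.  Class comparison
  reports per-class mean and SD (sample SD, ddof = 1, by default; ddof = 0
  exposed) and a two-sided Wilcoxon–Mann–Whitney rank-sum test:
  exact enumeration of all C(n₁+n₂, n₁) midrank assignments when both
  groups have ≤ 8 observations, otherwise the normal approximation with
  tie-corrected variance and a 0.5 continuity correction.
* **Scans**: the k-mer length scan refits the predictor (including depth
  re-selection) at each window length; the window-start scan slides a 5-mer
  along the N-terminus.  Both report either the best mean CV metric
  (default) or the resubstitution metric of the final tree.

## Synthetic data generator

The generator draws each position independently from class-conditional
categorical distributions over the 20 residues — deliberately matching the
feature geometry the tree assumes.

* `table1_preset()` carries the published top-5 position-specific residue
  percentages per class *exactly*; the unlisted remainder mass at each
  position is distributed over the other residues by exponential tilting
  `w_r ∝ exp(t·charge_r)`, with one scalar `t` per class solved (Brent's
  method) so the expected mean net charge hits −0.28 (acetylated) and +0.61
  (unacetylated).  This preserves the printed frequencies while reproducing
  the class charge separation.  `emulated_study_dataset()` draws 411 + 400
  sequences from it.
* `motif_rule_preset()` draws sequences from the class-averaged categoricals
  (no marginal signal) and assigns labels by planted NatA-style rules
  confined to positions 1–5 (`SXX[^R][^P]` → Ac, `A[^PR]` → Ac, Asp-2 → Ac,
  default unAc), each applied with a penetrance (probability the rule's
  label sticks; the complement flips it).  Because two rules hinge on
  position ≥ 2, a 1-mer predictor cannot resolve them — the ground truth
  behind the k-mer-scan jump — while all signal lies within the first five
  residues.
* `signal_truncated_preset(n)` keeps class-specific categoricals only at
  positions ≤ n and uses the class average beyond.

What the emulation does **not** model: positional dependence within a
sequence, homology clusters between records, and real curation noise.  Two
measurable consequences: the per-class charge SDs come out near 1.4 versus
1.65/1.93 in the real correlated data, so the rank-sum p of the charge
separation is more extreme (~10⁻¹⁵) than the ~2×10⁻¹⁰ observed on real
data; and tree topologies vary more across random splits than a single
curated dataset would suggest.  Passing tests therefore demonstrate
correctness of the machinery and recovery of planted structure, not
real-data generalization performance.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the study's own
scale (811-sequence datasets, 200/200 training splits, depth grid 2–10,
5-fold CV), with 100-dataset property sweeps at 80 sequences each and
parameter recovery at n = 10,000 per class; the whole suite completes in
well under a minute.  Stochastic reproduction checks use tolerances derived
from sampling spread at the emulated sample sizes (e.g. ~2.5-point SE for a
44% frequency at n = 411; ~0.08 SE for the mean charges), and the acceptance
script averages a handful of replicate draws to suppress Monte Carlo error
in the reported values.

## Known limitations

* Tree topology — hence the extracted motif strings — is split-dependent;
  only structural claims (path coverage fractions, rule classes) are stable
  across splits, and only those are asserted.
* No pruning, surrogate splits or ensembling; the depth bound is the sole
  capacity control, as in the modelled design.
* The exact-enumeration rank-sum path is O(C(n₁+n₂, n₁)) and capped at
  group sizes of 8.
* Curation against live UniProt/ECO evidence is out of scope; the loaders
  expect pre-extracted labeled tables.
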