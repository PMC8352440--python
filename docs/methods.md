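# Methods

## Model and assumptions

The toolkit operationalises guilt-by-association: genes close to a
disease's known genes in a functional interaction network are likely to be
associated with that disease, and similar diseases draw on overlapping
gene sets. Three assumptions follow. First, the disease–disease similarity
table (consumed as an opaque [0, 1] score) must carry a monotone
relatedness signal; the pipeline never recomputes it. Second, the network
edge weights must be meaningful as path lengths after one of the supported
transforms. Third, the candidate pool — genes of diseases similar to the
target — must contain most genes that could plausibly be associated with
the target; genes outside the pool are never scored.

The classification task is positive–unlabeled: only the target's known
genes are labeled. "Negatives" are sampled uniformly from the unlabeled
candidates, so the negative class is contaminated with unknown true
positives by construction. This matters quantitatively; see *Limitations*.

## Pipeline stages and parameters

**Similar-disease selection** (`candidates.select_similar_diseases`).
A disease qualifies when its recorded similarity to the target is positive
and at least `min_similarity` (default 0, i.e. any positive similarity, as
no principled cutoff exists for an opaque score). Ordering is by
descending similarity with lexicographic tie-breaks.

**Candidate pool** (`candidates.collect_candidates`). The pool is the
union of the similar diseases' gene sets plus the target's own known genes
(positives are candidates whose label happens to be known; the
labeled/unlabeled bookkeeping — pool minus labeled equals scored set —
requires them in the pool). `entry_count` counts (disease, gene)
memberships among similar diseases, so it exceeds the unique count
whenever diseases share genes.

**Edge lengths** (`features.edge_length`). Functional-network weights
encode interaction *strength* (unitless, higher = stronger), while
Dijkstra needs *lengths*. The default transform is `identity` (length =
stated weight); `reciprocal` (1/w), `neg_log` (−ln w, requires w < 1) and
`one_minus` (1 − w, requires w < 1) are offered for networks whose weights
should be inverted. The choice is the user's: weight semantics differ
between resources and silently "fixing" them would be worse than exposing
the option.

**Shortest paths** (`features.dijkstra`). Label-setting Dijkstra with a
binary heap, implemented in the package because deterministic behaviour is
part of the contract: frontier ties are settled in lexicographic gene-id
order and equal-length alternative paths keep the first-found predecessor,
so distance maps and predecessor trees are bit-identical across runs and
platforms. Correctness is checked in the tests against exhaustive
simple-path enumeration on small random graphs and against an independent
graph-library implementation.

**Features** (`features.build_feature_matrix`). One column per similar
disease (the target has no column — its distances would encode the label
and leak it). The entry for gene *g* and disease *D* is the minimum
Dijkstra distance from *g* to *D*'s genes, or the membership value
(default 1.0) when *g* itself belongs to *D*. The 1.0 convention treats
direct association like a unit-strength interaction; note it is *not* 0,
although a gene is at distance 0 from itself — the two conventions
conflict, and `membership_value=0` is available for users who prefer
consistency with the distance scale. Unreachable entries are imputed per
column as 1.5 × the largest finite value in that column: farther than
anything observed, but finite, so z-scoring stays defined. Candidate genes
absent from the network get sentinel rows (logged, not an error).
Normalization uses the sample standard deviation (ddof = 1);
zero-variance columns map to zeros rather than NaN. Rows are sorted by
gene id, making the matrix invariant to input order.

**LS-SVM** (`lssvm`). Training solves the (n+1)×(n+1) symmetric system
given in the README with one LU factorisation plus one step of iterative
refinement. No jitter is added silently: a relative residual above 1e−8,
or a non-finite solution, raises a singular-system error that suggests
reducing γ (which enlarges the stabilising I/(2γ) diagonal). Defaults:
γ = 1.0 (unitless risk weight; no value is canonical for this task) and
σ = the median pairwise Euclidean distance of the training rows (the
standard median heuristic; on z-scored features this adapts to the number
of dimensions). When σ is left automatic during cross-validation it is
recomputed on each training split. The decision score is a margin-style
quantity, not a calibrated probability, and is documented as such.

**Cross-validation** (`evaluate`). Plain random folds (sizes differing by
at most one) match the usual protocol; a `stratified` option deals folds
round-robin within each class, because with tens of labeled genes plain
random 10-fold splits regularly produce one-class folds, which are
rejected with an explicit error rather than silently skipped. Held-out
scores are pooled into a single curve per run (one ROC, one PR) rather
than averaging per-fold areas. AUC is the Mann–Whitney statistic with
ties credited ½, computed from midranks; the plotted ROC increments TP
and FP simultaneously at tied thresholds so its trapezoidal area equals
the rank AUC exactly. AUPR is step-wise average precision,
Σ (Rᵢ − Rᵢ₋₁)·Pᵢ over distinct thresholds, anchored at (0, 1);
trapezoidal interpolation in PR space is deliberately avoided because it
is optimistic.

**Final model and ranking** (`predict`). Negatives are sampled without
replacement from the unlabeled pool, balanced with the positives
(capped at the pool size minus one when the pool is smaller — sparse
similarity tables can produce tiny pools). Unlabeled candidates are
ranked by decision score, descending, ties lexicographic; the nomination
threshold defaults to 0 (the class boundary) and is reported in the
output metadata. `nomination_frequencies` optionally repeats
sampling + training to quantify how sensitive nominations are to the
arbitrary negative sample.

## Synthetic benchmark

`synthetic.generate` emits the three input files with planted structure:
a planted-partition network (`n_modules` = 4 modules of
`genes_per_module` = 50 genes; edge probabilities `p_within` = 0.3 inside
and `p_between` = 0.02 across modules; weights uniform on [0.1, 1]), and
`n_diseases` = 8 diseases of `genes_per_disease` = 25 genes, each drawing
1 − `leak_fraction` = 90% of its genes from one module (diseases cycle
over modules, so the target's module is shared with one other disease).
Disease similarity is the Jaccard overlap of the emitted gene sets — a
monotone relatedness signal standing in for ontology-based scores.
`holdout_fraction` = 20% of the target's genes are withheld from the
association table (but kept in the network) as the "novel" genes a
prioritizer should recover. Networks whose largest connected component
holds under 90% of genes are regenerated with an incremented seed (at most
10 attempts); the check is waived when `p_between` = 0, where disconnected
modules are the declared intent. All emitted files are byte-deterministic
in (config, seed).

What the generator does *not* emulate: heavy-tailed degree distributions
of real interactomes, evidence-weighted association scores, disease
ontology structure (similarity here is purely gene-set overlap), and
identifier noise. Passing benchmark tests therefore demonstrates that the
pipeline recovers planted modular signal, not that it reproduces results
on any particular real catalogue.

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
benchmark (200 genes, ~1,800 edges, 8 diseases) across five generator
seeds, with 10-fold cross-validation on ~40 labeled genes per run; each
end-to-end run takes well under a second, and the whole suite a few
seconds. These sizes were chosen so the planted structure is comfortably
above the noise floor while every oracle comparison (exhaustive path
enumeration, pair counting) stays exact.

## Limitations

* **Negative contamination bounds the measurable AUC.** On the default
  benchmark roughly a third of the candidate pool consists of
  target-module genes, so a balanced negative sample contains several
  genes that are statistically identical to positives. No classifier can
  rank those below genuine positives, which caps the pooled CV AUC
  around the mid-0.8s on this benchmark — a property of the
  positive–unlabeled protocol, not of the classifier. The acceptance
  script's label-shuffled null (≈ 0.5) separates this ceiling from
  chance performance.
* **Held-out genes can only be recovered if some similar disease also
  lists them.** Held-out target genes enter the scored pool only through
  the gene sets of similar diseases; the acceptance script reports this
  pool coverage alongside the recovery rate.
* **The membership convention (1.0) sits in the middle of the distance
  scale**, which blurs the most informative feature column whenever
  distances are typically below 1; `membership_value` is configurable.
* The dense KKT solve is O(n³) in the number of labeled genes — fine for
  thousands, not for millions.
* Decision scores are uncalibrated; the default nomination threshold of 0
  is a convention, not an estimate of any error rate.
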