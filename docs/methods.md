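# Methods

## Model

The package predicts missing gene–phenotype links in a heterogeneous
knowledge graph. The graph is undirected and bipartite by construction:
every edge joins a gene (upper-cased HGNC-style symbol) to a feature node —
a GO term, pathway, disease, or an interaction partner. Feature nodes carry
a *class* label; the class is the unit that receives one feature-matrix
column and one learned weight. Gene–gene relations (protein interactions
mapped to genes) are folded into this shape by mirroring: each partner also
appears as a class-qualified feature node (`PPI:SYMBOL`), so a gene's
adjacency within the PPI class counts its partners exactly once and the
gene/feature namespaces stay disjoint.

Training is a two-stage filter-then-weight scheme:

1. *Predictor selection.* A feature with K adjacent genes, k of them among
   the n seeds in an N-gene universe, gets the one-sided hypergeometric
   upper-tail p-value P(X ≥ k). Features with k = 0 are not tested — their
   p is 1 by construction and testing them would only dilute the FDR family.
   BH step-up at q (default 0.05) across all tested features jointly selects
   the predictors; per-class correction is available behind a flag.
2. *Scoring.* x₍gc₎ = number of class-c predictors adjacent to gene g;
   min–max scaling per column (constant columns map to zero — they carry no
   ranking information); score s(g) = Σ_c w_c x₍gc₎ with w on the unit
   simplex. The weight/threshold pair maximises Youden's J with seeds as
   positives and **all** other genes as negatives (the unlabeled-as-negative
   assumption; it biases specificity upward in absolute terms but leaves the
   ranking objective well-defined).

The target phenotype's own disease–gene node is excluded from predictor
candidates whenever the seeds come with phenotype labels: its adjacency
*defines* the seed set, so it would be a trivially perfect predictor that
scores exactly the training seeds and generalizes to nothing, and it would
silently dominate the learned weights. Disease nodes of *other* phenotypes
remain legitimate features. With a bare gene list no such node can be
identified; if the list coincides with some disease node's neighbourhood,
that node will dominate — supply the phenotype to avoid this.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fdr_q` | 0.05 | BH level for predictor selection (and temporal FDR) |
| `step` | 0.1 | simplex resolution of the weight search |
| `grid_max_columns` | 4 | exhaustive grid up to this many classes, coordinate ascent beyond |
| `n_folds` | 0 (off), ≤ 5 | cross-validation folds; each fold retrains everything, so cost scales ≈ N |
| CV `alpha` | 0.05 | per-fold held-out enrichment significance, uncorrected across folds |

Weight search: with d ≤ 4 classes the full simplex grid at step 0.1
(e.g. 66 vectors for d = 3) is enumerated; ordering puts weight on leading
columns first, so exact ties resolve deterministically toward sparser
leading-column solutions. With d > 4, deterministic unit-transfer coordinate
ascent starts from the (near-)uniform integer allocation and accepts the
best strictly-improving single transfer until a fixed point; it can stop in
a local optimum, which is the price of determinism at higher dimension.
Threshold candidates are the distinct scores plus midpoints of consecutive
distinct scores; ties in J break toward the lowest threshold (favouring
sensitivity, the natural choice for prioritization). Predictions use
score ≥ threshold; seed genes are always labelled `known` regardless of
score.

## Evaluation protocols

*Cross-validation* (N ≤ 5, balanced random partition, deterministic given
the seed) retrains predictor selection, matrix, scaling, weights and
threshold on the retained seeds only — the leakage-free reading; reusing
predictors across folds would be faster but lets held-out genes influence
their own features. Metrics treat held-out seeds as the only positives and
exclude training seeds from the population; the held-out enrichment universe
likewise excludes training seeds (they are neither discoverable nor held
out). A fold whose training fails (no predictors) is recorded as failed,
never dropped. The report's pass rule is ≥ 3 significant folds when N = 5,
strict majority otherwise.

*Temporal hold-out*: per disease, train on the genes linked to it in the old
graph, predict, and test enrichment of the newly associated genes (those
added after the cutoff and present in the old graph, minus training seeds)
against the background of **all** genes in the old graph; BH across diseases
at 5%. A disease has *sufficient power* when the minimal achievable p (at
maximal possible overlap) is below the realized post-FDR cut — with few
predictable genes even a perfect prediction cannot reach significance, and
the summary separates that stratum, as well as the training-J ≥ 0.9 stratum.

## Synthetic data

The generator plants ground truth in the simplest analyzable family: each
of a handful of *planted* features per class connects to every seed gene
with probability `p_in` and to every non-seed with `p_out`; *decoy* features
connect to all genes with `p_out`; all edges are independent Bernoulli
draws. Defaults — 200 genes, 20 seeds, 3 classes × (2 planted + 20 decoy),
p_in = 0.8, p_out = 0.05 — define the recovery benchmark used by the tests
and the acceptance script. `p_in = p_out` gives the signal-free null;
`p_in = 1, p_out = 0` the noiseless extreme with analytically exact
recovery. The temporal mode splits the true seeds at a simulated cutoff,
keeping planted edges for both halves but disease–gene edges only for the
pre-cutoff half.

What this emulates — and does not: real knowledge graphs have heavy-tailed
degree distributions, a GO term hierarchy (nested, strongly correlated
features), database-specific biases and literature-driven coupling between
a disease's seeds and its best-studied features. None of that is modelled.
Passing the recovery and calibration benchmarks shows the machinery is
correct and calibrated on independent-edge graphs; it does not certify
performance on real GO/PPI/DisGeNet topologies.

## Numerical and design choices

- Hypergeometric tail via the scipy survival function; exact 1.0 returned
  at k = 0 and K = N. BH via statsmodels (`fdr_bh`), adjusted values by the
  standard monotone min-transform. AUROC is the tie-aware rank statistic.
- The acceptance/test oracles recompute all of these independently (subset
  enumeration, literal step-up, pairwise concordance, exhaustive scan).
- Scaling parameters are stored with the model; new genes scale with the
  training min/max and clip to [0, 1], so a value at the training maximum
  maps to 1 exactly. Scores are invariant to uniformly doubling all raw
  counts — only relative scores within one model are meaningful.
- Edge identity is (gene, target, relation); sources accumulate in a set.
  Edges carried by several sources split their unit weight equally across
  sources in contribution reports.
- Multiple input phenotypes are unioned (not intersected) when resolving
  seeds; user-supplied associations *replace* the graph's disease–gene
  edges for the listed phenotypes before seed extraction.
- Rows with missing cells in edge tables are skipped and counted, not
  fatal; duplicate rows collapse. HGNC validity is not verifiable offline,
  so symbol normalization is limited to upper-casing and whitespace
  stripping.
- Determinism: all randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give
  byte-identical CSV outputs, and the job id is a content hash of inputs
  plus configuration.

## Null calibration and its conservatism

The held-out enrichment p-value is discrete. Under the null (an
uninformative model: i.i.d. random gene scores, threshold learned on the
training seeds exactly as in a real fold), the probability of p < α equals
the largest achievable tail value below α — strictly less than α, and for
tail distributions whose support near α is roughly geometric, on the order
of half of it, independent of graph size. The calibration experiment
(`null_fold_calibration`, 500 genes, 100 seeds, 5 folds) therefore measures
a slightly conservative rate — the test is valid (never anti-conservative)
but a rate statistically indistinguishable from α should not be expected at
small set sizes. Full-pipeline nulls (`p_in = p_out` graphs) are even more
conservative: BH correctly leaves ~96% of folds with no predictors at all,
and the few that train carry tiny prediction sets.

## Problem sizes used in tests and the acceptance script

Benchmarks run 30–50 replicates of the default 200-gene configuration, 200+
null fold-replicates at the 500-gene calibration size, and 60–100 temporal
replicates; kernel oracles enumerate all hypergeometric parameter
combinations with N ≤ 12 and 1000 random BH vectors. These sizes were
chosen so each estimate's Monte-Carlo error is small relative to the margin
it is compared against while a full run stays in the minutes range on one
core.

## Known limitations

- Unlabeled-as-negative training misestimates specificity when many true
  disease genes are unlabeled; scores are rankings, not probabilities.
- Per-class (not per-feature) weights: a class with one superb and many
  weak predictors cannot up-weight the superb one individually.
- Coordinate ascent beyond 4 classes is greedy and may miss the global
  optimum reachable by the exhaustive grid.
- Genes with zero predictor adjacency score exactly 0 and can never be
  predicted at any positive threshold.
- The gene-set enrichment universe (graph genes ∩ library coverage) will
  not numerically match services that use a different background.
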