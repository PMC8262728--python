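"""Model evaluation: cross-validation, ranking metrics, temporal hold-out.

Because complete true-negative sets do not exist for most diseases, headline
evaluation is enrichment-based: are the genes a model predicts significantly
over-represented for genes that were in fact associated later (temporal
hold-out) or held out of training (cross-validation)? The test is the same
hypergeometric upper tail used for predictor selection, with the gene
universe of the knowledge graph as background. Classic metrics (accuracy, F1,
AUROC) are reported alongside for each fold.

Cross-validation retrains the full pipeline — predictor selection, feature
matrix, weights and threshold — on the retained seeds of each fold, the
leakage-free reading of per-fold retraining. In the held-out enrichment, the
universe excludes the training seeds: they are neither discoverable nor held
out, and leaving them in would contaminate the background with guaranteed
positives. In the temporal evaluation the background is the full gene
universe of the old graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .enrichment import EnrichmentTest, bh_fdr, hypergeom_upper_tail
from .exceptions import (
    ConfigurationError,
    DomainError,
    MetricUndefinedError,
    TrainingError,
)
from .graph import KnowledgeGraph, SeedSet, normalize_gene_symbol
from .model import GenePrioritizer

MAX_FOLDS = 5  # the cross-validation contract caps N at 5


@dataclass(frozen=True)
class FoldResult:
    fold: int
    held_out: tuple[str, ...]
    accuracy: float = float("nan")
    f1: float = float("nan")
    auroc: float = float("nan")
    enrichment_p: float = float("nan")
    significant: bool = False
    failed: bool = False
    training_j: float = float("nan")
    n_predicted: int = 0


@dataclass(frozen=True)
class ValidationReport:
    folds: tuple[FoldResult, ...]
    n_folds: int
    alpha: float

    @property
    def n_significant_folds(self) -> int:
        return sum(f.significant for f in self.folds)

    @property
    def passed(self) -> bool:
        """Significant held-out enrichment in at least 3 folds (5-fold rule);
        for other fold counts, in a strict majority."""
        need = 3 if self.n_folds == 5 else self.n_folds // 2 + 1
        return self.n_significant_folds >= need

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    f.fold,
                    len(f.held_out),
                    f.accuracy,
                    f.f1,
                    f.auroc,
                    f.enrichment_p,
                    f.significant,
                    f.failed,
                    f.training_j,
                    f.n_predicted,
                )
                for f in self.folds
            ],
            columns=[
                "fold",
                "n_heldout",
                "accuracy",
                "f1",
                "auroc",
                "enrichment_p",
                "significant",
                "failed",
                "training_j",
                "n_predicted",
            ],
        )


def kfold_split(
    seeds: SeedSet | Iterable[str], n_folds: int, rng_seed: int = 0
) -> list[frozenset[str]]:
    """Random balanced partition of the seed genes into ``n_folds`` subsets."""
    genes = sorted(seeds.genes if isinstance(seeds, SeedSet) else set(seeds))
    if not 2 <= n_folds <= MAX_FOLDS:
        raise ConfigurationError(f"n_folds must be in [2, {MAX_FOLDS}], got {n_folds}")
    if len(genes) < n_folds:
        raise ConfigurationError(
            f"{len(genes)} seeds cannot be split into {n_folds} folds"
        )
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(genes))
    folds: list[frozenset[str]] = []
    for i in range(n_folds):
        folds.append(frozenset(genes[j] for j in perm[i::n_folds]))
    return folds


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative; ties 1/2."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise MetricUndefinedError("AUROC needs both classes")
    return float(roc_auc_score(y.astype(int), s))


def accuracy_f1(predicted_flags, labels) -> tuple[float, float]:
    """Plain accuracy and F1 (0 when precision + recall is 0)."""
    y = np.asarray(labels, dtype=bool).astype(int)
    yhat = np.asarray(predicted_flags, dtype=bool).astype(int)
    if y.shape != yhat.shape:
        raise DomainError("label vectors differ in length")
    return float(accuracy_score(y, yhat)), float(f1_score(y, yhat, zero_division=0))


def prediction_enrichment(
    predicted: Iterable[str], target_set: Iterable[str], universe: Iterable[str]
) -> EnrichmentTest:
    """Hypergeometric over-representation of a target gene set among predictions."""
    universe = frozenset(universe)
    if not universe:
        raise DomainError("empty universe")
    predicted = frozenset(predicted)
    target = frozenset(target_set)
    if not predicted <= universe or not target <= universe:
        raise DomainError("predicted and target sets must lie within the universe")
    k = len(predicted & target)
    p = hypergeom_upper_tail(k, len(target), len(predicted), len(universe))
    return EnrichmentTest(
        feature="predictions",
        feature_class="evaluation",
        k=k,
        K=len(target),
        n=len(predicted),
        N=len(universe),
        p=p,
    )


def cross_validate(
    kg: KnowledgeGraph,
    seeds: SeedSet | frozenset[str],
    n_folds: int = 5,
    fdr_q: float = 0.05,
    step: float = 0.1,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> ValidationReport:
    """N-fold cross-validation of the full pipeline (N <= 5).

    Each fold retrains predictor selection, feature matrix, weights and
    threshold on the retained seeds, then evaluates on the held-out seeds:
    accuracy/F1/AUROC with the held-out seeds as the only positives and
    non-seed genes as negatives (training seeds excluded from the metric
    population), and the hypergeometric enrichment of held-out genes among
    the fold's predictions, significant at ``alpha`` per fold.
    """
    if isinstance(seeds, SeedSet):
        seed_genes = seeds.genes
        exclude = tuple(seeds.phenotypes)  # the target's own DG node defines the seeds
    else:
        seed_genes = frozenset(seeds)
        exclude = ()
    folds = kfold_split(seed_genes, n_folds, rng_seed)
    results: list[FoldResult] = []
    for i, held_out in enumerate(folds):
        train = seed_genes - held_out
        try:
            pipe = GenePrioritizer(fdr_q=fdr_q, step=step, exclude_features=exclude).fit(
                kg, train
            )
        except TrainingError:
            results.append(FoldResult(fold=i, held_out=tuple(sorted(held_out)), failed=True))
            continue
        table = pipe.predict_table()
        eval_rows = table[~table["gene"].isin(train)]
        y = eval_rows["gene"].isin(held_out).to_numpy()
        yhat = (eval_rows["label"] == "predicted").to_numpy()
        acc, f1 = accuracy_f1(yhat, y)
        try:
            auc = auroc(eval_rows["score"].to_numpy(), y)
        except MetricUndefinedError:
            auc = float("nan")
        universe = kg.genes - train
        predicted = frozenset(eval_rows.loc[yhat, "gene"])
        test = prediction_enrichment(predicted, held_out, universe)
        results.append(
            FoldResult(
                fold=i,
                held_out=tuple(sorted(held_out)),
                accuracy=acc,
                f1=f1,
                auroc=auc,
                enrichment_p=test.p,
                significant=test.p < alpha,
                training_j=pipe.training_j_,
                n_predicted=len(predicted),
            )
        )
    return ValidationReport(folds=tuple(results), n_folds=n_folds, alpha=alpha)


def null_fold_calibration(
    n_genes: int = 500,
    n_seeds: int = 100,
    n_folds: int = 5,
    n_replicates: int = 40,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> tuple[float, int]:
    """Significance rate of the held-out enrichment under an uninformative model.

    Per replicate, every gene receives an i.i.d. random score (the signal-free
    case: the model knows nothing), the threshold is learned on the training
    seeds exactly as in a real fold, and the held-out enrichment p-value is
    computed for each of ``n_folds`` folds. Returns the fraction of
    fold-replicates significant at ``alpha`` and the number of folds run.

    The hypergeometric p-value is discrete, so the rate sits at the largest
    achievable p below ``alpha`` — slightly conservative. The default sizes
    keep the held-out sets large enough (n_seeds/n_folds = 20) for that
    granularity to be fine near 0.05; tiny held-out sets would make the rate
    collapse toward zero.
    """
    from .model import best_threshold

    rng = np.random.default_rng(rng_seed)
    significant = 0
    ran = 0
    genes = np.arange(n_genes)
    for _ in range(n_replicates):
        seed_idx = rng.choice(n_genes, n_seeds, replace=False)
        scores = rng.random(n_genes)
        folds = [seed_idx[i::n_folds] for i in range(n_folds)]
        for held in folds:
            train = np.setdiff1d(seed_idx, held)
            y = np.isin(genes, train)
            thr, _ = best_threshold(scores, y)
            mask = ~np.isin(genes, train)
            predicted = genes[mask & (scores >= thr)]
            p = hypergeom_upper_tail(
                int(np.isin(predicted, held).sum()),
                len(held),
                len(predicted),
                int(mask.sum()),
            )
            ran += 1
            significant += p < alpha
    return significant / ran, ran


# ---------------------------------------------------------------------------
# temporal hold-out


@dataclass(frozen=True)
class TemporalEvaluation:
    disease: str
    n_seeds: int
    trainable: bool
    new_genes: tuple[str, ...]  # post-cutoff additions (normalized)
    new_in_kg: tuple[str, ...]  # ... restricted to the old gene universe
    n_predicted: int = 0
    universe_size: int = 0
    overlap: int = 0
    p: float = float("nan")
    q: float = float("nan")
    significant: bool = False
    sufficient_power: bool = False
    training_j: float = float("nan")


@dataclass(frozen=True)
class TemporalSummary:
    n_diseases: int
    n_with_new_in_kg: int
    n_trainable: int
    n_evaluated: int
    n_significant: int
    n_sufficient_power: int
    n_significant_sufficient_power: int
    n_high_j: int  # training J >= 0.9
    n_significant_high_j: int
    median_new_genes: float
    iqr_new_genes: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def temporal_evaluate(
    kg_old: KnowledgeGraph,
    dg_new: Sequence[tuple[str, str]],
    diseases: Sequence[str] | None = None,
    dg_class: str = "DG",
    fdr_q: float = 0.05,
    step: float = 0.1,
    high_j: float = 0.9,
) -> tuple[list[TemporalEvaluation], TemporalSummary]:
    """Prospective-style validation on a temporal split of disease-gene data.

    For each disease: train on the genes it is linked to in the old graph,
    predict, and test the predictions for enrichment of the disease's newly
    associated genes (those added after the cutoff) against the background of
    all genes in the old graph. Diseases whose new genes are all absent from
    the graph are excluded from the enrichment (counted in the summary);
    p-values are BH-corrected across the evaluated diseases. A disease has
    "sufficient power" when even a maximal overlap could reach the realized
    post-FDR significance cut.
    """
    pairs = [(str(d).strip(), normalize_gene_symbol(g)) for d, g in dg_new]
    by_disease: dict[str, set[str]] = {}
    for d, g in pairs:
        if d and g:
            by_disease.setdefault(d, set()).add(g)
    if diseases is None:
        diseases = sorted(by_disease)

    universe = kg_old.genes
    N = len(universe)
    evals: list[TemporalEvaluation] = []
    for disease in diseases:
        new_genes = tuple(sorted(by_disease.get(disease, set())))
        old_seeds = (
            kg_old.neighbors(disease) if disease in kg_old.feature_ids else frozenset()
        )
        new_in_kg = tuple(sorted((set(new_genes) & universe) - old_seeds))
        if len(old_seeds) < 2:
            evals.append(
                TemporalEvaluation(
                    disease, len(old_seeds), False, new_genes, new_in_kg
                )
            )
            continue
        try:
            pipe = GenePrioritizer(
                fdr_q=fdr_q, step=step, exclude_features=(disease,)
            ).fit(kg_old, old_seeds)
        except TrainingError:
            evals.append(
                TemporalEvaluation(
                    disease, len(old_seeds), False, new_genes, new_in_kg
                )
            )
            continue
        predicted = pipe.predicted_genes()
        if not new_in_kg:
            evals.append(
                TemporalEvaluation(
                    disease,
                    len(old_seeds),
                    True,
                    new_genes,
                    new_in_kg,
                    n_predicted=len(predicted),
                    universe_size=N,
                    training_j=pipe.training_j_,
                )
            )
            continue
        test = prediction_enrichment(predicted, frozenset(new_in_kg), universe)
        evals.append(
            TemporalEvaluation(
                disease,
                len(old_seeds),
                True,
                new_genes,
                new_in_kg,
                n_predicted=len(predicted),
                universe_size=N,
                overlap=test.k,
                p=test.p,
                training_j=pipe.training_j_,
            )
        )

    # BH across the diseases that produced a p-value
    idx = [i for i, e in enumerate(evals) if not np.isnan(e.p)]
    if idx:
        q_adj, rejected = bh_fdr([evals[i].p for i in idx], fdr_q)
        # realized post-FDR cut: the largest rejected raw p (or the smallest
        # BH step threshold when nothing is rejected)
        rejected_ps = [evals[i].p for i, r in zip(idx, rejected) if r]
        power_cut = max(rejected_ps) if rejected_ps else fdr_q / len(idx)
        for pos, i in enumerate(idx):
            e = evals[i]
            evals[i] = TemporalEvaluation(
                e.disease,
                e.n_seeds,
                e.trainable,
                e.new_genes,
                e.new_in_kg,
                n_predicted=e.n_predicted,
                universe_size=e.universe_size,
                overlap=e.overlap,
                p=e.p,
                q=q_adj[pos],
                significant=bool(rejected[pos]),
                sufficient_power=_sufficient_power(e, power_cut),
                training_j=e.training_j,
            )

    evaluated = [e for e in evals if not np.isnan(e.p)]
    new_counts = [len(e.new_genes) for e in evals if e.new_genes]
    summary = TemporalSummary(
        n_diseases=len(evals),
        n_with_new_in_kg=sum(bool(e.new_in_kg) for e in evals),
        n_trainable=sum(e.trainable for e in evals),
        n_evaluated=len(evaluated),
        n_significant=sum(e.significant for e in evaluated),
        n_sufficient_power=sum(e.sufficient_power for e in evaluated),
        n_significant_sufficient_power=sum(
            e.significant for e in evaluated if e.sufficient_power
        ),
        n_high_j=sum(e.training_j >= high_j for e in evaluated),
        n_significant_high_j=sum(
            e.significant for e in evaluated if e.training_j >= high_j
        ),
        median_new_genes=float(np.median(new_counts)) if new_counts else float("nan"),
        iqr_new_genes=(
            float(np.percentile(new_counts, 75) - np.percentile(new_counts, 25))
            if new_counts
            else float("nan")
        ),
    )
    return evals, summary


def _sufficient_power(e: TemporalEvaluation, power_cut: float) -> bool:
    """Could even a perfect overlap have reached the significance cut?"""
    k_best = min(len(e.new_in_kg), e.n_predicted)
    if k_best == 0:
        return False
    p_best = hypergeom_upper_tail(
        k_best, len(e.new_in_kg), e.n_predicted, e.universe_size
    )
    return p_best <= power_cut


def temporal_frame(evals: Sequence[TemporalEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.disease,
                e.n_seeds,
                e.trainable,
                len(e.new_genes),
                len(e.new_in_kg),
                e.n_predicted,
                e.overlap,
                e.universe_size,
                e.p,
                e.q,
                e.significant,
                e.sufficient_power,
                e.training_j,
            )
            for e in evals
        ],
        columns=[
            "disease",
            "n_seeds",
            "trainable",
            "n_new",
            "n_new_in_kg",
            "n_predicted",
            "overlap",
            "universe",
            "p",
            "q",
            "significant",
            "sufficient_power",
            "training_j",
        ],
    )
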