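"""Similarity scoring model: adjacency features, learned weights, threshold.

Every gene is summarised by one count per feature class: how many of that
class's predictor features it is adjacent to. Counts are min-max scaled per
class to [0, 1] and combined into a score ``s(g) = sum_c w_c * x_gc`` with
non-negative weights summing to one — the gene's similarity to the profile of
the known disease genes. Weights and the decision threshold are learned by
maximising Youden's J statistic (sensitivity + specificity - 1) with the seed
genes as positives and every other gene in the graph as negatives.

The weight search is an exhaustive simplex grid with step 0.1 when there are
at most four classes, and deterministic coordinate ascent from the uniform
vector (same step) otherwise. Both are reproducible and make the learned
weights directly interpretable as per-class contribution bounds.

:class:`WeightedProfileClassifier` is the scikit-learn estimator over a
plain gene-by-class count matrix; :class:`GenePrioritizer` wraps the whole
graph pipeline (predictor selection -> matrix -> fit -> ranked predictions).
Module-level functions (`fit_model`, `score_and_predict`, ...) are thin
wrappers kept for script use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .enrichment import PredictorSet, find_predictors
from .exceptions import KgprioError, MetricUndefinedError, TrainingError
from .graph import KnowledgeGraph, SeedSet


# ---------------------------------------------------------------------------
# feature matrix and scaling


def build_feature_matrix(kg: KnowledgeGraph, predictors: PredictorSet) -> pd.DataFrame:
    """Gene-by-class matrix of predictor adjacency counts.

    Entry (g, c) is the number of class-c predictor features adjacent to gene
    g. Rows cover the full gene universe; columns are exactly the classes
    holding at least one predictor.
    """
    if predictors.empty:
        raise TrainingError(
            "no predictor features survived enrichment; "
            "adjust the selection of databases and input genes"
        )
    genes = sorted(kg.genes)
    classes = list(predictors.classes)
    mat = np.zeros((len(genes), len(classes)), dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, cls in enumerate(classes):
        for feature in predictors.predictors_by_class[cls]:
            for g in kg.neighbors(feature):
                mat[gene_index[g], j] += 1
    return pd.DataFrame(mat, index=genes, columns=classes)


@dataclass(frozen=True)
class ScalingParams:
    """Per-column min/max retained so new genes scale identically."""

    col_min: pd.Series
    col_max: pd.Series

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        span = (self.col_max - self.col_min).replace(0, np.nan)
        scaled = (matrix - self.col_min) / span
        return scaled.fillna(0.0).clip(0.0, 1.0)


def scale_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Min-max scale each column to [0, 1]; constant columns map to zeros."""
    if matrix.empty:
        raise TrainingError("cannot scale an empty feature matrix")
    params = ScalingParams(matrix.min(axis=0).astype(float), matrix.max(axis=0).astype(float))
    return params.transform(matrix), params


# ---------------------------------------------------------------------------
# J statistic and threshold search


def youden_j(true_labels, predicted_flags) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    y = np.asarray(true_labels, dtype=bool)
    yhat = np.asarray(predicted_flags, dtype=bool)
    if y.shape != yhat.shape:
        raise KgprioError("label vectors differ in length")
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise MetricUndefinedError("J needs at least one positive and one negative")
    sens = int((y & yhat).sum()) / pos
    spec = int((~y & ~yhat).sum()) / neg
    return sens + spec - 1.0


def best_threshold(scores, labels) -> tuple[float, float]:
    """Threshold on the score (predict positive at score >= t) maximising J.

    Candidates are the midpoints of consecutive distinct sorted scores plus
    the extreme scores themselves; ties go to the lowest threshold (favoring
    sensitivity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise KgprioError("scores and labels differ in length")
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise MetricUndefinedError("threshold search needs both classes")

    distinct = np.unique(s)
    candidates = [distinct[0]]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    if distinct.size > 1:
        candidates.append(distinct[-1])

    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = s >= t
        sens = int((y & pred).sum()) / pos
        spec = int((~y & ~pred).sum()) / neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


# ---------------------------------------------------------------------------
# weight search


def simplex_grid(n_cols: int, step: float = 0.1):
    """All non-negative weight vectors with the given step summing to 1.

    Ordered with earlier columns taking larger weights first, so ties during
    the search resolve toward sparser weight on the leading columns.
    """
    units = round(1.0 / step)

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total, -1, -1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for comp in compositions(units, n_cols):
        yield tuple(c / units for c in comp)


def _evaluate_weights(weights: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    scores = X @ weights
    return best_threshold(scores, y)


def _coordinate_ascent(X: np.ndarray, y: np.ndarray, step: float) -> tuple[np.ndarray, float, float]:
    """Deterministic unit-transfer ascent on the simplex from the uniform vector."""
    d = X.shape[1]
    units = round(1.0 / step)
    w_units = np.full(d, units // d, dtype=int)
    for i in range(units - w_units.sum()):
        w_units[i] += 1
    current = w_units / units
    thr, j = _evaluate_weights(current, X, y)
    improved = True
    while improved:
        improved = False
        best_move = None
        for i, k in itertools.product(range(d), range(d)):
            if i == k or w_units[i] == 0:
                continue
            trial = w_units.copy()
            trial[i] -= 1
            trial[k] += 1
            t_thr, t_j = _evaluate_weights(trial / units, X, y)
            if t_j > j + 1e-12 and (best_move is None or t_j > best_move[0] + 1e-12):
                best_move = (t_j, t_thr, trial)
        if best_move is not None:
            j, thr, w_units = best_move
            improved = True
    return w_units / units, thr, j


class WeightedProfileClassifier(ClassifierMixin, BaseEstimator):
    """Weighted-adjacency similarity classifier over a gene-by-class matrix.

    Parameters
    ----------
    step : float, default 0.1
        Resolution of the weight search on the simplex.
    grid_max_columns : int, default 4
        Up to this many columns the simplex grid is enumerated exhaustively;
        beyond it, coordinate ascent from the uniform vector is used.

    Attributes
    ----------
    weights_ : ndarray of shape (n_classes,)
        Learned non-negative per-class weights, summing to 1.
    threshold_ : float
        Score cut-off; genes scoring at or above it are predicted positive.
    training_j_ : float
        Youden's J achieved on the training genes.
    scaling_ : ScalingParams
        Per-column min/max of the raw training counts.
    columns_ : list
        Feature-class column labels seen in fit.
    """

    def __init__(self, step: float = 0.1, grid_max_columns: int = 4):
        self.step = step
        self.grid_max_columns = grid_max_columns

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(bool)
        if X.shape[0] != y.shape[0]:
            raise KgprioError("X and y differ in length")
        if X.shape[1] == 0:
            raise TrainingError("feature matrix has no columns")
        if int(y.sum()) < 2:
            raise TrainingError("need at least two seed genes among the rows")
        if int((~y).sum()) < 1:
            raise TrainingError("need at least one non-seed gene among the rows")

        self.columns_ = list(X.columns)
        scaled, self.scaling_ = scale_features(X)
        Xs = scaled.to_numpy(dtype=float)

        d = Xs.shape[1]
        if d == 1:
            weights = np.array([1.0])
            thr, j = _evaluate_weights(weights, Xs, y)
        elif d <= self.grid_max_columns:
            best = None
            for cand in simplex_grid(d, self.step):
                w = np.asarray(cand)
                thr, j = _evaluate_weights(w, Xs, y)
                if best is None or j > best[0] + 1e-12:
                    best = (j, thr, w)
            j, thr, weights = best
        else:
            weights, thr, j = _coordinate_ascent(Xs, y, self.step)

        self.weights_ = weights
        self.threshold_ = float(thr)
        self.training_j_ = float(j)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns_:
            if set(X.columns) == set(self.columns_):
                return X[self.columns_]
            raise KgprioError(
                f"matrix columns {list(X.columns)} do not match model columns {self.columns_}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        X = self._check_columns(pd.DataFrame(X))
        scaled = self.scaling_.transform(X).to_numpy(dtype=float)
        return scaled @ self.weights_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# trained-model artifact and prediction tables


@dataclass(frozen=True)
class TrainedModel:
    """The learned profile: per-class weights, threshold, training J."""

    weights: pd.Series  # index = feature-class labels
    threshold: float
    training_j: float
    scaling: ScalingParams
    predictor_set: PredictorSet | None = None

    def __post_init__(self):
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-9:
            raise KgprioError(f"weights must sum to 1 (got {total})")

    @property
    def classes(self) -> list[str]:
        return list(self.weights.index)

    def scores(self, matrix: pd.DataFrame) -> pd.Series:
        if list(matrix.columns) != self.classes:
            if set(matrix.columns) == set(self.classes):
                matrix = matrix[self.classes]
            else:
                raise KgprioError(
                    f"matrix columns {list(matrix.columns)} incompatible with "
                    f"model classes {self.classes}"
                )
        scaled = self.scaling.transform(matrix)
        return (scaled * self.weights).sum(axis=1)

    @classmethod
    def from_estimator(
        cls, est: WeightedProfileClassifier, predictor_set: PredictorSet | None = None
    ) -> "TrainedModel":
        return cls(
            weights=pd.Series(est.weights_, index=est.columns_, dtype=float),
            threshold=est.threshold_,
            training_j=est.training_j_,
            scaling=est.scaling_,
            predictor_set=predictor_set,
        )

    # plain-text round-trip so a model can be re-applied to a new graph
    def to_text(self) -> str:
        lines = [f"threshold\t{self.threshold!r}", f"training_j\t{self.training_j!r}"]
        for cls_label in self.classes:
            lines.append(
                "class\t{}\t{!r}\t{!r}\t{!r}".format(
                    cls_label,
                    float(self.weights[cls_label]),
                    float(self.scaling.col_min[cls_label]),
                    float(self.scaling.col_max[cls_label]),
                )
            )
        if self.predictor_set is not None:
            for c in self.predictor_set.classes:
                for f in sorted(self.predictor_set.predictors_by_class[c]):
                    lines.append(f"predictor\t{c}\t{f}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "TrainedModel":
        threshold = training_j = None
        classes, weights, mins, maxs = [], [], [], []
        predictors: dict[str, set[str]] = {}
        for line in text.strip().splitlines():
            parts = line.split("\t")
            if parts[0] == "threshold":
                threshold = float(parts[1])
            elif parts[0] == "training_j":
                training_j = float(parts[1])
            elif parts[0] == "class":
                classes.append(parts[1])
                weights.append(float(parts[2]))
                mins.append(float(parts[3]))
                maxs.append(float(parts[4]))
            elif parts[0] == "predictor":
                predictors.setdefault(parts[1], set()).add(parts[2])
        if threshold is None or training_j is None or not classes:
            raise KgprioError("incomplete model file")
        pset = None
        if predictors:
            pset = PredictorSet(
                tests=(),
                q_threshold=float("nan"),
                predictors_by_class={c: frozenset(v) for c, v in predictors.items()},
            )
        return cls(
            weights=pd.Series(weights, index=classes, dtype=float),
            threshold=threshold,
            training_j=training_j,
            scaling=ScalingParams(
                pd.Series(mins, index=classes, dtype=float),
                pd.Series(maxs, index=classes, dtype=float),
            ),
            predictor_set=pset,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_text(Path(path).read_text())


def fit_model(
    scaled: pd.DataFrame,
    seeds: SeedSet | frozenset[str],
    step: float = 0.1,
    grid_max_columns: int = 4,
    predictor_set: PredictorSet | None = None,
) -> TrainedModel:
    """Learn weights and threshold from a (scaled or raw) feature matrix.

    Rows indexed by gene symbol; positives are the seed genes among the rows.
    """
    seed_genes = seeds.genes if isinstance(seeds, SeedSet) else frozenset(seeds)
    y = np.array([g in seed_genes for g in scaled.index])
    est = WeightedProfileClassifier(step=step, grid_max_columns=grid_max_columns).fit(scaled, y)
    return TrainedModel.from_estimator(est, predictor_set)


def score_and_predict(
    model: TrainedModel,
    matrix: pd.DataFrame,
    seeds: SeedSet | frozenset[str],
) -> pd.DataFrame:
    """Score, rank and label every gene.

    Returns a frame with columns ``rank, gene, score, label`` plus one
    ``contrib_<class>`` column per feature class; a gene is ``known`` when it
    is a seed (regardless of score), ``predicted`` when it is not a seed and
    scores at or above the threshold, ``negative`` otherwise. Sorted by score
    descending with ties broken by gene symbol.
    """
    seed_genes = seeds.genes if isinstance(seeds, SeedSet) else frozenset(seeds)
    scores = model.scores(matrix)
    scaled = model.scaling.transform(matrix[model.classes])
    contrib = scaled * model.weights
    total = contrib.sum(axis=1)
    frac = contrib.div(total.replace(0, np.nan), axis=0).fillna(0.0)

    df = pd.DataFrame({"gene": scores.index, "score": scores.to_numpy()})
    df["label"] = [
        "known" if g in seed_genes
        else ("predicted" if s >= model.threshold else "negative")
        for g, s in zip(df["gene"], df["score"])
    ]
    for cls_label in model.classes:
        df[f"contrib_{cls_label}"] = frac[cls_label].to_numpy()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


class GenePrioritizer(BaseEstimator):
    """End-to-end pipeline estimator: graph + seeds -> ranked candidate genes.

    ``fit`` runs predictor selection on the seed genes, builds the
    gene-by-class adjacency matrix, and trains the weighted-profile
    classifier. ``predict_table`` returns the ranked results table for the
    training graph (or, via ``transform``-style reuse, for a new graph scored
    against the stored predictors and scaling).
    """

    def __init__(
        self,
        fdr_q: float = 0.05,
        step: float = 0.1,
        grid_max_columns: int = 4,
        per_class_fdr: bool = False,
        exclude_features: tuple[str, ...] = (),
    ):
        self.fdr_q = fdr_q
        self.step = step
        self.grid_max_columns = grid_max_columns
        self.per_class_fdr = per_class_fdr
        self.exclude_features = exclude_features

    def fit(self, kg: KnowledgeGraph, seeds: SeedSet | frozenset[str]):
        excluded = set(self.exclude_features)
        if isinstance(seeds, SeedSet):
            excluded |= set(seeds.phenotypes)
            seed_genes = seeds.genes
        else:
            seed_genes = frozenset(seeds)
        self.seeds_ = frozenset(seed_genes)
        self.predictors_ = find_predictors(
            kg,
            seed_genes,
            q_threshold=self.fdr_q,
            per_class=self.per_class_fdr,
            exclude_features=excluded,
        )
        if self.predictors_.empty:
            raise TrainingError(
                "no predictor features found for these seeds; "
                "adjust the selection of databases and input genes"
            )
        self.matrix_ = build_feature_matrix(kg, self.predictors_)
        y = np.array([g in seed_genes for g in self.matrix_.index])
        self.estimator_ = WeightedProfileClassifier(
            step=self.step, grid_max_columns=self.grid_max_columns
        ).fit(self.matrix_, y)
        self.model_ = TrainedModel.from_estimator(self.estimator_, self.predictors_)
        self.training_j_ = self.estimator_.training_j_
        return self

    def predict_table(self, kg: KnowledgeGraph | None = None) -> pd.DataFrame:
        matrix = self.matrix_ if kg is None else build_feature_matrix(kg, self.predictors_)
        return score_and_predict(self.model_, matrix, self.seeds_)

    def predicted_genes(self, kg: KnowledgeGraph | None = None) -> frozenset[str]:
        table = self.predict_table(kg)
        return frozenset(table.loc[table["label"] == "predicted", "gene"])
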