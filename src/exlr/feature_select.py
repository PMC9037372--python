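"""mRMR(MIQ) gene ranking and incremental feature selection with LOOCV-SVM AUC.

Candidate genes are first three-state discretized per gene (below mu -
alpha*sigma, within, above mu + alpha*sigma over the training samples, the
classic mRMR preprocessing).  Ranking is greedy: the first gene maximizes
the mutual information I(f; class); each subsequent step maximizes the
mutual-information quotient

    MIQ(f) = I(f; class) / mean_{s in selected} I(f; f_s)

with the redundancy denominator floored at 1e-12 and ties broken by
gene_id.  Incremental feature selection then evaluates the top-k prefix for
k = 1..K with a support vector machine scored by leave-one-out
cross-validated AUC, and keeps the smallest k attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from exlr.core_data import DataError, ExpressionMatrix

REDUNDANCY_FLOOR = 1e-12


@dataclass(frozen=True)
class SVMParams:
    """SVM configuration: C-classification, per-fold z-scaling of features.

    Linear kernel with C=1 is the default for n << p gene panels; an RBF
    kernel (gamma = 1/n_features) is available.  ``class_weight="balanced"``
    applies inverse-frequency weights to mitigate case/control imbalance.
    """

    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "auto"  # 1/n_features, used by rbf only
    class_weight: str | None = "balanced"

    def make(self) -> SVC:
        return SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            class_weight=self.class_weight,
        )


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Genes x samples matrix coded into {-1, 0, +1} around mu +/- alpha*sigma."""

    values: pd.DataFrame
    alpha: float


@dataclass(frozen=True)
class MRMRRanking:
    """Greedy MIQ ranking: ordered genes, per-step score, per-gene relevance."""

    gene_ids: list[str]
    scores: list[float]
    relevance: dict[str, float]


@dataclass(frozen=True)
class IFSCurve:
    """LOOCV AUC of the top-k ranked prefix for k=1..K and the chosen k."""

    k: np.ndarray
    loocv_auc: np.ndarray
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "loocv_auc": self.loocv_auc})


def discretize(log_expr: ExpressionMatrix, alpha: float = 1.0) -> DiscretizedMatrix:
    """Three-state coding per gene: -1 below mu-alpha*sigma, +1 above mu+alpha*sigma.

    mu and sigma (population sd) are taken per gene over the given samples;
    zero-variance genes map to all zeros.
    """
    if log_expr.shape[1] < 2:
        raise DataError("discretize needs >=2 samples")
    if alpha <= 0:
        raise DataError("alpha must be positive")
    arr = log_expr.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sigma = arr.std(axis=1, keepdims=True)
    coded = np.zeros_like(arr, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        coded[arr < mu - alpha * sigma] = -1
        coded[arr > mu + alpha * sigma] = 1
    coded[np.broadcast_to(sigma == 0, arr.shape)] = 0
    return DiscretizedMatrix(
        pd.DataFrame(coded, index=log_expr.gene_ids, columns=log_expr.sample_ids),
        alpha,
    )


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("mutual_information expects two equal-length vectors")
    n = x.size
    if n == 0:
        raise DataError("empty vectors")
    joint = pd.crosstab(x, y).to_numpy(dtype=float) / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def mrmr_rank_miq(
    disc: DiscretizedMatrix,
    labels: np.ndarray,
    candidates: list[str],
) -> MRMRRanking:
    """Greedy mRMR ranking of ``candidates`` under the MIQ criterion."""
    if not candidates:
        raise DataError("empty candidate list")
    missing = [g for g in candidates if g not in disc.values.index]
    if missing:
        raise DataError(f"candidate(s) not in matrix: {missing[:5]}")
    labels = np.asarray(labels, dtype=int)
    # sort once so every argmax tie resolves to the lexicographically first id
    pool = sorted(set(candidates))
    if len(pool) != len(candidates):
        raise DataError("duplicate candidate gene_ids")
    rows = {g: disc.values.loc[g].to_numpy() for g in pool}
    relevance = {g: mutual_information(rows[g], labels) for g in pool}

    selected: list[str] = []
    scores: list[float] = []
    pairwise: dict[tuple[str, str], float] = {}
    remaining = list(pool)
    while remaining:
        if not selected:
            crit = {g: relevance[g] for g in remaining}
        else:
            crit = {}
            for g in remaining:
                red = np.mean([pairwise[(g, s)] for s in selected])
                crit[g] = relevance[g] / max(red, REDUNDANCY_FLOOR)
        top = max(crit.values())
        best = min(g for g in remaining if crit[g] == top)  # gene_id tie-break
        selected.append(best)
        scores.append(float(crit[best]))
        remaining.remove(best)
        for g in remaining:
            pairwise[(g, best)] = mutual_information(rows[g], rows[best])
    return MRMRRanking(selected, scores, relevance)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scaling using training-fold statistics; constant -> 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_scores(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    features: list[str],
    svm_params: SVMParams = SVMParams(),
) -> np.ndarray:
    """Leave-one-out SVM decision scores, one per sample.

    Each sample is scored by an SVM trained on all other samples using the
    given features, z-scaled with the training fold's statistics.  Decision
    values are oriented so that positive means the case class.
    """
    if not features:
        raise DataError("empty feature list")
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n != expr.shape[1]:
        raise DataError("labels length does not match sample count")
    X = expr.subset_genes(features).values.to_numpy(dtype=float).T  # samples x features
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = labels[mask]
        if len(np.unique(y_train)) < 2:
            raise DataError(f"LOOCV fold {i} has a single class")
        X_train, X_test = _standardize(X[mask], X[i : i + 1])
        clf = svm_params.make()
        clf.fit(X_train, y_train)
        d = float(clf.decision_function(X_test)[0])
        scores[i] = d if clf.classes_[1] == 1 else -d
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties -> half credit
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ifs_select(
    ranking: MRMRRanking,
    expr: ExpressionMatrix,
    labels: np.ndarray,
    K: int | None = None,
    svm_params: SVMParams = SVMParams(),
) -> tuple[IFSCurve, list[str]]:
    """Incremental feature selection over the ranked prefix.

    Evaluates LOOCV AUC for the top-k genes, k = 1..K, and returns the curve
    plus the feature set at the smallest k attaining the maximal AUC
    (parsimony tie-break).
    """
    if K is None:
        K = len(ranking.gene_ids)
    if K < 1 or K > len(ranking.gene_ids):
        raise DataError(f"K={K} outside 1..{len(ranking.gene_ids)}")
    labels = np.asarray(labels, dtype=int)
    aucs = np.empty(K)
    for k in range(1, K + 1):
        scores = loocv_scores(expr, labels, ranking.gene_ids[:k], svm_params)
        aucs[k - 1] = roc_auc(scores, labels)
    selected_k = int(np.argmax(aucs)) + 1  # argmax returns the first (smallest) max
    curve = IFSCurve(np.arange(1, K + 1), aucs, selected_k)
    return curve, ranking.gene_ids[:selected_k]
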