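"""Final-model prediction, calibration, threshold choice and cohort evaluation.

The signature model is frozen after training: feature list (in mRMR rank
order), per-feature scaling statistics, SVM decision rule, Platt sigmoid
fitted on the training LOOCV scores, and a Youden-J threshold learned once
on those same scores.  Validation, independent-cohort and subgroup
evaluation apply the frozen model only — nothing is refit.

AUC confidence intervals use DeLong's method by default, or a stratified
bootstrap (2,000 resamples, seeded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import SVC

from exlr.core_data import DataError, ExpressionMatrix
from exlr.feature_select import SVMParams, loocv_scores, roc_auc

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    """Frozen diagnostic signature: features, scaler, SVM rule, Platt map, cut."""

    features: list[str]
    svm_params: SVMParams
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    support_vectors: np.ndarray  # scaled feature space
    dual_coef: np.ndarray
    intercept: float
    gamma_value: float  # resolved numeric gamma (rbf); ignored for linear
    orientation: float  # +1 if decision_function is case-positive, else -1
    platt_a: float
    platt_b: float
    threshold: float

    def decision_scores(self, expr: ExpressionMatrix) -> np.ndarray:
        """Signed decision values for each sample (positive = case side)."""
        if expr.unit != "log2tpm":
            raise DataError(f"predict expects log2tpm, got {expr.unit}")
        missing = [g for g in self.features if g not in expr.values.index]
        if missing:
            raise DataError(f"model feature(s) missing from matrix: {missing}")
        X = expr.subset_genes(self.features).values.to_numpy(dtype=float).T
        Xs = (X - self.scaler_mean) / self.scaler_sd
        if self.svm_params.kernel == "linear":
            K = Xs @ self.support_vectors.T
        elif self.svm_params.kernel == "rbf":
            d2 = ((Xs[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-self.gamma_value * d2)
        else:
            raise DataError(f"unsupported kernel {self.svm_params.kernel!r}")
        return self.orientation * (K @ self.dual_coef + self.intercept)

    def probabilities(self, scores: np.ndarray) -> np.ndarray:
        """Platt-calibrated case probability, monotone in the decision score."""
        from scipy.special import expit

        return expit(self.platt_a * np.asarray(scores) + self.platt_b)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "svm_params": {
                "kernel": self.svm_params.kernel,
                "C": self.svm_params.C,
                "gamma": self.svm_params.gamma,
                "class_weight": self.svm_params.class_weight,
            },
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma_value": self.gamma_value,
            "orientation": self.orientation,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        sp = payload["svm_params"]
        return cls(
            features=payload["features"],
            svm_params=SVMParams(
                kernel=sp["kernel"], C=sp["C"], gamma=sp["gamma"],
                class_weight=sp["class_weight"],
            ),
            scaler_mean=np.asarray(payload["scaler_mean"]),
            scaler_sd=np.asarray(payload["scaler_sd"]),
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=payload["intercept"],
            gamma_value=payload["gamma_value"],
            orientation=payload["orientation"],
            platt_a=payload["platt_a"],
            platt_b=payload["platt_b"],
            threshold=payload["threshold"],
        )


def _fit_platt(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Fit P(case | s) = sigmoid(a*s + b) by maximum likelihood (Newton/BFGS)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)

    def nll(theta):
        a, b = theta
        z = a * scores + b
        # log(1 + exp(-z)) stabilized
        return np.sum(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y))

    res = optimize.minimize(nll, x0=np.array([1.0, 0.0]), method="BFGS")
    a, b = res.x
    if a < 0:
        logger.warning("Platt slope negative; calibration reversed the orientation")
    return float(a), float(b)


def train_signature_model(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    features: list[str],
    svm_params: SVMParams = SVMParams(),
    *,
    loocv: np.ndarray | None = None,
    threshold_method: str = "youden",
) -> SignatureModel:
    """Fit the final SVM on all training samples and freeze the model.

    The Platt map and the decision threshold are learned from the training
    LOOCV scores (computed here if not supplied), never from held-out data.
    """
    labels = np.asarray(labels, dtype=int)
    X = expr.subset_genes(features).values.to_numpy(dtype=float).T
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    clf = svm_params.make()
    clf.fit(Xs, labels)
    orientation = 1.0 if clf.classes_[1] == 1 else -1.0
    gamma_value = clf._gamma if hasattr(clf, "_gamma") else 1.0 / Xs.shape[1]
    if loocv is None:
        loocv = loocv_scores(expr, labels, features, svm_params)
    platt_a, platt_b = _fit_platt(loocv, labels)
    threshold = choose_threshold(loocv, labels, method=threshold_method)
    return SignatureModel(
        features=list(features),
        svm_params=svm_params,
        scaler_mean=mu,
        scaler_sd=sd,
        support_vectors=clf.support_vectors_,
        dual_coef=clf.dual_coef_[0],
        intercept=float(clf.intercept_[0]),
        gamma_value=float(gamma_value),
        orientation=orientation,
        platt_a=platt_a,
        platt_b=platt_b,
        threshold=threshold,
    )


def predict(model: SignatureModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample decision score and calibrated probability from a frozen model."""
    scores = model.decision_scores(expr)
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "score": scores,
            "probability": model.probabilities(scores),
            "predicted_case": scores >= model.threshold,
        }
    )


def choose_threshold(
    scores: np.ndarray, labels: np.ndarray, method: str = "youden", fixed: float = 0.0
) -> float:
    """Decision threshold on training scores.

    ``youden`` maximizes sensitivity + specificity - 1 over midpoints of
    consecutive distinct scores (rule: score >= threshold is called case);
    ties take the lower threshold.  ``fixed`` returns the supplied constant.
    """
    if method == "fixed":
        return float(fixed)
    if method != "youden":
        raise DataError(f"unknown threshold method {method!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DataError("choose_threshold needs both classes")
    u = np.unique(scores)
    if u.size == 1:
        return float(u[0])  # degenerate: J = 0 everywhere
    candidates = (u[:-1] + u[1:]) / 2.0
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        j = (pos >= t).mean() + (neg < t).mean() - 1.0
        if j > best_j:  # strict: ties keep the lower threshold
            best_j, best_t = j, t
    return float(best_t)


@dataclass(frozen=True)
class EvaluationReport:
    """Cohort-level diagnostic performance at a frozen threshold."""

    cohort_name: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_case: int
    n_control: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "cohort_name": self.cohort_name,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity_pct": round(100 * self.sensitivity, 2),
            "specificity_pct": round(100 * self.specificity, 2),
            "accuracy_pct": round(100 * self.accuracy, 2),
            "n_case": self.n_case,
            "n_control": self.n_control,
            "threshold": self.threshold,
        }


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based CI for the AUC, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    auc = roc_auc(scores, labels)
    # placements: V10_i = fraction of negatives below pos_i (half credit on ties)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    for b in range(n_boot):
        sample = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        aucs[b] = roc_auc(sample, lab)
    lo, hi = np.quantile(aucs, [(1 - level) / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    *,
    cohort_name: str = "cohort",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Sensitivity/specificity/accuracy at the threshold plus AUC with 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_case = int((labels == 1).sum())
    n_control = int((labels == 0).sum())
    if n_case == 0 or n_control == 0:
        raise DataError("evaluate needs both classes present")
    called = scores >= threshold
    tp = int((called & (labels == 1)).sum())
    fn = n_case - tp
    tn = int((~called & (labels == 0)).sum())
    fp = n_control - tn
    auc = roc_auc(scores, labels)
    if ci_method == "delong":
        ci_low, ci_high = delong_ci(scores, labels)
    elif ci_method == "bootstrap":
        ci_low, ci_high = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")
    ci_low = min(ci_low, auc)
    ci_high = max(ci_high, auc)
    return EvaluationReport(
        cohort_name=cohort_name,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        n_case=n_case,
        n_control=n_control,
        threshold=float(threshold),
    )


def _apply_filter(design: pd.DataFrame, spec: dict) -> pd.Index:
    mask = pd.Series(True, index=design.index)
    for col, allowed in spec.items():
        if col not in design.columns:
            raise DataError(f"unknown design column {col!r} in subgroup filter")
        allowed = [allowed] if isinstance(allowed, str) else list(allowed)
        mask &= design[col].isin(allowed)
    return design.index[mask]


def evaluate_subgroups(
    model: SignatureModel,
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    plan: list[tuple[str, dict, dict]],
    *,
    ci_method: str = "delong",
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the frozen model on (case-filter, control-filter) subgroups.

    ``plan`` entries are (name, case_filter, control_filter) where a filter
    maps design columns to allowed values, e.g. ``{"cohort": "CRC",
    "stage": ["I", "II"]}``.  Case and control sets must be disjoint; empty
    subgroups are skipped with a warning.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    preds = predict(model, expr).set_index("sample_id")
    reports = []
    for name, case_filter, control_filter in plan:
        case_ids = _apply_filter(design, case_filter)
        ctrl_ids = _apply_filter(design, control_filter)
        overlap = set(case_ids) & set(ctrl_ids)
        if overlap:
            raise DataError(f"subgroup {name!r}: case/control overlap ({len(overlap)} samples)")
        case_ids = [s for s in case_ids if s in preds.index]
        ctrl_ids = [s for s in ctrl_ids if s in preds.index]
        if not case_ids or not ctrl_ids:
            logger.warning("subgroup %r empty on one side; skipped", name)
            continue
        scores = preds.loc[case_ids + ctrl_ids, "score"].to_numpy()
        labels = np.concatenate([np.ones(len(case_ids), int), np.zeros(len(ctrl_ids), int)])
        reports.append(
            evaluate(
                scores, labels, model.threshold,
                cohort_name=name, ci_method=ci_method, seed=seed,
            ).to_dict()
        )
    return pd.DataFrame(reports)
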