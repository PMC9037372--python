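"""Two-group differential expression with an empirical-Bayes moderated t-statistic.

Per gene, the contrast is the difference of group means of log2(TPM+1).
Gene-wise residual variances ``s_g^2`` (pooled, d_g = n-2 df) are shrunk
toward a prior estimated by matching the moments of ``log s_g^2`` to a
scaled-F distribution: with a scaled-inverse-chi-square prior
``s^2 ~ s0^2 * d0 / chi^2_{d0}``, the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated statistic ``t = log2fc / (s~_g * sqrt(1/n1 + 1/n2))`` has
``d0 + d_g`` degrees of freedom.  (d0, s0^2) solve the closed-form moment
equations on the log-variance scale: the excess variance of
``log s_g^2 - digamma(d_g/2) + log(d_g/2)`` over ``trigamma(d_g/2)`` equals
``trigamma(d0/2)``, inverted by Newton iteration; a non-positive excess
means no detectable spread in the true variances and d0 = +infinity (full
shrinkage).

Multiple testing uses the Benjamini-Hochberg step-up procedure, and the
candidate filter reproduces the signature-gene rule: upregulated
protein-coding/lncRNA genes with log2(FC) > 0.59, adjusted p < 0.05 and
expression frequency > 0.5 in the training samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from exlr.core_data import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = np.finfo(float).eps


@dataclass(frozen=True)
class EBayesFit:
    """Estimated variance prior and the per-gene quantities it shrinks."""

    d0: float  # prior df; may be +inf
    s0_sq: float  # prior variance
    s_g_sq: np.ndarray  # per-gene pooled residual variance
    d_g: int  # residual df (n - 2)

    @property
    def posterior_var(self) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(self.s_g_sq, self.s0_sq)
        return (self.d0 * self.s0_sq + self.d_g * self.s_g_sq) / (self.d0 + self.d_g)


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s_g_sq: np.ndarray, d_g: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from pooled variances with common residual df."""
    s2 = np.asarray(s_g_sq, dtype=float)
    positive = s2 > 0
    if not positive.all():
        logger.warning("%d zero-variance gene(s) excluded from prior fit", int((~positive).sum()))
        s2 = s2[positive]
    if s2.size < 2:
        raise DataError("too few positive variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def fit_moderated_t(
    log_expr: ExpressionMatrix,
    labels: np.ndarray,
    *,
    d0_override: float | None = None,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Moderated two-group t-test per gene on a log2(TPM+1) matrix.

    ``labels`` is a boolean vector over samples (True = case).  ``d0_override``
    forces the prior df (0 disables shrinkage; +inf yields full shrinkage to
    s0^2, which is then the mean log-scale variance back-transformed).
    Returns the prior fit and a table (gene_id, log2fc, t_mod, p, adj_p).
    """
    if log_expr.unit != "log2tpm":
        raise DataError(f"fit_moderated_t expects log2tpm, got {log_expr.unit}")
    labels = np.asarray(labels, dtype=bool)
    if labels.size != log_expr.shape[1]:
        raise DataError("labels length does not match sample count")
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise DataError(f"both groups need >=2 samples (got case={n1}, control={n0})")
    arr = log_expr.values.to_numpy(dtype=float)
    case = arr[:, labels]
    ctrl = arr[:, ~labels]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n0 - 1)
    d_g = n1 + n0 - 2
    s_g_sq = ss / d_g
    zero_var = s_g_sq <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s); variance floored",
            RuntimeWarning,
            stacklevel=2,
        )
        s_g_sq = np.where(zero_var, VARIANCE_FLOOR, s_g_sq)

    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            _, s0_sq = estimate_prior(s_g_sq, d_g)
        elif d0 == 0:
            s0_sq = float(np.median(s_g_sq))  # irrelevant at zero weight
        else:
            _, s0_sq = estimate_prior(s_g_sq, d_g)
    else:
        d0, s0_sq = estimate_prior(s_g_sq, d_g)

    fit = EBayesFit(d0=d0, s0_sq=s0_sq, s_g_sq=s_g_sq, d_g=d_g)
    se = np.sqrt(fit.posterior_var * (1.0 / n1 + 1.0 / n0))
    t_mod = log2fc / se
    df_total = d0 + d_g
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "gene_id": log_expr.gene_ids,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
            "adj_p": bh_adjust(p),
        }
    )
    return fit, table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1, ties preserved)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any():
        raise DataError("NaN in p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def expression_frequency(
    tpm: ExpressionMatrix,
    gene: str | None = None,
    samples: list[str] | None = None,
    threshold: float = 0.0,
) -> float | pd.Series:
    """Fraction of samples in which a gene is detected (TPM > ``threshold``).

    With ``gene=None`` returns the per-gene Series for the whole matrix.
    """
    if tpm.unit != "tpm":
        raise DataError(f"expression_frequency expects tpm, got {tpm.unit}")
    mat = tpm.values if samples is None else tpm.subset_samples(samples).values
    if mat.shape[1] == 0:
        raise DataError("empty sample subset")
    freq = (mat > threshold).mean(axis=1)
    if gene is None:
        return freq
    if gene not in mat.index:
        raise DataError(f"unknown gene {gene!r}")
    return float(freq.loc[gene])


@dataclass(frozen=True)
class CandidateRules:
    """Signature-candidate filter: upregulated long-RNA genes.

    Defaults follow the published rule verbatim: log2(FC) > 0.59 (the printed
    cut, not log2(1.5) = 0.585), adjusted p < 0.05, expression frequency >
    0.5, biotype protein-coding or lncRNA.
    """

    min_log2fc: float = 0.59
    max_adj_p: float = 0.05
    min_frequency: float = 0.5
    biotypes: frozenset = field(default_factory=lambda: frozenset({"protein_coding", "lncRNA"}))


def de_table(
    tpm: ExpressionMatrix,
    annotation: pd.DataFrame,
    labels: np.ndarray,
    *,
    pseudocount: float = 1.0,
    detection_threshold: float = 0.0,
    d0_override: float | None = None,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Full differential-expression table on a TPM matrix.

    Fits the moderated t on log2(TPM+pseudocount) and annotates each gene
    with mean case/control TPM, expression frequency (over all samples in
    the matrix) and biotype.
    """
    if tpm.unit != "tpm":
        raise DataError(f"de_table expects tpm, got {tpm.unit}")
    log_expr = ExpressionMatrix(np.log2(tpm.values + pseudocount), "log2tpm")
    fit, table = fit_moderated_t(log_expr, labels, d0_override=d0_override)
    labels = np.asarray(labels, dtype=bool)
    arr = tpm.values.to_numpy(dtype=float)
    table["mean_case_tpm"] = arr[:, labels].mean(axis=1)
    table["mean_control_tpm"] = arr[:, ~labels].mean(axis=1)
    table["expression_frequency"] = np.asarray(
        expression_frequency(tpm, threshold=detection_threshold)
    )
    biotype = annotation.set_index("gene_id")["biotype"]
    table["biotype"] = table["gene_id"].map(biotype).fillna("other")
    return fit, table


def select_candidates(de: pd.DataFrame, rules: CandidateRules = CandidateRules()) -> list[str]:
    """Apply the candidate rules; deterministic order (log2fc desc, gene_id)."""
    required = {"gene_id", "log2fc", "adj_p", "expression_frequency", "biotype"}
    missing = required - set(de.columns)
    if missing:
        raise DataError(f"DE table missing column(s) {sorted(missing)}")
    mask = (
        de["biotype"].isin(rules.biotypes)
        & (de["log2fc"] > rules.min_log2fc)
        & (de["adj_p"] < rules.max_adj_p)
        & (de["expression_frequency"] > rules.min_frequency)
    )
    hits = de.loc[mask].sort_values(
        ["log2fc", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    if hits.empty:
        raise DataError("no candidates; relax rules")
    return hits["gene_id"].tolist()
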