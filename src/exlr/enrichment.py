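"""Per-sample gene-set scoring (ssGSEA), over-representation and group tests.

The ssGSEA score of a gene set in one sample is the sum over the ranked
gene list (descending expression) of the difference between the weighted
in-set empirical CDF (weights = rank^alpha, alpha = 0.25 by default) and
the uniform out-of-set ECDF.  The statistic is purely rank-based, so any
strictly monotone within-sample transformation of expression (TPM vs
log-TPM, for instance) leaves every score unchanged.

This is the scoring core of signature-based cell-type estimation: given
cell-type marker sets it yields per-sample cell-type enrichment scores
(without any spillover compensation or calibrated reference — marker sets
are supplied by the user), and given pathway collections it yields pathway
activity scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from exlr.core_data import DataError, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    *,
    normalize: str = "raw",
    strict: bool = False,
) -> pd.DataFrame:
    """ssGSEA enrichment scores (sets x samples).

    Sets with no member gene in the matrix are skipped with a warning
    (``strict=True`` raises instead).  ``normalize="range"`` divides all
    scores by the largest absolute score so the matrix lies in [-1, 1].
    Ties in expression get average ranks and a deterministic gene_id order,
    making the score invariant to the row order of the input.
    """
    if expr.unit not in ("tpm", "log2tpm"):
        raise DataError(f"ssgsea_score expects tpm or log2tpm, got {expr.unit}")
    if normalize not in ("raw", "range"):
        raise DataError(f"unknown normalization {normalize!r}")
    genes = np.array(expr.gene_ids)
    n_genes = genes.size
    arr = expr.values.to_numpy(dtype=float)
    membership = {}
    for name, members in sets.items():
        present = np.isin(genes, list(members))
        if not present.any():
            if strict:
                raise DataError(f"gene set {name!r} has no member in the matrix")
            logger.warning("gene set %r has no member in the matrix; skipped", name)
            continue
        membership[name] = present
    if not membership:
        raise DataError("no gene set overlaps the matrix")

    scores = pd.DataFrame(
        0.0, index=list(membership), columns=expr.sample_ids
    )
    # deterministic gene_id tie-break keeps scores row-order invariant
    gene_order_key = np.argsort(genes, kind="mergesort")
    for j, sample in enumerate(expr.sample_ids):
        col = arr[:, j]
        ranks = stats.rankdata(col)  # 1 = lowest expression, average ties
        # order genes by decreasing rank; ties resolved by gene_id
        order = gene_order_key[np.argsort(-ranks[gene_order_key], kind="mergesort")]
        r_sorted = ranks[order]
        weights = np.abs(r_sorted) ** alpha
        for name, present in membership.items():
            in_set = present[order]
            n_out = n_genes - int(in_set.sum())
            w_in = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / n_out if n_out else np.zeros(n_genes)
            scores.iloc[scores.index.get_loc(name), j] = float(np.sum(p_in - p_out))
    if normalize == "range":
        top = np.abs(scores.to_numpy()).max()
        if top > 0:
            scores = scores / top
    return scores


def ora_hypergeometric(
    deg: set,
    universe: set,
    pathways: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in a DEG list.

    p = P[X >= overlap] with X hypergeometric(|universe|, |pathway|, |DEG|);
    pathways are intersected with the universe first; BH across pathways.
    """
    from exlr.diffexp import bh_adjust

    deg = set(deg)
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    if not deg <= universe:
        raise DataError(f"{len(deg - universe)} DEG(s) not in the universe")
    rows = []
    for name, members in pathways.items():
        in_universe = members & universe
        if not in_universe:
            logger.warning("pathway %r disjoint from universe; skipped", name)
            continue
        overlap = len(in_universe & deg)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(in_universe), len(deg))
        )
        rows.append(
            {"pathway": name, "size": len(in_universe), "overlap": overlap, "p": min(p, 1.0)}
        )
    if not rows:
        raise DataError("no pathway overlaps the universe")
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table


def group_compare(
    scores: pd.DataFrame,
    design: pd.DataFrame,
    *,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-set cohort comparisons of enrichment scores.

    Wilcoxon rank-sum tests for each cohort pair (exact when both groups
    have <= ``exact_max_n`` samples and no ties force the normal
    approximation; tie-corrected normal approximation otherwise) and a
    one-way ANOVA across the three cohorts.  The trend flag marks sets
    whose group medians are strictly ordered along healthy < CRA < CRC or
    the reverse.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    shared = [s for s in scores.columns if s in design.index]
    if not shared:
        raise DataError("no overlap between score samples and design")
    cohorts = design.loc[shared, "cohort"]
    groups = {c: [s for s in shared if cohorts[s] == c] for c in ("CRC", "CRA", "healthy")}
    pairs = [("CRC", "CRA"), ("CRC", "healthy"), ("CRA", "healthy")]
    rows = []
    for set_name in scores.index:
        row: dict = {"set": set_name}
        vals = {c: scores.loc[set_name, ids].to_numpy(dtype=float) for c, ids in groups.items()}
        for a, b in pairs:
            key = f"p_{a}_vs_{b}"
            if len(vals[a]) < 2 or len(vals[b]) < 2:
                row[key] = np.nan
                continue
            method = (
                "exact"
                if len(vals[a]) <= exact_max_n and len(vals[b]) <= exact_max_n
                else "asymptotic"
            )
            res = stats.mannwhitneyu(vals[a], vals[b], alternative="two-sided", method=method)
            row[key] = float(res.pvalue)
        present = [c for c in groups if len(vals[c]) >= 2]
        if len(present) == 3:
            row["p_anova"] = float(stats.f_oneway(*[vals[c] for c in present]).pvalue)
            med = {c: np.median(vals[c]) for c in present}
            row["trend"] = bool(
                med["healthy"] < med["CRA"] < med["CRC"]
                or med["CRC"] < med["CRA"] < med["healthy"]
            )
        else:
            row["p_anova"] = np.nan
            row["trend"] = False
        rows.append(row)
    return pd.DataFrame(rows)
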