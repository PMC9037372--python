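"""TPM quantification over long-RNA genes and correlation-based sample QC.

Gene-level read counts are converted within each sample to transcripts per
million restricted to the long-RNA biotypes (protein-coding and lncRNA by
default):

    TPM_i = (RC_i / L_i) / sum_j (RC_j / L_j) * 1e6

where RC_i is the read count and L_i the union-exon length in bp, and the
denominator runs over the selected genes only.  Poor samples are then
removed when their median pairwise correlation with the other samples falls
below a threshold (0.9 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exlr.core_data import DataError, ExpressionMatrix

DEFAULT_BIOTYPES = frozenset({"protein_coding", "lncRNA"})


def compute_tpm(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame,
    biotypes: frozenset | set = DEFAULT_BIOTYPES,
) -> ExpressionMatrix:
    """Convert counts to TPM over the genes with a selected biotype.

    The matrix is first restricted to annotated genes with biotype in
    ``biotypes`` (original row order preserved); the per-sample length-
    normalized rates are then scaled to sum to one million.
    """
    if counts.unit != "counts":
        raise DataError(f"compute_tpm expects a counts matrix, got {counts.unit}")
    annot = annotation.set_index("gene_id")
    missing = [g for g in counts.gene_ids if g not in annot.index]
    if missing:
        raise DataError(f"gene(s) missing from annotation: {missing[:5]}")
    keep = [g for g in counts.gene_ids if annot.at[g, "biotype"] in biotypes]
    if not keep:
        raise DataError(f"no genes with biotype in {sorted(biotypes)}")
    values = counts.values.loc[keep]
    lengths = annot.loc[keep, "length_bp"].to_numpy(dtype=float)
    rates = values.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(values.columns[zero])
        raise DataError(f"sample(s) with zero total rate over selected genes: {bad[:5]}")
    tpm = rates / totals * 1.0e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=values.index, columns=values.columns), "tpm"
    )


def log2_transform(tpm: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); the downstream working scale."""
    if tpm.unit != "tpm":
        raise DataError(f"log2_transform expects a tpm matrix, got {tpm.unit}")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(tpm.values + pseudocount), "log2tpm")


@dataclass(frozen=True)
class QCReport:
    """Per-sample median pairwise correlation and the keep/remove decision."""

    table: pd.DataFrame  # sample_id, median_correlation, kept
    threshold: float

    @property
    def kept_samples(self) -> list[str]:
        return self.table.loc[self.table["kept"], "sample_id"].tolist()

    @property
    def removed_samples(self) -> list[str]:
        return self.table.loc[~self.table["kept"], "sample_id"].tolist()


def sample_qc(
    tpm: ExpressionMatrix,
    threshold: float = 0.9,
    *,
    method: str = "pearson",
    log_scale: bool = True,
    pseudocount: float = 1.0,
) -> tuple[QCReport, ExpressionMatrix]:
    """Remove samples whose median pairwise correlation is below ``threshold``.

    Correlation is Pearson on log2(TPM+1) by default (``method="spearman"``
    and ``log_scale=False`` are available); the median excludes the sample's
    self-correlation.  Applied to all samples jointly, before any
    train/validation split.
    """
    if tpm.unit not in ("tpm", "log2tpm"):
        raise DataError(f"sample_qc expects tpm or log2tpm, got {tpm.unit}")
    n = tpm.shape[1]
    if n < 3:
        raise DataError(f"sample_qc needs >=3 samples, got {n}")
    arr = tpm.values.to_numpy(dtype=float)
    if log_scale and tpm.unit == "tpm":
        arr = np.log2(arr + pseudocount)
    if method == "spearman":
        arr = stats.rankdata(arr, axis=0)
    elif method != "pearson":
        raise DataError(f"unknown correlation method {method!r}")
    corr = np.corrcoef(arr, rowvar=False)
    off_diag = corr[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    medians = np.median(off_diag, axis=1)
    kept = medians >= threshold
    report = QCReport(
        pd.DataFrame(
            {
                "sample_id": tpm.sample_ids,
                "median_correlation": medians,
                "kept": kept,
            }
        ),
        threshold,
    )
    filtered = tpm.subset_samples([s for s, k in zip(tpm.sample_ids, kept) if k])
    return report, filtered
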