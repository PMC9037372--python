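"""Seeded synthetic three-cohort exLR profiles with ground-truth manifests.

The generator emulates the statistical shape of a plasma EV long-RNA
profile over CRC / CRA (adenoma) / healthy cohorts: log-normal baseline
abundances over ~15,000 annotated genes, negative-binomial counts
(variance = mu + dispersion * mu^2) scaled by per-sample library size and
gene length, a set of planted CRC-upregulated genes (with an optional
half-size effect in CRA creating the carcinogenesis-ordered trend), random
dropout zeros, and censored exponential survival outcomes whose log-hazard
is linear in a latent per-sample score.  Every draw flows from a single
integer seed, so identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from exlr.core_data import DataError, ExpressionMatrix, GeneSetCollection


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-simulation parameters.

    Defaults mirror the study design: 72 CRC / 42 CRA / 80 healthy samples
    over ~15,000 long-RNA-annotated genes, with 20 planted CRC-upregulated
    genes at log2 fold changes in [1.0, 2.0] and bulk-RNA-typical
    negative-binomial dispersion 0.2.  ``scaled`` shrinks cohort sizes for
    fast runs.
    """

    n_genes: int = 15000
    biotype_fractions: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.65,
            "lncRNA": 0.25,
            "pseudogene": 0.07,
            "other": 0.03,
        }
    )
    n_crc: int = 72
    n_cra: int = 42
    n_healthy: int = 80
    n_planted_up: int = 20
    log2fc_range: tuple = (1.0, 2.0)
    cra_half_effect: bool = True
    nb_dispersion: float = 0.2
    library_size_range: tuple = (5.0e6, 1.5e7)
    gene_length_range: tuple = (200, 10000)
    dropout_rate: float = 0.05
    baseline_hazard: float = 0.02  # events per month
    hr_per_sd: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0

    def scaled(self, factor: float) -> "SimulationConfig":
        """Shrink cohort sizes by ``factor`` (at least 4 samples per cohort)."""
        return replace(
            self,
            n_crc=max(4, round(self.n_crc * factor)),
            n_cra=max(4, round(self.n_cra * factor)),
            n_healthy=max(4, round(self.n_healthy * factor)),
        )

    def validate(self) -> None:
        if self.n_genes < 1:
            raise DataError("n_genes must be positive")
        if abs(sum(self.biotype_fractions.values()) - 1.0) > 1e-9:
            raise DataError("biotype fractions must sum to 1")
        if self.n_planted_up > self.n_genes:
            raise DataError("more planted genes than genes")
        for name in ("log2fc_range", "library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DataError(f"{name} not ordered")
        if self.nb_dispersion <= 0:
            raise DataError("nb_dispersion must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DataError("dropout_rate must lie in [0, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise DataError("censor_rate must lie in [0, 1)")
        if min(self.n_crc, self.n_cra, self.n_healthy) < 2:
            raise DataError("each cohort needs >=2 samples")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: planted genes with effects, latent survival scores, HR."""

    planted_log2fc: dict  # gene_id -> true log2 fold change in CRC
    latent_score: pd.Series  # CRC sample_id -> standardized latent score
    hr_per_sd: float
    all_gene_ids: list

    @property
    def planted_genes(self) -> list[str]:
        return sorted(self.planted_log2fc)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate counts, annotation, design (with survival) and the truth manifest.

    Planted genes are drawn from the upper half of baseline abundance among
    protein-coding/lncRNA genes so that a detectable signature exists (a
    marker expressed in almost no sample could never satisfy the
    expression-frequency rule); their means are multiplied by 2^log2fc in
    CRC and, when ``cra_half_effect``, by 2^(log2fc/2) in CRA.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    gene_ids = np.array([f"SIMG{i:05d}.1" for i in range(n)])
    biotypes = rng.choice(
        list(cfg.biotype_fractions),
        size=n,
        p=list(cfg.biotype_fractions.values()),
    )
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SIM{i}" for i in range(n)],
            "biotype": biotypes,
            "length_bp": lengths,
        }
    )

    # baseline relative abundance (transcript copies), heavy-tailed as in bulk RNA
    abundance = rng.lognormal(mean=1.0, sigma=2.5, size=n)

    long_rna = np.isin(biotypes, ("protein_coding", "lncRNA"))
    eligible = np.flatnonzero(long_rna & (abundance >= np.median(abundance[long_rna])))
    if eligible.size < cfg.n_planted_up:
        raise DataError("not enough expressed long-RNA genes to plant effects")
    planted_idx = rng.choice(eligible, size=cfg.n_planted_up, replace=False)
    true_lfc = rng.uniform(*cfg.log2fc_range, size=cfg.n_planted_up)
    planted_log2fc = {gene_ids[i]: float(l) for i, l in zip(planted_idx, true_lfc)}

    cohorts = (
        ["CRC"] * cfg.n_crc + ["CRA"] * cfg.n_cra + ["healthy"] * cfg.n_healthy
    )
    sample_ids = (
        [f"CRC_{i:03d}" for i in range(cfg.n_crc)]
        + [f"CRA_{i:03d}" for i in range(cfg.n_cra)]
        + [f"HC_{i:03d}" for i in range(cfg.n_healthy)]
    )
    n_samples = len(sample_ids)
    lib_sizes = rng.uniform(*cfg.library_size_range, size=n_samples)

    fold = np.ones((n, n_samples))
    for j, cohort in enumerate(cohorts):
        if cohort == "CRC":
            fold[planted_idx, j] = 2.0**true_lfc
        elif cohort == "CRA" and cfg.cra_half_effect:
            fold[planted_idx, j] = 2.0 ** (true_lfc / 2.0)

    rate = abundance[:, None] * lengths[:, None] * fold  # expected read share
    mu = rate / rate.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
    if cfg.dropout_rate > 0:
        # technical dropout hits weakly expressed transcripts: logistic in
        # log-mean, with the midpoint solved so the overall rate matches
        p_drop = _dropout_probabilities(mu, cfg.dropout_rate)
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=gene_ids, columns=sample_ids), "counts"
    )

    stages = rng.choice(["I", "II", "III", "IV"], size=cfg.n_crc, p=[0.2, 0.3, 0.3, 0.2])
    cea = rng.choice(["negative", "positive"], size=cfg.n_crc, p=[0.45, 0.55])
    design = pd.DataFrame({"sample_id": sample_ids, "cohort": cohorts})
    design["stage"] = pd.NA
    design["cea_status"] = pd.NA
    design.loc[design["cohort"] == "CRC", "stage"] = stages
    design.loc[design["cohort"] == "CRC", "cea_status"] = cea
    for col in ("os_time", "dfs_time"):
        design[col] = np.nan
    for col in ("os_event", "dfs_event"):
        design[col] = pd.array([pd.NA] * n_samples, dtype="boolean")
    design["split"] = pd.NA

    crc_ids = [s for s, c in zip(sample_ids, cohorts) if c == "CRC"]
    latent = pd.Series(rng.standard_normal(len(crc_ids)), index=crc_ids)
    truth = SyntheticTruth(
        planted_log2fc=planted_log2fc,
        latent_score=latent,
        hr_per_sd=cfg.hr_per_sd,
        all_gene_ids=list(gene_ids),
    )
    design = simulate_survival(
        design,
        latent,
        hr_per_sd=cfg.hr_per_sd,
        censor_rate=cfg.censor_rate,
        seed=int(rng.integers(2**31)),
        baseline_hazard=cfg.baseline_hazard,
    )
    return matrix, annotation, design, truth


def _dropout_probabilities(mu: np.ndarray, rate: float, slope: float = 1.0) -> np.ndarray:
    """Per-entry dropout probability, logistic in log mean expression.

    p = 1 / (1 + exp(slope * (log mu - x0))) with the midpoint x0 solved so
    the matrix-wide mean probability equals ``rate``: zeros concentrate in
    low-abundance genes, as technical dropout does.
    """
    log_mu = np.log(np.maximum(mu, 1e-12))

    def mean_p(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(slope * (log_mu - x0)))))

    lo, hi = log_mu.min() - 50.0, log_mu.max() + 50.0
    x0 = optimize.brentq(lambda x: mean_p(x) - rate, lo, hi)
    return 1.0 / (1.0 + np.exp(slope * (log_mu - x0)))


def simulate_survival(
    design: pd.DataFrame,
    scores: pd.Series,
    hr_per_sd: float,
    censor_rate: float,
    seed: int,
    *,
    baseline_hazard: float = 0.02,
    endpoints: tuple = ("OS", "DFS"),
) -> pd.DataFrame:
    """Fill OS/DFS columns for CRC samples with score-linked exponential times.

    The hazard is ``baseline_hazard * hr_per_sd**z`` with z the standardized
    score (log-hazard linear in the score); censoring is independent
    Uniform(0, c) with c solved so the expected censored fraction matches
    ``censor_rate``.  ``hr_per_sd = 1`` is the null (score-independent
    survival); values <= 0 are rejected.
    """
    if hr_per_sd <= 0:
        raise DataError("hr_per_sd must be positive")
    design = design.copy()
    crc_mask = design["cohort"] == "CRC"
    crc_ids = design.loc[crc_mask, "sample_id"].tolist()
    if not crc_ids:
        raise DataError("no CRC samples to simulate survival for")
    missing = [s for s in crc_ids if s not in scores.index]
    if missing:
        raise DataError(f"score(s) missing for CRC sample(s): {missing[:5]}")
    z = scores.loc[crc_ids].to_numpy(dtype=float)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    rates = baseline_hazard * hr_per_sd**z

    rng = np.random.default_rng(seed)
    for endpoint in endpoints:
        tcol, ecol = (
            ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
        )
        times = rng.exponential(1.0 / rates)
        if censor_rate > 0:
            c_max = _solve_censor_horizon(rates, censor_rate)
            censor_times = rng.uniform(0.0, c_max, size=times.size)
            observed = times <= censor_times
            times = np.minimum(times, censor_times)
        else:
            observed = np.ones(times.size, dtype=bool)
        design.loc[crc_mask, tcol] = times
        design.loc[crc_mask, ecol] = pd.array(observed, dtype="boolean")
    return design


def _solve_censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Horizon c of Uniform(0, c) censoring hitting the target censored fraction.

    For T ~ Exp(rate) and C ~ Uniform(0, c), P(censored) = P(C < T) =
    mean over samples of (1 - exp(-rate*c)) / (rate*c).
    """

    def expected_censored(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e6
    while expected_censored(hi) > censor_rate and hi < 1e12:
        hi *= 10
    return float(optimize.brentq(lambda c: expected_censored(c) - censor_rate, lo, hi))


def make_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    set_size: int,
    signal_fraction: float,
    seed: int,
    *,
    n_signal_sets: int | None = None,
) -> tuple[GeneSetCollection, dict]:
    """Random gene sets, some enriched for planted genes.

    ``n_signal_sets`` sets (half by default) draw ``signal_fraction`` of
    their members from the planted genes and the rest at random; the
    manifest maps each set name to whether it carries signal.
    """
    if set_size > len(truth.all_gene_ids):
        raise DataError("set_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    if n_signal_sets is None:
        n_signal_sets = n_sets // 2 if signal_fraction > 0 else 0
    planted = truth.planted_genes
    background = [g for g in truth.all_gene_ids if g not in set(planted)]
    sets = {}
    manifest = {}
    for i in range(n_sets):
        name = f"SET_{i:03d}"
        is_signal = i < n_signal_sets and signal_fraction > 0
        if is_signal:
            n_sig = min(int(round(signal_fraction * set_size)), len(planted))
            members = list(rng.choice(planted, size=n_sig, replace=False))
            members += list(
                rng.choice(background, size=set_size - n_sig, replace=False)
            )
        else:
            members = list(rng.choice(background, size=set_size, replace=False))
        sets[name] = frozenset(members)
        manifest[name] = is_signal
    return GeneSetCollection(sets), manifest
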