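import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from exlr.core_data import DataError, ExpressionMatrix
from exlr.diffexp import (
    CandidateRules,
    bh_adjust,
    de_table,
    estimate_prior,
    expression_frequency,
    fit_moderated_t,
    select_candidates,
    trigamma_inverse,
)

from conftest import make_matrix


def random_log_matrix(seed, genes=300, n1=6, n0=6, shift=0.0):
    rng = np.random.default_rng(seed)
    arr = rng.normal(5, 1, (genes, n1 + n0)) * rng.uniform(0.5, 2.0, (genes, 1))
    arr[: genes // 10, :n1] += shift
    m = make_matrix(arr, "log2tpm")
    labels = np.array([True] * n1 + [False] * n0)
    return m, labels


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        m, labels = random_log_matrix(0, genes=1000)
        _, tab = fit_moderated_t(m, labels, d0_override=0.0)
        arr = m.values.to_numpy()
        t_ref = stats.ttest_ind(arr[:, labels].T, arr[:, ~labels].T, equal_var=True)
        np.testing.assert_allclose(tab["t_mod"], t_ref.statistic, atol=1e-10)
        np.testing.assert_allclose(tab["p"], t_ref.pvalue, atol=1e-10)

    def test_d0_infinite_gives_constant_posterior_variance(self):
        m, labels = random_log_matrix(1)
        fit, _ = fit_moderated_t(m, labels, d0_override=np.inf)
        assert np.unique(fit.posterior_var).size == 1
        assert fit.posterior_var[0] == pytest.approx(fit.s0_sq)

    def test_posterior_variance_between_prior_and_sample(self):
        m, labels = random_log_matrix(2)
        fit, _ = fit_moderated_t(m, labels)
        lo = np.minimum(fit.s_g_sq, fit.s0_sq)
        hi = np.maximum(fit.s_g_sq, fit.s0_sq)
        assert ((fit.posterior_var >= lo - 1e-12) & (fit.posterior_var <= hi + 1e-12)).all()

    def test_antisymmetric_under_label_swap(self):
        m, labels = random_log_matrix(3)
        _, t1 = fit_moderated_t(m, labels)
        _, t2 = fit_moderated_t(m, ~labels)
        np.testing.assert_allclose(t1["t_mod"], -t2["t_mod"], rtol=1e-10)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-10)

    def test_prior_recovery_on_scaled_inv_chisq_variances(self):
        # oracle: independent root-finding on the trigamma moment equation
        d0_true, s0_true, d_g = 4.0, 0.05, 18
        rng = np.random.default_rng(5)
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s_g = true_var * rng.chisquare(d_g, size=5000) / d_g
        d0_hat, s0_hat = estimate_prior(s_g, d_g)
        e = np.log(s_g) - special.digamma(d_g / 2) + np.log(d_g / 2)
        excess = e.var(ddof=1) - special.polygamma(1, d_g / 2)
        from scipy.optimize import brentq

        d0_oracle = 2 * brentq(
            lambda y: special.polygamma(1, y) - excess, 1e-3, 1e6
        )
        assert d0_hat == pytest.approx(d0_oracle, rel=1e-6)
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s0_hat == pytest.approx(s0_true, rel=0.10)

    def test_matches_limma_on_small_matrix(self, tmp_path):
        """Independent oracle: limma's eBayes on the identical contrast."""
        m, labels = random_log_matrix(7, genes=150, n1=5, n0=5)
        mat_path = tmp_path / "m.tsv"
        m.values.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mat_path}", row.names=1))
            design <- cbind(Intercept=1, Case=c(rep(1,5), rep(0,5)))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{tmp_path}/r.tsv", sep="\\t", quote=FALSE)
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if res.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {res.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        fit, tab = fit_moderated_t(m, labels)
        assert fit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert fit.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(tab["t_mod"], ref["t"], rtol=1e-6)

    def test_small_group_rejected(self):
        m, _ = random_log_matrix(8, n1=6, n0=6)
        labels = np.array([True] + [False] * 11)
        with pytest.raises(DataError, match=">=2"):
            fit_moderated_t(m, labels)

    def test_zero_variance_gene_floored_with_warning(self):
        arr = np.ones((3, 6)) * 4.0
        arr[1] = np.arange(6)
        arr[2] = np.arange(6)[::-1]
        m = make_matrix(arr, "log2tpm")
        labels = np.array([True] * 3 + [False] * 3)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit, tab = fit_moderated_t(m, labels)
        assert np.isfinite(tab["t_mod"]).all()

    def test_null_simulation_p_uniform_and_fdr_controlled(self):
        m, labels = random_log_matrix(9, genes=2000, n1=8, n0=8, shift=0.0)
        _, tab = fit_moderated_t(m, labels)
        assert (tab["adj_p"] < 0.05).mean() < 0.01
        ks = stats.kstest(tab["p"], "uniform")
        assert ks.pvalue > 0.01


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_nan_rejected(self):
        with pytest.raises(DataError, match="NaN"):
            bh_adjust(np.array([0.1, np.nan]))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_and_bounds(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        # brute force: min over tail of p_(j) * m / j
        brute = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            brute[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        np.testing.assert_allclose(adj, brute, rtol=1e-12)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)


class TestExpressionFrequency:
    def test_matches_detection_fraction(self):
        rng = np.random.default_rng(2)
        arr = np.zeros((1, 100))
        expressed = rng.choice(100, size=77, replace=False)
        arr[0, expressed] = rng.uniform(1, 10, size=77)
        arr_full = np.vstack([arr, 1e6 - arr])  # make columns sum to 1e6
        m = make_matrix(arr_full, "tpm")
        assert expression_frequency(m, "g1") == pytest.approx(0.77)

    def test_all_zero_gene(self):
        m = make_matrix([[0.0, 0.0], [1e6, 1e6]], "tpm")
        assert expression_frequency(m, "g1") == 0.0

    def test_custom_detection_threshold(self):
        arr = np.array([[0.5, 2.0, 3.0]])
        m = make_matrix(np.vstack([arr, 1e6 - arr]), "tpm")
        assert expression_frequency(m, "g1", threshold=1.0) == pytest.approx(2 / 3)

    def test_unknown_gene_errors(self):
        m = make_matrix([[1e6]], "tpm")
        with pytest.raises(DataError, match="unknown gene"):
            expression_frequency(m, "nope")


class TestSelectCandidates:
    def table(self, **overrides):
        base = pd.DataFrame(
            {
                "gene_id": ["up_strong", "up_rarely_seen", "down", "weak_fc", "lnc_up"],
                "log2fc": [1.92, 1.5, -1.0, 0.3, 0.8],
                "adj_p": [0.001, 0.001, 0.001, 0.001, 0.01],
                "expression_frequency": [0.77, 0.4, 0.9, 0.9, 0.6],
                "biotype": ["protein_coding"] * 4 + ["lncRNA"],
            }
        )
        for key, val in overrides.items():
            base[key] = val
        return base

    def test_filters_and_order(self):
        got = select_candidates(self.table())
        assert got == ["up_strong", "lnc_up"]  # descending log2fc

    def test_low_frequency_excluded(self):
        assert "up_rarely_seen" not in select_candidates(self.table())

    def test_downregulated_excluded(self):
        assert "down" not in select_candidates(self.table())

    def test_empty_result_errors(self):
        strict = CandidateRules(min_log2fc=10.0)
        with pytest.raises(DataError, match="relax rules"):
            select_candidates(self.table(), strict)


def test_de_table_annotates_means_frequency_biotype(small_cohort):
    counts, annotation, design, truth = small_cohort
    from exlr.quantify import compute_tpm

    tpm = compute_tpm(counts, annotation)
    labels = design.set_index("sample_id").loc[tpm.sample_ids, "cohort"].eq("CRC").to_numpy()
    _, tab = de_table(tpm, annotation, labels)
    assert {"mean_case_tpm", "mean_control_tpm", "expression_frequency", "biotype"} <= set(
        tab.columns
    )
    planted = tab.set_index("gene_id").loc[truth.planted_genes]
    background = tab.loc[~tab["gene_id"].isin(truth.planted_genes)]
    assert planted["log2fc"].median() > background["log2fc"].median()
    assert (planted["mean_case_tpm"] > planted["mean_control_tpm"]).mean() > 0.8


def test_trigamma_inverse_round_trip():
    for y in (0.01, 0.5, 3.0, 50.0):
        x = special.polygamma(1, y)
        assert trigamma_inverse(x) == pytest.approx(y, rel=1e-8)
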