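import numpy as np
import pytest

from exlr.core_data import DataError
from exlr.feature_select import (
    REDUNDANCY_FLOOR,
    SVMParams,
    discretize,
    ifs_select,
    loocv_scores,
    mrmr_rank_miq,
    mutual_information,
    roc_auc,
)

from conftest import make_matrix


class TestDiscretize:
    def test_constant_gene_all_zero(self):
        m = make_matrix(np.full((1, 5), 3.0), "log2tpm")
        assert (discretize(m).values.to_numpy() == 0).all()

    def test_three_point_symmetric(self):
        m = make_matrix([[-10.0, 0.0, 10.0]], "log2tpm")
        assert discretize(m, 1.0).values.to_numpy().tolist() == [[-1, 0, 1]]

    def test_large_alpha_all_zero(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(4, 10)), "log2tpm")
        assert (discretize(m, alpha=1e6).values.to_numpy() == 0).all()


class TestMutualInformation:
    def test_independent_product_table_is_zero(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y) == pytest.approx(0.0)

    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 10)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_derived_joint_counts(self):
        x = np.array([0] * 4 + [1] * 4)
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])  # joint ((3,1),(1,3))
        expected = 2 * (3 / 8) * np.log2(1.5) + 2 * (1 / 8) * np.log2(0.5)
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(-1, 2, 30)
            y = rng.integers(-1, 2, 30)
            assert mutual_information(x, y) == pytest.approx(
                mutual_information(y, x), abs=1e-12
            )
            assert mutual_information(x, y) >= -1e-12

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            mutual_information(np.array([1, 2]), np.array([1]))


def brute_force_miq(rows, labels, pool):
    """Exhaustive greedy oracle: re-evaluates the criterion at every step."""
    selected, remaining = [], sorted(pool)
    while remaining:
        best, best_val = None, None
        for g in remaining:  # double loop over candidates
            rel = mutual_information(rows[g], labels)
            if not selected:
                val = rel
            else:
                red = np.mean([mutual_information(rows[g], rows[s]) for s in selected])
                val = rel / max(red, REDUNDANCY_FLOOR)
            if best_val is None or val > best_val or (val == best_val and g < best):
                best, best_val = g, val
        selected.append(best)
        remaining.remove(best)
    return selected


class TestMrmrMiq:
    def test_single_candidate(self):
        m = make_matrix([[0.0, 1.0, 5.0, 6.0]], "log2tpm")
        disc = discretize(m)
        r = mrmr_rank_miq(disc, np.array([0, 0, 1, 1]), ["g1"])
        assert r.gene_ids == ["g1"]
        assert r.scores[0] == pytest.approx(r.relevance["g1"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(20, 61))
            k = int(rng.integers(2, 9))
            labels = rng.integers(0, 2, n)
            arr = rng.normal(size=(k, n)) + labels * rng.uniform(0, 2, (k, 1))
            arr[0] = arr[1] + rng.normal(0, 0.01, n)  # near-duplicate pair
            m = make_matrix(arr, "log2tpm")
            disc = discretize(m)
            genes = list(disc.values.index)
            ranking = mrmr_rank_miq(disc, labels, genes)
            rows = {g: disc.values.loc[g].to_numpy() for g in genes}
            assert ranking.gene_ids == brute_force_miq(rows, labels, genes)

    def test_duplicate_of_top_gene_not_ranked_second(self):
        rng = np.random.default_rng(3)
        n = 40
        labels = rng.integers(0, 2, n)
        informative = labels * 3.0 + rng.normal(0, 0.3, n)
        other = labels * 2.0 + rng.normal(0, 0.5, n)
        noise = rng.normal(size=(2, n))
        arr = np.vstack([informative, informative.copy(), other, noise])
        m = make_matrix(arr, "log2tpm", genes=["a_top", "b_dup", "c_other", "d_n1", "e_n2"])
        disc = discretize(m)
        ranking = mrmr_rank_miq(disc, labels, list(m.gene_ids))
        assert ranking.gene_ids[0] == "a_top"  # gene_id tie-break on the duplicate
        assert ranking.gene_ids[1] != "b_dup"

    def test_invariant_to_candidate_order(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 30)
        m = make_matrix(rng.normal(size=(6, 30)), "log2tpm")
        disc = discretize(m)
        genes = list(m.gene_ids)
        r1 = mrmr_rank_miq(disc, labels, genes)
        r2 = mrmr_rank_miq(disc, labels, genes[::-1])
        assert r1.gene_ids == r2.gene_ids

    def test_first_gene_maximizes_relevance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 50)
        arr = np.vstack([labels + rng.normal(0, 0.2, 50), rng.normal(size=(3, 50))])
        m = make_matrix(arr, "log2tpm")
        disc = discretize(m)
        r = mrmr_rank_miq(disc, labels, list(m.gene_ids))
        assert r.relevance[r.gene_ids[0]] == max(r.relevance.values())


class TestRocAuc:
    def test_enumerated_example(self):
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc(np.ones(6), np.array([0, 1] * 3)) == 0.5

    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_one_class_errors(self):
        with pytest.raises(DataError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(scores, labels) == pytest.approx(
                conc / (pos.size * neg.size), abs=1e-12
            )


class TestLoocv:
    def test_separated_clouds_sign_match(self):
        rng = np.random.default_rng(7)
        labels = np.array([0] * 10 + [1] * 10)
        arr = rng.normal(0, 1, (3, 20)) + labels * 5.0
        m = make_matrix(arr, "log2tpm")
        scores = loocv_scores(m, labels, list(m.gene_ids))
        assert ((scores > 0) == labels.astype(bool)).all()

    def test_equals_independent_per_fold_runs(self):
        rng = np.random.default_rng(8)
        n = 16
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        arr = rng.normal(size=(4, n)) + labels * 0.8
        m = make_matrix(arr, "log2tpm")
        params = SVMParams()
        scores = loocv_scores(m, labels, list(m.gene_ids), params)
        from sklearn.svm import SVC

        X = m.values.to_numpy().T
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            mu = X[mask].mean(axis=0)
            sd = np.where(X[mask].std(axis=0) == 0, 1.0, X[mask].std(axis=0))
            clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
            clf.fit((X[mask] - mu) / sd, labels[mask])
            d = clf.decision_function(((X[i] - mu) / sd).reshape(1, -1))[0]
            if clf.classes_[1] == 0:
                d = -d
            assert scores[i] == d  # bitwise on a deterministic kernel

    def test_constant_feature_contributes_nothing(self):
        rng = np.random.default_rng(9)
        labels = np.array([0] * 8 + [1] * 8)
        informative = labels * 2.0 + rng.normal(0, 0.3, 16)
        arr = np.vstack([informative, np.full(16, 7.0)])
        m = make_matrix(arr, "log2tpm", genes=["info", "const"])
        both = loocv_scores(m, labels, ["info", "const"])
        alone = loocv_scores(m, labels, ["info"])
        np.testing.assert_allclose(both, alone, atol=1e-10)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(size=(5, 24)), "log2tpm")
        aucs = []
        for _ in range(40):
            labels = rng.permutation([0] * 12 + [1] * 12)
            aucs.append(roc_auc(loocv_scores(m, labels, list(m.gene_ids)), labels))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_single_class_fold_errors(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(2, 4)), "log2tpm")
        with pytest.raises(DataError, match="single class"):
            loocv_scores(m, np.array([0, 1, 1, 1]), list(m.gene_ids))


class TestIfsSelect:
    def test_smallest_argmax_convention(self, monkeypatch):
        import exlr.feature_select as fs

        curve_vals = iter([0.7, 0.9, 0.9, 0.85])
        monkeypatch.setattr(fs, "loocv_scores", lambda *a, **k: np.zeros(4))
        monkeypatch.setattr(fs, "roc_auc", lambda *a, **k: next(curve_vals))
        ranking = fs.MRMRRanking(["a", "b", "c", "d"], [1, 1, 1, 1], {})
        m = make_matrix(np.zeros((4, 4)), "log2tpm", genes=["a", "b", "c", "d"])
        curve, features = fs.ifs_select(ranking, m, np.array([0, 0, 1, 1]), 4)
        assert curve.selected_k == 2
        assert features == ["a", "b"]

    def test_recovers_planted_informative_genes(self):
        rng = np.random.default_rng(11)
        n = 40
        labels = np.array([0] * 20 + [1] * 20)
        planted = [f"p{i}" for i in range(3)]
        noise = [f"z{i:02d}" for i in range(27)]
        arr = np.vstack(
            [labels * rng.uniform(1.5, 2.5) + rng.normal(0, 0.6, n) for _ in planted]
            + [rng.normal(size=n) for _ in noise]
        )
        m = make_matrix(arr, "log2tpm", genes=planted + noise)
        disc = discretize(m)
        ranking = mrmr_rank_miq(disc, labels, planted + noise)
        curve, features = ifs_select(ranking, m, labels, K=10)
        assert features == ranking.gene_ids[: curve.selected_k]
        assert len(set(features) & set(planted)) >= 2
        # brute-force recomputation of the curve
        for k in (1, curve.selected_k):
            expected = roc_auc(loocv_scores(m, labels, ranking.gene_ids[:k]), labels)
            assert curve.loocv_auc[k - 1] == pytest.approx(expected, abs=1e-12)

    def test_k_out_of_range(self):
        ranking_stub = type("R", (), {"gene_ids": ["a"]})()
        m = make_matrix(np.zeros((1, 4)), "log2tpm", genes=["a"])
        with pytest.raises(DataError):
            ifs_select(ranking_stub, m, np.array([0, 0, 1, 1]), K=5)
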