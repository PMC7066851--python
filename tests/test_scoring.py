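import numpy as np
import pandas as pd
import pytest

from m6apattern import (
    M6AScorer,
    auc_rank,
    compute_m6ascore,
    dichotomize_score,
    fisher_exact_2x2,
    kruskal_wallis,
    max_stat_cutpoint,
    spearman_corr,
    wilcoxon_ranksum,
)

from oracles import fisher_two_sided_enum


class TestM6AScore:
    def test_hand_svd_two_identical_genes(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0]] * 2, index=["g1", "g2"],
            columns=["s1", "s2", "s3"],
        )
        res = compute_m6ascore(expr, ["g1", "g2"])
        np.testing.assert_allclose(res.pc1, [-1.4142, 0.0, 1.4142], atol=1e-4)
        np.testing.assert_allclose(res.pc2, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.score, [-1.4142, 0.0, 1.4142], atol=1e-4)

    def test_score_is_pc1_plus_pc2(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 20)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(20)],
        )
        res = compute_m6ascore(expr, [f"g{i}" for i in range(6)])
        np.testing.assert_allclose(
            res.score, res.pc1 + res.pc2, atol=1e-12
        )

    def test_consistency_with_loadings(self, rng):
        """Score equals the projection of the z-scored matrix onto the
        returned loadings, to numerical precision."""
        expr = pd.DataFrame(
            rng.normal(size=(8, 30)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(30)],
        )
        res = compute_m6ascore(expr, [f"g{i}" for i in range(8)])
        sub = expr.loc[res.genes]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        proj = z.to_numpy().T @ res.loadings.to_numpy()
        np.testing.assert_allclose(res.score, proj.sum(axis=1), atol=1e-10)

    def test_invariant_to_gene_order_and_constant_padding(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        sig = [f"g{i}" for i in range(5)]
        a = compute_m6ascore(expr, sig)
        padded = pd.concat(
            [expr.sample(frac=1.0, random_state=0),
             pd.DataFrame(2.0, index=["flat1", "flat2"], columns=expr.columns)]
        )
        b = compute_m6ascore(padded, sig[::-1])
        np.testing.assert_allclose(a.score, b.score, atol=1e-10)

    def test_degenerate_inputs_error(self):
        const = pd.DataFrame(
            1.0, index=["g1", "g2"], columns=["s1", "s2", "s3"]
        )
        with pytest.raises(ValueError, match="usable"):
            compute_m6ascore(const, ["g1", "g2"])
        tiny = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            compute_m6ascore(tiny, ["g1"])

    def test_orientation_to_reference(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 40)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(40)],
        )
        sig = [f"g{i}" for i in range(6)]
        base = compute_m6ascore(expr, sig)
        ref = -(base.pc1 + 0.2 * rng.normal(size=40))  # anti-aligned with PC1
        res = compute_m6ascore(expr, sig, orient_to=ref)
        rho, _ = spearman_corr(res.pc1.to_numpy(), ref.to_numpy())
        assert rho > 0  # PC1 flipped to track the reference

    def test_estimator_matches_function(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 25)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(25)],
        )
        sig = [f"g{i}" for i in range(6)]
        scorer = M6AScorer(signature_genes=sig).fit(expr.T)
        np.testing.assert_allclose(
            scorer.transform(expr.T), compute_m6ascore(expr, sig).score,
            atol=1e-10,
        )


class TestDichotomize:
    def test_basic(self):
        assert list(dichotomize_score(np.array([1.0, 2.0, 3.0]), 2.0)) == [
            "low", "low", "high",
        ]

    def test_cut_at_max_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            dichotomize_score(np.array([1.0, 2.0, 3.0]), 3.0)

    def test_consistent_with_cutpoint_result(self, rng):
        score = rng.normal(size=80)
        t = rng.exponential(30, 80)
        e = np.ones(80, dtype=int)
        cut = max_stat_cutpoint(score, t, e)
        groups = dichotomize_score(score, cut.cutpoint)
        assert (groups == "low").sum() == cut.n_low
        assert (groups == "high").sum() == cut.n_high


class TestSpearman:
    def test_perfect_inversion(self):
        assert spearman_corr([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_identity(self):
        assert spearman_corr([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)

    def test_hand_rank_pearson(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestKruskalWallis:
    def test_hand_rank_sum(self):
        h, _ = kruskal_wallis([1, 2, 3, 4, 5, 6], list("AABBCC"))
        assert h == pytest.approx(4.5714, abs=1e-4)

    def test_identical_distributions(self):
        h, p = kruskal_wallis([1, 2, 1, 2], list("AABB"))
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_constant_values_guarded(self):
        h, p = kruskal_wallis([3.0, 3.0, 3.0, 3.0], list("AABB"))
        assert (h, p) == (0.0, 1.0)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(9)
        reps, rejected = 500, 0
        for _ in range(reps):
            values = rng.normal(size=60)
            groups = np.repeat(["a", "b", "c"], 20)
            rejected += kruskal_wallis(values, groups)[1] < 0.05
        rate = rejected / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


class TestWilcoxon:
    def test_identical_multisets(self):
        u, p = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert p > 0.9

    def test_complete_separation(self):
        u, _ = wilcoxon_ranksum([5, 6, 7], [1, 2])
        assert u == 6.0  # n1*n2

    def test_exact_enumeration_small_sample(self):
        u, p = wilcoxon_ranksum([1, 2], [3, 4, 5])
        assert u == 0.0
        assert p == pytest.approx(0.2)  # 2/C(5,2)


class TestFisher:
    def test_hand_enumeration(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]).p == pytest.approx(34 / 70)

    def test_diagonal_table(self):
        res = fisher_exact_2x2([[0, 5], [5, 0]])
        assert res.p == pytest.approx(2 / 252)
        assert res.or_defined

    def test_uniform_table(self):
        res = fisher_exact_2x2([[2, 2], [2, 2]])
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_margin(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p == 1.0
        assert not res.or_defined

    def test_continuity_corrected_odds_ratio(self):
        res = fisher_exact_2x2([[0, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            res = fisher_exact_2x2([[a, b], [c, d]])
            expected = (
                1.0
                if 0 in (a + b, c + d, a + c, b + d)
                else fisher_two_sided_enum(int(a), int(b), int(c), int(d))
            )
            assert res.p == pytest.approx(expected, abs=1e-12)

    def test_non_integer_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc_rank([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0]) == 0.5

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        score = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert auc_rank(score, labels) == pytest.approx(
            roc_auc_score(labels, score), abs=1e-12
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_rank([1.0, 2.0], [1, 1])

    def test_icb_auc_matches_generating_model(self, cohort):
        """AUC of the (negated) latent-aligned score against drawn responses
        is close to the generating-model AUC computed by Monte Carlo from
        the true response probabilities."""
        truth = cohort.truth
        resp = cohort.clinical["response"].to_numpy()
        measured = auc_rank(-truth.latent_score.to_numpy(), resp)
        mc_rng = np.random.default_rng(31)
        aucs = []
        probs = truth.response_prob.to_numpy()
        for _ in range(300):
            draw = mc_rng.binomial(1, probs)
            if draw.min() == draw.max():
                continue
            aucs.append(auc_rank(-truth.latent_score.to_numpy(), draw))
        assert abs(measured - np.mean(aucs)) <= 0.05
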