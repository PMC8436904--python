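import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairsig.errors import ValidationError
from pairsig.io import GeneSet
from pairsig.microenv import (
    correlate_risk,
    estimate_scores,
    group_expression_test,
    ssgsea_score,
)

from conftest import make_expr


def brute_force_score(values, gene_ids, members, alpha):
    """Independent step-by-step evaluation of the running-sum statistic."""
    ranks = stats.rankdata(values)  # rank 1 = lowest expression
    order = sorted(range(len(values)), key=lambda i: -ranks[i])
    in_set = [gene_ids[i] in members for i in order]
    w = [ranks[i] ** alpha if gene_ids[i] in members else 0.0 for i in order]
    total_in = sum(w)
    total_out = sum(1 for x in in_set if not x)
    score = 0.0
    run_in = run_out = 0.0
    for k in range(len(order)):
        run_in += w[k] / total_in
        run_out += (0 if in_set[k] else 1) / total_out
        score += run_in - run_out
    return score


class TestSsgsea:
    def test_top_genes_positive_bottom_negative(self):
        vals = np.arange(20, 0, -1, dtype=float)[:, None]  # G0 highest
        expr = make_expr(vals)
        top = GeneSet("top", [f"G{i}" for i in range(5)])
        bottom = GeneSet("bot", [f"G{i}" for i in range(15, 20)])
        assert ssgsea_score(expr, top, min_overlap=1).iloc[0] > 0
        assert ssgsea_score(expr, bottom, min_overlap=1).iloc[0] < 0

    def test_five_gene_brute_force_oracle(self):
        vals = np.array([[5.0], [3.0], [9.0], [1.0], [7.0]])
        expr = make_expr(vals)
        s = ssgsea_score(expr, GeneSet("s", ["G2"]), alpha=0.25, min_overlap=1)
        ref = brute_force_score(vals[:, 0], expr.gene_ids, {"G2"}, 0.25)
        assert s.iloc[0] == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 50, (12, 4))
        expr = make_expr(vals)
        members = set(rng.choice(expr.gene_ids, size=4, replace=False))
        s = ssgsea_score(expr, GeneSet("s", sorted(members)), min_overlap=1)
        for j, sample in enumerate(expr.sample_ids):
            ref = brute_force_score(vals[:, j], expr.gene_ids, members, 0.25)
            assert s[sample] == pytest.approx(ref, abs=1e-10)

    def test_complement_antisymmetry_unweighted(self):
        # with alpha=0 both ECDFs are uniform and the roles swap exactly
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 9, (30, 6))
        expr = make_expr(vals)
        sset = [f"G{i}" for i in range(10)]
        comp = [f"G{i}" for i in range(10, 30)]
        s = ssgsea_score(expr, GeneSet("s", sset), alpha=0.0, min_overlap=1)
        c = ssgsea_score(expr, GeneSet("c", comp), alpha=0.0, min_overlap=1)
        np.testing.assert_allclose(s.to_numpy(), -c.to_numpy(), atol=1e-10)

    def test_complement_sign_opposition_on_enriched_fixture(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 2, (30, 8))
        vals[:10] += 5.0  # the set genes dominate the top of every ranking
        expr = make_expr(vals)
        s = ssgsea_score(expr, GeneSet("s", [f"G{i}" for i in range(10)]), min_overlap=1)
        c = ssgsea_score(
            expr, GeneSet("c", [f"G{i}" for i in range(10, 30)]), min_overlap=1
        )
        assert (np.sign(s.to_numpy()) == -np.sign(c.to_numpy())).all()

    def test_rank_invariance_per_sample_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 5, (25, 5))
        gs = GeneSet("s", [f"G{i}" for i in range(8)])
        s1 = ssgsea_score(make_expr(vals), gs, min_overlap=1)
        s2 = ssgsea_score(make_expr(np.exp(vals)), gs, min_overlap=1)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_rank_reversal_property(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 10, (50, 30))
        gs = GeneSet("s", [f"G{i}" for i in range(15)])
        s = ssgsea_score(make_expr(vals), gs)
        s_rev = ssgsea_score(make_expr(vals.max() - vals + 1.0), gs)
        assert stats.spearmanr(s, s_rev).statistic < -0.8

    def test_empty_intersection_error(self):
        expr = make_expr(np.ones((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(ValidationError, match="XX"):
            ssgsea_score(expr, GeneSet("s", ["XX", "YY"]), min_overlap=1)

    def test_min_overlap_enforced(self):
        expr = make_expr(np.arange(12, dtype=float).reshape(12, 1) + 1)
        with pytest.raises(ValidationError, match="min_overlap"):
            ssgsea_score(expr, GeneSet("s", ["G0", "G1"]), min_overlap=5)


class TestEstimateScores:
    def _expr(self, seed=0, n_genes=60, n_samples=20):
        rng = np.random.default_rng(seed)
        return make_expr(rng.uniform(0.5, 8, (n_genes, n_samples)))

    def test_sum_identity_exact(self):
        expr = self._expr()
        ms = estimate_scores(
            expr,
            GeneSet("stromal", [f"G{i}" for i in range(12)]),
            GeneSet("immune", [f"G{i}" for i in range(20, 35)]),
        )
        t = ms.table
        np.testing.assert_array_equal(
            t["estimate_score"].to_numpy(),
            (t["stromal_score"] + t["immune_score"]).to_numpy(),
        )

    def test_sample_permutation_equivariance(self):
        expr = self._expr(seed=1)
        stromal = GeneSet("stromal", [f"G{i}" for i in range(12)])
        immune = GeneSet("immune", [f"G{i}" for i in range(20, 35)])
        ms = estimate_scores(expr, stromal, immune)
        perm = list(reversed(expr.sample_ids))
        ms_p = estimate_scores(expr.subset_samples(perm), stromal, immune)
        pd.testing.assert_frame_equal(ms.table.loc[perm], ms_p.table)

    def test_disjoint_null_sets_uncorrelated(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            expr = make_expr(rng.uniform(0.5, 8, (200, 200)))
            ms = estimate_scores(
                expr,
                GeneSet("stromal", [f"G{i}" for i in range(20)]),
                GeneSet("immune", [f"G{i}" for i in range(100, 120)]),
            )
            rho = stats.spearmanr(
                ms.table["stromal_score"], ms.table["immune_score"]
            ).statistic
            assert abs(rho) < 0.2


class TestCorrelateRisk:
    def _abundance(self, sample_ids, **cols):
        return pd.DataFrame({"sample_id": sample_ids, **cols})

    def test_identity_rho_one(self):
        ids = [f"S{i}" for i in range(12)]
        s = pd.Series(np.arange(12, dtype=float), index=ids)
        out = correlate_risk(s, self._abundance(ids, cd8=np.arange(12, dtype=float)))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_negation_rho_minus_one(self):
        ids = [f"S{i}" for i in range(12)]
        s = pd.Series(np.arange(12, dtype=float), index=ids)
        out = correlate_risk(s, self._abundance(ids, m2=-np.arange(12, dtype=float) + 20))
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_hand_ranked_five_samples(self):
        ids = [f"S{i}" for i in range(5)]
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=ids)
        ab = self._abundance(ids, nk=[2.0, 1.0, 4.0, 3.0, 5.0])
        out = correlate_risk(s, ab)
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        expected = 1 - 6 * d2 / (5 * 24)
        assert out.iloc[0]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_samples(self):
        s = pd.Series([1.0], index=["S0"])
        with pytest.raises(ValidationError):
            correlate_risk(s, self._abundance(["S0"], x=[1.0]))


class TestGroupExpression:
    def _setup(self, delta, seed=0, n=40):
        rng = np.random.default_rng(seed)
        hi = rng.normal(5 + delta, 1.0, (1, n // 2))
        lo = rng.normal(5, 1.0, (1, n // 2))
        vals = np.clip(np.hstack([hi, lo]), 0.01, None)
        expr = make_expr(vals, gene_ids=["CKPT1"])
        groups = pd.Series(
            ["high"] * (n // 2) + ["low"] * (n // 2), index=expr.sample_ids
        )
        return expr, groups

    def test_identical_groups_no_star(self):
        rng = np.random.default_rng(1)
        half = rng.uniform(1, 5, (1, 10))
        expr = make_expr(np.hstack([half, half]), gene_ids=["CKPT1"])
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=expr.sample_ids)
        out = group_expression_test(expr, ["CKPT1"], groups)
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        assert out.iloc[0]["stars"] == ""
        assert out.iloc[0]["direction"] == "none"

    def test_shifted_distribution_detected(self):
        expr, groups = self._setup(delta=2.0, n=200)
        out = group_expression_test(expr, ["CKPT1"], groups)
        assert out.iloc[0]["p"] < 1e-3
        assert out.iloc[0]["direction"] == "up"

    def test_missing_gene_error(self):
        expr, groups = self._setup(delta=0.0)
        with pytest.raises(ValidationError, match="MISSING"):
            group_expression_test(expr, ["MISSING"], groups)
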