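"""Gene-set scoring: GMT handling, FAIME, Fisher/KS/cumulative-rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from s2p.empirical_null import PermutationPlan, empirical_p
from s2p.fixtures import random_gene_sets, random_score_matrix
from s2p.gene2pathway import (
    FaimeParams,
    cumulative_rank_test,
    derive_seed,
    faime_score,
    faime_statistic,
    filter_sets,
    fisher_test,
    ks_test,
    read_gmt,
    score_all,
    write_gmt,
)
from s2p.genescore import GeneScoreMatrix
from oracles import hypergeom_upper_tail_exact, ks_d_bruteforce, rank_sum_enumeration


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestGmt:
    def test_read_two_sets(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tfirst\tA\tB\tC\nS2\tsecond\tB\tD\n")
        coll = read_gmt(str(p))
        assert len(coll) == 2
        assert coll.sets["S1"].members == ["A", "B", "C"]

    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\tA\tB\n")
        assert read_gmt(str(p)).sets["S1"].members == ["A", "B"]

    def test_short_line_and_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("S1\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(str(p))
        p.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate set_id"):
            read_gmt(str(p))

    def test_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tfirst\tA\tB\tC\nS2\tsecond\tB\tD\n")
        coll = read_gmt(str(p))
        out = tmp_path / "copy.gmt"
        write_gmt(coll, str(out))
        assert out.read_text() == p.read_text()


class TestFilterSets:
    def _coll(self, tmp_path, lines):
        p = tmp_path / "f.gmt"
        p.write_text("".join(lines))
        return read_gmt(str(p))

    def test_five_gene_boundary(self, tmp_path):
        coll = self._coll(tmp_path, [
            "S4\td\tA\tB\tC\tD\tZZ\n",          # 4 genes in universe
            "S5\td\tA\tB\tC\tD\tE\n",           # exactly 5
        ])
        universe = list("ABCDEFGH")
        kept = filter_sets(coll, universe, min_size=5)
        assert kept.set_ids == ["S5"]

    def test_min_size_one_is_identity(self, tmp_path):
        coll = self._coll(tmp_path, ["S1\td\tA\tB\n", "S2\td\tC\n"])
        kept = filter_sets(coll, list("ABC"), min_size=1)
        assert kept.set_ids == ["S1", "S2"]

    def test_idempotent_and_sizes_bounded(self, tmp_path):
        coll = self._coll(tmp_path, [
            "S1\td\tA\tB\tC\tD\tE\tF\n", "S2\td\tA\tB\n",
        ])
        universe = list("ABCDEF")
        once = filter_sets(coll, universe, min_size=3, max_size=10)
        twice = filter_sets(once, universe, min_size=3, max_size=10)
        assert all(len(s) >= 3 for s in once)
        assert {s.set_id: s.members for s in once} == {
            s.set_id: s.members for s in twice
        }

    def test_bad_arguments(self, tmp_path):
        coll = self._coll(tmp_path, ["S1\td\tA\tB\tC\n"])
        with pytest.raises(ValueError, match="min_size"):
            filter_sets(coll, list("ABC"), min_size=0)
        with pytest.raises(ValueError, match="universe"):
            filter_sets(coll, [])


class TestFaime:
    def test_equal_scores_give_zero(self):
        m = GeneScoreMatrix([f"g{i}" for i in range(10)], ["s"],
                            np.full((10, 1), 3.3))
        f = faime_score(m, {"g0", "g1", "g2"}, FaimeParams())
        assert f[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        """N=4, x=(4,3,2,1), alpha=5, set = top two genes; value frozen from
        a 30-digit arbitrary-precision evaluation of the weight formula."""
        assert faime_statistic(
            np.array([4.0, 3.0, 2.0, 1.0]), np.array([0, 1]), alpha=5.0
        ) == pytest.approx(0.66925037230067655, abs=1e-12)

    def test_antisymmetry_under_complement(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            x = rng.normal(size=n)
            k = int(rng.integers(1, n))
            members = rng.choice(n, size=k, replace=False)
            comp = np.setdiff1d(np.arange(n), members)
            f1 = faime_statistic(x, members, alpha=5.0)
            f2 = faime_statistic(x, comp, alpha=5.0)
            assert f1 == pytest.approx(-f2, abs=1e-12)

    def test_rank_component_is_monotone_invariant_but_weights_are_not(self):
        x = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        y = np.exp(x)  # strictly monotone transform
        assert np.array_equal(stats.rankdata(-x), stats.rankdata(-y))
        assert faime_statistic(x, np.array([0, 2]), 5.0) != pytest.approx(
            faime_statistic(y, np.array([0, 2]), 5.0)
        )

    def test_improper_subset_rejected(self):
        m = GeneScoreMatrix(["g0", "g1"], ["s"], np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="proper non-empty subset"):
            faime_score(m, {"g0", "g1"}, FaimeParams())
        with pytest.raises(ValueError, match="proper non-empty subset"):
            faime_score(m, {"absent"}, FaimeParams())


class TestFisher:
    def test_matches_exact_hypergeometric_tail(self):
        """a=3 of the 4 significant genes fall in a 5-gene set (N=20)."""
        # members g0..g4; significant (score >= 1): g0,g1,g2 in-set + g5 out
        values = np.zeros(20)
        values[[0, 1, 2, 5]] = 1.0
        scores = _series(values)
        members = [f"g{i}" for i in range(5)]
        odds, p = fisher_test(scores, members, ("threshold", 1.0))
        assert p == pytest.approx(
            float(hypergeom_upper_tail_exact(3, 20, 5, 4)), abs=1e-15
        )
        assert odds == pytest.approx((3 * 14) / (2 * 1))

    def test_zero_overlap_gives_p_one(self):
        values = np.zeros(20)
        values[[10, 11]] = 5.0
        p = fisher_test(_series(values), [f"g{i}" for i in range(5)],
                        ("threshold", 1.0))[1]
        assert p == pytest.approx(1.0)

    def test_complete_containment_tail_is_single_pmf_term(self):
        values = np.zeros(10)
        values[[0, 1, 2]] = 2.0
        scores = _series(values)
        members = ["g0", "g1", "g2"]
        _, p = fisher_test(scores, members, ("threshold", 1.0))
        assert p == pytest.approx(float(stats.hypergeom.pmf(3, 10, 3, 3)), abs=1e-15)

    def test_degenerate_rule_rejected(self):
        scores = _series(np.ones(6))
        with pytest.raises(ValueError, match="threshold"):
            fisher_test(scores, ["g0", "g1"], ("threshold", 0.0))

    def test_top_k_rule_and_haldane_only_when_needed(self):
        scores = _series(np.arange(8.0))
        odds, _ = fisher_test(scores, ["g6", "g7"], ("top_k", 2))
        assert odds == pytest.approx((2.5 * 6.5) / (0.5 * 0.5))  # a cell is 0


class TestKs:
    def test_complete_separation(self):
        scores = _series([1.0, 2.0, 3.0, 4.0, 5.0])
        d, _ = ks_test(scores, ["g0", "g1"])
        assert d == 1.0

    def test_identical_distributions(self):
        scores = _series([1.0, 2.0, 1.0, 2.0])
        d, p = ks_test(scores, ["g0", "g1"])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_interleaved_example(self):
        scores = _series([1.0, 2.0, 3.0, 4.0])
        d, _ = ks_test(scores, ["g0", "g2"])  # in {1,3} vs out {2,4}
        assert d == 0.5

    def test_matches_bruteforce_ecdf_sup(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 50))
            k = int(rng.integers(2, n - 1))
            scores = _series(np.round(rng.normal(size=n), 1))  # force ties
            members = [f"g{i}" for i in rng.choice(n, size=k, replace=False)]
            d, _ = ks_test(scores, members)
            mask = scores.index.isin(members)
            assert d == pytest.approx(
                ks_d_bruteforce(
                    scores[mask].tolist(), scores[~mask].tolist()
                ),
                abs=1e-12,
            )


class TestCumulativeRank:
    def test_exact_small_case(self):
        """In-set holds ranks {1,2} of N=5: T=3, one-sided p = 1/10."""
        scores = _series([5.0, 4.0, 3.0, 2.0, 1.0])
        t, _, p = cumulative_rank_test(scores, ["g0", "g1"], alternative="greater")
        assert t == 3.0 and p == pytest.approx(0.1)

    def test_worst_ranks_boundary_by_enumeration(self):
        scores = _series([5.0, 4.0, 3.0, 2.0, 1.0])
        t, _, p = cumulative_rank_test(scores, ["g3", "g4"], alternative="greater")
        ranks = stats.rankdata(-scores.to_numpy())
        p_low, _ = rank_sum_enumeration(list(ranks), 2, t)
        assert p == pytest.approx(p_low) == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 11))
            k = int(rng.integers(1, n))
            scores = _series(rng.integers(0, 4, size=n).astype(float))
            members = [f"g{i}" for i in rng.choice(n, size=k, replace=False)]
            t, _, p_g = cumulative_rank_test(scores, members, "greater")
            ranks = list(stats.rankdata(-scores.to_numpy(), method="average"))
            p_low, p_high = rank_sum_enumeration(ranks, k, t)
            assert p_g == pytest.approx(p_low, abs=1e-12)
            p_l = cumulative_rank_test(scores, members, "less")[2]
            assert p_l == pytest.approx(p_high, abs=1e-12)

    def test_symmetric_half_split_two_sided(self):
        scores = _series(np.arange(8.0, 0.0, -1.0))
        # ranks of g0..g7 are 1..8; {1,4,5,8} sums to k(N+1)/2 = 18
        t, z, p = cumulative_rank_test(scores, ["g0", "g3", "g4", "g7"])
        assert t == 18.0 and z == 0.0 and p == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact_wilcoxon(self):
        """N=50, k=10: continuity-corrected normal p within 0.05 of the
        exact Mann-Whitney tail (tie-free data)."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=50)
            members_pos = rng.choice(50, size=10, replace=False)
            scores = _series(x)
            members = [f"g{i}" for i in members_pos]
            _, _, p = cumulative_rank_test(scores, members, "greater")
            mask = scores.index.isin(members)
            exact = stats.mannwhitneyu(
                scores[mask], scores[~mask], alternative="greater",
                method="exact",
            ).pvalue
            assert abs(p - exact) <= 0.05

    def test_degenerate_membership_rejected(self):
        scores = _series(np.arange(4.0))
        with pytest.raises(ValueError, match="proper non-empty subset"):
            cumulative_rank_test(scores, [f"g{i}" for i in range(4)])


class TestScoreAll:
    def test_one_set_one_sample(self):
        m = random_score_matrix([f"g{i}" for i in range(12)], 1, seed=4)
        coll = random_gene_sets(m.gene_ids, 1, 5, seed=4)
        res = score_all(m, coll, method="faime",
                        params=FaimeParams(n_perm=99, seed=7))
        assert res.score.shape == (1, 1) and res.p.shape == (1, 1)
        assert res.q[0, 0] == res.p[0, 0]  # single test: BH is identity

    def test_invariant_to_gene_row_permutation_for_analytic_methods(self):
        m = random_score_matrix([f"g{i}" for i in range(20)], 2, seed=8)
        coll = random_gene_sets(m.gene_ids, 4, 6, seed=8)
        perm = np.random.default_rng(1).permutation(20)
        m_perm = GeneScoreMatrix(
            [m.gene_ids[i] for i in perm], list(m.sample_ids), m.values[perm]
        )
        for method in ("ks", "cumulative_rank"):
            a = score_all(m, coll, method=method)
            b = score_all(m_perm, coll, method=method)
            np.testing.assert_allclose(a.score, b.score, atol=1e-12)
            np.testing.assert_allclose(a.p, b.p, atol=1e-12)
        # FAIME observed scores are rank-based too
        fa = score_all(m, coll, "faime", FaimeParams(n_perm=1, seed=0))
        fb = score_all(m_perm, coll, "faime", FaimeParams(n_perm=1, seed=0))
        np.testing.assert_allclose(fa.score, fb.score, atol=1e-12)

    def test_faime_composes_from_parts(self):
        """score_all(faime) equals faime_score + empirical_p assembled by hand."""
        m = random_score_matrix([f"g{i}" for i in range(15)], 2, seed=5)
        coll = random_gene_sets(m.gene_ids, 3, 6, seed=5)
        params = FaimeParams(alpha=4.0, n_perm=150, seed=42)
        res = score_all(m, coll, method="faime", params=params)
        for i, sid in enumerate(res.set_ids):
            members = coll.sets[sid].members
            f = faime_score(m, members, params)
            np.testing.assert_allclose(res.score[i], f, atol=1e-15)
            for j, samp in enumerate(m.sample_ids):
                idx = np.sort([m.gene_ids.index(g) for g in members])
                plan = PermutationPlan(
                    n_perm=params.n_perm,
                    seed=derive_seed(params.seed, sid, samp),
                )
                p, _ = empirical_p(
                    f[j],
                    lambda x, mem: faime_statistic(x, mem, params.alpha),
                    m.values[:, j], idx, plan,
                )
                assert res.p[i, j] == p

    def test_fisher_requires_explicit_rule(self):
        m = random_score_matrix([f"g{i}" for i in range(12)], 1, seed=2)
        coll = random_gene_sets(m.gene_ids, 2, 5, seed=2)
        with pytest.raises(ValueError, match="sig_rule"):
            score_all(m, coll, method="fisher")

    def test_empty_collection_rejected(self):
        from s2p.gene2pathway import GeneSetCollection

        m = random_score_matrix([f"g{i}" for i in range(6)], 1, seed=1)
        with pytest.raises(ValueError, match="min_size"):
            score_all(m, GeneSetCollection(sets={}))

    def test_q_dominates_p_and_bh_per_sample(self):
        m = random_score_matrix([f"g{i}" for i in range(30)], 3, seed=6)
        coll = random_gene_sets(m.gene_ids, 8, 6, seed=6)
        res = score_all(m, coll, "cumulative_rank")
        assert np.all(res.q >= res.p - 1e-15)
        from s2p.empirical_null import bh_fdr

        for j in range(3):
            np.testing.assert_allclose(res.q[:, j], bh_fdr(res.p[:, j]))
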