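"""DEG calling, KS enrichment and anti-aging scoring.

The KS statistic is checked against an independent exact-rational oracle
(`fractions.Fraction`) over every tag subset of every list length up to 8.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from senoscreen import SimConfig, gen_compendium
from senoscreen.connectivity import (
    antiaging_score,
    call_degs,
    ks_enrichment,
    permutation_pvalues,
    rank_compounds,
    screen,
    signature_from_degs,
)
from senoscreen.datatypes import ExpressionMatrix, GeneSignature, RankedProfile


def ks_oracle(positions, n):
    """Exact-rational evaluation of the two-sided running-sum statistic."""
    t = len(positions)
    a = max(Fraction(j + 1, t) - Fraction(pos, n) for j, pos in enumerate(positions))
    b = max(Fraction(pos, n) - Fraction(j, t) for j, pos in enumerate(positions))
    return float(a) if a >= b else -float(b)


def profile_of_length(n):
    genes = [f"g{i:02d}" for i in range(n)]
    return RankedProfile.from_scores("p", {g: float(n - i) for i, g in enumerate(genes)})


class TestKSEnrichment:
    def test_hand_example_top_tags(self):
        """N=4 with tags at ranks 1,2: a = max(1/4, 1/2) = 0.5 wins over b = 1/4."""
        profile = profile_of_length(4)
        assert ks_enrichment(profile, {"g00", "g01"}, min_overlap=2) == pytest.approx(0.5)

    def test_exhaustive_oracle_all_subsets_up_to_n8(self):
        """Matches the exact-rational running-sum oracle for every tag subset, N<=8."""
        for n in range(1, 9):
            profile = profile_of_length(n)
            for t in range(1, n + 1):
                for combo in combinations(range(n), t):
                    tags = {profile.genes[i] for i in combo}
                    got = ks_enrichment(profile, tags, min_overlap=1)
                    want = ks_oracle([i + 1 for i in combo], n)
                    assert got == pytest.approx(want, abs=1e-12), (n, combo)

    def test_reverse_list_mirror_symmetry(self):
        """Reversing the profile mirrors the enrichment, up to rank granularity.

        Reversal swaps the two one-sided deviations with a single 1/N step
        (a' = b - 1/N, b' = a + 1/N), so the score magnitude is preserved to
        within 1/N always, and the sign flips whenever one side dominates by
        more than one step. Tags stacked at the top therefore score the
        mirror negative of tags stacked at the bottom.
        """
        rng = np.random.default_rng(5)
        n = 50
        genes = [f"g{i:03d}" for i in range(n)]
        scores = dict(zip(genes, rng.normal(size=n)))
        fwd = RankedProfile.from_scores("f", scores)
        rev = RankedProfile.from_scores("r", {g: -s for g, s in scores.items()})
        for _ in range(50):
            tags = set(rng.choice(genes, size=5, replace=False))
            f, r = ks_enrichment(fwd, tags), ks_enrichment(rev, tags)
            assert abs(abs(f) - abs(r)) <= 1 / n + 1e-12
        # deterministic extreme: top tags vs the same tags after reversal
        ordered = profile_of_length(n)
        top = set(ordered.genes[:5])
        reversed_prof = RankedProfile.from_scores(
            "rr", {g: float(i) for i, g in enumerate(ordered.genes)}
        )
        f, r = ks_enrichment(ordered, top), ks_enrichment(reversed_prof, top)
        assert f > 0 > r and abs(f + r) <= 1 / n + 1e-12

    def test_random_tags_symmetric_about_zero(self):
        """Mean score over random tag placements is ~0 (two-sided statistic)."""
        rng = np.random.default_rng(6)
        profile = profile_of_length(100)
        scores = [
            ks_enrichment(profile, set(rng.choice(profile.genes, 10, replace=False)))
            for _ in range(4000)
        ]
        assert abs(np.mean(scores)) < 0.01

    def test_min_overlap_enforced(self, tiny_profile):
        with pytest.raises(ValueError, match="2"):
            ks_enrichment(tiny_profile, {"a", "b", "x", "y"}, min_overlap=3)

    def test_missing_tags_dropped_with_warning(self, tiny_profile, caplog):
        with caplog.at_level("WARNING"):
            score = ks_enrichment(tiny_profile, {"a", "b", "zzz"}, min_overlap=2)
        assert score == pytest.approx(0.5)
        assert "absent" in caplog.text


class TestAntiagingScore:
    @pytest.mark.parametrize("n_fill", [10, 1990])
    def test_perfect_reversal_approaches_plus_one(self, n_fill):
        """Signature-down genes on top, signature-up at the bottom.

        The max-deviation statistic evaluated at tag ranks gives
        es_down = 1 - t/N and es_up = -(1 - (t-1)/N) for the extreme
        arrangement, so the combined score is 1 - (2t-1)/(2N) -> 1 as the
        universe grows.
        """
        t = 5
        genes = [f"d{i}" for i in range(t)] + [f"n{i:04d}" for i in range(n_fill)] + [
            f"u{i}" for i in range(t)
        ]
        n = len(genes)
        profile = RankedProfile.from_scores(
            "rev", {g: float(n - i) for i, g in enumerate(genes)}
        )
        sig = GeneSignature(
            up=frozenset(f"u{i}" for i in range(t)),
            down=frozenset(f"d{i}" for i in range(t)),
        )
        res = antiaging_score(profile, sig)
        assert res.es_down == pytest.approx(1 - t / n)
        assert res.es_up == pytest.approx(-(1 - (t - 1) / n))
        assert res.antiaging_score == pytest.approx(1 - (2 * t - 1) / (2 * n))
        if n >= 1000:
            assert res.antiaging_score > 0.99

    def test_same_sign_scores_zero(self):
        # both signature sides at the top -> same-sign enrichment -> score 0
        genes = [f"u{i}" for i in range(3)] + [f"d{i}" for i in range(3)] + [
            f"n{i}" for i in range(14)
        ]
        profile = RankedProfile.from_scores(
            "same", {g: float(len(genes) - i) for i, g in enumerate(genes)}
        )
        sig = GeneSignature(
            up=frozenset(f"u{i}" for i in range(3)),
            down=frozenset(f"d{i}" for i in range(3)),
        )
        res = antiaging_score(profile, sig)
        assert np.sign(res.es_up) == np.sign(res.es_down)
        assert res.antiaging_score == 0.0

    def test_score_bounds_and_nonsignature_invariance(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(60)]
        sig = GeneSignature(up=frozenset(genes[:5]), down=frozenset(genes[5:10]))
        scores = dict(zip(genes, rng.normal(size=60)))
        res = antiaging_score(RankedProfile.from_scores("x", scores), sig)
        assert -1 <= res.antiaging_score <= 1
        # relabel non-signature genes: score must not change
        relabeled = {
            (g if g in sig.genes else f"z{g}"): s for g, s in scores.items()
        }
        res2 = antiaging_score(RankedProfile.from_scores("y", relabeled), sig)
        assert res2.antiaging_score == pytest.approx(res.antiaging_score, abs=1e-12)


class TestPermutationAndRanking:
    def test_ranking_deterministic_with_ties(self):
        from senoscreen.datatypes import ConnectivityResult

        results = [
            ConnectivityResult(cid, 0.5, -0.5, -1.0, 0.5, perm_p=p)
            for cid, p in [("b", 0.2), ("a", 0.2), ("c", 0.1)]
        ]
        ranked = rank_compounds(results)
        assert [r.compound_id for r in ranked] == ["c", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_simple_score_order(self):
        from senoscreen.datatypes import ConnectivityResult

        results = [
            ConnectivityResult(f"c{i}", 0, 0, 0, s)
            for i, s in enumerate([0.9, 0.1, -0.5])
        ]
        assert [r.antiaging_score for r in rank_compounds(results)] == [0.9, 0.1, -0.5]

    def test_perm_p_small_nperm_rejected(self, tiny_profile):
        with pytest.raises(ValueError):
            permutation_pvalues([], [], None, n_perm=10)

    def test_null_compound_perm_p_roughly_uniform(self, aging_signature):
        """~5% of null compounds fall below p=0.05."""
        cfg = SimConfig(seed=61, n_null_compounds=200, n_reversers=0, n_mimickers=0)
        profiles, _ = gen_compendium(cfg, aging_signature)
        ranked = screen(profiles, aging_signature, n_perm=500, seed=61)
        rate = (ranked["perm_p"] < 0.05).mean()
        assert 0.01 <= rate <= 0.09

    def test_doubling_nperm_converges(self, aging_signature):
        cfg = SimConfig(seed=62, n_null_compounds=5, n_reversers=2, n_mimickers=0)
        profiles, _ = gen_compendium(cfg, aging_signature)
        r1 = screen(profiles, aging_signature, n_perm=1000, seed=1)
        r2 = screen(profiles, aging_signature, n_perm=2000, seed=1)
        merged = r1.merge(r2, on="compound_id", suffixes=("_1", "_2"))
        assert (abs(merged["perm_p_1"] - merged["perm_p_2"]) < 2 / np.sqrt(1000)).all()


class TestCallDegs:
    def test_fold_change_gate_blocks_small_shifts(self):
        """log2 shift of 0.2 (linear FC 1.149 < 1.20) never passes, whatever p."""
        rng = np.random.default_rng(71)
        n = 8
        a = 10.0 + rng.normal(0, 0.001, size=(1, n))
        b = 10.2 + rng.normal(0, 0.001, size=(1, n))
        matrix = ExpressionMatrix(
            values=pd.DataFrame(
                np.hstack([a, b]),
                index=["gene1"],
                columns=[f"a_{i}" for i in range(n)] + [f"b_{i}" for i in range(n)],
            ),
            design=pd.Series(
                ["a"] * n + ["b"] * n,
                index=[f"a_{i}" for i in range(n)] + [f"b_{i}" for i in range(n)],
            ),
        )
        degs = call_degs(matrix, "a", "b")
        assert degs.loc["gene1", "p_value"] < 1e-6  # highly significant...
        assert not degs.loc["gene1", "passes"]  # ...but below the FC gate

    def test_planted_fixture_recall_and_fdr(self, expression_fixture):
        matrix, truth = expression_fixture
        degs = call_degs(matrix, "young", "old")
        called = set(degs.index[degs["passes"]])
        planted = set(truth.loc[truth["is_de"], "gene"])
        recall = len(called & planted) / len(planted)
        assert recall > 0.9
        # the raw-p pass set carries false positives (~5% of nulls clear both
        # gates at 6v6); the emitted BH q-values control the FDR
        q_called = set(degs.index[degs["passes"] & (degs["q_value"] < 0.05)])
        q_fdr = len(q_called - planted) / max(len(q_called), 1)
        assert q_fdr < 0.2
        assert len(q_called & planted) / len(planted) > 0.9

    def test_identical_groups_pass_none(self):
        rng = np.random.default_rng(72)
        base = rng.normal(8, 2, size=(200, 4))
        jitter = rng.normal(0, 1e-6, size=(200, 8))
        values = np.hstack([base, base]) + jitter
        cols = [f"a_{i}" for i in range(4)] + [f"b_{i}" for i in range(4)]
        matrix = ExpressionMatrix(
            values=pd.DataFrame(values, index=[f"g{i}" for i in range(200)], columns=cols),
            design=pd.Series(["a"] * 4 + ["b"] * 4, index=cols),
        )
        degs = call_degs(matrix, "a", "b")
        assert degs["passes"].sum() == 0

    def test_degenerate_gene_p_one(self):
        cols = ["a_1", "a_2", "b_1", "b_2"]
        matrix = ExpressionMatrix(
            values=pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["flat"], columns=cols),
            design=pd.Series(["a", "a", "b", "b"], index=cols),
        )
        degs = call_degs(matrix, "a", "b")
        assert degs.loc["flat", "p_value"] == 1.0

    def test_single_sample_group_rejected(self):
        cols = ["a_1", "b_1", "b_2"]
        matrix = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=cols),
            design=pd.Series(["a", "b", "b"], index=cols),
        )
        with pytest.raises(ValueError):
            call_degs(matrix, "a", "b")


class TestSignatureFromDegs:
    def test_all_failing_errors(self):
        degs = pd.DataFrame(
            {"log2fc": [0.1], "p_value": [0.9], "q_value": [0.9],
             "direction": ["up"], "passes": [False]},
            index=["g1"],
        )
        with pytest.raises(ValueError, match="up"):
            signature_from_degs(degs)

    def test_max_per_side_keeps_smallest_p(self):
        rng = np.random.default_rng(81)
        n = 10
        genes = [f"u{i}" for i in range(n)] + [f"d{i}" for i in range(n)]
        p = rng.uniform(0.0001, 0.01, size=2 * n)
        degs = pd.DataFrame(
            {
                "log2fc": [1.0] * n + [-1.0] * n,
                "p_value": p,
                "q_value": p,
                "direction": ["up"] * n + ["down"] * n,
                "passes": [True] * 2 * n,
            },
            index=genes,
        )
        sig = signature_from_degs(degs, max_per_side=5)
        # independent re-sort oracle
        up_sorted = sorted(genes[:n], key=lambda g: (degs.at[g, "p_value"], g))[:5]
        down_sorted = sorted(genes[n:], key=lambda g: (degs.at[g, "p_value"], g))[:5]
        assert sig.up == frozenset(up_sorted)
        assert sig.down == frozenset(down_sorted)
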