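"""Enrichment-score machinery against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germkit as gk
from germkit.enrichment import P_FLOOR, permutation_test
from germkit.errors import ValidationError


def es_bruteforce(stats_desc, member_mask, weight=1.0):
    """Naive step-by-step running sum; independent of the vectorized path."""
    n = len(stats_desc)
    nh = sum(member_mask)
    total = sum(abs(s) ** weight for s, m in zip(stats_desc, member_mask) if m)
    if total == 0:
        total = nh
        weights = [1.0 if m else 0.0 for m in member_mask]
    else:
        weights = [abs(s) ** weight if m else 0.0 for s, m in zip(stats_desc, member_mask)]
    running, cur = [], 0.0
    for i in range(n):
        cur += weights[i] / total if member_mask[i] else -1.0 / (n - nh)
        running.append(cur)
    best = max(running)
    worst = min(running)
    return best if best >= -worst - 1e-12 else worst  # magnitude ties -> positive


def make_list(stats):
    stats = np.asarray(stats, dtype=float)
    genes = np.array([f"g{i}" for i in range(len(stats))], dtype=object)
    return gk.RankedList(genes=genes, stats=np.sort(stats)[::-1])


TOY = make_list([5, 4, 3, 2, 1])


class TestRankGenes:
    def test_signed_logp_hand_case(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [2.0, -1.0, 0.5],
             "p": [0.01, 0.001, 0.5], "fdr": [0.02, 0.002, 0.6]}
        )
        r = gk.rank_genes(gk.DETable(df, "t"))
        assert r.genes.tolist() == ["a", "c", "b"]
        np.testing.assert_allclose(r.stats, [2.0, math.log10(2), -3.0], atol=1e-12)

    def test_tie_breaks_by_lfc_then_gene(self):
        df = pd.DataFrame(
            {"gene_id": ["z", "a", "m"], "log2fc": [1.0, 1.0, 3.0],
             "p": [0.1, 0.1, 0.1], "fdr": [0.1, 0.1, 0.1]}
        )
        r = gk.rank_genes(gk.DETable(df, "t"))
        assert r.genes.tolist() == ["m", "a", "z"]

    def test_p_floor_keeps_stats_finite(self):
        df = pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0], "p": [0.0], "fdr": [0.0]})
        r = gk.rank_genes(gk.DETable(df, "t"))
        assert r.stats[0] == pytest.approx(-math.log10(P_FLOOR))


class TestEnrichmentScore:
    def test_top_gene_hits_plus_one(self):
        es, _ = gk.enrichment_score(TOY, gk.GeneSet("s", "", {"g0"}))
        assert es == pytest.approx(1.0)

    def test_bottom_gene_hits_minus_one(self):
        es, rs = gk.enrichment_score(TOY, gk.GeneSet("s", "", {"g4"}))
        assert es == pytest.approx(-1.0)
        np.testing.assert_allclose(rs, [-0.25, -0.5, -0.75, -1.0, 0.0], atol=1e-12)

    def test_two_gene_hand_walk(self):
        es, rs = gk.enrichment_score(TOY, gk.GeneSet("s", "", {"g0", "g2"}))
        assert es == pytest.approx(2 / 3)
        np.testing.assert_allclose(
            rs, [0.625, 0.625 - 1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_running_sum_terminates_at_zero(self, null_ranked):
        rng = np.random.default_rng(0)
        genes = rng.choice(null_ranked.genes, 40, replace=False)
        _, rs = gk.enrichment_score(null_ranked, gk.GeneSet("s", "", set(genes.tolist())))
        assert abs(rs[-1]) < 1e-9

    def test_matches_bruteforce_on_random_instances(self):
        """100 random instances, N <= 50, against the naive running-sum oracle."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(5, 51)
            stats = np.sort(rng.normal(0, 2, n))[::-1]
            k = rng.integers(1, n)
            members = rng.choice(n, k, replace=False)
            mask = np.zeros(n, bool)
            mask[members] = True
            r = make_list(stats)
            s = gk.GeneSet("s", "", set(r.genes[mask].tolist()))
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, _ = gk.enrichment_score(r, s, weight=weight)
            assert es == pytest.approx(es_bruteforce(r.stats, mask, weight), abs=1e-12)

    def test_weight_zero_equals_classical_ks(self):
        """At weight 0 the statistic is the two-sample KS distance between
        in-set and out-of-set rank distributions (up to sign)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(8, 50)
            stats = np.sort(rng.normal(0, 1, n))[::-1]
            k = rng.integers(1, n)
            mask = np.zeros(n, bool)
            mask[rng.choice(n, k, replace=False)] = True
            r = make_list(stats)
            es, _ = gk.enrichment_score(r, gk.GeneSet("s", "", set(r.genes[mask].tolist())),
                                        weight=0.0)
            hit_cdf = np.cumsum(mask) / mask.sum()
            miss_cdf = np.cumsum(~mask) / (~mask).sum()
            assert abs(es) == pytest.approx(np.max(np.abs(hit_cdf - miss_cdf)), abs=1e-12)

    def test_weight_zero_invariant_to_monotone_rescaling(self):
        r1 = make_list([5, 4, 3, 2, 1])
        r2 = make_list([500, 40, 3, 0.2, 0.01])
        s = {"g0", "g3"}
        es1, _ = gk.enrichment_score(r1, gk.GeneSet("s", "", s), weight=0.0)
        es2, _ = gk.enrichment_score(r2, gk.GeneSet("s", "", s), weight=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValidationError, match="empty intersection"):
            gk.enrichment_score(TOY, gk.GeneSet("s", "", {"absent"}))
        with pytest.raises(ValidationError, match="entire"):
            gk.enrichment_score(TOY, gk.GeneSet("s", "", {f"g{i}" for i in range(5)}))


def exhaustive_oracle(r, member_genes, weight=1.0):
    """Enumerate every same-size subset and return (p, subset ES values)."""
    n = len(r)
    k = len(member_genes)
    mask = np.isin(r.genes, list(member_genes))
    es_obs = es_bruteforce(r.stats, mask, weight)
    es_all = []
    for combo in itertools.combinations(range(n), k):
        m = np.zeros(n, bool)
        m[list(combo)] = True
        es_all.append(es_bruteforce(r.stats, m, weight))
    es_all = np.asarray(es_all)
    same = es_all > 0 if es_obs >= 0 else es_all < 0
    p = ((same) & (np.abs(es_all) >= abs(es_obs) - 1e-15)).sum() / same.sum()
    return es_obs, p, es_all


class TestPermutationTest:
    def test_exhaustive_matches_enumeration_exactly(self):
        r = make_list([3.0, 2.5, 1.8, 0.9, -0.7, -2.2])
        members = {"g0", "g2"}
        es_obs, p_oracle, _ = exhaustive_oracle(r, members)
        res = permutation_test(r, gk.GeneSet("s", "", members), mode="exhaustive", seed=1)
        assert res.es == pytest.approx(es_obs, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == math.comb(6, 2)

    def test_sampled_p_converges_to_exhaustive(self):
        """Sampled p (50k perms) within 3x Monte-Carlo SE of the exact p."""
        r = make_list([3.0, 2.5, 1.8, 0.9, -0.7, -2.2])
        members = {"g0", "g2"}
        _, p_exact, _ = exhaustive_oracle(r, members)
        res = permutation_test(r, gk.GeneSet("s", "", members), n_perm=50_000, seed=7)
        se = math.sqrt(p_exact * (1 - p_exact) / 50_000)
        assert abs(res.p - p_exact) <= 3 * se + 2 / 50_000  # +1 convention offset

    def test_plus_one_convention_floor(self, null_ranked):
        """An observed ES beating every permutation floors p at the plus-one
        convention over the same-sign null.

        The two top-ranked genes reach ES = 1.0 exactly, which no other
        size-2 subset can match, so every sampled permutation is beaten and
        p = 1 / (1 + #same-sign permutations) >= 1 / (n_perm + 1).
        """
        top = set(null_ranked.genes[:2].tolist())
        res = permutation_test(null_ranked, gk.GeneSet("s", "", top), n_perm=200, seed=5)
        assert res.es == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / (1 + res.n_same_sign))
        assert res.p >= 1 / 201

    def test_seed_reproducibility(self, null_ranked):
        s = gk.GeneSet("s", "", set(null_ranked.genes[10:40].tolist()))
        r1 = permutation_test(null_ranked, s, n_perm=300, seed=42)
        r2 = permutation_test(null_ranked, s, n_perm=300, seed=42)
        assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)

    def test_null_nes_centres_on_unit_magnitude(self):
        """Random sets on a random list: mean NES over repeats near +-1."""
        rng = np.random.default_rng(8)
        r = make_list(rng.normal(0, 1, 200))
        nes = []
        for i in range(200):
            genes = set(rng.choice(r.genes, 15, replace=False).tolist())
            res = permutation_test(r, gk.GeneSet("s", "", genes), n_perm=250, seed=i)
            nes.append(res.nes)
        nes = np.asarray(nes)
        pos = nes[nes > 0]
        se = pos.std(ddof=1) / math.sqrt(len(pos))
        assert abs(pos.mean() - 1.0) <= 3 * se


class TestFisherCombine:
    def test_closed_forms(self):
        assert gk.fisher_combine([0.2]) == pytest.approx(0.2, abs=1e-12)
        x = -2 * math.log(0.5) * 2
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert gk.fisher_combine([0.5, 0.5]) == pytest.approx(expected, abs=1e-12)
        assert gk.fisher_combine([0.5, 0.5]) == pytest.approx(0.59657, abs=1e-5)
        assert gk.fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    @given(st.lists(st.floats(1e-10, 1.0, allow_nan=False), min_size=1, max_size=3))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_matches_chi_square_series(self, p):
        """Agreement with the closed-form df=2k survival series for k <= 3."""
        x = -2 * sum(math.log(v) for v in p)
        k = len(p)
        series = math.exp(-x / 2) * sum((x / 2) ** j / math.factorial(j) for j in range(k))
        assert gk.fisher_combine(p) == pytest.approx(series, abs=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6), st.data())
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_in_each_input(self, p, data):
        i = data.draw(st.integers(0, len(p) - 1))
        smaller = list(p)
        smaller[i] = p[i] / 2
        assert gk.fisher_combine(smaller) <= gk.fisher_combine(p) + 1e-15

    def test_zero_p_rejected(self):
        with pytest.raises(ValidationError, match="floor"):
            gk.fisher_combine([0.0, 0.5])


class TestGermScore:
    def test_separated_arms_give_positive_score(self):
        rng = np.random.default_rng(1)
        r = make_list(np.linspace(5, -5, 120))
        sig = gk.SignaturePair(
            "toy",
            gk.GeneSet("toy_up", "", set(r.genes[:15].tolist())),
            gk.GeneSet("toy_down", "", set(r.genes[-15:].tolist())),
        )
        res = gk.germ_score(r, sig, n_perm=400, seed=3)
        assert res.up.nes > 0 and res.down.nes < 0 and res.score > 0
        assert res.combined_p < 0.05

    def test_overlapping_arms_rejected(self):
        r = make_list(np.arange(20.0))
        with pytest.raises(ValidationError):
            gk.SignaturePair("bad", gk.GeneSet("u", "", {"g1", "g2"}),
                             gk.GeneSet("d", "", {"g2", "g3"}))

    def test_seeded_determinism(self, null_ranked):
        sig = gk.SignaturePair(
            "s",
            gk.GeneSet("s_up", "", set(null_ranked.genes[:25].tolist())),
            gk.GeneSet("s_down", "", set(null_ranked.genes[-25:].tolist())),
        )
        a = gk.germ_score(null_ranked, sig, n_perm=200, seed=11)
        b = gk.germ_score(null_ranked, sig, n_perm=200, seed=11)
        assert (a.score, a.combined_p) == (b.score, b.combined_p)
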