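"""Weighted-KS enrichment scores, permutation null, empirical p and NES."""

import itertools

import numpy as np
import pytest
from scipy.stats import ks_2samp

from twaskit import (
    GeneSetCatalog,
    RankedList,
    cgsea_run,
    empirical_p,
    enrichment_score,
    normalized_es,
    permutation_null,
    size_filter,
)
from twaskit.cgsea import pool_twas

from conftest import make_ranked


class TestRankedList:
    def test_sorted_descending_with_tie_break(self):
        r = RankedList(np.array(["b", "a", "c"], dtype=object), np.array([1.0, 1.0, 3.0]))
        assert r.genes.tolist() == ["c", "a", "b"]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            RankedList(np.array(["a", "a"], dtype=object), np.array([1.0, 2.0]))

    def test_pool_twas_max_abs(self):
        import pandas as pd

        df = pd.DataFrame(
            {"GENE": ["g1", "g1", "g2"], "PANEL": ["MS", "EL", "MS"], "TWAS.Z": [1.0, -3.0, 2.0]}
        )
        r = pool_twas(df, pooling="max_abs")
        assert dict(zip(r.genes, r.stats)) == {"g1": -3.0, "g2": 2.0}


class TestSizeFilter:
    def make(self, sizes, n_ranked=600):
        ranked = make_ranked(n_ranked, seed=0)
        sets = {
            f"S{i}": (f"S{i}", ranked.genes[:s].tolist()) for i, s in enumerate(sizes)
        }
        return ranked, GeneSetCatalog(sets=sets, universe=ranked.genes.tolist())

    def test_boundaries(self):
        ranked, cat = self.make([9, 10, 500, 501])
        out = size_filter(cat, ranked, 10, 500)
        assert sorted(out.sets) == ["S1", "S2"]

    def test_intersection_precedes_size(self):
        ranked = make_ranked(50, seed=1)
        members = ranked.genes[:8].tolist() + [f"x{i}" for i in range(5)]
        cat = GeneSetCatalog(sets={"S": ("S", members)}, universe=[])
        assert size_filter(cat, ranked, 10, 500).sets == {}
        assert "S" in size_filter(cat, ranked, 5, 500).sets


class TestEnrichmentScore:
    def test_single_member_top_rank(self, small_ranked):
        es, _ = enrichment_score(small_ranked, {"a"}, weight_exp=0.0)
        assert es == pytest.approx(1.0)

    def test_single_member_bottom_rank(self, small_ranked):
        es, _ = enrichment_score(small_ranked, {"e"}, weight_exp=0.0)
        assert es == pytest.approx(-1.0)

    def test_weighted_hand_computation(self, small_ranked):
        """S={ranks 1,3}, stats 5..1, weights |stat|: running sum peaks at 2/3."""
        es, dev = enrichment_score(small_ranked, {"a", "c"}, weight_exp=1.0)
        assert es == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert dev[0] == pytest.approx(5 / 8)

    def test_bounds_random_battery(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            r = make_ranked(n, seed=int(rng.integers(1e6)))
            k = int(rng.integers(1, n))
            mem = set(rng.choice(r.genes, size=k, replace=False).tolist())
            es, _ = enrichment_score(r, mem, weight_exp=float(rng.choice([0, 0.5, 1, 2])))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_classic_ks_reduction(self, rng):
        """weight_exp=0 equals the two-sample KS statistic on rank positions."""
        for _ in range(100):
            n = int(rng.integers(5, 51))
            r = make_ranked(n, seed=int(rng.integers(1e6)))
            k = int(rng.integers(1, n))
            mem = set(rng.choice(r.genes, size=k, replace=False).tolist())
            es, _ = enrichment_score(r, mem, weight_exp=0.0)
            pos = np.arange(1, n + 1)
            hit = np.array([g in mem for g in r.genes])
            assert abs(es) == pytest.approx(ks_2samp(pos[hit], pos[~hit]).statistic, abs=1e-12)

    def test_zero_stats_fallback_uniform(self, caplog):
        r = RankedList(np.array(list("abcd"), dtype=object), np.array([0.0, 0.0, 0.0, 0.0]))
        es, _ = enrichment_score(r, {"a"}, weight_exp=1.0)
        es0, _ = enrichment_score(r, {"a"}, weight_exp=0.0)
        assert es == pytest.approx(es0)

    def test_no_member_error(self, small_ranked):
        with pytest.raises(ValueError):
            enrichment_score(small_ranked, {"zzz"})


class TestPermutationNull:
    def test_determinism(self):
        r = make_ranked(60, seed=2)
        a = permutation_null(r, 8, n_perm=100, seed=9)
        b = permutation_null(r, 8, n_perm=100, seed=9)
        assert np.array_equal(a, b)

    def test_mean_matches_exhaustive_enumeration(self):
        """N=8, |S|=2: all C(8,2)=28 subsets vs the sampled null mean."""
        genes = np.array([f"g{i}" for i in range(8)], dtype=object)
        r = RankedList(genes, np.arange(8, 0, -1).astype(float))
        exact = np.mean(
            [
                enrichment_score(r, set(c), weight_exp=1.0)[0]
                for c in itertools.combinations(r.genes.tolist(), 2)
            ]
        )
        null = permutation_null(r, 2, n_perm=4000, weight_exp=1.0, seed=3)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean() - exact) < 3 * se

    def test_sign_flip_symmetry_unweighted(self):
        """Flipping all stats mirrors the exhaustive ES distribution.

        Magnitudes match exactly; signed scores mirror except where the
        running sum's extreme deviations tie in magnitude and the
        deterministic tie-break picks the earlier one.
        """
        genes = np.array([f"g{i}" for i in range(8)], dtype=object)
        stats_ = np.array([4.0, 3.0, 2.5, 1.0, -0.5, -1.5, -2.0, -3.0])
        r_fwd = RankedList(genes, stats_)
        r_rev = RankedList(genes, -stats_)
        fwd, rev = [], []
        for c in itertools.combinations(genes.tolist(), 3):
            fwd.append(enrichment_score(r_fwd, set(c), weight_exp=0.0)[0])
            rev.append(enrichment_score(r_rev, set(c), weight_exp=0.0)[0])
        fwd, rev = np.array(fwd), np.array(rev)
        assert np.allclose(np.sort(np.abs(fwd)), np.sort(np.abs(rev)), atol=1e-12)
        # signed mirror holds whenever the extreme deviations do not tie
        for c, f in zip(itertools.combinations(genes.tolist(), 3), fwd):
            _, dev = enrichment_score(r_rev, set(c), weight_exp=0.0)
            tied = abs(dev.max() + dev.min()) < 1e-12
            if not tied:
                assert enrichment_score(r_rev, set(c), weight_exp=0.0)[0] == pytest.approx(
                    -f, abs=1e-12
                )

    def test_set_size_too_large(self):
        r = make_ranked(10, seed=0)
        with pytest.raises(ValueError):
            permutation_null(r, 10, n_perm=100)


class TestEmpiricalP:
    def test_below_all_null_gives_one(self):
        assert empirical_p(0.01, np.linspace(0.2, 0.9, 100)) == 1.0

    def test_floor_at_one_over_nperm(self):
        null = np.linspace(-0.5, 0.5, 10000)
        assert empirical_p(0.99, null) == pytest.approx(1e-4)

    def test_median_gives_half(self):
        rng = np.random.default_rng(4)
        null = rng.normal(size=10000)
        p = empirical_p(float(np.median(null)), null)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_signed_mode_mirrors_negative_side(self):
        null = np.array([-0.5, -0.2, 0.1, 0.4])
        assert empirical_p(-0.3, null, side="signed") == pytest.approx(1 / 4)

    def test_default_upper_tail_for_negative_score(self):
        null = np.array([-0.5, -0.2, 0.1, 0.4])
        assert empirical_p(-0.3, null) == pytest.approx(3 / 4)


class TestNormalizedEs:
    def test_equal_to_same_sign_mean(self):
        null = np.array([0.2, 0.4, -0.3, -0.1])
        assert normalized_es(0.3, null) == pytest.approx(1.0)

    def test_zero_es(self):
        assert normalized_es(0.0, np.array([0.1, -0.1])) == 0.0

    def test_no_same_sign_nan(self, caplog):
        assert np.isnan(normalized_es(-0.5, np.array([0.1, 0.2])))


class TestCgseaRun:
    def test_deterministic_reruns(self):
        ranked = make_ranked(300, seed=5)
        rng = np.random.default_rng(8)
        sets = {
            f"C{i}": (f"C{i}", rng.choice(ranked.genes, size=15, replace=False).tolist())
            for i in range(10)
        }
        cat = GeneSetCatalog(sets=sets, universe=ranked.genes.tolist())
        a = cgsea_run(ranked, cat, n_perm=200, seed=11)
        b = cgsea_run(ranked, cat, n_perm=200, seed=11)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_planted_enrichment_ranks_first(self):
        ranked = make_ranked(400, seed=6)
        rng = np.random.default_rng(9)
        sets = {
            f"C{i}": (f"C{i}", rng.choice(ranked.genes, size=20, replace=False).tolist())
            for i in range(8)
        }
        sets["PLANTED"] = ("PLANTED", ranked.genes[:20].tolist())
        cat = GeneSetCatalog(sets=sets, universe=ranked.genes.tolist())
        out = cgsea_run(ranked, cat, n_perm=500, seed=12)
        assert out.loc[0, "CHEMICAL.ID"] == "PLANTED"
        assert out.loc[0, "NES"] > 1.0
        assert out.loc[0, "P"] == pytest.approx(1 / 500)

    def test_empty_catalog_warning(self, caplog):
        ranked = make_ranked(50, seed=7)
        cat = GeneSetCatalog(sets={"S": ("S", ranked.genes[:3].tolist())}, universe=[])
        out = cgsea_run(ranked, cat, n_perm=200, min_size=10)
        assert out.empty
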