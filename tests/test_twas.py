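"""Gene-level association statistic, p-value conversions, BH and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twaskit import (
    WeightPanel,
    benjamini_hochberg,
    filter_significant,
    harmonize_alleles,
    panel_overlap,
    twas_association,
    two_sided_p,
    z_from_p,
)


def bh_oracle(p):
    """Definition-based step-up q-values by O(n^2) enumeration.

    For the i-th smallest p, q_(i) = min over j >= i of p_(j) * m / j,
    capped at 1 and mapped back to input order.
    """
    p = list(map(float, p))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank, idx in enumerate(indexed, start=1):
        candidates = [
            p[jdx] * m / j for j, jdx in enumerate(indexed, start=1) if j >= rank
        ]
        q[idx] = min(min(candidates), 1.0)
    return np.array(q)


def quadratic_form_oracle(w, z, sigma):
    """Loop-based evaluation of w'z / sqrt(w' Sigma w)."""
    num = sum(wi * zi for wi, zi in zip(w, z))
    den = 0.0
    for i in range(len(w)):
        for j in range(len(w)):
            den += w[i] * sigma[i][j] * w[j]
    return num / den**0.5


class TestAssociation:
    def test_single_snp_identity(self):
        assert twas_association([1.0], [2.22], [[1.0]], ridge=0.0) == pytest.approx(2.22)

    def test_two_snp_closed_form(self):
        z = twas_association([1.0, 1.0], [1.0, 1.0], np.eye(2), ridge=0.0)
        assert z == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            w = rng.standard_normal(5)
            z = rng.standard_normal(5)
            a = rng.standard_normal((5, 5))
            sigma = a @ a.T + np.eye(5)
            d = np.sqrt(np.diag(sigma))
            sigma = sigma / np.outer(d, d)
            got = twas_association(w, z, sigma, ridge=0.0)
            assert got == pytest.approx(quadratic_form_oracle(w, z, sigma), abs=1e-12)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            w = rng.standard_normal(4)
            z = rng.standard_normal(4)
            sigma = np.eye(4) * 0.7 + 0.3
            base = twas_association(w, z, sigma)
            for c in (1e-3, 0.5, 7.0, 1e4):
                assert twas_association(c * w, z, sigma) == pytest.approx(base, abs=1e-12)

    def test_degenerate_denominator_skipped(self, caplog):
        assert twas_association([0.0, 0.0], [1.0, 1.0], np.eye(2), ridge=0.0) is None

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            twas_association([1.0, 2.0], [1.0], np.eye(2))


class TestPvalues:
    def test_z_zero_gives_one(self):
        assert two_sided_p(0.0) == 1.0

    def test_textbook_quantile(self):
        assert two_sided_p(1.959964) == pytest.approx(0.05, abs=1e-6)

    @pytest.mark.parametrize(
        ("p", "expected_z"),
        [(3.78e-2, 2.08), (4.59e-2, 2.00), (4.32e-2, 2.02), (2.66e-2, 2.22)],
    )
    def test_printed_two_decimal_z_recovered(self, p, expected_z):
        """Worked examples: |Z| recovered from a printed two-sided p."""
        assert round(float(z_from_p(p)), 2) == expected_z

    def test_negative_z_two_sided(self):
        assert two_sided_p(-2.02) == pytest.approx(4.32e-2, abs=5e-4)

    def test_p_one_gives_zero(self):
        assert z_from_p(1.0) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-8, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, z):
        assert z_from_p(two_sided_p(z)) == pytest.approx(abs(z), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            z_from_p(0.0)
        with pytest.raises(ValueError):
            z_from_p(1.5)


class TestBenjaminiHochberg:
    def test_all_equal(self):
        p = np.full(5, 0.2)
        assert np.allclose(benjamini_hochberg(p), p)

    def test_hand_enumeration(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0

    def test_matches_definition_oracle(self, rng):
        for _ in range(300):
            n = rng.integers(1, 9)
            p = rng.uniform(1e-6, 1.0, size=n)
            assert np.array_equal(benjamini_hochberg(p), bh_oracle(p))

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-5, 1.0, size=40)
        assert np.allclose(benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1])

    def test_order_preserving_under_permutation(self, rng):
        p = rng.uniform(0.001, 1.0, size=12)
        q = benjamini_hochberg(p)
        perm = rng.permutation(12)
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])


def make_panel(**kw):
    defaults = dict(
        gene="G1",
        panel="MS",
        snps=["rs1", "rs2", "rs3"],
        a1=["A", "C", "A"],
        a2=["G", "T", "T"],
        weights=np.array([0.5, -1.0, 2.0]),
        cv_r2=0.5,
    )
    defaults.update(kw)
    return WeightPanel(**defaults)


class TestHarmonize:
    def gwas(self, rows):
        return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "Z"])

    def test_identical_alleles_unchanged(self):
        panel = make_panel(snps=["rs1"], a1=["A"], a2=["G"], weights=[1.0])
        w, z, kept = harmonize_alleles(panel, self.gwas([("rs1", "A", "G", 1.5)]))
        assert z[0] == 1.5 and kept == ["rs1"]

    def test_swapped_alleles_flip_sign(self):
        panel = make_panel(snps=["rs1"], a1=["A"], a2=["G"], weights=[1.0])
        w, z, _ = harmonize_alleles(panel, self.gwas([("rs1", "G", "A", 1.5)]))
        assert z[0] == -1.5

    def test_ambiguous_and_missing_dropped(self):
        # rs3 is A/T ambiguous, rs2 absent from the GWAS -> one SNP survives
        panel = make_panel()
        out = harmonize_alleles(panel, self.gwas([("rs1", "A", "G", 2.0)]))
        assert out is not None
        w, z, kept = out
        assert kept == ["rs1"] and len(w) == 1

    def test_nothing_left_returns_none(self, caplog):
        panel = make_panel(snps=["rs9"], a1=["A"], a2=["G"], weights=[1.0])
        assert harmonize_alleles(panel, self.gwas([("rs1", "A", "G", 1.0)])) is None

    def test_allele_mismatch_dropped(self):
        panel = make_panel(snps=["rs1"], a1=["A"], a2=["G"], weights=[1.0])
        assert harmonize_alleles(panel, self.gwas([("rs1", "C", "T", 1.0)])) is None


class TestFilterSignificant:
    def frame(self, fdr, r2):
        return pd.DataFrame({"GENE": [f"g{i}" for i in range(len(fdr))], "FDR.P": fdr, "MODELCV.R2": r2})

    def test_fdr_boundary_strict(self):
        out = filter_significant(self.frame([0.05], [0.5]))
        assert out.empty

    def test_r2_boundary_nonstrict(self):
        out = filter_significant(self.frame([0.01], [0.01]))
        assert len(out) == 1

    def test_known_strata_counts(self):
        fdr = [0.01, 0.01, 0.2, 0.01]
        r2 = [0.5, 0.005, 0.5, 0.01]
        assert len(filter_significant(self.frame(fdr, r2))) == 2


class TestPanelOverlap:
    def test_disjoint(self):
        regions = panel_overlap({"A": ["g1"], "B": ["g2"]})
        assert regions[("A", "B")] == 0
        assert regions[("A",)] == 1 and regions[("B",)] == 1

    def test_identical(self):
        regions = panel_overlap({"A": ["g1", "g2"], "B": ["g1", "g2"]})
        assert regions[("A", "B")] == 2
        assert regions[("A",)] == 0 and regions[("B",)] == 0

    def test_planted_structure_partitions_union(self):
        lists = {
            "A": ["g1", "g2", "g3"],
            "B": ["g2", "g3", "g4"],
            "C": ["g3", "g5"],
        }
        regions = panel_overlap(lists)
        assert regions[("A", "B", "C")] == 1  # g3
        assert regions[("A", "B")] == 1  # g2
        assert regions[("C",)] == 1  # g5
        union = set().union(*lists.values())
        assert sum(regions.values()) == len(union)
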