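"""Gene-level association from GWAS summary statistics and eQTL weights.

A transcriptome-wide association study (TWAS) tests whether genetically
predicted expression of a gene is associated with a trait.  Given per-SNP
eQTL weights ``w`` for a gene, GWAS Z-scores ``z`` at the same SNPs and the
SNP-SNP correlation (LD) matrix ``Sigma`` from a reference panel, the gene
statistic is

    z_twas = w'z / sqrt(w' Sigma w)

which is standard normal under the null of no association.  This module
implements allele harmonization between the weight panel and the GWAS table,
the statistic itself, two-sided p-values, Benjamini-Hochberg q-values, the
significance filter (FDR q < 0.05 and cross-validation R^2 >= 0.01), and
cross-panel overlap counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: SNPs whose two alleles are reverse complements of each other; their strand
#: cannot be resolved without allele frequencies, so they are dropped.
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class WeightPanel:
    """Per-gene eQTL weight vector from one tissue panel.

    Attributes
    ----------
    gene : str
        Gene identifier.
    panel : str
        Tissue/cell panel label (e.g. ``MS``, ``EL``, ``TF``, ``NBL``, ``YBL``).
    snps : list of str
        Ordered SNP identifiers.
    a1, a2 : list of str
        Effect and other allele per SNP.
    weights : ndarray
        Expression weights, one per SNP; at least one nonzero.
    cv_r2 : float
        Cross-validation R^2 of the expression prediction model, in [0, 1].
    """

    gene: str
    panel: str
    snps: list[str]
    a1: list[str]
    a2: list[str]
    weights: np.ndarray
    cv_r2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.snps) == len(self.a1) == len(self.a2) == self.weights.size):
            raise ValueError(f"{self.gene}: SNP/allele/weight lengths differ")
        if not np.any(self.weights != 0):
            raise ValueError(f"{self.gene}: all weights are zero")
        if not 0.0 <= self.cv_r2 <= 1.0:
            raise ValueError(f"{self.gene}: cv_r2 {self.cv_r2} outside [0, 1]")


def harmonize_alleles(
    panel: WeightPanel, gwas: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]] | None:
    """Align a weight panel with a GWAS summary table.

    SNPs are matched by identifier.  If the GWAS effect allele equals the
    panel's other allele (alleles swapped) the GWAS Z sign is flipped.
    Strand-ambiguous SNPs (A/T, C/G) and SNPs absent from the GWAS table or
    with irreconcilable alleles are dropped together with their weights.

    Parameters
    ----------
    panel : WeightPanel
    gwas : DataFrame with columns SNP, A1, A2, Z.

    Returns
    -------
    (weights, z, snp_ids) aligned arrays, or None when no SNP survives
    (the gene is skipped with a logged warning, never a crash).
    """
    lookup = {
        s: (a1, a2, z)
        for s, a1, a2, z in zip(gwas["SNP"], gwas["A1"], gwas["A2"], gwas["Z"])
    }
    w_out: list[float] = []
    z_out: list[float] = []
    kept: list[str] = []
    for snp, pa1, pa2, w in zip(panel.snps, panel.a1, panel.a2, panel.weights):
        if (pa1, pa2) in AMBIGUOUS_PAIRS:
            continue
        rec = lookup.get(snp)
        if rec is None:
            continue
        ga1, ga2, z = rec
        if (ga1, ga2) == (pa1, pa2):
            pass
        elif (ga1, ga2) == (pa2, pa1):
            z = -z
        else:
            continue  # allele mismatch beyond a swap
        w_out.append(w)
        z_out.append(z)
        kept.append(snp)
    if not kept:
        logger.warning("gene %s: no usable SNP after harmonization; skipped", panel.gene)
        return None
    return np.asarray(w_out), np.asarray(z_out), kept


def twas_association(
    weights: np.ndarray,
    z: np.ndarray,
    ld: np.ndarray,
    ridge: float = 1e-4,
) -> float | None:
    """TWAS Z-statistic ``w'z / sqrt(w'(Sigma + ridge*I)w)``.

    The small ridge added to the LD diagonal guards against reference
    matrices that are numerically non-positive-definite.  The statistic is
    invariant to positive rescaling of the weights.

    Returns None (with a warning) when the denominator is not positive.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(z, dtype=float)
    ld = np.asarray(ld, dtype=float)
    if w.shape[0] != z.shape[0] or ld.shape != (w.shape[0], w.shape[0]):
        raise ValueError("weights, z and LD dimensions disagree")
    denom2 = float(w @ (ld + ridge * np.eye(len(w))) @ w)
    if denom2 <= 1e-12:
        logger.warning("non-positive TWAS denominator (%g); gene skipped", denom2)
        return None
    return float(w @ z) / np.sqrt(denom2)


def two_sided_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value, p = 2 * (1 - Phi(|z|)).

    Clipped away from exact zero so downstream BH (which requires
    p in (0, 1]) never sees an underflowed value.
    """
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
    return float(p) if np.isscalar(z) else p


def z_from_p(p: float | np.ndarray) -> float | np.ndarray:
    """Absolute Z recovering a two-sided p: |z| = Phi^{-1}(1 - p/2)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("p must lie in (0, 1]")
    z = stats.norm.isf(p_arr / 2.0)
    return float(z) if np.isscalar(p) else z


def benjamini_hochberg(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def twas_scan(
    panels: Iterable[WeightPanel],
    gwas: pd.DataFrame,
    ld_by_gene: Mapping[str, np.ndarray],
    ridge: float = 1e-4,
    fdr_scope: str = "panel",
) -> pd.DataFrame:
    """Run the TWAS statistic over a collection of weight panels.

    Parameters
    ----------
    panels : iterable of WeightPanel
    gwas : GWAS summary DataFrame (SNP, A1, A2, Z).
    ld_by_gene : mapping gene id -> LD matrix over the panel's SNP order.
        The matrix rows/columns corresponding to dropped SNPs are subset
        automatically during harmonization.
    fdr_scope : ``"panel"`` (BH within each tissue panel, the default) or
        ``"global"`` (one BH pass over all rows).

    Returns
    -------
    DataFrame with columns GENE, PANEL, BEST.GWAS.ID, TWAS.Z, TWAS.P,
    FDR.P, MODELCV.R2, N.SNPS (Table-style naming).
    """
    if fdr_scope not in ("panel", "global"):
        raise ValueError("fdr_scope must be 'panel' or 'global'")
    rows = []
    for panel in panels:
        aligned = harmonize_alleles(panel, gwas)
        if aligned is None:
            continue
        w, z, kept = aligned
        ld = np.asarray(ld_by_gene[panel.gene], dtype=float)
        if ld.shape[0] != len(panel.snps):
            raise ValueError(f"{panel.gene}: LD dimension != panel SNP count")
        idx = [panel.snps.index(s) for s in kept]
        ld_sub = ld[np.ix_(idx, idx)]
        tz = twas_association(w, z, ld_sub, ridge=ridge)
        if tz is None:
            continue
        # best GWAS SNP: largest |z| among harmonized SNPs, ties by SNP id
        order = sorted(range(len(kept)), key=lambda i: (-abs(z[i]), kept[i]))
        rows.append(
            {
                "GENE": panel.gene,
                "PANEL": panel.panel,
                "BEST.GWAS.ID": kept[order[0]],
                "TWAS.Z": tz,
                "TWAS.P": two_sided_p(tz),
                "MODELCV.R2": panel.cv_r2,
                "N.SNPS": len(kept),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["GENE", "PANEL", "BEST.GWAS.ID", "TWAS.Z", "TWAS.P", "MODELCV.R2", "N.SNPS"],
    )
    if out.empty:
        out["FDR.P"] = pd.Series(dtype=float)
        return out
    if fdr_scope == "panel":
        out["FDR.P"] = out.groupby("PANEL")["TWAS.P"].transform(
            lambda s: benjamini_hochberg(s.to_numpy())
        )
    else:
        out["FDR.P"] = benjamini_hochberg(out["TWAS.P"].to_numpy())
    return out[
        ["GENE", "PANEL", "BEST.GWAS.ID", "TWAS.Z", "TWAS.P", "FDR.P", "MODELCV.R2", "N.SNPS"]
    ]


def filter_significant(
    results: pd.DataFrame, fdr_max: float = 0.05, r2_min: float = 0.01
) -> pd.DataFrame:
    """Significant genes: FDR.P strictly < fdr_max AND MODELCV.R2 >= r2_min."""
    if not (0 < fdr_max <= 1 and 0 <= r2_min <= 1):
        raise ValueError("thresholds outside their domain")
    mask = (results["FDR.P"] < fdr_max) & (results["MODELCV.R2"] >= r2_min)
    return results.loc[mask].reset_index(drop=True)


def panel_overlap(gene_lists: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts across per-panel significant gene lists.

    Returns a dict mapping each non-empty panel subset (sorted tuple) to the
    number of genes belonging to exactly those panels.  Region counts
    partition the union of all lists.
    """
    sets = {k: set(v) for k, v in gene_lists.items()}
    if len(sets) > 6:
        raise ValueError("at most 6 panels supported")
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set.union(*(sets[c] for c in names if c not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
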