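"""Synthetic data with planted ground truth for every pipeline stage.

The generators here emulate the shape of the real inputs an integrative
TWAS study consumes — GWAS summary Z-scores over LD blocks, sparse eQTL
weight panels with cross-validation R^2, two-batch case/control expression
matrices, chemical-gene GMT catalogs and confidence-scored interaction
networks — while planting known gene-trait effects, differential expression,
set enrichment and dense modules so that downstream stages can be tested
for calibration and recovery without any external download.

Conventions
-----------
* LD within a gene is first-order autoregressive (entry (i,j) = rho^|i-j|),
  genes are independent of each other.
* Expression is simulated directly on the log2-intensity scale (Gaussian),
  matching array data analyzed on log scale.
* One global seed expands into per-component child streams via
  ``numpy.random.SeedSequence`` spawn keys, so adding a generator never
  perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .twas import WeightPanel

#: fixed spawn keys for per-component child seeds
_STREAMS = {"ld": 1, "weights": 2, "gwas": 3, "expression": 4, "gene_sets": 5, "ppi": 6}

#: unambiguous allele pairs used for simulated SNPs (no A/T or C/G)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass
class SimulationConfig:
    """Knobs for the full synthetic study.

    Defaults mirror the scale of the real study where stated (two expression
    batches standing in for the two cohorts, ~30 cases vs ~45 controls is
    approximated by 30 per group; chemical sets between 10 and 500 genes;
    10,000 permutations) and a desk-scale gene count elsewhere.
    """

    seed: int = 0
    n_genes: int = 2000
    n_snps_per_gene: int = 5
    ld_rho: float = 0.5
    n_gwas: int = 12500
    causal_gene_fraction: float = 0.02
    effect_size: float = 6.0
    n_samples_per_group: int = 30
    n_batches: int = 2
    batch_shift: float = 2.0
    de_log2fc: float = 2.0
    n_chemical_sets: int = 200
    set_size_range: tuple[int, int] = (10, 500)
    n_permutations: int = 10000

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_snps_per_gene",
            "n_gwas",
            "n_samples_per_group",
            "n_batches",
            "n_chemical_sets",
            "n_permutations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.set_size_range
        if lo > hi:
            raise ValueError("set_size_range min must be <= max")


@dataclass
class GroundTruth:
    """Planted truth: what downstream stages are supposed to recover."""

    causal_genes: set[str] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)
    enriched_chemicals: list[str] = field(default_factory=list)
    planted_modules: list[set[str]] = field(default_factory=list)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_ld_block(n_snps: int, rho: float, seed: int = 0) -> np.ndarray:
    """AR(1) SNP correlation matrix: entry (i, j) = rho^|i-j|.

    Symmetric positive definite with unit diagonal for rho in [0, 1).
    (Deterministic; the seed argument is accepted for interface symmetry.)
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(n_snps)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_weight_panel(
    n_genes: int,
    n_snps_per_gene: int,
    sparsity: float = 0.6,
    seed: int = 0,
    panel: str = "MS",
    fraction_low_r2: float = 0.0,
) -> list[WeightPanel]:
    """Sparse eQTL weight panels with cross-validation R^2.

    Each gene receives ``max(1, round(sparsity * n_snps_per_gene))`` nonzero
    standard-normal weights.  Exactly ``round(fraction_low_r2 * n_genes)``
    genes get cv R^2 below 0.01 (to exercise the model-quality filter);
    the rest draw cv R^2 uniformly from [0.01, 0.8].
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    rng = _rng(seed, "weights")
    genes = gene_ids(n_genes)
    n_low = int(round(fraction_low_r2 * n_genes))
    low_idx = set(rng.choice(n_genes, size=n_low, replace=False).tolist())
    n_nonzero = max(1, int(round(sparsity * n_snps_per_gene)))
    panels = []
    for gi, gene in enumerate(genes):
        snps = [f"rs{gi * n_snps_per_gene + j + 1}" for j in range(n_snps_per_gene)]
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps_per_gene)
        a1 = [_ALLELE_PAIRS[k][0] for k in pair_idx]
        a2 = [_ALLELE_PAIRS[k][1] for k in pair_idx]
        w = np.zeros(n_snps_per_gene)
        nz = rng.choice(n_snps_per_gene, size=n_nonzero, replace=False)
        w[nz] = rng.standard_normal(n_nonzero)
        # guard the degenerate draw of an exactly-zero weight
        w[nz[np.abs(w[nz]) < 1e-12]] = 1.0
        if gi in low_idx:
            cv_r2 = rng.uniform(0.0, 0.0099)
        else:
            cv_r2 = rng.uniform(0.01, 0.8)
        panels.append(
            WeightPanel(gene=gene, panel=panel, snps=snps, a1=a1, a2=a2, weights=w, cv_r2=cv_r2)
        )
    return panels


def simulate_gwas_z(
    panels: Sequence[WeightPanel],
    ld_by_gene: Mapping[str, np.ndarray],
    causal_genes: set[str] | None = None,
    effect_size: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP GWAS Z-score table consistent with the LD structure.

    For a non-causal gene the SNP Z-vector is multivariate normal with mean
    zero and covariance equal to the gene's LD matrix, so the downstream TWAS
    statistic is exactly standard normal under the null.  For a causal gene
    the mean is ``Sigma @ w * effect_size`` — the pattern a true
    expression-mediated effect induces on marginal SNP statistics — giving
    the TWAS statistic a noncentrality of ``effect_size * sqrt(w' Sigma w)``
    (see :func:`twas_noncentrality`).
    """
    causal_genes = causal_genes or set()
    missing = causal_genes - {p.gene for p in panels}
    if missing:
        raise ValueError(f"causal genes not in panel: {sorted(missing)[:5]}")
    rng = _rng(seed, "gwas")
    rows = []
    for panel in panels:
        ld = np.asarray(ld_by_gene[panel.gene], dtype=float)
        if ld.shape[0] != len(panel.snps):
            raise ValueError(f"{panel.gene}: LD dimension mismatch")
        chol = np.linalg.cholesky(ld)
        z = chol @ rng.standard_normal(len(panel.snps))
        if panel.gene in causal_genes and effect_size != 0.0:
            z = z + ld @ panel.weights * effect_size
        for snp, a1, a2, zz in zip(panel.snps, panel.a1, panel.a2, z):
            rows.append((snp, a1, a2, zz))
    return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "Z"])


def twas_noncentrality(panel: WeightPanel, ld: np.ndarray, effect_size: float) -> float:
    """Expected TWAS Z for a causal gene: effect_size * sqrt(w' Sigma w)."""
    w = panel.weights
    return effect_size * float(np.sqrt(w @ np.asarray(ld, dtype=float) @ w))


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    n_batches: int = 2,
    de_genes: Mapping[str, float] | None = None,
    batch_shift: float = 2.0,
    batch_scale: float = 0.25,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group expression matrix on log2 scale with batch artifacts.

    Samples are split evenly between cases and controls and assigned to
    batches in a balanced round-robin within each group, so batch and group
    are not confounded.  Batch ``b`` adds a location shift ``b * batch_shift``
    and a scale factor ``1 + batch_scale * b`` on the gene-level noise
    (``batch_shift=0`` with ``batch_scale=0`` makes batches identically
    distributed).  For each
    planted gene, the case-minus-control mean difference equals its log2
    fold-change; all other genes differ only by noise.

    Returns (matrix genes x samples, annotation with sample/group/batch).
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    de_genes = dict(de_genes or {})
    genes = gene_ids(n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in de_genes:
        if g not in gene_index:
            raise ValueError(f"planted DE gene {g} not among the {n_genes} genes")
    rng = _rng(seed, "expression")
    n_samples = 2 * n_per_group
    groups = np.array(["case"] * n_per_group + ["control"] * n_per_group)
    batches = np.empty(n_samples, dtype=int)
    batches[:n_per_group] = np.arange(n_per_group) % n_batches
    batches[n_per_group:] = np.arange(n_per_group) % n_batches
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    mat = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for b in range(n_batches):
        cols = batches == b
        scale = 1.0 + batch_scale * b
        mat[:, cols] = baseline[:, None] + (mat[:, cols] - baseline[:, None]) * scale
        mat[:, cols] += b * batch_shift
    for g, lfc in de_genes.items():
        mat[gene_index[g], groups == "case"] += lfc
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    matrix = pd.DataFrame(mat, index=genes, columns=samples)
    ann = pd.DataFrame({"sample": samples, "group": groups, "batch": [f"B{b+1}" for b in batches]})
    return matrix, ann


def simulate_gene_sets(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    enriched_sets: Mapping[str, tuple[int, float]] | None = None,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """GMT-style chemical/annotation catalog with optional planted enrichment.

    ``universe`` must be ordered by the ranking statistic (best first) for
    the enrichment planting to be meaningful.  Unplanted sets sample
    uniformly from the universe with sizes uniform in ``size_range``.  A
    planted set ``set_id -> (n_top_genes, rank_bias)`` draws a fraction
    ``rank_bias`` of its members from the top ``n_top_genes`` of the ranking
    and the rest uniformly, so its members concentrate at the top of the
    list.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    lo, hi = size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValueError("size_range outside [1, |universe|]")
    enriched_sets = dict(enriched_sets or {})
    rng = _rng(seed, "gene_sets")
    catalog: dict[str, tuple[str, list[str]]] = {}
    plain_ids = [f"CHEM{i:04d}" for i in range(1, n_sets + 1)]
    for sid in plain_ids:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        catalog[sid] = (f"chemical {sid}", [universe[i] for i in sorted(members)])
    for sid, (n_top, bias) in enriched_sets.items():
        size = int(rng.integers(lo, hi + 1))
        n_biased = min(int(round(bias * size)), n_top, size)
        top = rng.choice(min(n_top, len(universe)), size=n_biased, replace=False)
        rest_pool = np.arange(len(universe))
        rest_pool = rest_pool[~np.isin(rest_pool, top)]
        rest = rng.choice(rest_pool, size=size - n_biased, replace=False)
        members = sorted(set(top.tolist()) | set(rest.tolist()))
        catalog[sid] = (f"enriched chemical {sid}", [universe[i] for i in members])
    return catalog


def simulate_ppi(
    n_vertices: int,
    planted_cliques: Sequence[int] = (),
    background_edge_prob: float = 0.02,
    score_range: tuple[float, float] = (0.15, 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Confidence-scored interaction edge list with planted dense modules.

    Clique members are fully connected with scores in the top fifth of
    ``score_range``; background edges follow an Erdos-Renyi model with
    uniform scores over the full range.

    Returns (edge list DataFrame [node1, node2, combined_score], GroundTruth
    with the planted vertex sets).
    """
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ValueError("background_edge_prob must lie in [0, 1]")
    if sum(planted_cliques) > n_vertices:
        raise ValueError("sum of clique sizes exceeds n_vertices")
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("score_range must lie within [0, 1]")
    rng = _rng(seed, "ppi")
    vertices = [f"V{i:04d}" for i in range(1, n_vertices + 1)]
    edges: dict[tuple[str, str], float] = {}
    truth = GroundTruth()
    start = 0
    for size in planted_cliques:
        members = vertices[start : start + size]
        start += size
        truth.planted_modules.append(set(members))
        for i in range(size):
            for j in range(i + 1, size):
                score = rng.uniform(hi - 0.2 * (hi - lo), hi)
                edges[(members[i], members[j])] = score
    if background_edge_prob > 0:
        for i in range(n_vertices):
            draws = rng.random(n_vertices - i - 1)
            for off, d in enumerate(draws):
                j = i + 1 + off
                if d < background_edge_prob:
                    key = (vertices[i], vertices[j])
                    if key not in edges:
                        edges[key] = rng.uniform(lo, hi)
    rows = [(a, b, s) for (a, b), s in edges.items()]
    df = pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
    return df, truth
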