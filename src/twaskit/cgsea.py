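"""Chemical gene-set enrichment against a genome-wide TWAS ranking (CGSEA).

Chemical-gene catalogs (CTD-style) list, per chemical, the genes whose
expression the chemical perturbs.  CGSEA asks whether those genes cluster at
either extreme of a genome-wide ranking of gene-trait association (here the
pooled TWAS Z-scores): a weighted Kolmogorov-Smirnov running sum walks down
the ranking, stepping up by |stat|^weight_exp at member genes and down by a
uniform miss increment elsewhere; the enrichment score (ES) is the signed
maximum deviation.  Significance comes from a gene-label permutation null —
random member subsets of the same size drawn from the ranking — with an
empirical one-sided p floored at 1/n_perm, and a normalized ES (NES)
obtained by dividing the observed ES by the mean same-sign null magnitude.

Only summary statistics exist at this stage of the pipeline, so phenotype
permutation is impossible; gene-label permutation matches preranked-GSEA
practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import GeneSetCatalog
from .twas import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes sorted by a real-valued statistic, best (largest) first.

    Ties are broken by lexicographic gene id; duplicate genes are invalid.
    """

    genes: np.ndarray
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if self.genes.size != self.stats.size:
            raise ValueError("genes and stats lengths differ")
        if len(set(self.genes.tolist())) != self.genes.size:
            raise ValueError("duplicate gene ids in ranked list")
        order = sorted(range(self.genes.size), key=lambda i: (-self.stats[i], self.genes[i]))
        self.genes = self.genes[order]
        self.stats = self.stats[order]

    @classmethod
    def from_scores(cls, scores: dict[str, float] | pd.Series) -> "RankedList":
        items = dict(scores)
        return cls(np.array(list(items.keys()), dtype=object), np.array(list(items.values())))

    def __len__(self) -> int:
        return int(self.genes.size)


def pool_twas(results: pd.DataFrame, pooling: str = "max_abs") -> RankedList:
    """Pool a multi-panel TWAS table into one statistic per gene.

    ``max_abs`` keeps each gene's largest-|Z| panel entry (sign retained);
    ``mean`` averages the gene's Z across panels.
    """
    if pooling == "max_abs":
        idx = results.groupby("GENE")["TWAS.Z"].apply(lambda s: s.abs().idxmax())
        scores = results.loc[idx].set_index("GENE")["TWAS.Z"]
    elif pooling == "mean":
        scores = results.groupby("GENE")["TWAS.Z"].mean()
    else:
        raise ValueError("pooling must be 'max_abs' or 'mean'")
    return RankedList.from_scores(scores)


def size_filter(
    catalog: GeneSetCatalog,
    ranked: RankedList,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCatalog:
    """Intersect sets with the ranked genes; drop sets outside [min, max]."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    present = set(ranked.genes.tolist())
    kept: dict[str, tuple[str, list[str]]] = {}
    for sid, (desc, members) in catalog.sets.items():
        inter = [g for g in members if g in present]
        if min_size <= len(inter) <= max_size:
            kept[sid] = (desc, inter)
    return GeneSetCatalog(sets=kept, universe=list(catalog.universe))


def _running_sum(
    stats_abs_w: np.ndarray, hit: np.ndarray
) -> np.ndarray:
    """Deviation P_hit(i) - P_miss(i) along the ranking for one hit mask."""
    n = hit.size
    n_hits = int(hit.sum())
    hit_w = np.where(hit, stats_abs_w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = hit.astype(float)  # uniform fallback when all |stat|^w are 0
        total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~hit) / (n - n_hits)
    return p_hit - p_miss


def enrichment_score(
    ranked: RankedList, members: set[str] | list[str], weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    ``weight_exp=0`` reduces to the classic (unweighted) KS statistic; the
    default 1.0 weights hit increments by |stat|.  If every member's
    |stat|^weight_exp is zero the hit increments fall back to uniform
    (logged).  ES lies in [-1, 1].
    """
    if weight_exp < 0:
        raise ValueError("weight_exp must be nonnegative")
    members = set(members)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("no set member present in the ranked list")
    if n_hits == len(ranked):
        raise ValueError("set covers the whole ranked list; P_miss undefined")
    w = np.abs(ranked.stats) ** weight_exp if weight_exp != 0 else np.ones(len(ranked))
    if weight_exp > 0 and np.all(w[hit] == 0):
        logger.warning("all member |stat| are zero; falling back to uniform increments")
    dev = _running_sum(w, hit)
    es = float(dev[np.argmax(np.abs(dev))])
    return es, dev


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 10000,
    weight_exp: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Null ES sample from gene-label permutation.

    Each permutation draws a uniform random subset of ``set_size`` genes
    from the ranked list and records its ES.  Reproducible given the seed;
    within a run the null for a given set size can be shared across all
    chemicals of that size.
    """
    n = len(ranked)
    if set_size >= n:
        raise ValueError("set_size must be smaller than the ranked list")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.stats) ** weight_exp if weight_exp != 0 else np.ones(n)
    miss_step = 1.0 / (n - set_size)
    out = np.empty(n_perm)
    # vectorized in blocks to bound memory at ~ block * n floats
    block = max(1, int(2e6 // n))
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        # b uniform subsets without replacement, drawn as top-k of random keys
        keys = rng.random((b, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        hit_w = np.zeros((b, n))
        rows = np.repeat(np.arange(b), set_size)
        hit_w[rows, idx.ravel()] = w[idx.ravel()]
        totals = hit_w.sum(axis=1, keepdims=True)
        zero = totals[:, 0] <= 0
        if np.any(zero):
            hit_ind = np.zeros((b, n))
            hit_ind[rows, idx.ravel()] = 1.0
            hit_w[zero] = hit_ind[zero]
            totals = hit_w.sum(axis=1, keepdims=True)
        p_hit = np.cumsum(hit_w, axis=1) / totals
        miss = np.full((b, n), miss_step)
        miss[rows, idx.ravel()] = 0.0
        p_miss = np.cumsum(miss, axis=1)
        dev = p_hit - p_miss
        arg = np.argmax(np.abs(dev), axis=1)
        out[start : start + b] = dev[np.arange(b), arg]
    return out


def empirical_p(es_obs: float, null: np.ndarray, side: str = "greater") -> float:
    """Empirical tail probability of an observed ES, floored at 1/n_perm.

    ``side="greater"`` (default) is the upper tail on the signed score,
    p = max(#{null >= es_obs}, 1) / n_perm: with the ranking statistic
    signed so that risk-increasing association sorts to the top,
    enrichment of trait-associated genes shows up as a large positive ES,
    and under the null this p is exactly uniform on the 1/n_perm grid.
    ``side="signed"`` mirrors the tail to the side of the observed score's
    sign (detects bottom-of-list concentration as well, at the cost of
    null uniformity of the resulting p).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    if side not in ("greater", "signed"):
        raise ValueError("side must be 'greater' or 'signed'")
    if side == "signed" and es_obs < 0:
        count = int(np.sum(null <= es_obs))
    else:
        count = int(np.sum(null >= es_obs))
    return max(count, 1) / null.size


def normalized_es(es_obs: float, null: np.ndarray) -> float:
    """ES divided by the mean magnitude of same-sign null scores.

    NES keeps the sign of the observed ES; if no same-sign null score
    exists the value is undefined and NaN is returned with a warning.
    """
    null = np.asarray(null, dtype=float)
    if es_obs == 0:
        return 0.0
    same = null[null > 0] if es_obs > 0 else null[null < 0]
    if same.size == 0 or np.mean(np.abs(same)) == 0:
        logger.warning("no same-sign null scores; NES undefined")
        return float("nan")
    return float(es_obs / np.mean(np.abs(same)))


def cgsea_run(
    ranked: RankedList,
    catalog: GeneSetCatalog,
    n_perm: int = 10000,
    weight_exp: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
    seed: int = 0,
    side: str = "greater",
) -> pd.DataFrame:
    """Full CGSEA pass: size filter, ES, shared permutation null, BH-FDR.

    Null ES samples are cached per set size within the run (all chemicals
    with the same effective size share one null, seeded deterministically
    from ``seed`` and the size).  Output columns mirror the chemical table:
    CHEMICAL.ID, CHEMICAL.NAME, ES, NES, P, FDR, SIZE.
    """
    surviving = size_filter(catalog, ranked, min_size=min_size, max_size=max_size)
    if not surviving.sets:
        logger.warning("no gene set survives the size filter")
        return pd.DataFrame(
            columns=["CHEMICAL.ID", "CHEMICAL.NAME", "ES", "NES", "P", "FDR", "SIZE"]
        )
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for sid in sorted(surviving.sets):
        desc, members = surviving.sets[sid]
        size = len(members)
        es, _ = enrichment_score(ranked, members, weight_exp=weight_exp)
        if size not in null_cache:
            child = np.random.default_rng([seed, size]).integers(0, 2**31 - 1)
            null_cache[size] = permutation_null(
                ranked, size, n_perm=n_perm, weight_exp=weight_exp, seed=int(child)
            )
        null = null_cache[size]
        rows.append(
            {
                "CHEMICAL.ID": sid,
                "CHEMICAL.NAME": desc,
                "ES": es,
                "NES": normalized_es(es, null),
                "P": empirical_p(es, null, side=side),
                "SIZE": size,
            }
        )
    out = pd.DataFrame(rows)
    out["FDR"] = benjamini_hochberg(out["P"].to_numpy())
    out = out.sort_values(["P", "CHEMICAL.ID"], kind="mergesort").reset_index(drop=True)
    return out[["CHEMICAL.ID", "CHEMICAL.NAME", "ES", "NES", "P", "FDR", "SIZE"]]
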