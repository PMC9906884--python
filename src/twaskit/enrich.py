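"""Gene-list intersection and hypergeometric over-representation analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .twas import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Flat gene-set catalog (GMT semantics) with a background universe.

    ``sets`` maps a set id to ``(description, member gene list)``; members
    are de-duplicated on construction, as is the universe.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sets = {
            sid: (desc, list(dict.fromkeys(members)))
            for sid, (desc, members) in self.sets.items()
        }
        self.universe = list(dict.fromkeys(self.universe))


def intersect_genes(twas_genes: Iterable[str], deg_genes: Iterable[str]) -> list[str]:
    """Exact set intersection, sorted lexicographically for determinism."""
    return sorted(set(twas_genes) & set(deg_genes))


def hypergeom_ora(
    study: Iterable[str],
    catalog: GeneSetCatalog,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per catalog set.

    With N universe genes, K of them in the set, and a study list of n
    genes overlapping the set in k, the enrichment p-value is the upper
    tail P[X >= k] for X ~ Hypergeometric(N, K, n).  BH adjustment runs
    across all tested sets.  Study genes outside the universe are dropped
    with a warning; sets are restricted to the universe and those smaller
    than ``min_set_size`` after restriction are not tested.
    """
    universe = set(catalog.universe)
    if not universe:
        raise ValueError("empty universe")
    study_set = set(study)
    dropped = study_set - universe
    if dropped:
        logger.warning("%d study genes outside the universe dropped", len(dropped))
    study_set &= universe
    N, n = len(universe), len(study_set)
    rows = []
    for sid in sorted(catalog.sets):
        desc, members = catalog.sets[sid]
        in_universe = set(members) & universe
        K = len(in_universe)
        if K < min_set_size:
            continue
        k = len(in_universe & study_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sid, desc, k, K, n, N, min(max(p, 5e-324), 1.0)))
    out = pd.DataFrame(
        rows, columns=["ID", "Description", "k", "K", "n", "N", "pvalue"]
    )
    if out.empty:
        out["p.adjust"] = pd.Series(dtype=float)
        return out
    out["p.adjust"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out
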