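"""Readers and writers for the pipeline's interchange formats.

Everything on disk is tab-separated text: GWAS summary tables, weight-panel
manifests with per-gene weight files, LD matrices, expression matrices with
sample annotations, GMT gene-set catalogs and STRING-style edge lists.
Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCatalog
from .twas import WeightPanel

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


# ---------------------------------------------------------------- tables


def read_table(
    path: str | Path,
    required: Mapping[str, type] | Sequence[str],
) -> pd.DataFrame:
    """Read a TSV with a header and validate required columns.

    ``required`` is either a list of column names or a mapping name ->
    numeric type to coerce.  Extra columns and row order are preserved.
    Raises :class:`FormatError` naming any missing column, or the first
    unparseable numeric cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    names = list(required.keys()) if isinstance(required, Mapping) else list(required)
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if isinstance(required, Mapping):
        for col, typ in required.items():
            if typ in (float, int):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise FormatError(
                        f"{path.name}: unparseable numeric cell at row {row + 2}, "
                        f"column {col!r}: {df.loc[row, col]!r}"
                    )
                df[col] = coerced.astype(typ)
    return df


def read_gwas(path: str | Path) -> pd.DataFrame:
    """GWAS summary TSV with columns SNP, A1, A2, Z."""
    return read_table(path, {"SNP": str, "A1": str, "A2": str, "Z": float})


def write_gwas(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- weights/LD


def write_weight_panels(
    panels: Sequence[WeightPanel],
    ld_by_gene: Mapping[str, np.ndarray],
    outdir: str | Path,
) -> Path:
    """Write a manifest plus one weight TSV and one LD TSV per gene.

    Returns the manifest path.  Manifest columns: GENE, PANEL, CVR2,
    WEIGHT_FILE, LD_FILE.
    """
    outdir = Path(outdir)
    (outdir / "weights").mkdir(parents=True, exist_ok=True)
    (outdir / "ld").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in panels:
        wfile = f"weights/{p.gene}.{p.panel}.tsv"
        pd.DataFrame(
            {"SNP": p.snps, "A1": p.a1, "A2": p.a2, "WEIGHT": p.weights}
        ).to_csv(outdir / wfile, sep="\t", index=False)
        lfile = f"ld/{p.gene}.tsv"
        if not (outdir / lfile).exists():
            np.savetxt(outdir / lfile, np.asarray(ld_by_gene[p.gene]), delimiter="\t")
        rows.append((p.gene, p.panel, p.cv_r2, wfile, lfile))
    manifest = outdir / "weights_manifest.tsv"
    pd.DataFrame(rows, columns=["GENE", "PANEL", "CVR2", "WEIGHT_FILE", "LD_FILE"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def read_weight_panels(
    manifest_path: str | Path,
) -> tuple[list[WeightPanel], dict[str, np.ndarray]]:
    """Read panels and LD matrices back from a manifest written above."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    man = read_table(manifest_path, {"GENE": str, "PANEL": str, "CVR2": float})
    panels = []
    ld: dict[str, np.ndarray] = {}
    for rec in man.itertuples(index=False):
        w = read_table(base / rec.WEIGHT_FILE, {"SNP": str, "A1": str, "A2": str, "WEIGHT": float})
        panels.append(
            WeightPanel(
                gene=rec.GENE,
                panel=rec.PANEL,
                snps=w["SNP"].tolist(),
                a1=w["A1"].tolist(),
                a2=w["A2"].tolist(),
                weights=w["WEIGHT"].to_numpy(),
                cv_r2=float(rec.CVR2),
            )
        )
        if rec.GENE not in ld:
            ld[rec.GENE] = np.loadtxt(base / rec.LD_FILE, delimiter="\t", ndmin=2)
    return panels, ld


# ---------------------------------------------------------------- expression


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{Path(path).name}: missing values in expression matrix")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="GENE")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return read_table(path, ["sample", "group", "batch"])


# ---------------------------------------------------------------- GMT


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file: per line, set id, description, then member genes.

    Duplicate members within a set are de-duplicated with a warning; empty
    member fields are skipped.  A line with fewer than three fields raises
    :class:`FormatError` naming the line number.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    universe: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: GMT line has < 3 fields")
            sid, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: duplicate members in set %s", path.name, lineno, sid)
            sets[sid] = (desc, deduped)
            universe.extend(deduped)
    return GeneSetCatalog(sets=sets, universe=universe)


def write_gmt(catalog: GeneSetCatalog | Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    sets = catalog.sets if isinstance(catalog, GeneSetCatalog) else catalog
    with open(path, "w") as fh:
        for sid, (desc, members) in sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------- edges


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """STRING-style edge list (node1, node2, combined_score).

    Integer scores on the 0-1000 convention are auto-detected (any score
    above 1) and divided by 1000.
    """
    df = read_table(path, {"node1": str, "node2": str, "combined_score": float})
    if (df["combined_score"] > 1.0).any():
        df = df.assign(combined_score=df["combined_score"] / 1000.0)
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)
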