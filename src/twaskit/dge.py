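"""Batch adjustment and moderated-t differential expression.

Two-cohort microarray studies carry batch artifacts (per-batch location and
scale shifts) that swamp the case/control contrast.  The screening pipeline
here mirrors standard array practice: empirical-Bayes location/scale batch
adjustment (ComBat) with the group label protected as a covariate, followed
by an empirical-Bayes moderated two-sample t-test in which per-gene residual
variances are shrunk toward a pooled prior, and a Benjamini-Hochberg pass.
Differentially expressed genes are those with |log2FC| > 1 and adjusted
p < 0.05 (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .twas import benjamini_hochberg

logger = logging.getLogger(__name__)


def _check_study(matrix: pd.DataFrame, groups: pd.Series, batches: pd.Series) -> None:
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if groups.value_counts().min() < 2:
        raise ValueError("need >= 2 samples per group")
    if batches.value_counts().min() < 2:
        raise ValueError("a batch with a single sample has undefined variance")


def combat_adjust(
    matrix: pd.DataFrame, groups: pd.Series | list, batches: pd.Series | list
) -> pd.DataFrame:
    """Remove per-batch location/scale effects by parametric empirical Bayes.

    The group label enters the standardization design as a covariate so the
    case/control contrast is preserved.  With a single batch the matrix is
    returned unchanged (identity path).  Gene and sample order are never
    permuted.

    Parameters
    ----------
    matrix : genes x samples DataFrame on log2 scale.
    groups, batches : per-sample labels aligned with the matrix columns.
    """
    groups = pd.Series(list(groups), index=matrix.columns)
    batches = pd.Series(list(batches), index=matrix.columns)
    if batches.nunique() == 1:
        return matrix.copy()
    _check_study(matrix, groups, batches)

    import anndata as ad  # deferred: heavy import
    import scanpy as sc

    # group enters as a numeric indicator: a one-hot categorical covariate
    # would make the batch+covariate design rank-deficient
    group_levels = sorted(groups.astype(str).unique())
    group_ind = groups.astype(str).map({g: float(i) for i, g in enumerate(group_levels)})
    adata = ad.AnnData(
        X=matrix.to_numpy(dtype=float).T.copy(),
        obs=pd.DataFrame(
            {"batch": batches.astype(str).values, "group": group_ind.values},
            index=matrix.columns.astype(str),
        ),
    )
    adata.obs["batch"] = adata.obs["batch"].astype("category")
    sc.pp.combat(adata, key="batch", covariates=["group"])
    out = pd.DataFrame(adata.X.T, index=matrix.index, columns=matrix.columns)
    return out


def _invert_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in variance-shrinkage EB)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi^2 variance prior.

    Matches the first two moments of log s_g^2 (corrected by digamma terms)
    to the theoretical distribution, returning (d0, s0_sq).  A non-positive
    excess variance yields d0 = inf, i.e. all gene variances equal s0_sq.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError("all residual variances are zero: degenerate input")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0 or not np.isfinite(excess):
        logger.info("variance prior: no excess dispersion; using d0 = inf")
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _invert_trigamma(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    matrix: pd.DataFrame,
    groups: pd.Series | list,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test, one row per gene.

    Per gene, the two-group fit gives log2fc (case minus control) and pooled
    residual variance s_g^2 with d_g = n1 + n2 - 2 degrees of freedom.  The
    prior (d0, s0^2) is estimated from all genes (or forced via ``prior_df``
    / ``prior_var``), the posterior variance is

        s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

    and t~ = log2fc / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a t
    distribution with d0 + d_g degrees of freedom.  ``prior_df=0`` recovers
    the ordinary two-sample t; ``prior_df=inf`` fixes every variance at s0^2.

    Returns a DataFrame with columns GENE, logFC, t, P.Value, adj.P.
    """
    groups = pd.Series(list(groups), index=matrix.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    # 'case'/'control' convention: case first when present, else sorted order
    case = "case" if "case" in labels else labels[0]
    ctrl = [l for l in labels if l != case][0]
    x1 = matrix.loc[:, groups == case].to_numpy(dtype=float)
    x2 = matrix.loc[:, groups == ctrl].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero: degenerate input")

    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_variance_prior(s2, df_resid)
        d0 = d0_est if prior_df is None else prior_df
        s0_sq = s0_est if prior_var is None else prior_var
    else:
        d0, s0_sq = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "GENE": matrix.index,
            "logFC": lfc,
            "t": t,
            "P.Value": p,
            "adj.P": benjamini_hochberg(p),
        }
    ).reset_index(drop=True)


def deg_filter(
    results: pd.DataFrame, lfc_min: float = 1.0, adjp_max: float = 0.05
) -> pd.DataFrame:
    """Differentially expressed genes: |log2FC| > lfc_min AND adj.P < adjp_max.

    Both inequalities are strict.
    """
    if lfc_min < 0 or not 0 < adjp_max <= 1:
        raise ValueError("thresholds outside their domain")
    if results.empty:
        return results.copy()
    mask = (results["logFC"].abs() > lfc_min) & (results["adj.P"] < adjp_max)
    return results.loc[mask].reset_index(drop=True)
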