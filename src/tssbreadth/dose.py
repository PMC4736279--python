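"""Dose-response of transcription to region-specific H3K4me3 change.

Percent H3K4me3 change at the upstream / TSS / downstream regions is
computed on the linear (background-relative) scale from the log2 summaries,
each region is residualized against the other two by ordinary least squares
(with the grand mean added back so the sign keeps its increase/decrease
meaning), and the response curve bins genes by integer % H3K4me3 change and
fits the slope of mean transcription change over the 1-10 % range.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("upstream", "tss", "downstream")


def region_changes(ctrl_summary: pd.DataFrame, case_summary: pd.DataFrame,
                   de: pd.DataFrame) -> pd.DataFrame:
    """Per-gene % H3K4me3 change per region joined with transcription change.

    A difference of d log2 units becomes 100 * (2^d - 1) percent, so +1 log2
    unit is +100 % and -1 log2 unit is -50 %. Genes missing from any of the
    three tables are dropped with a log message.
    """
    ctrl = ctrl_summary.set_index("gene_id")
    case = case_summary.set_index("gene_id")
    ded = de.set_index("gene_id")
    shared = ctrl.index.intersection(case.index).intersection(ded.index)
    dropped = max(len(ctrl), len(case), len(ded)) - len(shared)
    if dropped:
        logger.info("dropping %d genes absent from one of the tables", dropped)
    cols = {"upstream": "upstream_mean", "tss": "tss_mean",
            "downstream": "downstream_mean"}
    out = pd.DataFrame({"gene_id": shared})
    for region, col in cols.items():
        d = case.loc[shared, col].to_numpy() - ctrl.loc[shared, col].to_numpy()
        out[region] = 100.0 * (2.0 ** d - 1.0)
    out["transcription"] = ded.loc[shared, "pct_change"].to_numpy()
    if "de_flag" in ded:
        out["de_flag"] = ded.loc[shared, "de_flag"].to_numpy()
    return out


def residualize(table: pd.DataFrame,
                regions: tuple[str, ...] = REGIONS) -> pd.DataFrame:
    """Remove each region's linear dependence on the other two regions.

    Adds ``<region>_resid`` columns: OLS residual of the region's % change on
    the other two regions' raw % changes (with intercept), plus the region's
    grand mean so "increased" keeps its sign meaning. Collinear regressors
    fall back to a single-regressor fit with a warning.
    """
    if len(table) < 30:
        raise ValueError("need at least 30 genes to residualize")
    out = table.copy()
    X_all = {r: table[r].to_numpy(dtype=float) for r in regions}
    n = len(table)
    for region in regions:
        y = X_all[region]
        others = [r for r in regions if r != region]
        X = np.column_stack([np.ones(n)] + [X_all[r] for r in others])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("collinear regressors for %s; single-regressor fit",
                           region)
            X = np.column_stack([np.ones(n), X_all[others[0]]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[f"{region}_resid"] = resid + y.mean()
    return out


def response_curve(table: pd.DataFrame, region: str = "downstream",
                   use_residualized: bool = True,
                   bin_range: tuple[int, int] = (-10, 10),
                   slope_range: tuple[float, float] = (1.0, 10.0)
                   ) -> tuple[pd.DataFrame, float, float]:
    """Mean transcription change per integer bin of % H3K4me3 change.

    Genes are grouped by rounding the region's % change to the nearest
    integer within ``bin_range``; each bin reports the mean % transcription
    change, its standard error over genes, and the gene count. The slope is
    an unweighted least-squares fit of the bin means against the bin centers
    over ``slope_range``; empty bins are omitted from the fit.

    Returns (curve, slope, slope_se).
    """
    col = f"{region}_resid" if use_residualized else region
    x = table[col].to_numpy(dtype=float)
    y = table["transcription"].to_numpy(dtype=float)
    centers = np.rint(x).astype(int)
    rows = []
    for c in range(bin_range[0], bin_range[1] + 1):
        sel = centers == c
        m = int(sel.sum())
        if m == 0:
            continue
        vals = y[sel]
        rows.append({"bin_center": c, "mean_transcription": float(vals.mean()),
                     "se": float(vals.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
                     "n": m})
    curve = pd.DataFrame(rows)
    fitsel = curve[(curve["bin_center"] >= slope_range[0])
                   & (curve["bin_center"] <= slope_range[1])]
    if len(fitsel) < 2:
        return curve, np.nan, np.nan
    xs = fitsel["bin_center"].to_numpy(dtype=float)
    ys = fitsel["mean_transcription"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(xs)), xs])
    beta, res, *_ = np.linalg.lstsq(X, ys, rcond=None)
    dof = len(xs) - 2
    if dof > 0:
        s2 = float(((ys - X @ beta) ** 2).sum() / dof)
        cov = s2 * np.linalg.inv(X.T @ X)
        slope_se = float(np.sqrt(cov[1, 1]))
    else:
        slope_se = np.nan
    return curve, float(beta[1]), slope_se


def fraction_increased(table: pd.DataFrame, genes,
                       use_residualized: bool = True) -> pd.DataFrame:
    """Fraction of the listed genes with a positive change per region.

    Computed on the residualized changes by default, with the binomial
    standard error sqrt(p (1 - p) / n).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    sub = table[table["gene_id"].isin(genes)]
    rows = []
    for region in REGIONS:
        col = f"{region}_resid" if use_residualized else region
        vals = sub[col].to_numpy(dtype=float)
        n = len(vals)
        frac = float((vals > 0).mean())
        rows.append({"region": region, "fraction_increased": frac,
                     "se": float(np.sqrt(frac * (1 - frac) / n)), "n": n})
    return pd.DataFrame(rows)


def external_geneset_summary(table: pd.DataFrame,
                             gene_lists: dict[str, list[str]],
                             use_residualized: bool = False) -> pd.DataFrame:
    """Zero-centered mean region change for external gene lists.

    Region changes are centered so the average over all genes in the table is
    zero at each region, then averaged within each list; the SE is the
    one-sample standard error over the list's genes.
    """
    rows = []
    cols = {r: (f"{r}_resid" if use_residualized else r) for r in REGIONS}
    centered = {r: table[c].to_numpy(dtype=float) - table[c].mean()
                for r, c in cols.items()}
    ids = table["gene_id"].to_numpy()
    for name, genes in gene_lists.items():
        sel = np.isin(ids, list(genes))
        n = int(sel.sum())
        if n < 5:
            logger.warning("gene list %s overlaps only %d table genes", name, n)
        for region in REGIONS:
            vals = centered[region][sel]
            rows.append({
                "gene_list": name, "region": region, "n": n,
                "mean_change": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            })
    return pd.DataFrame(rows)
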