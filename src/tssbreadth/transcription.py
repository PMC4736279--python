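"""Association of breadth patterns with transcription and gene function.

Covers the four association analyses: expression level by pattern (rank-sum
test against the unclassified reference), between-sample variance with the
level dependence removed by Loess, per-pattern Fisher odds ratios against
differential-expression status, and hypergeometric gene-set
overrepresentation with Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .classify import FOUR_PATTERNS

logger = logging.getLogger(__name__)

REFERENCE_LABELS = ("unclassified", "unmarked")
DE_P_THRESHOLD = 0.01


def flag_differential(de: pd.DataFrame,
                      p_threshold: float = DE_P_THRESHOLD) -> pd.DataFrame:
    """(Re)derive DE flags from p-values and the sign of the % change."""
    out = de.copy()
    sig = out["p_value"] < p_threshold
    out["de_flag"] = np.where(~sig, "neither",
                              np.where(out["pct_change"] > 0,
                                       "increased", "decreased"))
    return out


def exclude_multi_tss_genes(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose multiple TSSs carry different four-pattern labels."""
    pat = calls[calls["label"].isin(FOUR_PATTERNS)]
    n_labels = pat.groupby("gene_id")["label"].nunique()
    conflicted = set(n_labels[n_labels > 1].index)
    if conflicted:
        logger.warning("excluding %d genes with conflicting TSS patterns",
                       len(conflicted))
    return calls[~calls["gene_id"].isin(conflicted)]


def expression_by_pattern(expr_means: pd.Series, calls: pd.DataFrame,
                          reference_labels: tuple[str, ...] = REFERENCE_LABELS
                          ) -> pd.DataFrame:
    """Mean expression per breadth pattern, relative to the reference group.

    ``expr_means`` maps gene_id to mean (linear-scale) expression. For each
    four-pattern group the % difference of the mean against the reference
    group (unclassified/unmarked TSSs) is reported with a two-sided Wilcoxon
    rank-sum p-value (normal approximation with tie correction for groups
    above 50, exact below).
    """
    calls = exclude_multi_tss_genes(calls)
    labels = calls.set_index("gene_id")["label"]
    shared = labels.index.intersection(expr_means.index)
    labels, values = labels.loc[shared], expr_means.loc[shared]
    ref = values[labels.isin(reference_labels)]
    if len(ref) == 0:
        raise ValueError("no reference (unclassified) genes in the universe")
    rows = []
    for pattern in FOUR_PATTERNS:
        grp = values[labels == pattern]
        if len(grp) == 0:
            logger.warning("pattern %s empty; omitted", pattern)
            continue
        method = "asymptotic" if min(len(grp), len(ref)) > 50 else "exact"
        p = mannwhitneyu(grp, ref, alternative="two-sided", method=method).pvalue
        rows.append({
            "pattern": pattern,
            "n": len(grp),
            "mean": grp.mean(),
            "pct_diff_vs_reference": 100.0 * (grp.mean() / ref.mean() - 1.0),
            "wilcoxon_p": p,
        })
    out = pd.DataFrame(rows)
    out.attrs["reference_n"] = len(ref)
    out.attrs["reference_mean"] = float(ref.mean())
    return out


def detrended_variance(expr: pd.DataFrame, span: float = 0.5) -> pd.Series:
    """Between-sample variance with its dependence on level removed.

    Fits a Loess curve of log variance on mean log2 expression across genes
    and returns the residuals (index = gene_id). Requires >= 3 samples and
    >= 30 genes for a stable local fit.
    """
    samples = expr.drop(columns="gene_id")
    if samples.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate variance")
    if len(expr) < 30:
        raise ValueError("need at least 30 genes for a stable Loess fit")
    log_expr = np.log2(samples.to_numpy() + 1e-9)
    mean = log_expr.mean(axis=1)
    log_var = np.log(log_expr.var(axis=1, ddof=1) + 1e-12)
    fitted = lowess(log_var, mean, frac=span, return_sorted=False)
    return pd.Series(log_var - fitted, index=expr["gene_id"], name="var_residual")


def _fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Cross-product OR, two-sided exact p, and the log-OR standard error.

    A zero cell triggers the Haldane +0.5 correction for the OR and SE only;
    the exact p-value is computed on the raw table.
    """
    p = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    oddsr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt((1.0 / cells).sum()))
    return float(oddsr), float(p), se


def pattern_de_fisher(calls: pd.DataFrame, de: pd.DataFrame,
                      directions: tuple[str, ...] = ("increased", "decreased")
                      ) -> pd.DataFrame:
    """Fisher's exact association of each pattern with DE status.

    The universe is the set of genes holding a four-pattern label and present
    in the differential table. For each pattern and DE direction the 2x2
    table is (pattern membership) x (DE in that direction), and the
    cross-product odds ratio is reported with the two-sided exact p and the
    log-OR standard error sqrt(sum of reciprocal cells).
    """
    calls = exclude_multi_tss_genes(calls)
    labels = calls[calls["label"].isin(FOUR_PATTERNS)].set_index("gene_id")["label"]
    flags = de.set_index("gene_id")["de_flag"]
    shared = labels.index.intersection(flags.index)
    labels, flags = labels.loc[shared], flags.loc[shared]
    rows = []
    for direction in directions:
        is_de = (flags == direction).to_numpy()
        for pattern in FOUR_PATTERNS:
            in_pat = (labels == pattern).to_numpy()
            a = int((in_pat & is_de).sum())
            b = int((in_pat & ~is_de).sum())
            c = int((~in_pat & is_de).sum())
            d = int((~in_pat & ~is_de).sum())
            oddsr, p, se = _fisher_2x2(a, b, c, d)
            rows.append({"pattern": pattern, "direction": direction,
                         "n_pattern_de": a, "n_pattern": a + b, "n_de": a + c,
                         "n_universe": a + b + c + d,
                         "odds_ratio": oddsr, "p_value": p, "log_or_se": se})
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> source/description <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              source: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, source, *genes]) + "\n")


def overrepresentation(pattern_genes, gene_sets: dict[str, list[str]],
                       background, source: str = "") -> pd.DataFrame:
    """Hypergeometric overrepresentation of gene sets in a pattern group.

    Sets are intersected with the background (all genes with detectable
    H3K4me3). The p-value is the upper tail P(overlap >= observed); the odds
    ratio is the cross-product ratio of the 2x2 partition of the background;
    FDR is Benjamini-Hochberg across the tested sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    pattern = set(pattern_genes) & background
    rows = []
    for name, genes in gene_sets.items():
        gset = set(genes) & background
        if not gset:
            continue
        overlap = len(pattern & gset)
        m, k, q = len(background), len(gset), len(pattern)
        p = float(hypergeom.sf(overlap - 1, m, k, q))
        a = overlap
        b = q - overlap
        c = k - overlap
        d = m - q - c
        cells = np.array([a, b, c, d], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        oddsr = (cells[0] * cells[3]) / (cells[1] * cells[2])
        rows.append({"name": name, "source": source, "N": overlap,
                     "odds_ratio": float(oddsr), "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value").reset_index(drop=True)
    return out
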