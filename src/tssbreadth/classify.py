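"""Breadth-pattern classification of H3K4me3-marked TSSs.

A TSS is "marked" when its TSS-region mean belongs to the upper component of
a two-normal mixture with high posterior probability. Marked TSSs are then
classified on two axes, fit separately to the upstream-TSS and
downstream-TSS differences (both bimodal): a small drop (high-mean
component) means the mark is "extended" on that side. The four-pattern
labels are narrow peak (neither side extended), upstream extended,
downstream extended and broad symmetric (both); marked TSSs below the
per-axis confidence on either axis stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixture import MixtureFit, fit_gmm2

FOUR_PATTERNS = ["narrow_peak", "upstream_extended",
                 "downstream_extended", "broad_symmetric"]
ALL_LABELS = FOUR_PATTERNS + ["unclassified", "unmarked"]

MARKED_CONFIDENCE = 0.95
PATTERN_CONFIDENCE = 0.8


def select_marked(fit: MixtureFit, values: np.ndarray,
                  confidence: float = MARKED_CONFIDENCE) -> np.ndarray:
    """Flag TSSs whose signal sits in the upper mixture component.

    ``values`` are TSS-region means; marked means the posterior of the
    high-mean component is at least ``confidence``.
    """
    return fit.posterior_high(values) >= confidence


def classify_patterns(summary: pd.DataFrame, marked: np.ndarray,
                      confidence: float = PATTERN_CONFIDENCE,
                      seed: int = 0) -> pd.DataFrame:
    """Call a breadth pattern for every TSS in a region summary.

    Mixtures are fit on the marked subset of the two difference statistics.
    On each axis "extended" requires posterior(high component) >= confidence
    and "not extended" requires posterior(low component) >= confidence;
    anything in between leaves the TSS unclassified. Unmarked TSSs never
    receive a pattern.

    Returns a frame with gene_id, label, and the two extended posteriors.
    """
    marked = np.asarray(marked, dtype=bool)
    if len(marked) != len(summary):
        raise ValueError("marked flags do not match summary rows")
    up_diff = summary["upstream_minus_tss"].to_numpy()
    down_diff = summary["downstream_minus_tss"].to_numpy()
    fit_up = fit_gmm2(up_diff[marked], seed=seed)
    fit_down = fit_gmm2(down_diff[marked], seed=seed + 1)

    post_up = fit_up.posterior_high(up_diff)
    post_down = fit_down.posterior_high(down_diff)
    up_ext = post_up >= confidence
    up_not = post_up <= 1 - confidence
    down_ext = post_down >= confidence
    down_not = post_down <= 1 - confidence

    labels = np.full(len(summary), "unclassified", dtype=object)
    labels[up_not & down_not] = "narrow_peak"
    labels[up_ext & down_not] = "upstream_extended"
    labels[up_not & down_ext] = "downstream_extended"
    labels[up_ext & down_ext] = "broad_symmetric"
    labels[~marked] = "unmarked"
    post_up = np.where(marked, post_up, np.nan)
    post_down = np.where(marked, post_down, np.nan)
    return pd.DataFrame({
        "gene_id": summary["gene_id"],
        "label": labels,
        "posterior_upstream_extended": post_up,
        "posterior_downstream_extended": post_down,
    })


def classify_matrix(matrix, marked_confidence: float = MARKED_CONFIDENCE,
                    confidence: float = PATTERN_CONFIDENCE, seed: int = 0,
                    upstream_window: str = "methods") -> pd.DataFrame:
    """Full classification of a normalized profile matrix (convenience)."""
    from .coverage import summarize_regions

    summary = summarize_regions(matrix, upstream_window=upstream_window)
    fit = fit_gmm2(summary["tss_mean"].to_numpy(), seed=seed + 17)
    marked = select_marked(fit, summary["tss_mean"].to_numpy(),
                           marked_confidence)
    return classify_patterns(summary, marked, confidence=confidence, seed=seed)


def cohens_kappa(table: np.ndarray) -> tuple[float, float, float]:
    """Cohen's kappa, its null-hypothesis SE and one-sided p for kappa > 0.

    The p-value uses the asymptotic normal test: under independence the
    standard error of kappa is
    sqrt(p_e + p_e^2 - sum_i p_i. p_.i (p_i. + p_.i)) / ((1 - p_e) sqrt(n)).
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = np.trace(p)
    p_e = float(row @ col)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0, np.nan, np.nan
    kappa = (p_o - p_e) / (1 - p_e)
    var0 = (p_e + p_e ** 2 - float((row * col * (row + col)).sum()))
    se0 = np.sqrt(var0) / ((1 - p_e) * np.sqrt(n))
    pval = float(norm.sf(kappa / se0)) if se0 > 0 else np.nan
    return float(kappa), float(se0), pval


@dataclass
class AgreementResult:
    table: pd.DataFrame  # 4x4 contingency counts, rows = calls A
    percent_agreement: float
    kappa: float
    kappa_se0: float
    p_value: float
    n: int


def agreement(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> AgreementResult:
    """Compare two pattern classifications on co-classified TSSs.

    Restricted to TSSs holding one of the four breadth patterns in both
    call sets; percent agreement is the diagonal fraction and kappa corrects
    it for chance agreement from the marginals.
    """
    a = calls_a.set_index("gene_id")["label"]
    b = calls_b.set_index("gene_id")["label"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    keep = a.isin(FOUR_PATTERNS) & b.isin(FOUR_PATTERNS)
    if not keep.any():
        raise ValueError("no TSS classified into a four-pattern label in both")
    a, b = a[keep], b[keep]
    table = pd.crosstab(a, b).reindex(index=FOUR_PATTERNS,
                                      columns=FOUR_PATTERNS, fill_value=0)
    counts = table.to_numpy()
    n = int(counts.sum())
    kappa, se0, pval = cohens_kappa(counts)
    return AgreementResult(table, 100.0 * np.trace(counts) / n,
                           kappa, se0, pval, n)
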