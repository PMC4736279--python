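"""PWM scanning of promoter windows and breadth-stratified enrichment.

Promoter sequences cover -1..+1 kb around each TSS in transcription
orientation. Matches are log-odds scores at or above a fraction of the
motif's maximum achievable score (default 80 %), scanned on both strands
with reverse-strand hits reported at the forward window coordinate. Match
densities are then compared between breadth-pattern groups and the
H3K4me3-marked background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.motifs.matrix import FrequencyPositionMatrix
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SCORE_FRACTION = 0.8
PSEUDOCOUNT = 1e-3
ENRICHMENT_THRESHOLD = 1.2
ALPHABET = "ACGT"


@dataclass
class Pwm:
    """A position probability matrix over ACGT."""

    motif_id: str
    matrix: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.matrix, axis=1))

    def to_bio(self) -> bio_motifs.Motif:
        counts = {b: (self.matrix[:, i] * 1000).tolist()
                  for i, b in enumerate(ALPHABET)}
        m = bio_motifs.Motif(alphabet=ALPHABET,
                             counts=FrequencyPositionMatrix(ALPHABET, counts))
        m.name = self.motif_id
        m.pseudocounts = {b: self.pseudocount * 1000 for b in ALPHABET}
        m.background = {b: float(self.background[i])
                        for i, b in enumerate(ALPHABET)}
        return m


def read_meme(path) -> list[Pwm]:
    """Read motifs from a MEME minimal-format file."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = []
        for m in records:
            mat = np.column_stack([np.asarray(m.pwm[b], dtype=float)
                                   for b in ALPHABET])
            mat = mat / mat.sum(axis=1, keepdims=True)
            out.append(Pwm(motif_id=m.name or m.base_id, matrix=mat))
    return out


def write_meme(pwms: list[Pwm], path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                     f"nsites= 1000 E= 0\n")
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def scan(sequences: dict[str, str], pwm: Pwm,
         score_fraction: float = SCORE_FRACTION,
         window_start: int = -1000) -> pd.DataFrame:
    """Scan promoter windows for PWM matches on both strands.

    Positions are TSS-relative starts of the matched window (``window_start``
    is the TSS-relative coordinate of the first sequence base). Reverse-
    complement matches are reported at the forward coordinate, and a position
    matching on both strands (e.g. a palindrome) is counted once, keeping the
    better score. Sequences with more than 10 % N are skipped with a warning.
    """
    m = pwm.to_bio()
    pssm = m.pssm
    threshold = score_fraction * pssm.max
    pssm_rc = pssm.reverse_complement()
    rows = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < len(pwm):
            continue
        n_frac = seq.count("N") / len(seq)
        if n_frac > 0.10:
            logger.warning("sequence %s has %.0f%% N; skipped",
                           seq_id, 100 * n_frac)
            continue
        fwd = np.asarray(pssm.calculate(Seq(seq)), dtype=float)
        rev = np.asarray(pssm_rc.calculate(Seq(seq)), dtype=float)
        fwd = np.nan_to_num(np.atleast_1d(fwd), nan=-np.inf)
        rev = np.nan_to_num(np.atleast_1d(rev), nan=-np.inf)
        hit_f = fwd >= threshold
        hit_r = rev >= threshold
        for i in np.where(hit_f | hit_r)[0]:
            if hit_f[i] and (not hit_r[i] or fwd[i] >= rev[i]):
                strand, score = "+", fwd[i]
            else:
                strand, score = "-", rev[i]
            rows.append((seq_id, pwm.motif_id, int(i) + window_start,
                         strand, float(score)))
    return pd.DataFrame(rows, columns=["gene_id", "motif_id", "position",
                                       "strand", "score"])


def profile_enrichment(matches: pd.DataFrame, calls: pd.DataFrame,
                       background_labels: tuple[str, ...] | None = None,
                       bin_width: int = 50,
                       window: tuple[int, int] = (-1000, 1000),
                       min_group: int = 20,
                       enrichment_threshold: float = ENRICHMENT_THRESHOLD
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positional match density per pattern group relative to the background.

    The background defaults to all H3K4me3-marked TSSs (every label except
    ``unmarked``). For each four-pattern group the per-position-bin match
    density (matches per TSS) is divided by the background density; the
    overall ratio over the whole window carries the enriched flag
    (ratio >= ``enrichment_threshold``). Groups under ``min_group`` TSSs are
    suppressed.

    Returns (per-pattern overall ratios, positional ratio profiles).
    """
    from .classify import FOUR_PATTERNS

    if background_labels is None:
        background_labels = tuple(l for l in calls["label"].unique()
                                  if l != "unmarked")
    labels = calls.set_index("gene_id")["label"]
    edges = np.arange(window[0], window[1] + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2

    def density(genes: set[str]) -> tuple[np.ndarray, float]:
        sub = matches[matches["gene_id"].isin(genes)]
        hist, _ = np.histogram(sub["position"], bins=edges)
        n = max(len(genes), 1)
        return hist / n, len(sub) / n

    bg_genes = set(labels[labels.isin(background_labels)].index)
    bg_profile, bg_overall = density(bg_genes)
    overall_rows, profile_rows = [], []
    for pattern in FOUR_PATTERNS:
        genes = set(labels[labels == pattern].index)
        if len(genes) < min_group:
            logger.warning("pattern %s has %d TSSs (< %d); profile suppressed",
                           pattern, len(genes), min_group)
            continue
        prof, overall = density(genes)
        ratio = overall / bg_overall if bg_overall > 0 else np.nan
        if overall == 0:
            logger.warning("pattern %s has zero matches", pattern)
        overall_rows.append({
            "pattern": pattern, "n_tss": len(genes),
            "matches_per_tss": overall, "background_per_tss": bg_overall,
            "enrichment_ratio": ratio,
            "enriched": bool(ratio >= enrichment_threshold)
            if np.isfinite(ratio) else False,
        })
        with np.errstate(divide="ignore", invalid="ignore"):
            prof_ratio = np.where(bg_profile > 0, prof / bg_profile, np.nan)
        for c, dens, r in zip(centers, prof, prof_ratio):
            profile_rows.append({"pattern": pattern, "bin_center": c,
                                 "density": dens, "ratio": r})
    return pd.DataFrame(overall_rows), pd.DataFrame(profile_rows)


def overall_marked_enrichment(matches: pd.DataFrame, calls: pd.DataFrame,
                              enrichment_threshold: float = ENRICHMENT_THRESHOLD
                              ) -> pd.DataFrame:
    """Per-motif enrichment of marked TSSs against all TSSs.

    This is the filter selecting motifs enriched by at least 20 % at TSSs
    with H3K4me3: match density over marked TSSs divided by density over the
    whole TSS universe.
    """
    labels = calls.set_index("gene_id")["label"]
    marked = set(labels[labels != "unmarked"].index)
    all_genes = set(labels.index)
    rows = []
    for motif_id, sub in matches.groupby("motif_id"):
        d_marked = len(sub[sub["gene_id"].isin(marked)]) / max(len(marked), 1)
        d_all = len(sub[sub["gene_id"].isin(all_genes)]) / max(len(all_genes), 1)
        ratio = d_marked / d_all if d_all > 0 else np.nan
        rows.append({"motif_id": motif_id, "marked_per_tss": d_marked,
                     "all_per_tss": d_all, "enrichment_ratio": ratio,
                     "enriched": bool(ratio >= enrichment_threshold)
                     if np.isfinite(ratio) else False})
    return pd.DataFrame(rows)
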