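"""TSS-anchored ChIP-seq coverage: read extension, binning, normalization.

The promoter window spans -1025..+1025 bp around each TSS and is averaged
into 41 bins of 50 bp, so the central bin is centered on the TSS itself and
bin centers run -1000, -950, ..., +1000 in the direction of transcription.
Normalized depth is expressed in log2 units relative to the input-measured
background: 0 means background level, +1.0 means twice the background and
-1.0 half of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIN_WIDTH = 50
N_BINS = 41
WINDOW = (-1025, 1025)
#: nominal bin centers in transcription-direction coordinates
BIN_CENTERS = np.arange(-1000, 1001, BIN_WIDTH)

#: analysis regions in TSS-relative coordinates (inclusive of bin centers)
REGION_TSS = (-250, 250)
REGION_DOWNSTREAM = (600, 700)
#: the upstream window: "methods" = 400-500 bp upstream; "figure" = 300-400 bp
UPSTREAM_WINDOWS = {"methods": (-500, -400), "figure": (-400, -300)}

LOG2_FLOOR = -3.0


def region_bins(lo: int, hi: int) -> np.ndarray:
    """Indices of the bins whose nominal centers fall inside [lo, hi]."""
    return np.where((BIN_CENTERS >= lo) & (BIN_CENTERS <= hi))[0]


def read_tss_bed(path) -> pd.DataFrame:
    """Read a TSS annotation from BED6 (name column = gene id).

    The TSS position is the interval start for + strand genes and end - 1
    for - strand genes.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    tss = np.where(bed["strand"] == "-", bed["end"] - 1, bed["start"])
    out = pd.DataFrame({
        "gene_id": bed["gene_id"], "chrom": bed["chrom"],
        "tss": tss.astype(np.int64), "strand": bed["strand"],
    })
    validate_tss(out)
    return out


def validate_tss(tss: pd.DataFrame) -> None:
    if tss["gene_id"].duplicated().any():
        dup = tss.loc[tss["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in TSS annotation: {dup!r}")
    if (tss["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    bad = ~tss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("TSS strand must be '+' or '-'")


def extend_reads(reads: pd.DataFrame, target_len: int = 200) -> pd.DataFrame:
    """Extend reads to ``target_len`` bp toward their 3' end.

    Each interval keeps its 5' start: + strand reads keep ``start`` and the
    end becomes start + target_len; - strand reads keep ``end`` and the start
    becomes end - target_len. Records without a valid strand are dropped with
    a warning.
    """
    ok = reads["strand"].isin(["+", "-"]).to_numpy()
    if not ok.all():
        logger.warning("dropping %d reads without strand", int((~ok).sum()))
        reads = reads.loc[ok]
    plus = (reads["strand"] == "+").to_numpy()
    start = np.where(plus, reads["start"], reads["end"] - target_len)
    end = start + target_len
    out = reads.copy()
    out["start"] = np.maximum(start, 0)
    out["end"] = end
    return out


@dataclass
class BinnedProfileMatrix:
    """TSS x 41-bin matrix of depth, oriented in transcription direction."""

    gene_ids: np.ndarray
    values: np.ndarray  # (n_tss, 41)
    truncated: np.ndarray = field(default=None)  # TSSs near a contig edge

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_BINS:
            raise ValueError(f"profile matrix must have {N_BINS} columns")
        if self.values.shape[0] != self.gene_ids.shape[0]:
            raise ValueError("row count does not match gene ids")
        if self.truncated is None:
            self.truncated = np.zeros(len(self.gene_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"bin_{c:+d}" for c in BIN_CENTERS])
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.5g")

    @classmethod
    def from_tsv(cls, path) -> "BinnedProfileMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df["gene_id"].to_numpy(), df.iloc[:, 1:].to_numpy())


def bin_depth(reads: pd.DataFrame, tss: pd.DataFrame) -> BinnedProfileMatrix:
    """Mean per-base coverage of extended reads in each 50 bp bin per TSS.

    Reads are half-open genomic intervals [start, end). Coverage is computed
    per chromosome, the -1025..+1025 window around each TSS is sliced and
    averaged into 41 bins, and rows of minus-strand TSSs are reversed so the
    last column is always the far downstream bin. TSSs whose window overhangs
    a contig edge get zero-filled bins and are flagged ``truncated``.
    """
    validate_tss(tss)
    tss = tss.reset_index(drop=True)
    half = WINDOW[1]
    n = len(tss)
    values = np.zeros((n, N_BINS))
    truncated = np.zeros(n, dtype=bool)
    for chrom, sub in tss.groupby("chrom", sort=False):
        r = reads[reads["chrom"] == chrom]
        hi = int(max(sub["tss"].max() + half + 1,
                     (r["end"].max() + 1) if len(r) else 1))
        diff = np.zeros(hi + 1, dtype=np.int64)
        if len(r):
            starts = np.clip(r["start"].to_numpy(), 0, hi)
            ends = np.clip(r["end"].to_numpy(), 0, hi)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        cov = np.cumsum(diff)[:-1]
        for i, row in sub.iterrows():
            lo, up = row["tss"] - half, row["tss"] + half
            window = np.zeros(2 * half, dtype=float)
            a, b = max(lo, 0), min(up, hi)
            if a > lo or b < up:
                truncated[i] = True
                logger.warning("TSS %s within %d bp of contig edge; bins truncated",
                               row["gene_id"], half)
            if b > a:
                window[a - lo:b - lo] = cov[a:b]
            binned = window.reshape(N_BINS, BIN_WIDTH).mean(axis=1)
            if row["strand"] == "-":
                binned = binned[::-1]
            values[i] = binned
    return BinnedProfileMatrix(tss["gene_id"].to_numpy(), values, truncated)


def normalize_and_subtract(
    raw: list[BinnedProfileMatrix],
    inputs: list[BinnedProfileMatrix],
    floor: float = LOG2_FLOOR,
    names: list[str] | None = None,
) -> BinnedProfileMatrix:
    """Normalize samples against their input backgrounds and average a group.

    Each sample's background level is estimated as the median cell of its
    binned input-control matrix (a robust library-size proxy for a flat
    background). The normalized value is log2(depth / background), clipped
    below at ``floor``, so a depth of exactly 2x background maps to +1.0 and
    0.5x background to -1.0; dividing every sample by its own background also
    equalizes backgrounds between samples. The group matrix is the mean of
    the per-sample log2 matrices.
    """
    if len(raw) == 0 or len(raw) != len(inputs):
        raise ValueError("need >=1 sample and one input per sample")
    names = names or [f"sample_{i + 1}" for i in range(len(raw))]
    acc = np.zeros_like(raw[0].values)
    for sample, inp, name in zip(raw, inputs, names):
        bg = float(np.median(inp.values))
        if not np.isfinite(bg) or bg <= 0:
            raise ValueError(f"zero or invalid background estimate for {name}")
        with np.errstate(divide="ignore"):
            norm = np.log2(sample.values / bg)
        acc += np.maximum(norm, floor)
    group = acc / len(raw)
    return BinnedProfileMatrix(raw[0].gene_ids, group,
                               np.any([m.truncated for m in raw], axis=0))


def summarize_regions(matrix: BinnedProfileMatrix,
                      upstream_window: str = "methods") -> pd.DataFrame:
    """Mean normalized depth over the TSS, upstream and downstream regions.

    Region means average the bins whose nominal centers fall inside the
    region; the two classification statistics are the upstream-TSS and
    downstream-TSS differences.
    """
    up_lo, up_hi = UPSTREAM_WINDOWS[upstream_window]
    tss_mean = matrix.values[:, region_bins(*REGION_TSS)].mean(axis=1)
    up_mean = matrix.values[:, region_bins(up_lo, up_hi)].mean(axis=1)
    down_mean = matrix.values[:, region_bins(*REGION_DOWNSTREAM)].mean(axis=1)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "tss_mean": tss_mean,
        "upstream_mean": up_mean,
        "downstream_mean": down_mean,
        "upstream_minus_tss": up_mean - tss_mean,
        "downstream_minus_tss": down_mean - tss_mean,
    })
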