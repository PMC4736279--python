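"""Synthetic ChIP-seq / RNA-seq data with known breadth-pattern structure.

The generator emulates the statistical structure the breadth analysis
assumes: four TSS archetypes of H3K4me3 over a -1..+1 kb window plus
unmarked sites, Poisson read noise over a flat input-measured background, a
disease condition that perturbs region-specific H3K4me3 and couples the
downstream change linearly to transcription change, per-pattern
differential-expression probabilities, pattern persistence between
conditions, and promoter sequences with planted motif matches.

Default parameters encode the printed effect sizes of the monocyte study
this pipeline reproduces: a +1.5 % transcription response per 1 % downstream
H3K4me3 increase, region-increase probabilities (0.788, 0.550, 0.471) for
overexpressed genes, 94.8 % pattern persistence in disease, a +151 %
transcription premium of the downstream-extended pattern, and per-pattern
overexpression probabilities whose marginal odds ratios are 0.14 (narrow)
and 2.37 (downstream extended) under classified-pattern proportions
(0.10, 0.36, 0.33, 0.21).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .classify import FOUR_PATTERNS
from .coverage import BIN_WIDTH, N_BINS, WINDOW, BinnedProfileMatrix, bin_depth

CHROM = "chrSim1"

#: archetype elevation intervals in fragment-center coordinates (bp relative
#: to the TSS, transcription direction). Aligned to bin boundaries so the
#: plateau covers bin centers out to -500 (upstream extended) and +650
#: (downstream extended).
_ELEVATION = {
    "narrow_peak": (-275, 275),
    "upstream_extended": (-525, 275),
    "downstream_extended": (-275, 675),
    "broad_symmetric": (-525, 675),
    "unmarked": None,
}
#: fragment centers are drawn over the binning window padded by half a
#: fragment so coverage is defined across all 41 bins
_CENTER_SPAN = (WINDOW[0] - 100, WINDOW[1] + 100)
#: boundaries of the three disease-perturbation thirds (upstream / TSS /
#: downstream); region multipliers are flat across each third so the blur of
#: the 200 bp fragment never leaks a neighbouring region's multiplier into
#: the scored bins
_THIRDS = (-350, 350)

_DEFAULT_PROPORTIONS = {
    # 48.5 % of TSSs carry no mark; the rest split the four breadth patterns
    # in the classified-cohort proportions 0.10 : 0.36 : 0.33 : 0.21
    "narrow_peak": 0.0515,
    "upstream_extended": 0.1854,
    "downstream_extended": 0.16995,
    "broad_symmetric": 0.10815,
    "unmarked": 0.485,
}


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic cohort."""

    n_tss: int = 2000
    n_samples_per_group: int = 6
    bin_width: int = BIN_WIDTH
    window: tuple[int, int] = WINDOW
    pattern_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    background_depth: float = 10.0       # per-base coverage of the background
    signal_height: float = 2.0           # log2 fold over background at the mark
    read_length: int = 50
    fragment_length: int = 200
    de_prob_by_pattern: dict[str, float] = field(default_factory=lambda: {
        "narrow_peak": 0.026, "upstream_extended": 0.12,
        "downstream_extended": 0.225, "broad_symmetric": 0.13,
        "unmarked": 0.10,
    })
    de_down_prob: float = 0.07
    persist_prob: float = 0.948
    beta_down: float = 1.5               # % transcription per 1 % downstream H3K4me3
    beta_tss: float = 0.0
    beta_up: float = 0.0
    frac_increase_by_region: tuple[float, float, float] = (0.788, 0.550, 0.471)
    region_change_sd_de: float = 5.0     # % scale of region changes, DE genes
    region_change_sd_null: float = 4.0
    region_coupling_sd: float = 0.0      # shared component across regions
    transcription_noise_sd: float = 3.0  # % noise on transcription change
    expr_multiplier_by_pattern: dict[str, float] = field(default_factory=lambda: {
        "narrow_peak": 1.0, "upstream_extended": 1.8,
        "downstream_extended": 2.51, "broad_symmetric": 1.9,
        "unmarked": 1.0,
    })
    expr_log2_mean: float = 5.0
    expr_log2_sd: float = 1.0
    sample_log2_sd: float = 0.25
    tss_spacing: int = 4000
    motif_length: int = 8
    n_motifs: int = 2
    plant_rate_by_pattern: dict[str, float] = field(default_factory=lambda: {
        "narrow_peak": 2.0, "upstream_extended": 1.0,
        "downstream_extended": 1.0, "broad_symmetric": 1.0, "unmarked": 0.5,
    })
    seq_window: tuple[int, int] = (-1000, 1000)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_tss <= 0:
            raise ValueError("n_tss must be positive")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be positive")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_proportions sum to {total}, not 1")
        for name, p in [*self.de_prob_by_pattern.items(),
                        ("persist_prob", self.persist_prob),
                        ("de_down_prob", self.de_down_prob),
                        *zip(("down", "tss", "up"), self.frac_increase_by_region)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name} = {p} outside [0, 1]")
        span = self.window[1] - self.window[0]
        if span != N_BINS * self.bin_width:
            raise ValueError(
                f"window {self.window} does not cover exactly {N_BINS} bins "
                f"of {self.bin_width} bp")

    @property
    def labels(self) -> list[str]:
        return FOUR_PATTERNS + ["unmarked"]

    def classified_proportions(self) -> dict[str, float]:
        """Pattern proportions renormalized over the four breadth patterns."""
        tot = sum(self.pattern_proportions[p] for p in FOUR_PATTERNS)
        return {p: self.pattern_proportions[p] / tot for p in FOUR_PATTERNS}

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["window"] = list(d["window"])
        d["seq_window"] = list(d["seq_window"])
        d["frac_increase_by_region"] = list(d["frac_increase_by_region"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("window", "seq_window", "frac_increase_by_region"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth per gene/TSS plus an echo of the generating config."""

    table: pd.DataFrame
    config: GeneratorConfig

    def region_change_table(self) -> pd.DataFrame:
        """The true per-gene % region/transcription changes, in the shape the
        dose-response module consumes."""
        cols = ["gene_id", "chg_upstream", "chg_tss", "chg_downstream",
                "chg_transcription", "de_flag"]
        return (self.table[cols]
                .rename(columns={"chg_upstream": "upstream",
                                 "chg_tss": "tss",
                                 "chg_downstream": "downstream",
                                 "chg_transcription": "transcription"})
                .copy())


def _draw_labels(rng: np.random.Generator, n: int,
                 proportions: dict[str, float]) -> np.ndarray:
    labels = list(proportions)
    probs = np.array([proportions[l] for l in labels])
    return np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n, p=probs)]


def _disease_labels(rng: np.random.Generator, ctrl: np.ndarray,
                    persist_prob: float) -> np.ndarray:
    """Resample patterns for the disease condition.

    Narrow peaks and unmarked sites never switch; the other patterns persist
    with the configured probability and otherwise move uniformly to one of
    the other two non-narrow patterns.
    """
    non_narrow = [p for p in FOUR_PATTERNS if p != "narrow_peak"]
    case = ctrl.copy()
    movable = np.isin(ctrl, non_narrow)
    switch = movable & (rng.random(ctrl.size) > persist_prob)
    for idx in np.where(switch)[0]:
        others = [p for p in non_narrow if p != ctrl[idx]]
        case[idx] = others[rng.integers(len(others))]
    return case


def simulate_truth(config: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw the complete per-gene ground truth of a synthetic cohort.

    One TSS per gene. Pattern labels are drawn from the configured simplex
    for the control condition and resampled under the persistence rule for
    the disease condition. Differential-transcription flags follow the
    per-pattern probabilities; % H3K4me3 changes at the three regions are
    normal with means set so the probability of an increase matches the
    configured fractions given the DE status (mirrored for DE-down genes,
    centered for the rest); % transcription change is the linear response to
    the region changes plus noise, sign-constrained to match the DE flag.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_tss
    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n)], dtype=object)
    ctrl = _draw_labels(rng, n, config.pattern_proportions)
    case = _disease_labels(rng, ctrl, config.persist_prob)

    p_up = np.array([config.de_prob_by_pattern[l] for l in ctrl])
    u = rng.random(n)
    de = np.where(u < p_up, "increased",
                  np.where(u < p_up + config.de_down_prob, "decreased",
                           "neither")).astype(object)

    # region changes: order of frac_increase_by_region is (down, tss, up)
    frac_down, frac_tss, frac_up = config.frac_increase_by_region
    sd = np.where(de == "neither", config.region_change_sd_null,
                  config.region_change_sd_de)
    sign = np.where(de == "increased", 1.0,
                    np.where(de == "decreased", -1.0, 0.0))
    changes = {}
    for region, frac in (("downstream", frac_down), ("tss", frac_tss),
                         ("upstream", frac_up)):
        mu = sign * config.region_change_sd_de * norm.ppf(frac)
        changes[region] = rng.normal(mu, sd)
    if config.region_coupling_sd > 0:
        shared = rng.normal(0.0, config.region_coupling_sd, size=n)
        for region in changes:
            changes[region] = changes[region] + shared

    linear = (config.beta_down * changes["downstream"]
              + config.beta_tss * changes["tss"]
              + config.beta_up * changes["upstream"])
    eps = rng.normal(0.0, config.transcription_noise_sd, size=n)
    # resample the noise of DE genes from the sign-consistent truncated
    # normal; the region-change marginals above are untouched
    s = config.transcription_noise_sd
    for flag, sgn in (("increased", 1.0), ("decreased", -1.0)):
        idx = np.where(de == flag)[0]
        if idx.size == 0:
            continue
        bound = -linear[idx] / s  # require sgn * (linear + eps) > 0
        if sgn > 0:
            eps[idx] = truncnorm.rvs(bound, np.inf, scale=s,
                                     random_state=rng)
        else:
            eps[idx] = truncnorm.rvs(-np.inf, bound, scale=s,
                                     random_state=rng)
    chg_expr = linear + eps

    p_val = np.where(
        de == "neither", rng.uniform(0.01, 1.0, size=n),
        10.0 ** rng.uniform(-12.0, np.log10(0.01), size=n))
    base_log2 = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=n)

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "pattern_ctrl": ctrl,
        "pattern_case": case,
        "de_flag": de,
        "chg_upstream": changes["upstream"],
        "chg_tss": changes["tss"],
        "chg_downstream": changes["downstream"],
        "chg_transcription": chg_expr,
        "p_value": p_val,
        "base_log2_expr": base_log2,
    })
    return SyntheticTruth(table, config)


@dataclass
class ReadTrack:
    """A set of 50 bp single-end read placements on the synthetic contig."""

    starts: np.ndarray
    strands: np.ndarray  # '+' / '-'
    read_length: int = 50
    chrom: str = CHROM

    def to_bed(self) -> pd.DataFrame:
        n = self.starts.size
        return pd.DataFrame({
            "chrom": np.full(n, self.chrom, dtype=object),
            "start": self.starts,
            "end": self.starts + self.read_length,
            "name": [f"read{i + 1}" for i in range(n)],
            "score": np.zeros(n, dtype=int),
            "strand": self.strands,
        })

    def write_bed(self, path) -> None:
        self.to_bed().to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SimulatedExperiment:
    tss: pd.DataFrame
    truth: SyntheticTruth
    chip_ctrl: list[ReadTrack]
    chip_case: list[ReadTrack]
    input_ctrl: list[ReadTrack]
    input_case: list[ReadTrack]

    @property
    def total_reads(self) -> int:
        return sum(t.starts.size for t in
                   self.chip_ctrl + self.chip_case
                   + self.input_ctrl + self.input_case)


def _segment_grid() -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Piecewise-constant segments of the fragment-center rate."""
    edges = sorted({_CENTER_SPAN[0], _CENTER_SPAN[1], *_THIRDS,
                    *(v for iv in _ELEVATION.values() if iv for v in iv)})
    segs = [(a, b) for a, b in zip(edges[:-1], edges[1:])]
    return np.asarray(edges), segs


def _rate_matrix(config: GeneratorConfig, labels: np.ndarray,
                 multipliers: np.ndarray | None) -> np.ndarray:
    """Expected fragment-center rate (per bp) per TSS and segment.

    Coverage from 200 bp fragments placed at per-bp center rate r(u) is the
    200 bp moving average of 200 * r, so rates are depth/fragment_length with
    depth = background * 2^signal_height inside the archetype's elevation
    interval. Disease region multipliers scale depth across whole thirds of
    the window.
    """
    _, segs = _segment_grid()
    n = len(labels)
    fold = 2.0 ** config.signal_height
    rates = np.empty((n, len(segs)))
    for j, (a, b) in enumerate(segs):
        seg_fold = np.ones(n)
        for lab, iv in _ELEVATION.items():
            if iv and iv[0] <= a and b <= iv[1]:
                seg_fold[labels == lab] = fold
        depth = config.background_depth * seg_fold
        if multipliers is not None:
            mid = (a + b) / 2
            col = 0 if mid < _THIRDS[0] else (1 if mid < _THIRDS[1] else 2)
            depth = depth * multipliers[:, col]
        rates[:, j] = depth / config.fragment_length
    return rates


def _draw_track(rng: np.random.Generator, config: GeneratorConfig,
                tss: pd.DataFrame, rates: np.ndarray) -> ReadTrack:
    """Draw one sample's reads from per-TSS, per-segment center rates."""
    _, segs = _segment_grid()
    seg_len = np.array([b - a for a, b in segs], dtype=float)
    counts = rng.poisson(rates * seg_len[None, :])
    total = int(counts.sum())
    seg_lo = np.array([a for a, _ in segs], dtype=float)
    flat = counts.ravel()
    tss_idx = np.repeat(np.repeat(np.arange(len(tss)), len(segs)), flat)
    seg_idx = np.repeat(np.tile(np.arange(len(segs)), len(tss)), flat)
    rel = seg_lo[seg_idx] + rng.random(total) * seg_len[seg_idx]
    pos = tss["tss"].to_numpy()[tss_idx]
    minus_gene = (tss["strand"].to_numpy()[tss_idx] == "-")
    centers = np.where(minus_gene, pos - rel, pos + rel)
    left = np.rint(centers).astype(np.int64) - config.fragment_length // 2
    # each fragment is observed from one of its ends
    from_right = rng.random(total) < 0.5
    starts = np.where(from_right,
                      left + config.fragment_length - config.read_length,
                      left)
    strands = np.where(from_right, "-", "+").astype(object)
    order = np.argsort(starts, kind="stable")
    return ReadTrack(starts[order], strands[order], config.read_length)


def make_annotation(config: GeneratorConfig, gene_ids: np.ndarray) -> pd.DataFrame:
    """TSS annotation on one synthetic contig, alternating strands."""
    n = len(gene_ids)
    pos = (np.arange(n) + 1) * config.tss_spacing
    strands = np.where(np.arange(n) % 2 == 0, "+", "-").astype(object)
    return pd.DataFrame({"gene_id": gene_ids, "chrom": CHROM,
                         "tss": pos, "strand": strands})


def generate_profiles(config: GeneratorConfig,
                      seed: int | None = None) -> SimulatedExperiment:
    """Simulate ChIP and input read placements for both conditions.

    Control samples realize the control-condition archetypes; disease samples
    realize the (possibly switched) disease patterns with each gene's true
    region changes applied as depth multipliers over the corresponding third
    of the window. Input samples are flat background. Deterministic given the
    config seed (or an explicit ``seed`` override).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = simulate_truth(config, rng)
    t = truth.table
    tss = make_annotation(config, t["gene_id"].to_numpy())

    mult = 1.0 + t[["chg_upstream", "chg_tss", "chg_downstream"]].to_numpy() / 100.0
    if (mult <= 0).any():
        mult = np.maximum(mult, 1e-3)
    rates_ctrl = _rate_matrix(config, t["pattern_ctrl"].to_numpy(), None)
    rates_case = _rate_matrix(config, t["pattern_case"].to_numpy(), mult)
    rates_input = np.full_like(rates_ctrl,
                               config.background_depth / config.fragment_length)

    chip_ctrl = [_draw_track(rng, config, tss, rates_ctrl)
                 for _ in range(config.n_samples_per_group)]
    chip_case = [_draw_track(rng, config, tss, rates_case)
                 for _ in range(config.n_samples_per_group)]
    input_ctrl = [_draw_track(rng, config, tss, rates_input)
                  for _ in range(config.n_samples_per_group)]
    input_case = [_draw_track(rng, config, tss, rates_input)
                  for _ in range(config.n_samples_per_group)]
    return SimulatedExperiment(tss, truth, chip_ctrl, chip_case,
                               input_ctrl, input_case)


def generate_expression(truth: SyntheticTruth, config: GeneratorConfig,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample expression tables and the differential summary.

    Baseline linear expression is lognormal with the per-pattern multiplier
    applied (downstream-extended genes default to 2.51x the unmarked
    reference); disease samples additionally carry each gene's true %
    transcription change. Returns (expression table with one column per
    sample, differential table with means / % change / p-value / DE flag).
    """
    if len(truth.table) != config.n_tss:
        raise ValueError("truth does not match the config's gene universe")
    rng = np.random.default_rng((config.seed + 101) if seed is None else seed)
    t = truth.table
    n = len(t)
    mult = np.array([config.expr_multiplier_by_pattern[l]
                     for l in t["pattern_ctrl"]])
    base = mult * 2.0 ** t["base_log2_expr"].to_numpy()
    case_level = base * (1.0 + t["chg_transcription"].to_numpy() / 100.0)
    cols = {"gene_id": t["gene_id"]}
    for i in range(config.n_samples_per_group):
        cols[f"ctrl_{i + 1}"] = base * 2.0 ** rng.normal(
            0, config.sample_log2_sd, n)
    for i in range(config.n_samples_per_group):
        cols[f"case_{i + 1}"] = case_level * 2.0 ** rng.normal(
            0, config.sample_log2_sd, n)
    expr = pd.DataFrame(cols)
    ctrl_cols = [c for c in expr if c.startswith("ctrl_")]
    case_cols = [c for c in expr if c.startswith("case_")]
    de = pd.DataFrame({
        "gene_id": t["gene_id"],
        "mean_ctrl": expr[ctrl_cols].mean(axis=1),
        "mean_case": expr[case_cols].mean(axis=1),
        "pct_change": t["chg_transcription"],
        "p_value": t["p_value"],
        "de_flag": t["de_flag"],
    })
    return expr, de


# ---------------------------------------------------------------------------
# motif data

_BASES = np.array(list("ACGT"))


def _make_pwms(rng: np.random.Generator, config: GeneratorConfig) -> list:
    from .motifs import Pwm

    pwms = []
    for m in range(config.n_motifs):
        cons = rng.integers(0, 4, size=config.motif_length)
        mat = np.full((config.motif_length, 4), 0.03)
        mat[np.arange(config.motif_length), cons] = 0.91
        pwms.append(Pwm(motif_id=f"SYN{m + 1:03d}", matrix=mat))
    return pwms


def generate_motif_data(config: GeneratorConfig,
                        truth: SyntheticTruth | None = None,
                        seed: int | None = None):
    """Promoter windows with planted motif consensus occurrences.

    Sequences are iid uniform ACGT over the -1..+1 kb window; each motif's
    exact consensus is planted Poisson(rate) times per promoter at uniform
    positions, at per-pattern rates. Returns (sequences by gene, PWM list,
    planted-match truth table).
    """
    rng = np.random.default_rng((config.seed + 202) if seed is None else seed)
    if truth is None:
        truth = simulate_truth(config, rng)
    lo, hi = config.seq_window
    length = hi - lo
    if config.motif_length > length:
        raise ValueError("motif longer than the sequence window")
    pwms = _make_pwms(rng, config)
    labels = truth.table["pattern_ctrl"].to_numpy()
    gene_ids = truth.table["gene_id"].to_numpy()
    seq_codes = rng.integers(0, 4, size=(len(gene_ids), length))
    rows = []
    for pwm in pwms:
        cons = np.argmax(pwm.matrix, axis=1)
        rates = np.array([config.plant_rate_by_pattern[l] for l in labels])
        counts = rng.poisson(rates)
        for i in np.where(counts > 0)[0]:
            for _ in range(counts[i]):
                start = int(rng.integers(0, length - config.motif_length + 1))
                seq_codes[i, start:start + config.motif_length] = cons
                rows.append((gene_ids[i], pwm.motif_id, start + lo, "+"))
    seqs = {g: "".join(_BASES[c]) for g, c in zip(gene_ids, seq_codes)}
    matches = pd.DataFrame(rows, columns=["gene_id", "motif_id",
                                          "position", "strand"])
    return seqs, pwms, matches
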