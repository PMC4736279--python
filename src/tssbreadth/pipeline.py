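"""End-to-end orchestration: profile -> classify -> associate -> dose-response.

Glue only: every computation lives in the stage modules. A single YAML config
carries all paths, thresholds and the seed; the run writes every stage output
plus a JSON report of the headline statistics (pattern counts, odds ratios,
dose-response slope, persistence kappa).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import coverage as cov
from . import dose
from . import synthetic as syn
from . import transcription as tr

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a full pipeline run."""

    out_dir: str = "results/run"
    # input paths; when reads_* are None the run simulates its own data
    reads_ctrl: list[str] | None = None
    reads_case: list[str] | None = None
    input_ctrl: list[str] | None = None
    input_case: list[str] | None = None
    tss_bed: str | None = None
    expression_tsv: str | None = None
    differential_tsv: str | None = None
    gene_sets_gmt: str | None = None
    motif_meme: str | None = None
    promoter_fasta: str | None = None
    # thresholds
    marked_confidence: float = cl.MARKED_CONFIDENCE
    pattern_confidence: float = cl.PATTERN_CONFIDENCE
    de_p_threshold: float = tr.DE_P_THRESHOLD
    loess_span: float = 0.5
    motif_score_fraction: float = 0.8
    upstream_window: str = "methods"
    log2_floor: float = cov.LOG2_FLOOR
    seed: int = 0
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("profile")
def _profiles(config: RunConfig):
    if config.reads_ctrl is None:
        gen_cfg = syn.GeneratorConfig(**{"seed": config.seed,
                                         **config.generator})
        exp = syn.generate_profiles(gen_cfg)
        expr, de = syn.generate_expression(exp.truth, gen_cfg)
        chip = {"ctrl": exp.chip_ctrl, "case": exp.chip_case}
        inputs = {"ctrl": exp.input_ctrl, "case": exp.input_case}
        read_frames = {g: [t.to_bed() for t in tracks]
                       for g, tracks in chip.items()}
        input_frames = {g: [t.to_bed() for t in tracks]
                        for g, tracks in inputs.items()}
        return exp.tss, read_frames, input_frames, expr, de, exp.truth
    for path, name in [(config.tss_bed, "tss_bed"),
                       (config.differential_tsv, "differential_tsv")]:
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing required input {name}: {path}")
    tss = cov.read_tss_bed(config.tss_bed)
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]

    def read_beds(paths):
        return [pd.read_csv(p, sep="\t", header=None, names=bed_cols)
                for p in paths]

    read_frames = {"ctrl": read_beds(config.reads_ctrl),
                   "case": read_beds(config.reads_case)}
    input_frames = {"ctrl": read_beds(config.input_ctrl),
                    "case": read_beds(config.input_case)}
    expr = (pd.read_csv(config.expression_tsv, sep="\t")
            if config.expression_tsv else None)
    de = pd.read_csv(config.differential_tsv, sep="\t")
    return tss, read_frames, input_frames, expr, de, None


@_stage("normalize")
def _normalize(config: RunConfig, tss, read_frames, input_frames):
    matrices = {}
    for group in ("ctrl", "case"):
        raws = [cov.bin_depth(cov.extend_reads(r), tss)
                for r in read_frames[group]]
        inps = [cov.bin_depth(cov.extend_reads(r), tss)
                for r in input_frames[group]]
        matrices[group] = cov.normalize_and_subtract(
            raws, inps, floor=config.log2_floor)
    return matrices


@_stage("classify")
def _classify(config: RunConfig, matrices):
    calls = {}
    for group, matrix in matrices.items():
        calls[group] = cl.classify_matrix(
            matrix, marked_confidence=config.marked_confidence,
            confidence=config.pattern_confidence, seed=config.seed,
            upstream_window=config.upstream_window)
    agree = cl.agreement(calls["ctrl"], calls["case"])
    return calls, agree


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: seed=%d marked_confidence=%.3f pattern_confidence=%.3f",
                config.seed, config.marked_confidence, config.pattern_confidence)

    tss, read_frames, input_frames, expr, de, truth = _profiles(config)
    matrices = _normalize(config, tss, read_frames, input_frames)
    for group, m in matrices.items():
        m.to_tsv(out / f"matrix_{group}.tsv")
    calls, agree = _classify(config, matrices)
    for group, c in calls.items():
        c.to_csv(out / f"patterns_{group}.tsv", sep="\t", index=False)
    agree.table.to_csv(out / "agreement_table.tsv", sep="\t")

    de = tr.flag_differential(de, config.de_p_threshold)

    try:
        fisher = tr.pattern_de_fisher(calls["ctrl"], de)
        fisher.to_csv(out / "pattern_de_fisher.tsv", sep="\t", index=False)
        expr_assoc = None
        if expr is not None:
            ctrl_cols = [c for c in expr if c.startswith("ctrl_")]
            means = expr.set_index("gene_id")[ctrl_cols].mean(axis=1)
            expr_assoc = tr.expression_by_pattern(means, calls["ctrl"])
            expr_assoc.to_csv(out / "expression_by_pattern.tsv", sep="\t",
                              index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("associate", exc) from exc

    try:
        summ_ctrl = cov.summarize_regions(matrices["ctrl"],
                                          config.upstream_window)
        summ_case = cov.summarize_regions(matrices["case"],
                                          config.upstream_window)
        changes = dose.region_changes(summ_ctrl, summ_case, de)
        changes = dose.residualize(changes)
        curve, slope, slope_se = dose.response_curve(changes)
        curve.to_csv(out / "response_curve.tsv", sep="\t", index=False)
        de_up = de.loc[de["de_flag"] == "increased", "gene_id"]
        frac = dose.fraction_increased(changes, de_up)
        frac.to_csv(out / "fraction_increased.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("dose_response", exc) from exc

    pattern_counts = calls["ctrl"]["label"].value_counts().to_dict()
    report = {
        "seed": config.seed,
        "thresholds": {"marked_confidence": config.marked_confidence,
                       "pattern_confidence": config.pattern_confidence,
                       "de_p_threshold": config.de_p_threshold},
        "n_tss": int(len(tss)),
        "pattern_counts": {k: int(v) for k, v in pattern_counts.items()},
        "persistence": {"percent_agreement": agree.percent_agreement,
                        "kappa": agree.kappa, "p_value": agree.p_value,
                        "n": agree.n},
        "fisher_or": {
            f"{r.pattern}|{r.direction}": r.odds_ratio
            for r in fisher.itertuples()},
        "dose_response": {"downstream_slope": slope,
                          "downstream_slope_se": slope_se},
        "fraction_increased": {
            r.region: r.fraction_increased for r in frac.itertuples()},
    }
    if truth is not None:
        truth_labels = truth.table.set_index("gene_id")["pattern_ctrl"]
        merged = calls["ctrl"].set_index("gene_id").join(
            truth_labels.rename("truth"))
        classified = merged["truth"].isin(cl.FOUR_PATTERNS)
        report["recovery_accuracy"] = float(
            (merged.loc[classified, "label"]
             == merged.loc[classified, "truth"]).mean())
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
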