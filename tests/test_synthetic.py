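import numpy as np
import pandas as pd
import pytest

from tssbreadth import classify as cl
from tssbreadth import coverage as cov
from tssbreadth import motifs as mo
from tssbreadth import synthetic as syn


class TestConfig:
    def test_defaults_validate(self):
        cfg = syn.GeneratorConfig()
        assert abs(sum(cfg.pattern_proportions.values()) - 1) < 1e-9
        assert cfg.classified_proportions() == pytest.approx(
            {"narrow_peak": 0.10, "upstream_extended": 0.36,
             "downstream_extended": 0.33, "broad_symmetric": 0.21}, abs=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"n_tss": 0},
        {"background_depth": -1.0},
        {"persist_prob": 1.5},
        {"window": (-1000, 1000)},  # does not cover 41 bins of 50 bp
        {"pattern_proportions": {"narrow_peak": 0.5, "unmarked": 0.6}},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = syn.GeneratorConfig(n_tss=50, seed=9)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = syn.GeneratorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = syn.GeneratorConfig(n_tss=60, n_samples_per_group=2, seed=3)
        a = syn.generate_profiles(cfg)
        b = syn.generate_profiles(cfg)
        pd.testing.assert_frame_equal(a.truth.table, b.truth.table)
        for ta, tb in zip(a.chip_ctrl + a.chip_case + a.input_ctrl,
                          b.chip_ctrl + b.chip_case + b.input_ctrl):
            np.testing.assert_array_equal(ta.starts, tb.starts)
            np.testing.assert_array_equal(ta.strands, tb.strands)
        ea, _ = syn.generate_expression(a.truth, cfg)
        eb, _ = syn.generate_expression(b.truth, cfg)
        pd.testing.assert_frame_equal(ea, eb)

    def test_read_conservation(self):
        cfg = syn.GeneratorConfig(n_tss=40, n_samples_per_group=2, seed=4)
        exp = syn.generate_profiles(cfg)
        total = sum(t.starts.size for t in
                    exp.chip_ctrl + exp.chip_case
                    + exp.input_ctrl + exp.input_case)
        assert exp.total_reads == total
        assert all(len(t.to_bed()) == t.starts.size for t in exp.chip_ctrl)


class TestProfiles:
    def test_narrow_archetype_background_outside_peak(self):
        """Pure narrow cohort: downstream +600..+650 bins sit at background."""
        props = {k: 0.0 for k in syn.GeneratorConfig().pattern_proportions}
        props["narrow_peak"] = 1.0
        cfg = syn.GeneratorConfig(n_tss=150, n_samples_per_group=4,
                                  pattern_proportions=props,
                                  background_depth=40.0,  # low-noise regime
                                  persist_prob=1.0, seed=5)
        exp = syn.generate_profiles(cfg)
        raws = [cov.bin_depth(cov.extend_reads(t.to_bed()), exp.tss)
                for t in exp.chip_ctrl]
        inps = [cov.bin_depth(cov.extend_reads(t.to_bed()), exp.tss)
                for t in exp.input_ctrl]
        m = cov.normalize_and_subtract(raws, inps)
        far_down = np.isin(cov.BIN_CENTERS, [600, 650])
        assert abs(m.values[:, far_down].mean()) < 0.05
        center = cov.BIN_CENTERS == 0
        assert m.values[:, center].mean() == pytest.approx(
            cfg.signal_height, abs=0.1)

    def test_pattern_counts_multinomial(self):
        cfg = syn.GeneratorConfig(n_tss=2000, seed=6)
        truth = syn.simulate_truth(cfg)
        counts = truth.table["pattern_ctrl"].value_counts()
        for label, p in cfg.pattern_proportions.items():
            expected = cfg.n_tss * p
            sd = np.sqrt(cfg.n_tss * p * (1 - p))
            assert abs(counts.get(label, 0) - expected) <= 3 * sd

    def test_narrow_and_unmarked_never_switch(self):
        cfg = syn.GeneratorConfig(n_tss=3000, persist_prob=0.5, seed=8)
        t = syn.simulate_truth(cfg).table
        frozen = t["pattern_ctrl"].isin(["narrow_peak", "unmarked"])
        assert (t.loc[frozen, "pattern_case"]
                == t.loc[frozen, "pattern_ctrl"]).all()
        switched = t.loc[~frozen, "pattern_case"] != t.loc[~frozen,
                                                           "pattern_ctrl"]
        assert (t.loc[~frozen, "pattern_case"] != "narrow_peak").all()
        assert switched.mean() == pytest.approx(0.5, abs=0.05)


class TestExpression:
    def test_zero_coefficient_decouples_transcription(self):
        cfg = syn.GeneratorConfig(n_tss=5000, beta_down=0.0, seed=9)
        t = syn.simulate_truth(cfg).table
        # exact decoupling holds where no sign constraint applies; DE genes
        # retain a weak residual association through their flag
        neither = t[t["de_flag"] == "neither"]
        r = np.corrcoef(neither["chg_downstream"],
                        neither["chg_transcription"])[0, 1]
        assert abs(r) < 0.05
        r_all = np.corrcoef(t["chg_downstream"], t["chg_transcription"])[0, 1]
        assert abs(r_all) < 0.2

    def test_unit_multipliers_equalize_pattern_means(self):
        cfg = syn.GeneratorConfig(
            n_tss=6000, seed=10,
            expr_multiplier_by_pattern={k: 1.0 for k in
                                        syn.GeneratorConfig().labels})
        truth = syn.simulate_truth(cfg)
        expr, _ = syn.generate_expression(truth, cfg)
        ctrl = expr.set_index("gene_id")[[c for c in expr
                                          if c.startswith("ctrl_")]]
        means = np.log2(ctrl.mean(axis=1)).groupby(
            truth.table.set_index("gene_id")["pattern_ctrl"]).mean()
        assert means.max() - means.min() < 0.15

    def test_fraction_increased_matches_default(self):
        cfg = syn.GeneratorConfig(n_tss=8000, seed=11)
        t = syn.simulate_truth(cfg).table
        up = t[t["de_flag"] == "increased"]
        frac = (up["chg_downstream"] > 0).mean()
        se = np.sqrt(0.788 * 0.212 / len(up))
        assert frac == pytest.approx(0.788, abs=3 * se)

    def test_de_flags_consistent_with_change_sign(self):
        t = syn.simulate_truth(syn.GeneratorConfig(n_tss=4000, seed=12)).table
        assert (t.loc[t["de_flag"] == "increased", "chg_transcription"] > 0).all()
        assert (t.loc[t["de_flag"] == "decreased", "chg_transcription"] < 0).all()
        assert (t.loc[t["de_flag"] != "neither", "p_value"] < 0.01).all()
        assert (t.loc[t["de_flag"] == "neither", "p_value"] >= 0.01).all()

    def test_mismatched_truth_rejected(self):
        cfg = syn.GeneratorConfig(n_tss=50, seed=1)
        truth = syn.simulate_truth(cfg)
        other = syn.GeneratorConfig(n_tss=60, seed=1)
        with pytest.raises(ValueError):
            syn.generate_expression(truth, other)


class TestMotifData:
    def test_zero_plant_rate_empty_truth(self):
        cfg = syn.GeneratorConfig(
            n_tss=30, seed=2,
            plant_rate_by_pattern={k: 0.0 for k in
                                   syn.GeneratorConfig().labels})
        _, _, planted = syn.generate_motif_data(cfg)
        assert len(planted) == 0

    def test_single_plant_position_and_scan_recovery(self):
        cfg = syn.GeneratorConfig(n_tss=1, seed=3, n_motifs=1,
                                  plant_rate_by_pattern={
                                      k: 0.0 for k in
                                      syn.GeneratorConfig().labels})
        truth = syn.simulate_truth(cfg)
        seqs, pwms, _ = syn.generate_motif_data(cfg, truth)
        gid = truth.table["gene_id"].iloc[0]
        pwm = pwms[0]
        seq = list(seqs[gid])
        seq[990:990 + len(pwm)] = list(pwm.consensus)  # position -10
        matches = mo.scan({gid: "".join(seq)}, pwm)
        assert (matches["position"] == -10).any()

    def test_plant_rate_ratio_recovered(self):
        rates = {k: 1.0 for k in syn.GeneratorConfig().labels}
        rates["narrow_peak"] = 2.0
        props = {k: 0.0 for k in syn.GeneratorConfig().pattern_proportions}
        props.update({"narrow_peak": 0.5, "broad_symmetric": 0.5})
        cfg = syn.GeneratorConfig(n_tss=2000, seed=4, n_motifs=1,
                                  pattern_proportions=props,
                                  plant_rate_by_pattern=rates)
        truth = syn.simulate_truth(cfg)
        _, _, planted = syn.generate_motif_data(cfg, truth)
        labels = truth.table.set_index("gene_id")["pattern_ctrl"]
        counts = planted.join(labels, on="gene_id")["pattern_ctrl"].value_counts()
        n_a = (labels == "narrow_peak").sum()
        n_b = (labels == "broad_symmetric").sum()
        ratio = (counts["narrow_peak"] / n_a) / (counts["broad_symmetric"] / n_b)
        # Poisson SE of a rate ratio at ~1000 TSSs per group
        se = ratio * np.sqrt(1 / counts["narrow_peak"]
                             + 1 / counts["broad_symmetric"])
        assert abs(ratio - 2.0) <= 3 * se

    def test_motif_longer_than_window_rejected(self):
        cfg = syn.GeneratorConfig(n_tss=5, seed=5, motif_length=50,
                                  seq_window=(-20, 20))
        with pytest.raises(ValueError, match="longer"):
            syn.generate_motif_data(cfg)
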