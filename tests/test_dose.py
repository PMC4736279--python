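import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tssbreadth import dose
from tssbreadth import synthetic as syn


def _summary(gene_ids, up, tss, down):
    return pd.DataFrame({"gene_id": gene_ids, "upstream_mean": up,
                         "tss_mean": tss, "downstream_mean": down})


def _de(gene_ids, pct=0.0):
    return pd.DataFrame({"gene_id": gene_ids,
                         "pct_change": np.full(len(gene_ids), pct),
                         "de_flag": ["neither"] * len(gene_ids)})


class TestRegionChanges:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, 0.0), (1.0, 100.0), (-1.0, -50.0),
    ])
    def test_log2_to_percent_scale(self, delta, expected):
        ids = ["g1"]
        ctrl = _summary(ids, [0.5], [1.0], [0.2])
        case = _summary(ids, [0.5 + delta], [1.0 + delta], [0.2 + delta])
        out = dose.region_changes(ctrl, case, _de(ids))
        for region in dose.REGIONS:
            assert out[region].iloc[0] == pytest.approx(expected)

    def test_missing_genes_dropped(self):
        ctrl = _summary(["g1", "g2"], [0, 0], [0, 0], [0, 0])
        case = _summary(["g1"], [0], [0], [0])
        out = dose.region_changes(ctrl, case, _de(["g1", "g2"]))
        assert out["gene_id"].tolist() == ["g1"]


class TestResidualize:
    def test_independent_columns_nearly_unchanged(self, rng):
        n = 2000
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "upstream": rng.normal(0, 4, n),
            "tss": rng.normal(0, 4, n),
            "downstream": rng.normal(0, 4, n),
            "transcription": rng.normal(0, 3, n),
        })
        out = dose.residualize(table)
        for region in dose.REGIONS:
            r = np.corrcoef(out[region], out[f"{region}_resid"])[0, 1]
            assert r > 0.99

    def test_perfect_dependence_zeroed(self, rng):
        n = 500
        up = rng.normal(0, 4, n)
        up -= up.mean()  # zero-mean so the added-back grand mean is zero
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "upstream": up, "tss": rng.normal(0, 4, n), "downstream": up,
            "transcription": np.zeros(n),
        })
        out = dose.residualize(table)
        assert np.abs(out["downstream_resid"]).max() < 1e-9

    def test_recovers_independent_component(self, rng):
        n = 5000
        up = rng.normal(0, 4, n)
        eps = rng.normal(0, 2, n)
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "upstream": up, "tss": rng.normal(0, 4, n),
            "downstream": up + eps, "transcription": np.zeros(n),
        })
        out = dose.residualize(table)
        r = np.corrcoef(out["downstream_resid"], eps)[0, 1]
        assert r > 0.99

    @given(st.integers(0, 2 ** 31 - 1))
    def test_residual_orthogonality(self, seed):
        g = np.random.default_rng(seed)
        n = 200
        shared = g.normal(0, 3, n)
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "upstream": shared + g.normal(0, 2, n),
            "tss": shared + g.normal(0, 2, n),
            "downstream": shared + g.normal(0, 2, n),
            "transcription": g.normal(0, 3, n),
        })
        out = dose.residualize(table)
        for region in dose.REGIONS:
            resid = out[f"{region}_resid"] - out[region].mean()
            for other in dose.REGIONS:
                if other != region:
                    r = np.corrcoef(resid, out[other])[0, 1]
                    assert abs(r) < 1e-8

    def test_too_few_genes_rejected(self):
        table = pd.DataFrame({"gene_id": ["g1"], "upstream": [1.0],
                              "tss": [1.0], "downstream": [1.0],
                              "transcription": [0.0]})
        with pytest.raises(ValueError):
            dose.residualize(table)


class TestResponseCurve:
    def test_single_bin_mean(self):
        n = 100
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "downstream": np.full(n, 2.0),
                              "transcription": np.full(n, 3.0)})
        curve, _, _ = dose.response_curve(table, use_residualized=False)
        assert curve.loc[curve["bin_center"] == 2,
                         "mean_transcription"].iloc[0] == pytest.approx(3.0)

    def test_independent_changes_null_slope(self, rng):
        n = 5000
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "downstream": rng.normal(0, 5, n),
                              "transcription": rng.normal(0, 3, n)})
        _, slope, slope_se = dose.response_curve(table,
                                                 use_residualized=False)
        assert abs(slope) < 0.1

    @pytest.mark.parametrize("beta", [0.0, 0.5, 1.5, 3.0])
    def test_slope_recovery_across_coefficients(self, beta):
        """The generator's response coefficient is recovered from the curve."""
        cfg = syn.GeneratorConfig(n_tss=5000, beta_down=beta, seed=21)
        table = dose.residualize(syn.simulate_truth(cfg).region_change_table())
        _, slope, _ = dose.response_curve(table)
        # 2 Monte-Carlo SE of the binned estimator (~0.03 per unit slope)
        assert slope == pytest.approx(beta, abs=0.08 + 0.02 * beta)

    def test_bins_partition_included_genes(self, rng):
        n = 3000
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "downstream": rng.normal(0, 4, n),
                              "transcription": rng.normal(0, 3, n)})
        curve, _, _ = dose.response_curve(table, use_residualized=False)
        in_range = np.abs(np.rint(table["downstream"])) <= 10
        assert curve["n"].sum() == in_range.sum()


class TestFractionIncreased:
    def test_all_positive(self):
        n = 50
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "upstream": np.ones(n), "tss": np.ones(n),
                              "downstream": np.ones(n)})
        out = dose.fraction_increased(table, table["gene_id"],
                                      use_residualized=False)
        assert (out["fraction_increased"] == 1.0).all()

    def test_symmetric_changes_near_half(self, rng):
        n = 4000
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "upstream": rng.normal(0, 4, n),
                              "tss": rng.normal(0, 4, n),
                              "downstream": rng.normal(0, 4, n)})
        out = dose.fraction_increased(table, table["gene_id"],
                                      use_residualized=False)
        assert np.allclose(out["fraction_increased"], 0.5, atol=0.03)

    def test_empty_list_errors(self):
        table = pd.DataFrame({"gene_id": ["g1"], "upstream": [1.0],
                              "tss": [1.0], "downstream": [1.0]})
        with pytest.raises(ValueError):
            dose.fraction_increased(table, [])


class TestExternalGenesetSummary:
    @staticmethod
    def _table(rng, n=2000):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "upstream": rng.normal(1, 4, n),
                             "tss": rng.normal(2, 4, n),
                             "downstream": rng.normal(3, 4, n)})

    def test_full_list_centers_to_zero(self, rng):
        table = self._table(rng)
        out = dose.external_geneset_summary(table,
                                            {"all": list(table["gene_id"])})
        assert np.allclose(out["mean_change"], 0.0, atol=1e-12)

    def test_random_list_near_zero(self, rng):
        table = self._table(rng)
        genes = list(rng.choice(table["gene_id"], 400, replace=False))
        out = dose.external_geneset_summary(table, {"rand": genes})
        assert np.all(np.abs(out["mean_change"]) < 3 * out["se"] + 0.3)

    def test_constructed_shift_recovered(self, rng):
        table = self._table(rng)
        shifted = list(table["gene_id"][:200])
        table.loc[:199, "downstream"] += 5.0
        out = dose.external_geneset_summary(table, {"up5": shifted})
        down = out[(out["region"] == "downstream")]["mean_change"].iloc[0]
        other = out[(out["region"] != "downstream")]["mean_change"].abs()
        assert down == pytest.approx(5.0 * (1 - 200 / 2000), abs=0.9)
        assert (other < 0.9).all()
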