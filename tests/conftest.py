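import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tssbreadth import classify as cl
from tssbreadth import coverage as cov
from tssbreadth import synthetic as syn

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def experiment() -> syn.SimulatedExperiment:
    """A default-condition synthetic cohort shared across the suite."""
    cfg = syn.GeneratorConfig(n_tss=500, seed=7)
    return syn.generate_profiles(cfg)


def _group_matrix(exp, chip, inputs):
    raws = [cov.bin_depth(cov.extend_reads(t.to_bed()), exp.tss) for t in chip]
    inps = [cov.bin_depth(cov.extend_reads(t.to_bed()), exp.tss)
            for t in inputs]
    return cov.normalize_and_subtract(raws, inps)


@pytest.fixture(scope="session")
def matrices(experiment):
    return {
        "ctrl": _group_matrix(experiment, experiment.chip_ctrl,
                              experiment.input_ctrl),
        "case": _group_matrix(experiment, experiment.chip_case,
                              experiment.input_case),
    }


@pytest.fixture(scope="session")
def calls(matrices):
    return {group: cl.classify_matrix(m, seed=3)
            for group, m in matrices.items()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
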