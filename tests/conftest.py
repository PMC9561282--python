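import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from driploop.pipeline import run_break_pipeline
from driploop.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def summarize_run(res):
    """Scalar summary of one simulated experiment (keeps memory light)."""
    ctrl, kd = res["correlation"]["ctrl"], res["correlation"]["kd"]
    out = {
        "accuracy": res["accuracy"],
        "counts": res["counts"],
        "ctrl_r": ctrl.statistic, "ctrl_p": ctrl.p,
        "kd_r": kd.statistic, "kd_p": kd.p,
    }
    if "preexisting_contrast" in res:
        out["contrast_p"] = res["preexisting_contrast"].test.p
    return out


N_MC_SEEDS = 50


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic experiment (99 sites, planted 40/51/8, seed 17)."""
    return run_break_pipeline(SimConfig(seed=17))


@pytest.fixture(scope="session")
def coupled_runs():
    """Per-seed summaries with dependence coupled to low pre-existing level."""
    return [summarize_run(run_break_pipeline(SimConfig(seed=s)))
            for s in range(1, N_MC_SEEDS + 1)]


@pytest.fixture(scope="session")
def uncoupled_runs():
    """Per-seed summaries with the class/pre-existing coupling disabled."""
    return [summarize_run(run_break_pipeline(SimConfig(seed=s, coupling_shift=0.0)))
            for s in range(1, N_MC_SEEDS + 1)]


@pytest.fixture
def tiny_cfg():
    """Desk-scale configuration: a few sites on small contigs, small library."""
    return SimConfig(
        n_sites=6,
        genome=(("chrA", 400_000), ("chrB", 400_000)),
        library_size=30_000,
        seed=11,
    )
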