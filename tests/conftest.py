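import numpy as np
import pytest

import raterdrift as rd
from raterdrift.experiments import RecoveryConfig, run_recovery
from raterdrift.inference import SamplerConfig

# Scaled-down study budget: 3 chains, 1000 warmup + 1000 retained draws.
SCALED_SAMPLER = dict(chains=3, iterations=2000, warmup=1000)


def _recovery(design, variant, reps, seed=0):
    cfg = RecoveryConfig(
        J_values=(100,), R_values=(5,), T_values=(3,),
        replications=reps, design=design, seed=seed,
        sampler=SamplerConfig(**SCALED_SAMPLER),
    )
    return run_recovery(cfg, variant=variant)


@pytest.fixture(scope="session")
def crossed_recovery():
    """10-rep recovery at (J=100, R=5, T=3), fully crossed, both variants."""
    return {
        "proposed": _recovery("crossed", "proposed", 10),
        "no_markov": _recovery("crossed", "proposed_no_markov", 10),
    }


@pytest.fixture(scope="session")
def link2_recovery():
    """10-rep recovery at (100, 5, 3) under the 2-rater link design."""
    return {
        "proposed": _recovery("link2", "proposed", 10),
        "no_markov": _recovery("link2", "proposed_no_markov", 10),
    }


@pytest.fixture(scope="session")
def link3_recovery():
    """6-rep recovery at (100, 5, 3) under the 3-rater link design."""
    return {
        "proposed": _recovery("link3", "proposed", 6),
        "no_markov": _recovery("link3", "proposed_no_markov", 6),
    }


@pytest.fixture(scope="session")
def reference_fit():
    """One seeded full-budget fit at (J=100, R=5, T=3), fully crossed."""
    truth = rd.draw_parameters(100, 5, 3, seed=101)
    design = rd.fully_crossed_design(100, 5, 3, seed=102)
    data = rd.simulate_scores(truth, design, seed=103)
    draws = rd.fit(data, "proposed", config=rd.SamplerConfig(seed=7))
    return truth, data, draws


@pytest.fixture(scope="session")
def small_study():
    """A small crossed study plus a quick proposed-model fit."""
    truth = rd.draw_parameters(20, 4, 3, seed=5)
    design = rd.fully_crossed_design(20, 4, 3, seed=6)
    data = rd.simulate_scores(truth, design, seed=7)
    draws = rd.fit(
        data, "proposed",
        config=rd.SamplerConfig(chains=2, iterations=900, warmup=400, seed=3),
    )
    return truth, data, draws


@pytest.fixture
def tiny_data():
    truth = rd.draw_parameters(6, 3, 2, seed=11)
    design = rd.fully_crossed_design(6, 3, 2, seed=12)
    return rd.simulate_scores(truth, design, seed=13)
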