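import dataclasses

import numpy as np
import pytest

import spatialedge as se

COHORT_CONFIG = se.STConfig(core_program_size=50, edge_program_size=50, n_genes=400)


@pytest.fixture(scope="session")
def default_sample():
    """One default-condition spatial sample (seed 1)."""
    return se.simulate_st_sample(seed=1)


@pytest.fixture(scope="session")
def annotated(default_sample):
    """The default sample run through the full annotation pipeline."""
    return se.annotate_sample(default_sample, seed=0)


@pytest.fixture(scope="session")
def velocity_result(annotated):
    return se.compute_velocity(annotated)


@pytest.fixture(scope="session")
def engine(annotated, velocity_result):
    labels = annotated.obs.loc[velocity_result.spot_ids, "region"]
    return se.PerturbationEngine(velocity_result, labels)


@pytest.fixture(scope="session")
def cohort12():
    """Twelve-sample synthetic cohort with 50 planted genes per
    direction, annotated."""
    samples = se.simulate_cohort(12, COHORT_CONFIG, seed=5)
    return [se.annotate_sample(a, seed=0) for a in samples]
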