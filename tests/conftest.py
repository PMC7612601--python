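import dataclasses

import numpy as np
import pytest

import swadapt as sw


@pytest.fixture(scope="session")
def scenarios():
    return sw.builtin_scenarios()


@pytest.fixture(scope="session")
def tds1(scenarios):
    return scenarios["TDS1"]


@pytest.fixture(scope="session")
def tds2(scenarios):
    return scenarios["TDS2"]


@pytest.fixture(scope="session")
def tds3(scenarios):
    return scenarios["TDS3"]


@pytest.fixture(scope="session")
def worked_example(tds2):
    """The TDS2 interim at p=3 with Z=1: all six candidates, fully scored."""
    policy = sw.AdaptationPolicy(w=0.5, eta=0.0, gamma=2.5)
    cands = sw.enumerate_candidates(tds2.design.X_init, 3, policy)
    sw.combined_scores(cands, 1.0, 3, tds2.design, tds2.vc, policy)
    return {c.matrix.to_string(): c for c in cands}


#: The six continuation matrices of the TDS2 interim, keyed M1..M6, with their
#: published information, benefit (Z=1, eta=0, gamma=2.5) and score (w=0.5).
WORKED_EXAMPLE_ROWS = {
    "M1": ("01111,00111,00000,00000", 188.5, 0.001, 0.420),
    "M2": ("01111,00111,00001,00000", 224.5, 0.013, 0.513),
    "M3": ("01111,00111,00001,00001", 204.7, 0.107, 0.563),
    "M4": ("01111,00111,00011,00000", 222.2, 0.107, 0.601),
    "M5": ("01111,00111,00011,00001", 215.2, 0.378, 0.856),
    "M6": ("01111,00111,00011,00011", 169.8, 0.501, 0.878),
}


def random_monotone_matrix(rng, C, P):
    """A random valid roll-out matrix with at least two distinct switch times."""
    while True:
        times = rng.integers(1, P + 2, size=C)  # P+1 encodes "never"
        if len(np.unique(np.minimum(times, P + 1))) > 1:
            break
    rows = [(np.arange(1, P + 1) >= t).astype(np.int8) for t in times]
    return sw.AllocationMatrix(np.array(rows))


@pytest.fixture
def small_config():
    """A small cross-sectional scenario for fast exact checks."""
    X = sw.AllocationMatrix.from_string("0111,0011,0001,0000")
    design = sw.TrialDesign(C=4, P=4, m=3, cohort=sw.Cohort.CROSS_SECTIONAL,
                            X_init=X, interim_periods=(2,), alpha=0.05,
                            beta=0.2, delta=0.5)
    vc = sw.VarianceComponents(sigma2_c=0.3, sigma2_pi=0.1, sigma2_e=1.0)
    policy = sw.AdaptationPolicy(w=0.5, eta=0.0, gamma=2.5)
    return sw.ScenarioConfig(design=design, vc=vc, policy=policy,
                             theta_true=0.5, n_reps=10, seed=7)
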