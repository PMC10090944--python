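import numpy as np
import pytest

from xlscreen import synthetic
from xlscreen.model_io import ScoreRecord


@pytest.fixture(scope="session")
def trimer_model():
    """Three-chain toy complex with distinct accessions."""
    return synthetic.gen_toy_complex(
        [("ACCA", 60), ("ACCB", 50), ("ACCC", 40)], seed=11
    )


@pytest.fixture(scope="session")
def dimer_model():
    return synthetic.gen_toy_complex([("ACCA", 50), ("ACCB", 40)], seed=5)


@pytest.fixture(scope="session")
def sim_cfg():
    return synthetic.SimConfig(
        seed=3,
        n_proteins=20,
        complex_spec=[("CPA", "CPB", "CPC", "CPD"), ("CPE", "CPF")],
    )


@pytest.fixture(scope="session")
def elution(sim_cfg):
    return synthetic.gen_elution_dataset(sim_cfg, seed=sim_cfg.seed)


def make_score_record(pair, best, n_models=1):
    scores = [(best, 0.5)] + [(best * 0.8, 0.5)] * (n_models - 1)
    return ScoreRecord(members=tuple(pair), model_scores=scores)


@pytest.fixture
def score_records():
    rng = np.random.default_rng(42)
    return [
        make_score_record((f"P{i:03d}", f"Q{i:03d}"), float(rng.uniform(0, 1)))
        for i in range(200)
    ]
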