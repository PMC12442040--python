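import logging

import pytest

import kmdmsi as K
from kmdmsi import evaluate as E

logging.getLogger("kmdmsi").setLevel(logging.ERROR)

#: Seed for every stochastic fixture in the suite.
SEED = 1


@pytest.fixture(scope="session")
def lipid_table():
    return K.load_lipid_table()


@pytest.fixture(scope="session")
def phantom64():
    return K.build_phantom(K.PhantomSpec(height=64, width=64, seed=SEED))


@pytest.fixture(scope="session")
def assignments():
    return K.default_assignments()


@pytest.fixture(scope="session")
def default_run(phantom64, assignments):
    """The default 64x64 phantom acquisition plus a full pipeline run."""
    dataset, truth = K.simulate_dataset(phantom64, assignments, seed=SEED)
    result = K.run_pipeline(dataset)
    return {
        "phantom": phantom64,
        "assignments": assignments,
        "dataset": dataset,
        "truth": truth,
        "result": result,
        "ions": E.theoretical_ions(assignments),
    }


@pytest.fixture(scope="session")
def tables_report():
    return K.recompute_tables()
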