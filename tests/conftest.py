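import pytest

from carrierdetect.pipeline import run_pipeline
from carrierdetect.synthetic_data import RunConfig, simulate_run

#: Single fixed seed for the shared end-to-end run; all stochastic
#: assertions on it are made against its truth table.
RUN_SEED = 42


@pytest.fixture(scope="session")
def default_run():
    """Desk-scale synthetic run: 5,000 carrier / 5 target / 3 contaminant
    reads plus two bad-pore channels emitting 10 noise reads each."""
    return simulate_run(RunConfig(seed=RUN_SEED))


@pytest.fixture(scope="session")
def default_result(default_run):
    return run_pipeline(default_run.reads, default_run.carrier_genome)


@pytest.fixture(scope="session")
def truth_by_id(default_run):
    return {label.read_id: label.origin for label in default_run.truth}
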