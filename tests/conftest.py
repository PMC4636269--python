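import numpy as np
import pytest

from acariscan import BioassayDataset, BioassayObservation
from acariscan.synth import ProbitTruth, SimulationConfig, simulate_bioassay


@pytest.fixture
def rng():
    return np.random.default_rng(20150934)


@pytest.fixture
def symmetric_toy():
    """Three log-spaced doses with mortality symmetric about dose 10."""
    return BioassayDataset(
        strain="toy",
        acaricide="toy",
        observations=[
            BioassayObservation(1.0, 100, 0),
            BioassayObservation(10.0, 100, 50),
            BioassayObservation(100.0, 100, 100),
        ],
    )


@pytest.fixture
def four_dose_assay():
    """Small 4-dose dataset drawn from a known probit line."""
    cfg = SimulationConfig(
        seed=11, probit=ProbitTruth(ld50=0.5, slope=1.8), n_doses=4, n_per_vial=40, n_replicates=1
    )
    return simulate_bioassay(cfg)


@pytest.fixture(scope="session")
def mutation_panel():
    from acariscan import load_mutation_panel

    return load_mutation_panel()
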