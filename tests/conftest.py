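import logging

import pytest
from hypothesis import settings

import braakadl as ba

# quiet the skip-pattern staging warnings during bulk simulation
logging.getLogger("braakadl").setLevel(logging.ERROR)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One staged default synthetic cohort (n=291), shared across tests."""
    cfg = ba.SyntheticConfig(seed=11)
    thresholds = ba.estimate_thresholds(ba.generate_reference(cfg))
    return ba.stage_cohort(ba.generate_cohort(cfg), thresholds)
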