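import numpy as np
import pytest

import scaleshort as ss

# published GPCM calibration of the SPD-10, used as ground truth for the
# synthetic-data generator throughout the suite
SPD7_ITEMS = ("CRF1", "CRF2", "CRF3", "CRF4", "CRF6", "CRF8", "CRF9")


@pytest.fixture(scope="session")
def spd10_bank() -> ss.ItemBank:
    return ss.load_spd10_bank()


@pytest.fixture(scope="session")
def spd10_profiles():
    return ss.load_spd10_profiles()


@pytest.fixture(scope="session")
def sim164(spd10_bank) -> ss.ResponseMatrix:
    """One instrument-sized synthetic sample (164 persons, 10 items)."""
    thetas = ss.simulate_thetas(164, 11)
    return ss.simulate_responses(spd10_bank, thetas, 12)


@pytest.fixture(scope="session")
def sim_large(spd10_bank) -> ss.ResponseMatrix:
    """A large synthetic sample for asymptotic checks."""
    thetas = ss.simulate_thetas(20000, 21)
    return ss.simulate_responses(spd10_bank, thetas, 22)
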