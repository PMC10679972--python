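from __future__ import annotations

import numpy as np
import pytest

from spatial_ith.synthetic_data import (
    DEConfig,
    DSPConfig,
    GenomicsConfig,
    simulate_de,
    simulate_dsp,
    simulate_genomics,
)


@pytest.fixture(scope="session")
def genomics_result():
    """One deterministic synthetic WES cohort shared across tests."""
    return simulate_genomics(GenomicsConfig(seed=1))


@pytest.fixture(scope="session")
def dsp_result():
    return simulate_dsp(DSPConfig(seed=1))


@pytest.fixture(scope="session")
def de_result():
    return simulate_de(DEConfig(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)
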