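import numpy as np
import pandas as pd
import pytest

from ednaquant import SimulationConfig, simulate_dilution_series, simulate_scenario


def make_standards(slope, intercept, copies, cq_jitter=None):
    """Plate table of standard wells lying on (or jittered around) a line."""
    copies = np.asarray(copies, dtype=float)
    cq = intercept + slope * np.log10(copies)
    if cq_jitter is not None:
        cq = cq + np.asarray(cq_jitter, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(copies.size)],
            "replicate": np.arange(1, copies.size + 1),
            "assay": "A",
            "reaction_type": "standard",
            "known_copies": copies,
            "cq": cq,
        }
    )


@pytest.fixture(scope="session")
def dilution_plate():
    """Deterministic ten-replicate serial-dilution plate (default config)."""
    return simulate_dilution_series(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def yangyang():
    """Default four-assay survey scenario: (plate, truth)."""
    return simulate_scenario("yangyang-default", seed=42)
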