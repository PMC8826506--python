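import numpy as np
import pytest

from tastekit.simulate import (
    HillParams,
    LigandDef,
    PlateRecord,
    ReceptorSimParams,
)


@pytest.fixture
def small_panel():
    return [
        LigandDef("sucralose", "sweetener", 100.0),
        LigandDef("sucrose", "sugar", 100.0),
        LigandDef("glycine", "amino_acid", 100.0),
        LigandDef("proline", "amino_acid", 100.0),
    ]


@pytest.fixture
def small_params():
    hill = {
        "sucralose": HillParams(150.0, 8.0, 1.5),
        "sucrose": HillParams(120.0, 25.0, 1.5),
        "glycine": HillParams(60.0, 35.0, 1.5),
        "proline": HillParams(0.0, 50.0, 1.5),
    }
    return {
        "rx": ReceptorSimParams(
            hill=hill, baseline=5.0, batch_scale_sd=0.15, noise_sd=6.0
        )
    }


def make_records(receptor, mix, values, batches=None):
    """Hand-build a well group with explicit responses."""
    mix = tuple(mix)
    if batches is None:
        batches = [i % 2 for i in range(len(values))]
    return [
        PlateRecord(receptor, mix, i, b, float(v))
        for i, (v, b) in enumerate(zip(values, batches))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
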