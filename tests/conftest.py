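"""Shared fixtures: deterministic sources, spectra and a small trained model."""

import numpy as np
import pytest

from pyrotrace import synth, thermometer


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flint_source(rng):
    return synth.random_source("fixture-src", rng)


@pytest.fixture()
def plain_source():
    """A source with no jitter, no carbon and a flat baseline."""
    return synth.FlintSource(
        source_id="plain",
        moganite_fraction=0.6,
        carbon_load=0.0,
        baseline_shape_coeffs=(0.0,),
        response_jitter={},
    )


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained thermometer shared by prediction-contract tests.

    Two sources, five temperatures, five replicates: enough structure
    for sane predictions without noticeable training time.
    """
    rng = np.random.default_rng(99)
    sources = [synth.random_source(f"s{i}", rng) for i in range(2)]
    spectra, temps = [], []
    for src in sources:
        for temp in (20.0, 200.0, 400.0, 600.0, 800.0):
            for _ in range(5):
                spectra.append(
                    synth.simulate_flint_raman(temp, src, seed=int(rng.integers(2**31 - 1)))
                )
                temps.append(temp)
    model = thermometer.train_thermometer(
        spectra,
        temps,
        hyperparams={"epochs": 90, "channels": (8, 16), "lr": 3e-3},
        seed=7,
    )
    return model, spectra, temps
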