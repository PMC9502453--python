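import numpy as np
import pytest
from hypothesis import settings

from ms2fp.records import Peak, SpectrumRecord

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_record(
    record_id="r1",
    compound_id="c1",
    peaks=((100.0, 50.0), (150.0, 100.0), (200.0, 10.0)),
    **kwargs,
):
    defaults = dict(
        instrument_type="LC-ESI-QTOF",
        ionisation_mode="positive",
        precursor_type="[M+H]+",
        precursor_mz=301.10728,
        molecular_weight=300.1,
        collision_energy_value=35.0,
        collision_energy_unit="V",
    )
    defaults.update(kwargs)
    return SpectrumRecord(
        record_id=record_id,
        compound_id=compound_id,
        peaks=[Peak(mz, i) for mz, i in peaks],
        **defaults,
    )


@pytest.fixture
def good_record():
    return make_record()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic dataset shared across tests."""
    from ms2fp.simulate import SynthConfig, generate

    return generate(SynthConfig(n_compounds=60, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
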