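import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import irkwall as ik
from irkwall.transport import RunConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ir192_spectrum():
    """Encapsulated-source fluence spectrum at the reference point."""
    return ik.attenuated_spectrum(ik.hdr_ir192_classic_source())


@pytest.fixture(scope="session")
def iner_chamber():
    return ik.standard_chamber("iner")


@pytest.fixture(scope="session")
def transparent():
    return ik.fictitious_material(0.0, 0.0, 1.0, name="transparent")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def iner_run_large(iner_chamber, ir192_spectrum):
    """The headline chamber run: encapsulated-source spectrum, 1e7 histories."""
    return ik.simulate_chamber(
        iner_chamber, ir192_spectrum, RunConfig(n_histories=10_000_000, seed=100)
    )


@pytest.fixture(scope="session")
def phantom_profiles(ir192_spectrum):
    """Dose profiles for the three source placements, 2e7 histories each."""
    phantom = ik.PhantomSpec()
    out = {}
    for pos, seed in (("central_axis", 101), ("A", 102), ("B", 103)):
        out[pos] = ik.simulate_phantom(
            phantom, pos, ir192_spectrum, RunConfig(n_histories=20_000_000, seed=seed)
        )
    return out
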