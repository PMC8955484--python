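"""Shared fixtures: the benchmark chloride/POPC system and cheap stand-ins."""

import numpy as np
import pytest

from uniportsim import ReleaseCurve, reference_config, simulate


@pytest.fixture(scope="session")
def ref():
    """Bundled benchmark profile (chloride/POPC, 200 nm vesicles)."""
    return reference_config()


@pytest.fixture(scope="session")
def ref_traj(ref):
    """Full 300 s adaptive reference run at 1 %mol carrier."""
    return simulate(ref.carrier, ref.membrane, ref.dispersion, 1.0, ref.guest_in, ref.sim)


@pytest.fixture()
def fake_simulator():
    """Analytic saturating-release stand-in for the transport engine.

    ``release(t) = 1 - exp(-k t)`` with a rate that grows linearly with D and
    dose and saturates in Dc, mimicking the carrier-limited regime.  Calls are
    counted on the function's ``calls`` attribute.
    """
    times = np.arange(0.0, 301.0, 5.0)

    def sim(params, dose):
        sim.calls += 1
        k = 0.004 * dose * (params["D"] / 1.5e-13) * (params["Dc"] / (params["Dc"] + 3e-14))
        return ReleaseCurve(times=times, release=1.0 - np.exp(-k * times), dose_molpct=dose)

    sim.calls = 0
    return sim
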