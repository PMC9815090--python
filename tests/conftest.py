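"""Shared fixtures: small networks, reference kinetics, calibrated surrogate."""

from types import SimpleNamespace

import numpy as np
import pytest

import reactorlifelines as rl


def make_ring(volumes, flow=0.8, dispersion=0.0):
    """One-way ring network over the given volumes."""
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.size
    flows = np.zeros((n, n))
    for a in range(n):
        flows[a, (a + 1) % n] = flow
    return rl.CompartmentNetwork(
        volumes=volumes, flows=flows, dispersion_rate=dispersion
    )


def fake_field(q_rel):
    """Duck-typed substrate field with prescribed per-compartment q_rel."""
    return SimpleNamespace(q_rel=np.asarray(q_rel, dtype=float))


@pytest.fixture(scope="session")
def kinetics():
    return rl.KineticsParams.penicillin_reference()


@pytest.fixture(scope="session")
def ring4():
    return make_ring([1.0, 1.5, 0.8, 1.2], flow=0.7)


@pytest.fixture(scope="session")
def calibrated():
    """Two-loop surrogate calibrated to the vessel's probe metrics."""
    return rl.calibrate_network()


@pytest.fixture(scope="session")
def gradient(calibrated, kinetics):
    network = calibrated.network.with_feed(0.37)
    field = rl.steady_substrate_field(network, kinetics, feed=0.37)
    return network, field


@pytest.fixture(scope="session")
def surrogate_lifelines(gradient):
    """A modest parcel ensemble on the calibrated surrogate (burned in)."""
    network, field = gradient
    raw = rl.simulate_parcels(
        network, field, n_parcels=60, duration=500.0, sample_dt=0.03, seed=1234
    )
    return rl.discard_initial(raw, 100.0)
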