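"""Shared fixtures: one canonical schedule, phantom and simulated session
(session-scoped, so the expensive simulation work is amortized)."""

import numpy as np
import pytest

from emfl import (
    NoiseParams,
    generate_schedule,
    make_phantom,
    simulate_session,
)
from emfl.glm import fit_session

CANONICAL_SEED = 11


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(5, seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(seed=23)


@pytest.fixture(scope="session")
def parcel_mask(phantom):
    return phantom.parcels > 0


@pytest.fixture(scope="session")
def emfl_session(phantom, schedule, parcel_mask):
    return simulate_session(phantom, schedule, seed=37, mask=parcel_mask)


@pytest.fixture(scope="session")
def emfl_fit(emfl_session, parcel_mask):
    return fit_session(emfl_session, mask=parcel_mask)


NOISELESS = NoiseParams(noise_sd=0.0, ar_coefficient=0.0, drift_amplitude=0.0,
                        session_jitter_sd=0.0, nuisance_leak_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(seed=23, noise=NOISELESS)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_phantom, schedule):
    mask = noiseless_phantom.parcels > 0
    return simulate_session(noiseless_phantom, schedule, seed=37, mask=mask)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_session, noiseless_phantom):
    return fit_session(noiseless_session, mask=noiseless_phantom.parcels > 0)


def masked_truth(phantom, fit):
    """Ground-truth amplitude matrix restricted to the fitted voxels."""
    amp = phantom.amplitude_matrix()
    return amp[:, fit.voxel_indices]


def estimable_truth(phantom, fit):
    """Ground-truth betas projected onto the identifiable subspace (the
    modality-mean split removed, matching the minimum-norm convention)."""
    amp = masked_truth(phantom, fit)
    v = fit.null_space[:, 0][: amp.shape[0]]
    return amp - np.outer(v, v @ amp)
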