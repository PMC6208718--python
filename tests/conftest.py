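"""Shared fixtures: the frozen synthetic torso-heart study.

All heavy fixtures are session-scoped and deterministic.  The study uses
a scaled-down concentric-sphere setup (30 heart nodes, 40 electrodes,
256 ms beats with 100 ms APD) so the whole suite runs at desk scale; the
package defaults keep the full-scale values.
"""

from __future__ import annotations

import numpy as np
import pytest

import epiwave as ew

# Frozen study conditions
GEOM_KW = dict(q_target=30, r_target=40, heart_radius=30.0,
               torso_radius=120.0, seed=0)
BEAT_KW = dict(cv=1.0, apd_base=100.0, apd_dispersion=10.0,
               amplitude=1.0, w_d=3.0, w_r=12.0, duration=256.0, fs=1000.0)
SNR_DB = 20.0

# Frozen lambda grids used whenever an arm is tuned on the fixture set
WEN_LAMBDAS = np.logspace(-3.0, 1.0, 13)
TIKH_LAMBDAS = np.logspace(-5.0, 0.0, 16)


def make_beat_pair(geometry, transfer, seed: int):
    """One paced beat plus its noisy body-surface recording."""
    beat = ew.simulate_beat(
        geometry, pacing_node=(7 * seed) % geometry.n_heart, seed=seed,
        **BEAT_KW,
    )
    phi_b = ew.forward_project(
        transfer, beat, ew.NoiseModel(snr_db=SNR_DB, seed=seed)
    )
    return beat, phi_b


@pytest.fixture(scope="session")
def geometry():
    return ew.make_sphere_geometry(**GEOM_KW)


@pytest.fixture(scope="session")
def transfer(geometry):
    return ew.monopole_transfer_matrix(geometry)


@pytest.fixture(scope="session")
def fixture_pair(geometry, transfer):
    """The frozen fixture beat: seed 0, pacing node 0, SNR 20 dB."""
    return make_beat_pair(geometry, transfer, 0)


@pytest.fixture(scope="session")
def beat_pairs_8(geometry, transfer):
    return [make_beat_pair(geometry, transfer, s) for s in range(8)]


@pytest.fixture(scope="session")
def beat_pairs_10(geometry, transfer):
    return [make_beat_pair(geometry, transfer, s) for s in range(10)]
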