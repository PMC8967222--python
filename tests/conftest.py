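"""Shared fixtures: protocols and the canonical diffusive-state benchmark.

The benchmark — 2,000 tracks of 20 displacements each at the fast protocol,
a slow state (D = 0.02 um^2/s, weight 0.3) and a fast state (D = 0.5,
weight 0.7), localization noise 0.03 um — is expensive enough that the
seeded replicate studies are computed once per session and shared between
the model-selection, parameter-recovery and EM-monotonicity tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from smtkit import (
    AcquisitionProtocol,
    MotionState,
    SimulationModel,
    select_model,
    simulate_switching_tracks,
)

D_SLOW, D_FAST = 0.02, 0.5
W_SLOW, W_FAST = 0.3, 0.7
SIGMA = 0.03
N_TRACKS = 2000
BENCH_FIT = dict(n_restarts=2, n_perturbations=2)
N_REPLICATES = 20


@pytest.fixture(scope="session")
def fast_protocol() -> AcquisitionProtocol:
    """Continuous acquisition, 21 frames -> 20 displacements per track."""
    return AcquisitionProtocol(0.012, 0.010, n_frames=21, label="fast")


@pytest.fixture(scope="session")
def slow_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(0.200, 0.010, n_frames=800, label="slow")


def make_two_state_tracks(protocol, seed, n_tracks=N_TRACKS):
    model = SimulationModel(
        states=(MotionState("bound", D_SLOW), MotionState("free", D_FAST)),
        initial_weights=(W_SLOW, W_FAST),
        localization_sigma_um=SIGMA,
        seed=seed,
    )
    return simulate_switching_tracks(model, protocol, n_tracks=n_tracks)


def make_single_state_tracks(protocol, seed, n_tracks=N_TRACKS):
    model = SimulationModel(
        states=(MotionState("free", D_FAST),),
        initial_weights=(1.0,),
        localization_sigma_um=SIGMA,
        seed=seed,
    )
    return simulate_switching_tracks(model, protocol, n_tracks=n_tracks)


@pytest.fixture(scope="session")
def two_state_replicates(fast_protocol):
    """20 seeded replicates: (selected model over K=1..4, per-track truth)."""
    out = []
    for seed in range(1, N_REPLICATES + 1):
        tracks, gt = make_two_state_tracks(fast_protocol, seed)
        sel = select_model(tracks, range(1, 5), seed=seed, keep_models=True, **BENCH_FIT)
        truth = (
            gt.step_labels.groupby("track_id")["state"].first().reindex(sel.track_ids).to_numpy()
        )
        out.append((sel, truth))
    return out


@pytest.fixture(scope="session")
def single_state_replicates(fast_protocol):
    """20 seeded replicates of the one-state control, selected over K=1..3."""
    out = []
    for seed in range(1, N_REPLICATES + 1):
        tracks, _ = make_single_state_tracks(fast_protocol, seed + 1000)
        out.append(select_model(tracks, range(1, 4), seed=seed, **BENCH_FIT))
    return out
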