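"""Synthetic single-molecule trajectory generator.

Emulates what an SMT microscope produces for a nuclear transcription factor:
HILO movies of sparse emitters that diffuse freely, rattle inside confinement
zones, or sit chromatin-bound, switch between those motion states, blur
during the camera exposure, carry localization noise, and photobleach.
Everything downstream (linking, diffusive-state classification, residence
times) is validated against this generator's ground truth, so the generative
model is spelled out precisely:

* True motion is Brownian at a fine sub-step resolution (>= 10 sub-steps per
  exposure). Confined states reflect off a hard disk of radius ``L`` centred
  on the position where the state was entered; bound states are ordinary
  Brownian motion with a (small) diffusivity.
* The observed position of a frame is the average of the sub-step positions
  sampled at mid-points of the exposure window (motion blur), plus isotropic
  Gaussian localization noise of s.d. ``sigma`` per axis. With mid-point
  sampling the per-axis displacement variance matches the continuous-blur
  result ``2 D (dt - t_E/3) + 2 sigma^2`` to O(1/m^2) in the sub-step count.
* State switching is a continuous-time jump process discretized at sub-step
  resolution: each state has an exponential exit rate ``1/mean_dwell`` and a
  uniform choice of destination state.
* Photobleaching is a per-molecule exponential lifetime; a frame is recorded
  only if the molecule survives its whole exposure, and a track ends at
  min(bleach, movie end).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .core import AcquisitionProtocol, TrackSet

__all__ = [
    "MotionState",
    "SimulationModel",
    "GroundTruth",
    "simulate_switching_tracks",
    "simulate_control_dwells",
    "simulate_bound_tracks",
    "sample_power_law",
    "render_frames",
]

STATE_LABELS = ("free", "confined", "bound")


@dataclass(frozen=True)
class MotionState:
    """One diffusive state of the mixture.

    ``label`` is one of ``free``/``confined``/``bound``. Confined states
    must carry a finite ``confinement_radius_um``; ``mean_dwell_s=None``
    means the state is never exited.
    """

    label: str
    diffusivity_um2_s: float
    confinement_radius_um: float | None = None
    mean_dwell_s: float | None = None

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"label must be one of {STATE_LABELS}, got {self.label!r}")
        if self.diffusivity_um2_s < 0:
            raise ValueError("diffusivity_um2_s must be >= 0")
        if self.label == "confined":
            if self.confinement_radius_um is None or self.confinement_radius_um <= 0:
                raise ValueError("confined states require a positive confinement_radius_um")
        if self.mean_dwell_s is not None and self.mean_dwell_s <= 0:
            raise ValueError("mean_dwell_s must be > 0 (or None for no switching)")


@dataclass(frozen=True)
class SimulationModel:
    """Full generative model: states, switching, noise, bleaching, seed.

    ``bleach_rate_s`` is the single-exponential photobleach hazard used for
    trajectory simulation; the control-dwell generator may instead use
    ``bleach_mixture`` — ``(amplitudes, timescales_s)`` of up to three
    exponentials — mirroring the triple-exponential photobleach model fitted
    to an H2B control.
    """

    states: tuple[MotionState, ...]
    initial_weights: tuple[float, ...]
    localization_sigma_um: float = 0.03
    bleach_rate_s: float = 0.0
    bleach_mixture: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    seed: int = 0
    n_blur_substeps: int = 10

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("at least one MotionState is required")
        if len(self.initial_weights) != len(self.states):
            raise ValueError("initial_weights must match the number of states")
        w = np.asarray(self.initial_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("initial_weights must be non-negative and sum to 1 (tol 1e-9)")
        if self.localization_sigma_um < 0 or self.bleach_rate_s < 0:
            raise ValueError("localization_sigma_um and bleach_rate_s must be >= 0")
        if self.n_blur_substeps < 10:
            raise ValueError("n_blur_substeps must be >= 10 (blur accuracy)")
        bound_D = [s.diffusivity_um2_s for s in self.states if s.label == "bound"]
        other_D = [s.diffusivity_um2_s for s in self.states if s.label != "bound"]
        if bound_D and other_D and max(bound_D) > min(other_D):
            raise ValueError("bound states must have the smallest diffusivities in the model")
        if self.bleach_mixture is not None:
            amps, taus = self.bleach_mixture
            if len(amps) == 0 or len(amps) != len(taus) or len(amps) > 3:
                raise ValueError("bleach_mixture must hold 1-3 (amplitude, timescale) pairs")
            a = np.asarray(amps, float)
            t = np.asarray(taus, float)
            if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-9:
                raise ValueError("bleach_mixture amplitudes must be >= 0 and sum to 1")
            if np.any(~np.isfinite(t)) or np.any(t <= 0):
                raise ValueError("bleach_mixture timescales must be positive and finite")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class GroundTruth:
    """True labels behind a simulated :class:`TrackSet`.

    ``step_labels`` has one row per recorded displacement (``track_id``,
    ``frame`` = start frame, ``state``: majority-occupancy state of the
    frame interval). ``bleach_time_s`` indexes *all* simulated molecules,
    including those bleaching before producing a 2-frame track.
    ``dwell_intervals`` lists the true state-visit intervals of every
    molecule up to min(bleach, movie end).
    """

    step_labels: pd.DataFrame
    bleach_time_s: pd.Series
    dwell_intervals: pd.DataFrame


# ---------------------------------------------------------------------------
# trajectory engine
# ---------------------------------------------------------------------------

def _visible_frames(lifetime: np.ndarray, t_e: float, dt: float, n_frames: int) -> np.ndarray:
    """Frames recorded before a lifetime expires (whole-exposure survival required)."""
    capped = np.minimum(lifetime, n_frames * dt + t_e)  # guard against inf
    return np.where(
        capped < t_e,
        0,
        np.minimum(n_frames, np.floor((capped - t_e) / dt).astype(int) + 1),
    )


def _substep_plan(protocol: AcquisitionProtocol, n_blur: int) -> list[tuple[float, bool]]:
    """Durations and record-flags covering one frame interval.

    The ``n_blur`` recorded positions sit at mid-points of the exposure
    window; the gap until the next frame start is covered by sub-steps no
    longer than the exposure (keeps reflection accurate at modest cost).
    """
    t_e, dt = protocol.exposure_s, protocol.frame_interval_s
    h = t_e / n_blur
    plan: list[tuple[float, bool]] = [(h / 2.0, True)]
    plan += [(h, True)] * (n_blur - 1)
    plan += [(h / 2.0, False)]
    gap = dt - t_e
    if gap > 1e-12:
        n_gap = int(np.ceil(gap / t_e))
        plan += [(gap / n_gap, False)] * n_gap
    return plan


def simulate_switching_tracks(
    model: SimulationModel,
    protocol: AcquisitionProtocol,
    n_tracks: int,
    fov_um: float | None = None,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate ``n_tracks`` state-switching, blurred, bleaching molecules.

    Molecules start at the origin, or uniformly inside a ``fov_um`` x
    ``fov_um`` field of view when given (useful for linking experiments).
    All randomness flows from ``model.seed``; the same seed gives a
    byte-identical :class:`TrackSet`.

    Returns the observed tracks (only molecules yielding >= 2 frames) and
    the full :class:`GroundTruth`.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    K = model.n_states
    rng = stage_rng(model.seed, "simulate_switching_tracks")

    D = np.array([s.diffusivity_um2_s for s in model.states])
    L = np.array(
        [s.confinement_radius_um if s.label == "confined" else np.nan for s in model.states]
    )
    is_conf = np.array([s.label == "confined" for s in model.states])
    exit_rate = np.array(
        [0.0 if s.mean_dwell_s is None else 1.0 / s.mean_dwell_s for s in model.states]
    )

    dt = protocol.frame_interval_s
    t_e = protocol.exposure_s
    n_frames = protocol.n_frames
    plan = _substep_plan(protocol, model.n_blur_substeps)

    # canonical draw order: bleach, initial state, initial position, loop, noise
    if model.bleach_rate_s > 0:
        bleach = rng.exponential(1.0 / model.bleach_rate_s, size=n_tracks)
    else:
        bleach = np.full(n_tracks, np.inf)
    state = rng.choice(K, size=n_tracks, p=np.asarray(model.initial_weights, float))
    if fov_um is not None:
        pos = rng.uniform(0.0, fov_um, size=(n_tracks, 2))
    else:
        pos = np.zeros((n_tracks, 2))
    center = pos.copy()

    # frames a molecule survives through (whole exposure required)
    n_vis = _visible_frames(bleach, t_e, dt, n_frames)
    n_sim = int(n_vis.max()) if n_vis.size else 0
    n_sim = max(n_sim, 0)

    observed = np.zeros((n_tracks, n_sim, 2))
    occ = np.zeros((n_tracks, n_sim, K), dtype=np.float32)
    row_idx = np.arange(n_tracks)

    # switch-event log for true dwell intervals
    ev_track: list[np.ndarray] = [row_idx.copy()]
    ev_time: list[np.ndarray] = [np.zeros(n_tracks)]
    ev_state: list[np.ndarray] = [state.copy()]

    t_now = 0.0
    any_switching = np.any(exit_rate > 0) and K > 1
    for f in range(n_sim):
        blur_sum = np.zeros((n_tracks, 2))
        for h, record in plan:
            if any_switching:
                p_sw = -np.expm1(-h * exit_rate[state])
                sw = rng.random(n_tracks) < p_sw
                if np.any(sw):
                    idx = row_idx[sw]
                    j = rng.integers(0, K - 1, size=idx.size)
                    new = j + (j >= state[idx])
                    state[idx] = new
                    center[idx] = pos[idx]
                    ev_track.append(idx)
                    ev_time.append(np.full(idx.size, t_now))
                    ev_state.append(new)
            step = rng.standard_normal((n_tracks, 2))
            pos = pos + np.sqrt(2.0 * D[state] * h)[:, None] * step
            conf = is_conf[state]
            if np.any(conf):
                rel = pos[conf] - center[conf]
                r = np.hypot(rel[:, 0], rel[:, 1])
                lim = L[state[conf]]
                out = r > lim
                if np.any(out):
                    r_new = np.clip(2.0 * lim[out] - r[out], 0.0, lim[out])
                    rel[out] *= (r_new / r[out])[:, None]
                    pos_conf = center[conf] + rel
                    pos[conf] = pos_conf
            occ[row_idx, f, state] += np.float32(h)
            if record:
                blur_sum += pos
            t_now += h
        observed[:, f, :] = blur_sum / model.n_blur_substeps

    if model.localization_sigma_um > 0 and n_sim > 0:
        observed = observed + model.localization_sigma_um * rng.standard_normal(observed.shape)

    # assemble tracks (>= 2 visible frames)
    keep = n_vis >= 2
    rows = []
    for tid in row_idx[keep]:
        nv = n_vis[tid]
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": np.arange(nv),
                    "x_um": observed[tid, :nv, 0],
                    "y_um": observed[tid, :nv, 1],
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    tracks = TrackSet(
        df,
        protocol,
        provenance={
            "source": "simulate_switching_tracks",
            "seed": model.seed,
            "n_tracks_requested": n_tracks,
            "fov_um": fov_um,
        },
        validate=bool(rows),
    )

    # ground truth: per-displacement majority-occupancy labels
    label_rows = []
    labels = np.array([s.label for s in model.states])
    for tid in row_idx[keep]:
        nv = n_vis[tid]
        maj = occ[tid, : nv - 1, :].argmax(axis=1)
        label_rows.append(
            pd.DataFrame({"track_id": tid, "frame": np.arange(nv - 1), "state": labels[maj]})
        )
    step_labels = (
        pd.concat(label_rows, ignore_index=True)
        if label_rows
        else pd.DataFrame(columns=["track_id", "frame", "state"])
    )

    bleach_s = pd.Series(bleach, index=pd.Index(row_idx, name="track_id"), name="bleach_time_s")
    dwells = _dwell_intervals(ev_track, ev_time, ev_state, bleach, protocol, labels)
    return tracks, GroundTruth(step_labels, bleach_s, dwells)


def _dwell_intervals(ev_track, ev_time, ev_state, bleach, protocol, labels) -> pd.DataFrame:
    ev = pd.DataFrame(
        {
            "track_id": np.concatenate(ev_track),
            "t_start_s": np.concatenate(ev_time),
            "state": np.concatenate(ev_state),
        }
    ).sort_values(["track_id", "t_start_s"], kind="stable")
    end_of_obs = np.minimum(bleach, protocol.movie_span_s)
    t_end = ev.groupby("track_id")["t_start_s"].shift(-1)
    ev["t_end_s"] = t_end.fillna(pd.Series(end_of_obs[ev["track_id"].to_numpy()], index=ev.index))
    ev["state"] = labels[ev["state"].to_numpy()]
    ev = ev[ev["t_end_s"] > ev["t_start_s"]]
    return ev.reset_index(drop=True)[["track_id", "state", "t_start_s", "t_end_s"]]


# ---------------------------------------------------------------------------
# control (H2B-like) dwell generator
# ---------------------------------------------------------------------------

def simulate_control_dwells(
    protocol: AcquisitionProtocol,
    model: SimulationModel,
    n_tracks: int,
    cell_id: object = "control",
    quantize: str = "nearest",
):
    """Observed dwell times of a permanently bound control (H2B analogue).

    The control's true residence is effectively unbounded; the observed
    dwell is limited by photobleaching (an up-to-three-exponential survival
    taken from ``model.bleach_mixture``, else the single ``bleach_rate_s``)
    and by the movie span. Dwells are quantized to the nearest whole frame
    (minimum one frame); ``quantize="none"`` keeps them continuous, which
    is useful when testing fit quality in isolation from camera sampling.
    """
    from .residence import DwellSample

    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if model.bleach_mixture is not None:
        amps = np.asarray(model.bleach_mixture[0], float)
        taus = np.asarray(model.bleach_mixture[1], float)
    else:
        if model.bleach_rate_s <= 0:
            raise ValueError(
                "bleach survival never decays (rate 0, no mixture): observed dwell "
                "would be unbounded; supply a positive bleach rate or mixture"
            )
        amps = np.array([1.0])
        taus = np.array([1.0 / model.bleach_rate_s])
    rng = stage_rng(model.seed, "simulate_control_dwells")
    comp = rng.choice(len(amps), size=n_tracks, p=amps)
    lifetime = rng.exponential(taus[comp])
    dwell = np.minimum(lifetime, protocol.movie_span_s)
    if quantize == "nearest":
        frames = np.maximum(np.rint(dwell / protocol.frame_interval_s), 1.0)
        times = frames * protocol.frame_interval_s
    elif quantize == "track":
        # the dwell a tracked molecule would yield: (observed frames - 1) * dt,
        # matching how dwells are extracted from trajectories
        n_vis = _visible_frames(dwell, protocol.exposure_s, protocol.frame_interval_s,
                                protocol.n_frames)
        times = (n_vis[n_vis >= 2] - 1) * protocol.frame_interval_s
    elif quantize == "none":
        times = dwell
    else:
        raise ValueError(f"unknown quantize mode {quantize!r}")
    return DwellSample(cell_id=cell_id, times_s=times, n_tracks=len(times))


# ---------------------------------------------------------------------------
# bound molecules with arbitrary residence (residence-pipeline test bed)
# ---------------------------------------------------------------------------

def sample_power_law(rng: np.random.Generator, n: int, alpha: float, t_min: float) -> np.ndarray:
    """Continuous power-law (Pareto) residence times, density ~ t^-alpha for t >= t_min."""
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    u = rng.random(n)
    return t_min * u ** (-1.0 / (alpha - 1.0))


def simulate_bound_tracks(
    protocol: AcquisitionProtocol,
    n_tracks: int,
    residence_s: np.ndarray | Callable[[np.random.Generator, int], np.ndarray],
    bleach_amplitudes: Sequence[float],
    bleach_timescales_s: Sequence[float],
    d_bound_um2_s: float = 0.005,
    sigma_um: float = 0.03,
    n_cells: int = 1,
    seed: int = 0,
) -> tuple[TrackSet, pd.DataFrame]:
    """Chromatin-bound molecules with caller-supplied residence times.

    A molecule stays bound (slow Brownian motion, diffusivity
    ``d_bound_um2_s``) for its residence time, then unbinds and leaves the
    imaging volume; it also photobleaches with the given multi-exponential
    survival. The track records frames while the molecule is both bound and
    fluorescent. Positions are Brownian at frame resolution plus
    localization noise (motion blur is negligible at a time-lapse protocol
    where exposure << frame interval). Tracks are assigned round-robin to
    ``n_cells`` synthetic cells.

    Returns the observed tracks and a per-molecule truth table
    (``track_id, residence_s, bleach_s``).
    """
    rng = stage_rng(seed, "simulate_bound_tracks")
    res = residence_s(rng, n_tracks) if callable(residence_s) else np.asarray(residence_s, float)
    if res.shape != (n_tracks,):
        raise ValueError("residence_s must provide one residence time per track")
    amps = np.asarray(bleach_amplitudes, float)
    taus = np.asarray(bleach_timescales_s, float)
    if abs(amps.sum() - 1.0) > 1e-9 or np.any(amps < 0):
        raise ValueError("bleach amplitudes must be >= 0 and sum to 1")
    comp = rng.choice(len(amps), size=n_tracks, p=amps)
    bleach = rng.exponential(taus[comp])

    dt, t_e = protocol.frame_interval_s, protocol.exposure_s
    t_obs = np.minimum(res, bleach)
    n_vis = _visible_frames(t_obs, t_e, dt, protocol.n_frames)
    max_vis = int(n_vis.max()) if n_vis.size else 0
    steps = np.sqrt(2.0 * d_bound_um2_s * dt) * rng.standard_normal((n_tracks, max(max_vis, 1), 2))
    steps[:, 0, :] = 0.0
    true_pos = np.cumsum(steps, axis=1)
    obs = true_pos + sigma_um * rng.standard_normal(true_pos.shape)

    rows = []
    for tid in np.flatnonzero(n_vis >= 2):
        nv = n_vis[tid]
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": np.arange(nv),
                    "x_um": obs[tid, :nv, 0],
                    "y_um": obs[tid, :nv, 1],
                    "cell_id": int(tid) % n_cells,
                }
            )
        )
    if not rows:
        raise ValueError("no molecule survived long enough to form a 2-frame track")
    df = pd.concat(rows, ignore_index=True)
    tracks = TrackSet(
        df,
        protocol,
        provenance={"source": "simulate_bound_tracks", "seed": seed, "n_cells": n_cells},
    )
    truth = pd.DataFrame(
        {"track_id": np.arange(n_tracks), "residence_s": res, "bleach_s": bleach}
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def render_frames(
    tracks: TrackSet | pd.DataFrame,
    psf_sigma_px: float,
    photons_per_spot: float,
    background: float,
    image_shape: tuple[int, int],
    pixel_size_um: float | None = None,
    n_frames: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render localizations into a Poisson-noise image stack.

    Each live emitter becomes a 2D Gaussian of integrated intensity
    ``photons_per_spot`` (pixel-integrated via the error function) on a
    uniform ``background`` (photons/pixel); every pixel then draws from a
    Poisson distribution. Deterministic under ``seed``.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    if isinstance(tracks, TrackSet):
        df = tracks.df
        px = tracks.protocol.pixel_size_um
    else:
        df = tracks
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required when passing a bare localization table")
        px = pixel_size_um
    ny, nx = image_shape
    if len(df):
        x_px = df["x_um"].to_numpy(float) / px
        y_px = df["y_um"].to_numpy(float) / px
        if np.any((x_px < 0) | (x_px >= nx) | (y_px < 0) | (y_px >= ny)):
            raise ValueError("emitter positions fall outside image_shape")
        frames_idx = df["frame"].to_numpy(int)
        nf = n_frames if n_frames is not None else int(frames_idx.max()) + 1
    else:
        if n_frames is None:
            raise ValueError("n_frames required when the track table is empty")
        x_px = y_px = frames_idx = np.array([])
        nf = n_frames

    rng = stage_rng(seed, "render_frames")
    xs = np.arange(nx)
    ys = np.arange(ny)
    stack = np.full((nf, ny, nx), float(background))
    from scipy.special import erf

    s = psf_sigma_px * np.sqrt(2.0)
    for f in range(nf):
        sel = frames_idx == f if len(df) else np.array([], bool)
        for xc, yc in zip(x_px[sel], y_px[sel]):
            gx = 0.5 * (erf((xs + 0.5 - xc) / s) - erf((xs - 0.5 - xc) / s))
            gy = 0.5 * (erf((ys + 0.5 - yc) / s) - erf((ys - 0.5 - yc) / s))
            stack[f] += photons_per_spot * np.outer(gy, gx)
    return rng.poisson(stack).astype(float)
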