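"""Core containers shared by every stage: acquisition protocols and track sets.

An :class:`AcquisitionProtocol` describes how a movie was recorded (frame
interval, exposure, pixel size, frame count) and performs all unit
conversions, so that downstream math never hard-codes camera constants.
A :class:`TrackSet` bundles a table of linked 2D trajectories with the
protocol they were recorded under; it is the exchange object between the
simulator, the linker, the diffusive-state classifier and the residence-time
analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionProtocol",
    "TrackSet",
    "FAST",
    "SLOW",
    "PROTOCOL_PRESETS",
    "TRACK_COLUMNS",
]

#: required columns of a track table, in order
TRACK_COLUMNS = ("track_id", "frame", "x_um", "y_um")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Camera/illumination settings of one SMT acquisition.

    Parameters
    ----------
    frame_interval_s
        Seconds between consecutive frame starts (``Δt``).
    exposure_s
        Seconds of camera integration per frame (``t_E``); must not exceed
        the frame interval.
    pixel_size_um
        Micrometers per camera pixel. Default 0.107 um/px, typical for a
        150x objective on an EM-CCD; always configurable, never baked into
        any formula.
    n_frames
        Number of frames in the movie.
    label
        Free-text name, e.g. ``"fast"`` or ``"slow"``.
    """

    frame_interval_s: float
    exposure_s: float
    pixel_size_um: float = 0.107
    n_frames: int = 800
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.exposure_s <= self.frame_interval_s):
            raise ValueError(
                f"exposure_s must satisfy 0 < exposure_s <= frame_interval_s, "
                f"got exposure_s={self.exposure_s}, frame_interval_s={self.frame_interval_s}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def rate_hz(self) -> float:
        """Acquisition rate in frames per second."""
        return 1.0 / self.frame_interval_s

    @property
    def movie_span_s(self) -> float:
        """Total movie duration in seconds."""
        return self.n_frames * self.frame_interval_s

    def px_to_um(self, x_px: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x_px) * self.pixel_size_um

    def um_to_px(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x_um) / self.pixel_size_um

    def frames_to_seconds(self, n: np.ndarray | int) -> np.ndarray | float:
        return np.asarray(n) * self.frame_interval_s


#: continuous acquisition preset: 12 ms frames with 10 ms exposure (~83 Hz)
FAST = AcquisitionProtocol(frame_interval_s=0.012, exposure_s=0.010, label="fast")
#: time-lapse preset: one 10 ms exposure every 200 ms (5 Hz)
SLOW = AcquisitionProtocol(frame_interval_s=0.200, exposure_s=0.010, label="slow")

PROTOCOL_PRESETS = {"fast": FAST, "slow": SLOW}


class TrackSet:
    """A collection of 2D trajectories recorded under one protocol.

    The table holds one row per localization with columns
    ``track_id, frame, x_um, y_um`` and optionally ``cell_id``. Within each
    track, frames are strictly consecutive (no gap closing is ever
    performed) and every track has at least two localizations.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        protocol: AcquisitionProtocol,
        provenance: dict | None = None,
        validate: bool = True,
    ) -> None:
        df = df.reset_index(drop=True)
        self.df = df
        self.protocol = protocol
        self.provenance = dict(provenance or {})
        if validate:
            self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        xy = self.df[["x_um", "y_um"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("track table contains non-finite coordinates")
        frames = self.df["frame"].to_numpy()
        if np.any(frames < 0):
            raise ValueError("track table contains negative frame indices")
        ids = self.df["track_id"].to_numpy()
        # frames within each track must be strictly consecutive
        order = np.lexsort((frames, ids))
        if not np.array_equal(order, np.arange(len(ids))):
            self.df = self.df.iloc[order].reset_index(drop=True)
            frames = self.df["frame"].to_numpy()
            ids = self.df["track_id"].to_numpy()
        same = ids[1:] == ids[:-1]
        dframe = np.diff(frames)
        bad = same & (dframe != 1)
        if np.any(bad):
            bad_id = ids[1:][bad][0]
            raise ValueError(
                f"track {bad_id!r} has a frame gap or repeated frame; "
                "tracks must have strictly consecutive frames"
            )
        _, counts = np.unique(ids, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every track must contain at least 2 localizations")

    # -- basic access -----------------------------------------------------
    @property
    def track_ids(self) -> np.ndarray:
        return pd.unique(self.df["track_id"])

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    def __len__(self) -> int:
        return self.n_tracks

    @property
    def has_cells(self) -> bool:
        return "cell_id" in self.df.columns

    def itertracks(self) -> Iterator[tuple[object, pd.DataFrame]]:
        """Yield ``(track_id, sub-table)`` pairs in track-id order of appearance."""
        for tid, sub in self.df.groupby("track_id", sort=False):
            yield tid, sub

    def positions(self, track_id: object) -> np.ndarray:
        """``(n, 2)`` array of x/y positions (um) of one track, frame-ordered."""
        sub = self.df[self.df["track_id"] == track_id]
        return sub[["x_um", "y_um"]].to_numpy(float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrackSet):
            return NotImplemented
        return self.protocol == other.protocol and self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )

    def __repr__(self) -> str:
        name = self.protocol.label or f"{self.protocol.rate_hz:.3g} Hz"
        return (
            f"TrackSet(n_tracks={self.n_tracks}, "
            f"n_localizations={len(self.df)}, protocol={name!r})"
        )
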