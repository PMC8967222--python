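"""File formats and run configuration.

Track tables are plain-text CSV with header ``track_id,frame,x_um,y_um``
(optional ``cell_id``); localization tables are ``frame,x_px,y_px`` with an
optional ``intensity``; image stacks go to multi-page TIFF; models and run
reports to JSON. Reading back a written track set is lossless (coordinates
are serialized at full precision).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PROTOCOL_PRESETS, AcquisitionProtocol, TrackSet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_localizations",
    "write_localizations",
    "write_stack",
    "read_stack",
    "RunConfig",
    "load_config",
    "dump_json",
]

_TRACK_HEADERS = (
    ["track_id", "frame", "x_um", "y_um"],
    ["track_id", "frame", "x_um", "y_um", "cell_id"],
)


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    cols = [c for c in ("track_id", "frame", "x_um", "y_um", "cell_id") if c in tracks.df.columns]
    tracks.df[cols].to_csv(path, index=False)


def read_tracks(path: str | Path, protocol: AcquisitionProtocol) -> TrackSet:
    """Read a track CSV, validating header, frame monotonicity and coordinates."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols not in [list(h) for h in _TRACK_HEADERS]:
        raise ValueError(
            f"unexpected track CSV header {cols}; expected "
            "track_id,frame,x_um,y_um[,cell_id]"
        )
    if df[["x_um", "y_um"]].isna().any().any():
        raise ValueError("track CSV contains NaN coordinates")
    frames = df["frame"].to_numpy()
    ids = df["track_id"].to_numpy()
    same = ids[1:] == ids[:-1]
    nonmono = same & (np.diff(frames) <= 0)
    if np.any(nonmono):
        raise ValueError(
            f"non-monotone frames within track {ids[1:][nonmono][0]!r}"
        )
    gap = same & (np.diff(frames) > 1)
    if np.any(gap):
        raise ValueError(f"frame gap within track {ids[1:][gap][0]!r}")
    return TrackSet(df, protocol, provenance={"source": str(path)})


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("frame", "x_px", "y_px", "intensity") if c in locs.columns]
    locs[cols].to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("frame", "x_px", "y_px"):
        if col not in df.columns:
            raise ValueError(f"localization CSV missing column {col!r}")
    return df


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), float)


def dump_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_ALLOWED = {
    "seed": int,
    "out": str,
    "protocols": {"fast": dict, "slow": dict},
    "simulate": {
        "fast": {
            "n_tracks": int,
            "states": list,
            "initial_weights": list,
            "localization_sigma_um": float,
            "bleach_rate_s": float,
        },
        "slow": {
            "n_tracks": int,
            "states": list,
            "initial_weights": list,
            "localization_sigma_um": float,
            "bleach_rate_s": float,
            "residence": {
                "alpha": float,
                "t_min_s": float,
                "d_bound_um2_s": float,
                "n_cells": int,
                "bleach_amplitudes": list,
                "bleach_timescales_s": list,
            },
        },
        "control": {
            "n_tracks": int,
            "bleach_amplitudes": list,
            "bleach_timescales_s": list,
        },
    },
    "states": {
        "k_min": int,
        "k_max": int,
        "n_restarts": int,
        "n_perturbations": int,
        "shared_noise": bool,
        "min_population": float,
        "posterior_threshold": float,
        "bound_D_max_um2_s": float,
        "max_lag": int,
    },
    "dwell": {
        "bound_radius_um": float,
        "min_bound_frames": int,
        "t_min_s": float,
    },
}


def _check_keys(cfg: dict, allowed: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in allowed:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(allowed[key], dict) and isinstance(val, dict):
            _check_keys(val, allowed[key], path + key + ".")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``configs/demo.yaml``)."""

    seed: int
    out: Path
    raw: dict = field(default_factory=dict)

    @property
    def protocols(self) -> dict[str, AcquisitionProtocol]:
        out = dict(PROTOCOL_PRESETS)
        for name, spec in self.raw.get("protocols", {}).items():
            out[name] = AcquisitionProtocol(label=name, **spec)
        return out

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _check_keys(raw, _ALLOWED)
    if "seed" not in raw or "out" not in raw:
        raise ValueError("config must define 'seed' and 'out'")
    return RunConfig(seed=int(raw["seed"]), out=Path(raw["out"]), raw=raw)
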