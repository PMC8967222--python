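"""Spot detection and trajectory linking.

Linking follows the acquisition rules of the study design: molecules may
move at most a fixed number of pixels between consecutive frames (4 px at
the 5 Hz time-lapse, 6 px at the ~83 Hz continuous acquisition), frame-pair
assignments minimize total squared displacement (optimal bipartite
assignment, not greedy), no gap closing is performed, and only tracks of at
least two frames are kept.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import AcquisitionProtocol, TrackSet

__all__ = ["detect_spots", "link_tracks", "tracks_to_localizations", "default_max_disp_px"]

#: printed linking thresholds by acquisition rate (px)
_RATE_MAX_DISP = {5.0: 4.0, 83.0: 6.0}


def default_max_disp_px(protocol: AcquisitionProtocol) -> float:
    """4 px at ~5 Hz, 6 px at ~83 Hz; other rates need an explicit value."""
    rate = protocol.rate_hz
    for r, d in _RATE_MAX_DISP.items():
        if abs(rate - r) / r < 0.15:
            return d
    raise ValueError(
        f"no default max displacement for a {rate:.3g} Hz protocol; pass max_disp_px"
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _gauss2d(params, xg, yg):
    a, x0, y0, s, b = params
    return b + a * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * s**2))


def _refine(frame: np.ndarray, y: int, x: int, psf_sigma_px: float) -> tuple[float, float, float]:
    """Sub-pixel refinement by least-squares 2D Gaussian fit around (y, x)."""
    r = max(int(np.ceil(2 * psf_sigma_px)), 2)
    ny, nx = frame.shape
    y0, y1 = max(y - r, 0), min(y + r + 1, ny)
    x0, x1 = max(x - r, 0), min(x + r + 1, nx)
    win = frame[y0:y1, x0:x1].astype(float)
    yg, xg = np.mgrid[y0:y1, x0:x1]
    b0 = float(win.min())
    a0 = float(win.max() - b0)
    p0 = np.array([a0, x, y, psf_sigma_px, b0])

    def resid(p):
        return (_gauss2d(p, xg, yg) - win).ravel()

    try:
        sol = optimize.least_squares(resid, p0, method="lm", max_nfev=200)
        a, xf, yf, s, b = sol.x
        if a > 0 and x0 - 1 <= xf <= x1 and y0 - 1 <= yf <= y1:
            return float(xf), float(yf), float(a)
    except Exception:
        pass
    # centroid fallback
    w = np.clip(win - b0, 0, None)
    tot = w.sum()
    if tot <= 0:
        return float(x), float(y), a0
    return float((w * xg).sum() / tot), float((w * yg).sum() / tot), a0


def detect_spots(
    frames: np.ndarray, threshold_sd: float = 3.0, psf_sigma_px: float = 1.2
) -> pd.DataFrame:
    """Detect and sub-pixel-localize spots in an image stack.

    Local maxima above ``background + threshold_sd * robust_noise_sd``
    (median / MAD per frame) are refined by a least-squares 2D Gaussian
    fit; detections within one PSF sigma of a brighter one are merged.

    Returns a localization table ``frame, x_px, y_px, intensity``.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n_frames, ny, nx) stack")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    rows = []
    for f, img in enumerate(frames):
        # PSF-matched filter suppresses single-pixel shot noise before
        # thresholding; the robust noise s.d. is taken on the smoothed image
        sm = ndimage.gaussian_filter(img, psf_sigma_px, mode="nearest")
        bg = np.median(sm)
        noise = 1.4826 * np.median(np.abs(sm - bg))
        thr = bg + threshold_sd * max(noise, 1e-12)
        is_max = sm == ndimage.maximum_filter(sm, size=3, mode="nearest")
        ys, xs = np.nonzero(is_max & (sm > thr))
        cands = []
        for y, x in zip(ys, xs):
            xf, yf, inten = _refine(img, int(y), int(x), psf_sigma_px)
            cands.append((xf, yf, inten))
        # merge duplicates within one PSF sigma, keeping the brighter
        cands.sort(key=lambda c: -c[2])
        kept: list[tuple[float, float, float]] = []
        for xf, yf, inten in cands:
            if all((xf - k[0]) ** 2 + (yf - k[1]) ** 2 > psf_sigma_px**2 for k in kept):
                kept.append((xf, yf, inten))
        for xf, yf, inten in kept:
            rows.append({"frame": f, "x_px": xf, "y_px": yf, "intensity": inten})
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "intensity"])


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_tracks(
    locs: pd.DataFrame,
    protocol: AcquisitionProtocol,
    max_disp_px: float | None = None,
    min_track_len: int = 2,
) -> TrackSet:
    """Link per-frame localizations into trajectories.

    Frame-to-frame assignment minimizes the total squared displacement over
    pairs within ``max_disp_px`` (optimal bipartite assignment); unmatched
    detections start new tracks; a track ends the first frame it goes
    unmatched (no gap closing); tracks shorter than ``min_track_len``
    frames are discarded. Localization coordinates are in pixels and are
    converted to micrometers using the protocol at output time, so the
    displacement threshold applies in pixels exactly as specified.
    """
    if max_disp_px is None:
        max_disp_px = default_max_disp_px(protocol)
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if min_track_len < 2:
        raise ValueError("min_track_len must be >= 2")
    for col in ("frame", "x_px", "y_px"):
        if col not in locs.columns:
            raise ValueError(f"localization table missing column {col!r}")
    dup = locs.duplicated(subset=["frame", "x_px", "y_px"])
    if dup.any():
        f = int(locs.loc[dup.idxmax(), "frame"])
        raise ValueError(f"duplicate localization (frame, position) rows in frame {f}")

    locs = locs.reset_index(drop=True)
    frames_present = np.sort(locs["frame"].unique())
    by_frame = {
        int(f): sub[["x_px", "y_px"]].to_numpy(float) for f, sub in locs.groupby("frame")
    }
    idx_by_frame = {int(f): sub.index.to_numpy() for f, sub in locs.groupby("frame")}

    max_sq = max_disp_px**2
    next_id = 0
    # active tracks: id -> (last frame, last position, list of (frame, x, y))
    active: dict[int, list] = {}
    finished: list[list] = []
    track_rows: dict[int, list[tuple[int, float, float]]] = {}

    prev_frame = None
    for f in frames_present:
        pts = by_frame[int(f)]
        if prev_frame is not None and f == prev_frame + 1 and active:
            ids = list(active.keys())
            last = np.array([active[i] for i in ids])
            d2 = ((last[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            big = 1e12
            cost = np.where(d2 <= max_sq, d2, big)
            ri, ci = optimize.linear_sum_assignment(cost)
            matched_tracks = set()
            matched_pts = set()
            for r, c in zip(ri, ci):
                if cost[r, c] < big:
                    tid = ids[r]
                    track_rows[tid].append((int(f), pts[c, 0], pts[c, 1]))
                    active[tid] = pts[c]
                    matched_tracks.add(tid)
                    matched_pts.add(c)
            for tid in list(active):
                if tid not in matched_tracks:
                    del active[tid]
        else:
            active.clear()
            matched_pts = set()
        for c in range(len(pts)):
            if c not in matched_pts:
                tid = next_id
                next_id += 1
                active[tid] = pts[c]
                track_rows[tid] = [(int(f), pts[c, 0], pts[c, 1])]
        prev_frame = f

    px = protocol.pixel_size_um
    recs = []
    for tid in sorted(track_rows):
        rows = track_rows[tid]
        if len(rows) < min_track_len:
            continue
        for fr, x, y in rows:
            recs.append((tid, fr, x * px, y * px))
    df = pd.DataFrame(recs, columns=["track_id", "frame", "x_um", "y_um"])
    if len(df):
        # renumber tracks consecutively for tidiness
        remap = {t: i for i, t in enumerate(pd.unique(df["track_id"]))}
        df["track_id"] = df["track_id"].map(remap)
    return TrackSet(
        df,
        protocol,
        provenance={
            "source": "link_tracks",
            "max_disp_px": max_disp_px,
            "min_track_len": min_track_len,
        },
        validate=bool(len(df)),
    )


def tracks_to_localizations(tracks: TrackSet) -> tuple[pd.DataFrame, np.ndarray]:
    """Strip track identity from a TrackSet, keeping truth ids separately.

    Returns a localization table (``frame, x_px, y_px``) shuffled-free and
    an array of the true track id of each row — the ground truth against
    which linking accuracy is scored.
    """
    px = tracks.protocol.pixel_size_um
    df = tracks.df.sort_values(["frame", "track_id"], kind="stable").reset_index(drop=True)
    locs = pd.DataFrame(
        {"frame": df["frame"], "x_px": df["x_um"] / px, "y_px": df["y_um"] / px}
    )
    return locs, df["track_id"].to_numpy()
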