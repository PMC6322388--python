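"""Micropillar detection, tracking, drift correction and traction forces.

The measurement chain mirrors standard pillar traction-force microscopy:

1. detect pillar tops in frame 0 as intensity peaks, refined to subpixel
   precision by a 2D Gaussian fit (centroid fallback);
2. link detections frame-to-frame by nearest neighbor within half a pitch;
3. estimate rigid stage drift from cell-free reference pillars and
   subtract it from every track;
4. displacement d(t) = position(t) - position(reference frame), force
   F(t) = k * |d(t)| for spring stiffness k (nN/um), peak force =
   max_t F(t) per pillar, and the movie summary is the mean of peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

__all__ = [
    "PillarTrack",
    "DriftSeries",
    "ForceTable",
    "detect_pillars",
    "track_pillars",
    "estimate_drift",
    "correct_drift",
    "compute_forces",
    "select_reference_pillars",
]


@dataclass
class PillarTrack:
    """One pillar's subpixel (x, y) position in um per frame."""

    pillar_id: int
    positions_um: np.ndarray  # (n_frames, 2)
    lost_frames: list[int] = field(default_factory=list)
    ambiguous_frames: list[int] = field(default_factory=list)
    drift_corrected: bool = False

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]


@dataclass
class DriftSeries:
    """Per-frame rigid drift estimate; zero at the reference frame."""

    drift_um: np.ndarray  # (n_frames, 2)
    reference_ids: list[int]


@dataclass
class ForceTable:
    """Per-pillar per-frame displacements and forces, plus peak summaries."""

    table: pd.DataFrame  # frame, pillar_id, dx_um, dy_um, force_nN
    peak_forces_nN: pd.Series  # indexed by pillar_id
    mean_peak_force_nN: float
    time_avg_force_nN: pd.Series
    stiffness_nN_per_um: float
    reference_frame: int


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _gaussian_2d(xy, amp, cx, cy, sigma, offset):
    x, y = xy
    return amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2)) + offset


def _refine_subpixel(
    frame: np.ndarray, peak_rc: tuple[int, int], half_window: int
) -> tuple[float, float, bool]:
    """Refine one peak to subpixel (row, col) by Gaussian fit.

    Returns (row, col, fit_ok); on fit failure falls back to the
    background-subtracted intensity-weighted centroid of the window.
    """
    r, c = peak_rc
    r0, r1 = max(r - half_window, 0), min(r + half_window + 1, frame.shape[0])
    c0, c1 = max(c - half_window, 0), min(c + half_window + 1, frame.shape[1])
    win = frame[r0:r1, c0:c1].astype(float)
    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                         np.arange(c0, c1, dtype=float), indexing="ij")
    offset0 = float(win.min())
    amp0 = float(win.max() - offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_2d,
            (cc.ravel(), rr.ravel()),
            win.ravel(),
            p0=(amp0, float(c), float(r), max(half_window / 2.0, 1.0), offset0),
            maxfev=2000,
        )
        # one reweighted pass with shot-noise weights (variance proportional
        # to the model intensity): near-efficient for photon-limited spots
        model = _gaussian_2d((cc.ravel(), rr.ravel()), *popt)
        popt, _ = optimize.curve_fit(
            _gaussian_2d,
            (cc.ravel(), rr.ravel()),
            win.ravel(),
            p0=popt,
            sigma=np.sqrt(np.maximum(model, 1.0)),
            maxfev=2000,
        )
        amp, cx, cy, sigma, _ = popt
        if amp > 0 and r0 - 1 <= cy <= r1 and c0 - 1 <= cx <= c1:
            return float(cy), float(cx), True
    except (RuntimeError, ValueError):
        pass
    w = np.clip(win - offset0, 0.0, None)
    total = w.sum()
    if total <= 0:
        return float(r), float(c), False
    return float((w * rr).sum() / total), float((w * cc).sum() / total), False


def detect_pillars(
    frame: np.ndarray,
    expected_pitch_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Detect pillar spots in one frame, returning (x, y) positions in um.

    Local maxima separated by at least half a pitch and brighter than an
    adaptive threshold (background median + half the peak excess) are
    refined to subpixel precision in a half-pitch window.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("constant frame: no pillars detectable")
    pitch_px = expected_pitch_um / pixel_size_um
    min_dist = max(int(pitch_px / 2), 1)
    bg = float(np.median(frame))
    threshold = bg + 0.5 * (float(frame.max()) - bg)
    smoothed = ndimage.gaussian_filter(frame, sigma=1.0)
    peaks = peak_local_max(smoothed, min_distance=min_dist,
                           threshold_abs=threshold)
    if peaks.size == 0:
        raise ValueError("no pillar detections above threshold")
    half_window = max(int(round(pitch_px / 2)), 3)
    out = np.empty((len(peaks), 2))
    for i, (r, c) in enumerate(peaks):
        row, col, _ = _refine_subpixel(frame, (int(r), int(c)), half_window)
        out[i] = (col * pixel_size_um, row * pixel_size_um)
    # deterministic grid-reading order: bin y into rows by the pitch so
    # subpixel jitter cannot shuffle ids within a row, then sort by x
    row_bin = np.round((out[:, 1] - out[:, 1].min()) / expected_pitch_um)
    order = np.lexsort((out[:, 0], row_bin))
    return out[order]


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

def _smooth_positions(positions: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average per coordinate; windows shrink at the edges.

    Frame 0 is left raw: it is the zero-force reference, and averaging it
    with later frames would leak any early force ramp (or drift-free
    motion onset) into the reference position.
    """
    if window <= 1:
        return positions
    n = positions.shape[0]
    half = window // 2
    out = np.empty_like(positions)
    out[0] = positions[0]
    for t in range(1, n):
        lo, hi = max(t - half, 0), min(t + half + 1, n)
        out[t] = positions[lo:hi].mean(axis=0)
    return out


def track_pillars(
    frames: np.ndarray,
    initial_positions_um: np.ndarray,
    pitch_um: float,
    pixel_size_um: float,
    smooth_frames: int = 5,
) -> list[PillarTrack]:
    """Track pillars through a frame stack.

    Each pillar is re-localized every frame by a Gaussian fit in a
    half-pitch window around its previous position; a candidate farther
    than pitch/2 means the pillar is lost for that frame and keeps its
    last position (flagged).

    ``smooth_frames`` applies a centered moving average over the track
    (default 5 frames, i.e. 10 s at 0.5 Hz) — short against the
    tens-of-seconds timescale of cellular force buildup, it suppresses
    frame-to-frame localization jitter without biasing force plateaus.
    Set 1 to disable.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    n_frames = frames.shape[0]
    init = np.asarray(initial_positions_um, dtype=float)
    search_um = pitch_um / 2.0
    half_window = max(int(round(pitch_um / 2.0 / pixel_size_um)), 3)

    tracks = [
        PillarTrack(pillar_id=i,
                    positions_um=np.zeros((n_frames, 2)))
        for i in range(len(init))
    ]
    for i, tr in enumerate(tracks):
        tr.positions_um[0] = init[i]

    for t in range(1, n_frames):
        frame = frames[t]
        for tr in tracks:
            prev = tr.positions_um[t - 1]
            pr = int(round(prev[1] / pixel_size_um))
            pc = int(round(prev[0] / pixel_size_um))
            pr = int(np.clip(pr, 0, frame.shape[0] - 1))
            pc = int(np.clip(pc, 0, frame.shape[1] - 1))
            row, col, _ = _refine_subpixel(frame, (pr, pc), half_window)
            cand = np.array([col * pixel_size_um, row * pixel_size_um])
            jump = float(np.hypot(*(cand - prev)))
            if jump > search_um:
                tr.positions_um[t] = prev
                tr.lost_frames.append(t)
            else:
                tr.positions_um[t] = cand
    for tr in tracks:
        tr.positions_um = _smooth_positions(tr.positions_um, smooth_frames)
    return tracks


# --------------------------------------------------------------------------
# drift
# --------------------------------------------------------------------------

def select_reference_pillars(
    tracks: list[PillarTrack], fraction: float = 0.25
) -> list[int]:
    """Auto-select cell-free reference pillars.

    Picks the quartile (by default) of pillars with the lowest total
    path length — a proxy for "not engaged by a cell". Manual selection
    by location is preferred when cell positions are known.
    """
    if not tracks:
        raise ValueError("no tracks")
    motion = [
        (float(np.linalg.norm(np.diff(tr.positions_um, axis=0), axis=1).sum()),
         tr.pillar_id)
        for tr in tracks
    ]
    motion.sort()
    k = max(int(np.ceil(fraction * len(tracks))), 1)
    return sorted(pid for _, pid in motion[:k])


def estimate_drift(
    tracks: list[PillarTrack],
    reference_ids: list[int],
    reference_frame: int = 0,
) -> DriftSeries:
    """Estimate rigid stage drift from reference (cell-free) pillars.

    drift(t) = mean over references of position(t) - position(reference
    frame); exactly zero at the reference frame.
    """
    if not reference_ids:
        raise ValueError("need at least one reference pillar")
    by_id = {tr.pillar_id: tr for tr in tracks}
    missing = [i for i in reference_ids if i not in by_id]
    if missing:
        raise ValueError(f"unknown reference pillar ids: {missing}")
    ref = np.stack([by_id[i].positions_um for i in reference_ids])  # (R, T, 2)
    drift = (ref - ref[:, reference_frame:reference_frame + 1, :]).mean(axis=0)
    return DriftSeries(drift_um=drift, reference_ids=list(reference_ids))


def correct_drift(
    tracks: list[PillarTrack], drift: DriftSeries
) -> list[PillarTrack]:
    """Subtract the drift series from every track (returns new tracks).

    Refuses to run twice on already-corrected tracks: the correction is
    not idempotent.
    """
    for tr in tracks:
        if tr.drift_corrected:
            raise ValueError(
                f"track {tr.pillar_id} is already drift-corrected"
            )
        if tr.positions_um.shape[0] != drift.drift_um.shape[0]:
            raise ValueError("drift series and tracks disagree on frame count")
    return [
        PillarTrack(
            pillar_id=tr.pillar_id,
            positions_um=tr.positions_um - drift.drift_um,
            lost_frames=list(tr.lost_frames),
            ambiguous_frames=list(tr.ambiguous_frames),
            drift_corrected=True,
        )
        for tr in tracks
    ]


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------

def compute_forces(
    tracks: list[PillarTrack],
    stiffness_nN_per_um: float,
    reference_frame: int = 0,
    engaged_ids: list[int] | None = None,
    reference_mode: str = "frame",
    extrapolate_window: int | None = None,
) -> ForceTable:
    """Convert tracks to traction forces via the linear spring law F = k*d.

    Displacement is taken from the zero-force reference position. With
    ``reference_mode="frame"`` (default) that is simply the position at
    ``reference_frame``. With ``"extrapolate"`` it is the intercept of a
    linear fit over the first ``extrapolate_window`` frames evaluated at
    the reference frame — unbiased whenever early motion (drift plus
    loading ramp) is approximately linear, and considerably less noisy
    than a single-frame fix.

    Peak force is the per-pillar max over frames; the movie summary
    averages peaks over the engaged pillars (all pillars if
    ``engaged_ids`` is None). The time-averaged force per pillar is also
    reported.
    """
    if stiffness_nN_per_um <= 0:
        raise ValueError("stiffness must be positive")
    if not tracks:
        raise ValueError("no tracks")
    if reference_mode not in ("frame", "extrapolate"):
        raise ValueError("reference_mode must be 'frame' or 'extrapolate'")
    n_frames = tracks[0].n_frames
    if not 0 <= reference_frame < n_frames:
        raise ValueError("reference_frame outside the movie")
    if extrapolate_window is None:
        extrapolate_window = max(min(n_frames // 2, 15), 2)

    rows = []
    for tr in tracks:
        if reference_mode == "extrapolate" and n_frames >= 3:
            w = min(extrapolate_window, n_frames)
            t_fit = np.arange(w)
            coef = np.polyfit(t_fit, tr.positions_um[:w], deg=1)  # (2, 2)
            ref_pos = coef[0] * reference_frame + coef[1]
        else:
            ref_pos = tr.positions_um[reference_frame]
        d = tr.positions_um - ref_pos
        f = stiffness_nN_per_um * np.hypot(d[:, 0], d[:, 1])
        for t in range(n_frames):
            rows.append((t, tr.pillar_id, d[t, 0], d[t, 1], f[t]))
    table = pd.DataFrame(rows, columns=[
        "frame", "pillar_id", "dx_um", "dy_um", "force_nN"])
    peaks = table.groupby("pillar_id")["force_nN"].max()
    time_avg = table.groupby("pillar_id")["force_nN"].mean()
    sel = peaks if engaged_ids is None else peaks.loc[engaged_ids]
    return ForceTable(
        table=table,
        peak_forces_nN=peaks,
        mean_peak_force_nN=float(sel.mean()),
        time_avg_force_nN=time_avg,
        stiffness_nN_per_um=stiffness_nN_per_um,
        reference_frame=reference_frame,
    )
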