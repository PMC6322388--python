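"""Synthetic micropillar-array time-lapses with known forces and drift.

Renders each pillar top as an isotropic Gaussian spot whose center moves
as rest_position + stage_drift(t) + force(t)/stiffness, so a tracker can
be validated against exact ground truth. Pillars behave as linear springs
(F = k * d); drift is a rigid per-frame translation of the whole field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["PillarArrayParams", "ForceEvent", "PillarMovie",
           "generate_pillar_movie", "plateau_force_series"]


@dataclass(frozen=True)
class ForceEvent:
    """A per-pillar applied force trajectory, one 2-vector (nN) per frame."""

    pillar_id: int
    force_nN: np.ndarray  # (n_frames, 2)


def plateau_force_series(
    n_frames: int,
    plateau_nN: float,
    direction_rad: float = 0.0,
    ramp_frames: int | None = None,
) -> np.ndarray:
    """Linear loading from zero to a plateau, emulating a spreading cell.

    The default ramp occupies the first half of the movie.
    """
    if ramp_frames is None:
        ramp_frames = max(n_frames // 2, 1)
    mag = np.minimum(np.arange(n_frames) / ramp_frames, 1.0) * plateau_nN
    u = np.array([np.cos(direction_rad), np.sin(direction_rad)])
    return mag[:, None] * u[None, :]


@dataclass(frozen=True)
class PillarArrayParams:
    """Geometry, optics, mechanics and noise of a simulated pillar movie.

    The 0.5 Hz default frame rate matches typical bright-field pillar
    acquisition; stiffness and pitch are simulator conventions (elastomer
    pillar arrays commonly fall in the 10-100 nN/um, few-um-pitch range).
    """

    grid_rows: int = 5
    grid_cols: int = 5
    pitch_um: float = 4.0
    psf_sigma_um: float = 0.4
    pillar_peak_intensity: float = 1000.0
    background_level: float = 100.0
    stiffness_nN_per_um: float = 20.0
    n_frames: int = 30
    frame_interval_s: float = 2.0
    pixel_size_um: float = 0.1
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0)
    force_events: tuple[ForceEvent, ...] = ()
    poisson_noise: bool = False
    gaussian_noise_sd: float = 0.0
    seed: int = 0
    margin_um: float = 3.0  # blank border so spots never leave the field

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.pitch_um <= 4.0 * self.psf_sigma_um:
            raise ValueError("unresolvable grid: require pitch > 4*psf_sigma")
        if self.stiffness_nN_per_um <= 0:
            raise ValueError("stiffness must be positive")
        if self.n_frames < 1 or self.frame_interval_s <= 0:
            raise ValueError("need n_frames >= 1 and positive frame interval")
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("pixel size and PSF sigma must be positive")
        if self.pillar_peak_intensity < 0 or self.background_level < 0:
            raise ValueError("intensities must be >= 0")
        n_pillars = self.grid_rows * self.grid_cols
        for ev in self.force_events:
            if not 0 <= ev.pillar_id < n_pillars:
                raise ValueError(f"force event for unknown pillar {ev.pillar_id}")
            f = np.asarray(ev.force_nN, dtype=float)
            if f.shape != (self.n_frames, 2) or not np.all(np.isfinite(f)):
                raise ValueError(
                    "force series must be finite with shape (n_frames, 2)"
                )

    @property
    def n_pillars(self) -> int:
        return self.grid_rows * self.grid_cols

    def rest_positions_um(self) -> np.ndarray:
        """Rest (x, y) positions in um, pillar id = row * grid_cols + col."""
        xs = self.margin_um + self.pitch_um * np.arange(self.grid_cols)
        ys = self.margin_um + self.pitch_um * np.arange(self.grid_rows)
        xx, yy = np.meshgrid(xs, ys)  # id-major over rows
        return np.column_stack([xx.ravel(), yy.ravel()])

    def field_size_px(self) -> tuple[int, int]:
        w_um = 2 * self.margin_um + self.pitch_um * (self.grid_cols - 1)
        h_um = 2 * self.margin_um + self.pitch_um * (self.grid_rows - 1)
        return (int(np.ceil(h_um / self.pixel_size_um)) + 1,
                int(np.ceil(w_um / self.pixel_size_um)) + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift_um_per_frame"] = list(self.drift_um_per_frame)
        d["force_events"] = [
            {"pillar_id": ev.pillar_id,
             "force_nN": np.asarray(ev.force_nN).tolist()}
            for ev in self.force_events
        ]
        return d


@dataclass
class PillarMovie:
    """Rendered frame stack plus exact per-pillar per-frame ground truth."""

    frames: np.ndarray  # (T, H, W)
    params: PillarArrayParams
    ground_truth: pd.DataFrame  # frame, pillar_id, x_um, y_um, dx_um, dy_um, fx_nN, fy_nN

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _render_spots(
    shape: tuple[int, int],
    centers_um: np.ndarray,
    sigma_um: float,
    peak: float,
    pixel_size_um: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    sigma_px = sigma_um / pixel_size_um
    half = int(np.ceil(5 * sigma_px))
    for x_um, y_um in centers_um:
        cx = x_um / pixel_size_um
        cy = y_um / pixel_size_um
        r0 = max(int(np.floor(cy)) - half, 0)
        r1 = min(int(np.ceil(cy)) + half + 1, shape[0])
        c0 = max(int(np.floor(cx)) - half, 0)
        c1 = min(int(np.ceil(cx)) + half + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                             np.arange(c0, c1, dtype=float), indexing="ij")
        img[r0:r1, c0:c1] += peak * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * sigma_px ** 2)
        )
    return img


def generate_pillar_movie(params: PillarArrayParams) -> PillarMovie:
    """Render a pillar time-lapse; deterministic for a fixed seed.

    Frame ``t`` places pillar ``i`` at
    ``rest_i + drift * t + force_i(t) / stiffness``; ground-truth
    displacement times stiffness reproduces the programmed force exactly.
    """
    rng = np.random.default_rng(params.seed)
    rest = params.rest_positions_um()
    shape = params.field_size_px()
    drift = np.asarray(params.drift_um_per_frame, dtype=float)

    forces = np.zeros((params.n_frames, params.n_pillars, 2))
    for ev in params.force_events:
        forces[:, ev.pillar_id, :] += np.asarray(ev.force_nN, dtype=float)
    displacements = forces / params.stiffness_nN_per_um

    frames = np.empty((params.n_frames, *shape), dtype=np.float64)
    records = []
    for t in range(params.n_frames):
        centers = rest + drift * t + displacements[t]
        img = _render_spots(shape, centers, params.psf_sigma_um,
                            params.pillar_peak_intensity, params.pixel_size_um)
        img += params.background_level
        if params.poisson_noise:
            # photon-limited (shot) noise: peak-SNR = sqrt(peak intensity)
            img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
        if params.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, params.gaussian_noise_sd, img.shape)
        frames[t] = np.clip(img, 0.0, None)
        for i in range(params.n_pillars):
            records.append((t, i, centers[i, 0], centers[i, 1],
                            displacements[t, i, 0], displacements[t, i, 1],
                            forces[t, i, 0], forces[t, i, 1]))

    truth = pd.DataFrame(records, columns=[
        "frame", "pillar_id", "x_um", "y_um",
        "dx_um", "dy_um", "fx_nN", "fy_nN",
    ])
    return PillarMovie(frames=frames, params=params, ground_truth=truth)
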