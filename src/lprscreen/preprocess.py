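"""Raw tracks -> fixed-size per-phase tensors for the autoencoders.

Preprocessing follows the screening pipeline's rules: well-center the
coordinates, forward-fill missing frames onto the uniform frame grid, and cap
per-frame distance at the largest displacement a 5 dpf larva can plausibly
produce in one frame (a full startle response), then cut out the phase
windows of the second light/dark cycle as (frames x 5) matrices in the
feature order (t, x, y, dist, vel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track_data import FRAME_COLUMNS, AssaySchedule, LarvaTrack, Phase

__all__ = [
    "WellGeometry",
    "PhaseTensor",
    "FeatureScaler",
    "compute_outlier_threshold",
    "center_coordinates",
    "forward_fill",
    "cap_outliers",
    "preprocess_track",
    "extract_phase",
    "downsample_tensor",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "save_tensors",
    "load_tensors",
    "compute_angular_velocity",
]

DEFAULT_WELL_RADIUS = 3.25  # mm; 6.5 mm round well of a 96-well plate


@dataclass(frozen=True)
class WellGeometry:
    """Well radius and per-well centers in the raw coordinate frame.

    ``centers`` maps well label -> (x, y); a ``default_center`` applies to
    wells not listed (e.g. exports already centered per well).
    """

    radius: float = DEFAULT_WELL_RADIUS
    centers: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_center: tuple[float, float] | None = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("well radius must be > 0")

    def center_of(self, well: str) -> tuple[float, float]:
        if well in self.centers:
            return self.centers[well]
        if self.default_center is None:
            raise KeyError(f"no center known for well {well!r}")
        return self.default_center


@dataclass
class PhaseTensor:
    """The (frames_per_phase x 5) matrix for one larva in one phase.

    Feature order is (t, x, y, dist, vel), with t re-zeroed to the window
    start.  At the default 25 frames/s and 180 s phases the shape is
    (4500, 5), flattening to a 22500-vector in frame-major order.
    """

    subject_id: str
    phase: Phase
    cycle: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(FRAME_COLUMNS):
            raise ValueError(f"phase tensor must be (frames, 5), got {self.matrix.shape}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("phase tensor contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def flatten(self) -> np.ndarray:
        """Frame-major flattening: frame 1's five features, then frame 2's, ..."""
        return self.matrix.reshape(-1)


def compute_outlier_threshold(
    body_length: float = 3.9,
    startle_multiple: float = 2.5,
    startle_duration: float = 120.0,
    frame_interval: float = 40.0,
) -> float:
    """Maximum plausible distance moved per frame, in mm/frame.

    A startle response covers ``startle_multiple`` body lengths in
    ``startle_duration`` ms; dividing by the number of recording frames the
    startle spans (``startle_duration / frame_interval``) gives the largest
    per-frame displacement the tracker should ever report.  With the
    defaults (3.9 mm larva, 2.5 body lengths, 120 ms startle, 40 ms frame
    interval at 25 frames/s) the cap is 3.25 mm/frame.
    """
    args = (body_length, startle_multiple, startle_duration, frame_interval)
    if any(a <= 0 for a in args):
        raise ValueError(f"all arguments must be > 0, got {args}")
    return (body_length * startle_multiple) / (startle_duration / frame_interval)


def center_coordinates(track: LarvaTrack, geometry: WellGeometry) -> LarvaTrack:
    """Express (x, y) as offsets from the well center; clip to the well disc.

    Points outside the well radius (tracking jitter) are pulled back to the
    boundary circle along the same bearing rather than dropped.
    """
    cx, cy = geometry.center_of(track.well)
    out = track.copy()
    x = out.frames["x"].to_numpy() - cx
    y = out.frames["y"].to_numpy() - cy
    r = np.hypot(x, y)
    over = r > geometry.radius
    if over.any():
        scale = geometry.radius / r[over]
        x[over] *= scale
        y[over] *= scale
    out.frames["x"] = x
    out.frames["y"] = y
    return out


def forward_fill(
    track: LarvaTrack,
    schedule: AssaySchedule | None = None,
    frame_rate: float | None = None,
) -> LarvaTrack:
    """Place frames on the uniform grid, forward-filling gaps.

    The grid is t_i = i / frame_rate for i = 0 .. duration*frame_rate - 1.
    A missing frame copies the previous frame's x, y, vel and gets dist = 0
    (the larva was not observed to move); a leading gap copies the first
    observed frame backward, also with dist = 0.
    """
    schedule = schedule or AssaySchedule()
    frame_rate = frame_rate or track.frame_rate
    if track.n_frames == 0:
        raise ValueError(f"cannot forward-fill empty track {track.subject_id}")
    n = int(round(schedule.total_duration * frame_rate))
    grid_t = np.arange(n) / frame_rate

    obs = track.frames[FRAME_COLUMNS].to_numpy()
    idx = np.rint(obs[:, 0] * frame_rate).astype(int)
    keep = (idx >= 0) & (idx < n)

    mat = np.full((n, len(FRAME_COLUMNS)), np.nan)
    mat[idx[keep]] = obs[keep]
    mat[:, 0] = grid_t

    present = ~np.isnan(mat[:, 1])
    if not present.any():
        raise ValueError(f"track {track.subject_id} has no frames inside the schedule")
    # forward fill x, y, vel; backfill the leading gap from the first frame
    last = np.maximum.accumulate(np.where(present, np.arange(n), -1))
    first = int(np.argmax(present))
    src = np.where(last >= 0, last, first)
    filled = ~present
    for col in (1, 2, 4):  # x, y, vel
        mat[filled, col] = mat[src[filled], col]
    mat[filled, 3] = 0.0  # dist: no observed movement on filled frames

    frames = pd.DataFrame(mat, columns=FRAME_COLUMNS)
    out = track.copy()
    out.frames = frames
    out.frame_rate = frame_rate
    return out


def cap_outliers(track: LarvaTrack, cap: float | None = None) -> tuple[LarvaTrack, int]:
    """Cap per-frame distance at ``cap`` mm/frame (default the startle cap).

    Velocity on capped frames is rescaled to cap * frame_rate so dist and
    vel stay consistent.  Returns the capped track and the number of frames
    modified.
    """
    if cap is None:
        cap = compute_outlier_threshold()
    if cap <= 0:
        raise ValueError("cap must be > 0")
    out = track.copy()
    dist = out.frames["dist"].to_numpy().copy()
    vel = out.frames["vel"].to_numpy().copy()
    over = dist > cap
    n_capped = int(over.sum())
    if n_capped:
        dist[over] = cap
        vel[over] = cap * out.frame_rate
        out.frames["dist"] = dist
        out.frames["vel"] = vel
    return out, n_capped


def preprocess_track(
    track: LarvaTrack,
    geometry: WellGeometry | None = None,
    schedule: AssaySchedule | None = None,
    frame_rate: float | None = None,
    cap: float | None = None,
) -> LarvaTrack:
    """Full preprocessing: center -> forward-fill -> cap. Idempotent."""
    geometry = geometry or WellGeometry()
    out = center_coordinates(track, geometry)
    out = forward_fill(out, schedule, frame_rate)
    out, _ = cap_outliers(out, cap)
    return out


def extract_phase(
    track: LarvaTrack,
    cycle: int,
    phase: Phase,
    schedule: AssaySchedule | None = None,
    frame_rate: float | None = None,
) -> PhaseTensor:
    """Cut one phase window of one cycle out of a preprocessed track.

    The window is half-open [start, end); with the default schedule the
    light phase of cycle 2 covers [720 s, 900 s) and yields 4500 frames.
    The t column is re-zeroed to the window start.
    """
    schedule = schedule or AssaySchedule()
    frame_rate = frame_rate or track.frame_rate
    start, end = schedule.phase_window(cycle, phase)
    i0 = int(round(start * frame_rate))
    i1 = int(round(end * frame_rate))
    if track.n_frames < i1:
        raise ValueError(
            f"track {track.subject_id} has {track.n_frames} frames; phase window "
            f"needs frames up to {i1} — preprocess (forward_fill) first"
        )
    mat = track.frames[FRAME_COLUMNS].to_numpy()[i0:i1].copy()
    mat[:, 0] -= start
    return PhaseTensor(subject_id=track.subject_id, phase=phase, cycle=cycle, matrix=mat)


def downsample_tensor(tensor: PhaseTensor, factor: int) -> PhaseTensor:
    """Aggregate consecutive frames by ``factor`` to shrink the input size.

    Within each bin of ``factor`` frames: t takes the bin-start time, x, y
    and vel take the bin's last frame, and dist sums (total distance is
    conserved).  Frame count must divide evenly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = tensor.n_frames
    if n % factor:
        raise ValueError(f"{n} frames not divisible by factor {factor}")
    if factor == 1:
        return tensor
    m = tensor.matrix.reshape(n // factor, factor, -1)
    out = np.column_stack(
        [m[:, 0, 0], m[:, -1, 1], m[:, -1, 2], m[:, :, 3].sum(axis=1), m[:, -1, 4]]
    )
    return PhaseTensor(tensor.subject_id, tensor.phase, tensor.cycle, out)


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature affine z-scoring fitted on control tensors."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scale) <= 0):
            raise ValueError("scale must be > 0 for every feature")


def fit_scaler(tensors) -> FeatureScaler:
    """Fit a per-feature z-scaler on the stacked frames of control tensors."""
    tensors = list(tensors)
    if len(tensors) < 2:
        raise ValueError("need at least 2 control tensors to fit a scaler")
    stacked = np.vstack([t.matrix for t in tensors])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [FRAME_COLUMNS[i] for i in zero]
        raise ValueError(f"zero-variance feature(s): {names}")
    return FeatureScaler(mean=mean, scale=sd)


def apply_scaler(scaler: FeatureScaler, tensor: PhaseTensor) -> PhaseTensor:
    mat = (tensor.matrix - scaler.mean) / scaler.scale
    return PhaseTensor(tensor.subject_id, tensor.phase, tensor.cycle, mat)


def invert_scaler(scaler: FeatureScaler, tensor: PhaseTensor) -> PhaseTensor:
    mat = tensor.matrix * scaler.scale + scaler.mean
    return PhaseTensor(tensor.subject_id, tensor.phase, tensor.cycle, mat)


def save_tensors(
    tensors,
    path,
    *,
    scaler: FeatureScaler | None = None,
    config: dict | None = None,
) -> None:
    """Store phase tensors in one HDF5 archive keyed by subject/phase.

    The scaler (if any) and a free-form config mapping are embedded so a
    trained model's exact input convention travels with the data.
    """
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for t in tensors:
            grp = f.require_group(t.subject_id)
            ds = grp.create_dataset(f"{t.phase.value}_{t.cycle}", data=t.matrix)
            ds.attrs["phase"] = t.phase.value
            ds.attrs["cycle"] = t.cycle
        if scaler is not None:
            f.attrs["scaler_mean"] = scaler.mean
            f.attrs["scaler_scale"] = scaler.scale
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def load_tensors(path):
    """Read back a tensor archive -> (tensors, scaler or None, config dict)."""
    import json

    import h5py

    tensors: list[PhaseTensor] = []
    with h5py.File(path, "r") as f:
        for subject in f:
            for name, ds in f[subject].items():
                tensors.append(
                    PhaseTensor(
                        subject_id=subject,
                        phase=Phase(ds.attrs["phase"]),
                        cycle=int(ds.attrs["cycle"]),
                        matrix=ds[...],
                    )
                )
        scaler = None
        if "scaler_mean" in f.attrs:
            scaler = FeatureScaler(
                mean=np.asarray(f.attrs["scaler_mean"]),
                scale=np.asarray(f.attrs["scaler_scale"]),
            )
        config = json.loads(f.attrs["config"]) if "config" in f.attrs else {}
    return tensors, scaler, config


def compute_angular_velocity(track: LarvaTrack) -> np.ndarray:
    """Signed angular velocity of the heading, deg/s, one value per interval.

    The heading at interval i is atan2(Δy_i, Δx_i) for moving frames
    (dist > 0); a stationary interval carries the previous heading forward.
    Angular velocity is the wrapped signed heading change between successive
    intervals, in (-180, 180] per interval, divided by the frame interval.
    Returns n_frames - 2 values.
    """
    if track.n_frames < 3:
        raise ValueError("angular velocity needs at least 3 frames")
    f = track.frames
    dx = np.diff(f["x"].to_numpy())
    dy = np.diff(f["y"].to_numpy())
    moving = (dx != 0) | (dy != 0)
    heading = np.degrees(np.arctan2(dy, dx))
    # carry heading forward over stationary intervals
    idx = np.maximum.accumulate(np.where(moving, np.arange(len(heading)), -1))
    first = int(np.argmax(moving)) if moving.any() else 0
    heading = heading[np.where(idx >= 0, idx, first)]
    if not moving.any():
        heading = np.zeros_like(heading)
    dh = np.diff(heading)
    dh = (dh + 180.0) % 360.0 - 180.0
    dh[dh == -180.0] = 180.0  # wrap to (-180, 180]
    dt = 1.0 / track.frame_rate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dh / dt
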