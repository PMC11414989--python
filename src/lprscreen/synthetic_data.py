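"""Synthetic LPR studies with known ground truth.

Real LPR data are larval swim trajectories in round 96-well plates: low
movement under light, a burst of swimming at each light-to-dark transition
that decays over minutes, plate-to-plate heterogeneity in baseline control
activity, and tracking dropouts.  The generator reproduces that structure
with a bounded correlated random walk in the well disc: per-frame step
lengths are gamma-distributed with a phase-dependent mean (the dark mean
carries an exponentially decaying burst), headings persist with Gaussian
turning noise and reflect off the well wall, pauses zero the step, and
frames are dropped at a configurable rate.  Treatment phenotypes perturb
the walk (activity scaling, thigmotaxis-like wall bias, delayed dark-onset
response), and a truth table records every larva's generating phenotype so
each pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_WELL_RADIUS
from .stats import ActivityState
from .track_data import (
    CONTROL,
    FRAME_COLUMNS,
    AssaySchedule,
    LarvaTrack,
    Treatment,
    write_morphology,
    write_plate_map,
    write_tracks,
)

__all__ = [
    "BehaviorParams",
    "PhenotypeSpec",
    "ComboSpec",
    "StudyConfig",
    "StudyData",
    "STATE_MULTIPLIERS",
    "simulate_larva",
    "simulate_tracks_array",
    "simulate_study",
    "write_study",
]

#: activity-state multiplier applied to a plate's control step means
STATE_MULTIPLIERS = {
    ActivityState.HYPOACTIVE: 0.4,
    ActivityState.NORMAL: 1.0,
    ActivityState.HYPERACTIVE: 2.2,
}

GAMMA_SHAPE = 2.0  # shape of the per-frame step-length distribution


@dataclass(frozen=True)
class BehaviorParams:
    """Kinetic parameters of the control swim model.

    light_step_mean is the mean per-frame step under light (mm/frame; 0.02
    at 25 frames/s is 0.5 mm/s of sustained swimming).  At each
    light-to-dark transition the dark step mean is elevated by
    dark_burst_amplitude decaying with time constant burst_decay_tau.
    turning_sd is the per-frame heading diffusion; pause_prob the chance a
    frame has no movement; missing_frame_prob the tracking dropout rate.
    """

    light_step_mean: float = 0.02  # mm/frame
    dark_burst_amplitude: float = 0.12  # mm/frame extra at dark onset
    burst_decay_tau: float = 60.0  # s
    turning_sd: float = 25.0  # deg per frame
    pause_prob: float = 0.35
    missing_frame_prob: float = 0.002

    def __post_init__(self) -> None:
        if min(self.light_step_mean, self.dark_burst_amplitude, self.burst_decay_tau,
               self.turning_sd) < 0:
            raise ValueError("behavior parameters must be >= 0")
        for p in (self.pause_prob, self.missing_frame_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PhenotypeSpec:
    """How a treatment perturbs the control walk.

    activity_scale multiplies the step means (0.2 is strongly hypoactive,
    2.5 strongly hyperactive); spatial_bias in [-1, 1] is the fraction of
    frames whose heading is drawn toward the wall (> 0, thigmotaxis-like)
    or the center (< 0); onset_delay (s) postpones the dark-transition
    burst.
    """

    activity_scale: float = 1.0
    spatial_bias: float = 0.0
    onset_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_scale < 0:
            raise ValueError("activity_scale must be >= 0")
        if not -1 <= self.spatial_bias <= 1:
            raise ValueError("spatial_bias must be in [-1, 1]")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")


CONTROL_PHENOTYPE = PhenotypeSpec()


@dataclass(frozen=True)
class ComboSpec:
    """One chemical-concentration combination to place in the study."""

    chemical: str
    concentration: float  # μM
    phenotype: PhenotypeSpec = CONTROL_PHENOTYPE
    n_replicates: int = 7

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("combo concentration must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    """Layout and conditions of one synthetic study."""

    n_plates: int = 4
    wells_per_plate: int = 96
    controls_per_plate: int = 8
    combos: tuple[ComboSpec, ...] = ()
    plate_state_distribution: dict[ActivityState, float] = field(
        default_factory=lambda: {
            ActivityState.HYPOACTIVE: 0.2,
            ActivityState.NORMAL: 0.6,
            ActivityState.HYPERACTIVE: 0.2,
        }
    )
    plate_states: tuple[ActivityState, ...] | None = None  # explicit override
    params: BehaviorParams = field(default_factory=BehaviorParams)
    schedule: AssaySchedule = field(default_factory=AssaySchedule)
    frame_rate: float = 25.0
    well_radius: float = DEFAULT_WELL_RADIUS
    morphology_abnormal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total_p = sum(self.plate_state_distribution.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"plate_state_distribution sums to {total_p}, not 1")
        if self.controls_per_plate < 2:
            raise ValueError("need at least 2 controls per plate")
        object.__setattr__(self, "combos", tuple(self.combos))
        if self.plate_states is not None:
            object.__setattr__(self, "plate_states", tuple(self.plate_states))
            if len(self.plate_states) != self.n_plates:
                raise ValueError("plate_states must list one state per plate")


@dataclass
class StudyData:
    """A simulated study: tracks plus the tables the readers consume."""

    tracks: list[LarvaTrack]
    plate_map: dict[str, Treatment]
    morphology: dict[str, bool]
    truth: pd.DataFrame
    config: StudyConfig


# ---------------------------------------------------------------------------
# the walker


def _burst_profile(schedule: AssaySchedule, t: np.ndarray, delay: np.ndarray,
                   tau: float) -> np.ndarray:
    """exp(-(t - dark_onset - delay)/tau) inside dark phases, else 0.

    Shape (n_walkers, n_frames); acclimation counts as a dark phase starting
    at t = 0.
    """
    period = schedule.cycle_light + schedule.cycle_dark
    u = t - schedule.acclimation
    in_acclim = u < 0
    in_cycle_dark = ~in_acclim & ((u % period) >= schedule.cycle_light)
    dark_onset = np.where(
        in_acclim,
        0.0,
        schedule.acclimation + np.floor(u / period) * period + schedule.cycle_light,
    )
    since = t[None, :] - dark_onset[None, :] - delay[:, None]
    active = (in_acclim | in_cycle_dark)[None, :] & (since >= 0)
    return np.where(active, np.exp(np.where(active, -since, 0.0) / tau), 0.0)


def simulate_tracks_array(
    light_mean: np.ndarray,
    burst_amp: np.ndarray,
    spatial_bias: np.ndarray,
    onset_delay: np.ndarray,
    params: BehaviorParams,
    schedule: AssaySchedule,
    frame_rate: float,
    well_radius: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized walk for a batch of larvae (one row per larva).

    ``light_mean`` and ``burst_amp`` are per-larva mm/frame step means
    (activity scaling already applied).  Returns arrays ``t`` (n_frames,)
    and ``x``, ``y``, ``dist``, ``vel``, ``present`` of shape
    (n_larvae, n_frames); ``present`` marks frames surviving tracking
    dropout.  dist is the realized displacement, so dist == |Δposition|
    exactly, and vel = dist * frame_rate.
    """
    n = len(light_mean)
    T = int(round(schedule.total_duration * frame_rate))
    t = np.arange(T) / frame_rate

    burst = _burst_profile(schedule, t, onset_delay, params.burst_decay_tau)
    mean_step = light_mean[:, None] + burst_amp[:, None] * burst  # (n, T)
    steps = rng.gamma(GAMMA_SHAPE, 1.0, size=(n, T)) * (mean_step / GAMMA_SHAPE)
    steps[rng.random((n, T)) < params.pause_prob] = 0.0
    turn = np.radians(rng.normal(0.0, params.turning_sd, size=(n, T)))
    biased = rng.random((n, T)) < np.abs(spatial_bias)[:, None]
    outward = (spatial_bias > 0)[:, None]

    x = np.empty((n, T))
    y = np.empty((n, T))
    dist = np.zeros((n, T))
    # start uniformly in the disc
    r0 = well_radius * np.sqrt(rng.random(n))
    a0 = rng.uniform(0, 2 * np.pi, n)
    px, py = r0 * np.cos(a0), r0 * np.sin(a0)
    heading = rng.uniform(0, 2 * np.pi, n)
    x[:, 0], y[:, 0] = px, py
    for i in range(1, T):
        heading = heading + turn[:, i]
        bias_now = biased[:, i]
        if bias_now.any():
            radial = np.arctan2(py, px)
            target = np.where(outward[:, 0], radial, radial + np.pi)
            heading = np.where(bias_now, target + turn[:, i], heading)
        s = steps[:, i]
        nx = px + s * np.cos(heading)
        ny = py + s * np.sin(heading)
        r = np.hypot(nx, ny)
        over = r > well_radius
        if over.any():
            f = (2.0 * well_radius / r[over]) - 1.0
            nx[over] *= f
            ny[over] *= f
        dx, dy = nx - px, ny - py
        d = np.hypot(dx, dy)
        moved = d > 0
        heading = np.where(moved, np.arctan2(dy, dx), heading)
        dist[:, i] = d
        px, py = nx, ny
        x[:, i], y[:, i] = px, py
    vel = dist * frame_rate
    present = rng.random((n, T)) >= params.missing_frame_prob
    return {"t": t, "x": x, "y": y, "dist": dist, "vel": vel, "present": present}


def _make_track(
    subject_id: str,
    plate_id: str,
    well: str,
    treatment: Treatment,
    arrays: dict[str, np.ndarray],
    row: int,
    frame_rate: float,
) -> LarvaTrack:
    keep = arrays["present"][row]
    frames = pd.DataFrame(
        {
            "t": arrays["t"][keep],
            "x": arrays["x"][row, keep],
            "y": arrays["y"][row, keep],
            "dist": arrays["dist"][row, keep],
            "vel": arrays["vel"][row, keep],
        },
        columns=FRAME_COLUMNS,
    )
    return LarvaTrack(
        subject_id=subject_id,
        plate_id=plate_id,
        well=well,
        treatment=treatment,
        frames=frames,
        frame_rate=frame_rate,
    )


def simulate_larva(
    params: BehaviorParams,
    phenotype: PhenotypeSpec = CONTROL_PHENOTYPE,
    schedule: AssaySchedule | None = None,
    frame_rate: float = 25.0,
    seed: int = 0,
    *,
    well_radius: float = DEFAULT_WELL_RADIUS,
    subject_id: str = "sim",
    plate_id: str = "P1",
    well: str = "A1",
    treatment: Treatment | None = None,
) -> LarvaTrack:
    """Simulate a single larva's track (see module docstring for the model)."""
    schedule = schedule or AssaySchedule()
    rng = np.random.default_rng(seed)
    arrays = simulate_tracks_array(
        light_mean=np.array([params.light_step_mean * phenotype.activity_scale]),
        burst_amp=np.array([params.dark_burst_amplitude * phenotype.activity_scale]),
        spatial_bias=np.array([phenotype.spatial_bias]),
        onset_delay=np.array([phenotype.onset_delay]),
        params=params,
        schedule=schedule,
        frame_rate=frame_rate,
        well_radius=well_radius,
        rng=rng,
    )
    return _make_track(
        subject_id, plate_id, well, treatment or Treatment(), arrays, 0, frame_rate
    )


def _well_label(index: int, wells_per_plate: int) -> str:
    n_cols = 12 if wells_per_plate % 12 == 0 else wells_per_plate
    row, col = divmod(index, n_cols)
    return f"{chr(ord('A') + row)}{col + 1}"


def simulate_study(config: StudyConfig) -> StudyData:
    """Simulate a whole multi-plate study with known ground truth.

    Each plate draws an activity state (or takes it from
    ``config.plate_states``) whose multiplier scales that plate's step
    means — controls and treated alike, since plate effects are shared.
    Combos are placed whole on plates round-robin after the control wells.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    states = list(ActivityState)
    if config.plate_states is not None:
        plate_states = list(config.plate_states)
    else:
        probs = [config.plate_state_distribution.get(s, 0.0) for s in states]
        plate_states = [states[i] for i in rng.choice(len(states), config.n_plates, p=probs)]

    # assign combos to plates round-robin, tracking capacity
    capacity = [config.wells_per_plate - config.controls_per_plate] * config.n_plates
    combo_plate: list[int] = []
    for i, combo in enumerate(config.combos):
        p = i % config.n_plates
        tried = 0
        while capacity[p] < combo.n_replicates and tried < config.n_plates:
            p = (p + 1) % config.n_plates
            tried += 1
        if capacity[p] < combo.n_replicates:
            raise ValueError(
                f"combo {combo.chemical} @ {combo.concentration} μM does not fit: "
                f"all plates at capacity"
            )
        capacity[p] -= combo.n_replicates
        combo_plate.append(p)

    # per-larva parameter rows
    rows = []  # (subject, plate, well, treatment, phenotype, state)
    for p in range(config.n_plates):
        plate_id = f"P{p + 1}"
        widx = 0
        for _ in range(config.controls_per_plate):
            well = _well_label(widx, config.wells_per_plate)
            rows.append((f"{plate_id}-{well}", plate_id, well, Treatment(),
                         CONTROL_PHENOTYPE, plate_states[p]))
            widx += 1
        for combo, cp in zip(config.combos, combo_plate):
            if cp != p:
                continue
            trt = Treatment(chemical=combo.chemical, concentration=combo.concentration)
            for _ in range(combo.n_replicates):
                well = _well_label(widx, config.wells_per_plate)
                rows.append((f"{plate_id}-{well}", plate_id, well, trt,
                             combo.phenotype, plate_states[p]))
                widx += 1

    mult = np.array([STATE_MULTIPLIERS[r[5]] for r in rows])
    scale = np.array([r[4].activity_scale for r in rows]) * mult
    light_mean = config.params.light_step_mean * scale
    burst_amp = config.params.dark_burst_amplitude * scale
    spatial_bias = np.array([r[4].spatial_bias for r in rows])
    onset_delay = np.array([r[4].onset_delay for r in rows])

    arrays = simulate_tracks_array(
        light_mean, burst_amp, spatial_bias, onset_delay,
        config.params, config.schedule, config.frame_rate, config.well_radius, rng,
    )

    tracks = [
        _make_track(sub, plate, well, trt, arrays, i, config.frame_rate)
        for i, (sub, plate, well, trt, _, _) in enumerate(rows)
    ]
    plate_map = {r[0]: r[3] for r in rows}
    abnormal = rng.random(len(rows)) < config.morphology_abnormal_fraction
    morphology = {r[0]: bool(a) for r, a in zip(rows, abnormal)}
    truth = pd.DataFrame(
        {
            "subject": [r[0] for r in rows],
            "plate": [r[1] for r in rows],
            "well": [r[2] for r in rows],
            "plate_state": [r[5].value for r in rows],
            "chemical": [r[3].chemical for r in rows],
            "concentration_um": [r[3].concentration for r in rows],
            "activity_scale": [r[4].activity_scale for r in rows],
            "spatial_bias": [r[4].spatial_bias for r in rows],
            "onset_delay": [r[4].onset_delay for r in rows],
            "morphology_abnormal": abnormal.astype(int),
        }
    )
    return StudyData(
        tracks=tracks, plate_map=plate_map, morphology=morphology,
        truth=truth, config=config,
    )


def write_study(study: StudyData, directory) -> dict[str, Path]:
    """Write tracks.csv.gz, plate_map.csv, morphology.csv and truth.csv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": d / "tracks.csv.gz",
        "plate_map": d / "plate_map.csv",
        "morphology": d / "morphology.csv",
        "truth": d / "truth.csv",
    }
    write_tracks(study.tracks, paths["tracks"])
    write_plate_map(study.plate_map, paths["plate_map"])
    write_morphology(study.morphology, paths["morphology"])
    study.truth.to_csv(paths["truth"], index=False)
    return paths
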