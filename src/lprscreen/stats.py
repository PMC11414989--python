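"""The statistical screening framework: K-S tests, plate stratification,
combo screening and abnormal-larva labeling.

This is the "traditional" half of the pipeline.  A two-sample
Kolmogorov–Smirnov test (non-parametric, two-sided, no multiplicity
adjustment) drives three decisions:

* control plates are stratified into hypoactive / normal / hyperactive
  activity states by comparing each plate's controls to the pooled controls
  of all other plates (p < 0.01),
* each chemical-concentration combination is screened against its
  same-plate controls (p < 0.05), and
* larvae from significant combinations whose total cycle-2 distance falls
  at or below the matched controls' 30th percentile, or at or above their
  70th, are labeled abnormal.  These labels supervise the autoencoders'
  logistic heads and form the validation set.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .track_data import AssaySchedule, LarvaTrack, Phase
from . import preprocess

__all__ = [
    "KSResult",
    "ActivityState",
    "AbnormalLabelSet",
    "ks_two_sample",
    "stratify_control_plates",
    "screen_combinations",
    "label_abnormal_larvae",
    "cycle_window_values",
    "total_cycle_distance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    """Two-sample K-S statistic D = sup |ECDF_a - ECDF_b| and its p-value."""

    D: float
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.D <= 1 and 0 <= self.p <= 1):
            raise ValueError(f"invalid KSResult D={self.D} p={self.p}")


class ActivityState(enum.Enum):
    """Plate-level control activity category relative to pooled controls."""

    HYPOACTIVE = "hypoactive"
    NORMAL = "normal"
    HYPERACTIVE = "hyperactive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AbnormalLabelSet:
    """Subjects labeled abnormal, with the provenance of the labeling rule."""

    subjects: frozenset[str]
    metric: str
    lower_pct: float
    upper_pct: float
    combos: tuple[tuple[str, float], ...]

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.subjects

    def __len__(self) -> int:
        return len(self.subjects)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample two-sided K-S test (asymptotic p-value).

    D is the supremum gap between the two empirical CDFs; the p-value uses
    the standard asymptotic two-sided formula.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    with np.errstate(divide="ignore"):
        res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    p = float(res.pvalue)
    if not np.isfinite(p):  # degenerate sizes: Kolmogorov limit distribution
        en = np.sqrt(a.size * b.size / (a.size + b.size))
        p = float(sps.kstwobign.sf(en * res.statistic))
    return KSResult(D=float(res.statistic), p=float(min(max(p, 0.0), 1.0)))


def _track_phase_values(
    track: LarvaTrack,
    metric: str,
    cycle: int,
    phase: Phase | None,
    schedule: AssaySchedule,
) -> np.ndarray:
    """Per-frame metric values of one track over one cycle (or one phase)."""
    phases = [Phase.LIGHT, Phase.DARK] if phase is None else [phase]
    vals = []
    for ph in phases:
        start, end = schedule.phase_window(cycle, ph)
        i0 = int(round(start * track.frame_rate))
        i1 = int(round(end * track.frame_rate))
        if metric == "distance":
            vals.append(track.frames["dist"].to_numpy()[i0:i1])
        elif metric == "angular_velocity":
            omega = preprocess.compute_angular_velocity(track)
            # omega[j] belongs to the interval ending at frame j+2
            vals.append(omega[max(i0 - 2, 0) : i1 - 2])
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return np.concatenate(vals)


def cycle_window_values(
    tracks,
    metric: str = "distance",
    *,
    cycle: int = 2,
    phase: Phase | None = None,
    schedule: AssaySchedule | None = None,
    unit: str = "frame",
) -> np.ndarray:
    """Pool the per-frame metric over a cycle window across tracks.

    ``unit="frame"`` pools raw per-frame values; ``unit="larva"`` reduces
    each track to its mean per-frame value first.
    """
    schedule = schedule or AssaySchedule()
    parts = [_track_phase_values(t, metric, cycle, phase, schedule) for t in tracks]
    if unit == "frame":
        return np.concatenate(parts) if parts else np.array([])
    if unit == "larva":
        return np.array([p.mean() for p in parts])
    raise ValueError(f"unit must be 'frame' or 'larva', got {unit!r}")


def total_cycle_distance(
    track: LarvaTrack, cycle: int = 2, schedule: AssaySchedule | None = None
) -> float:
    """Total distance moved (mm) over both phases of one cycle."""
    schedule = schedule or AssaySchedule()
    return float(
        _track_phase_values(track, "distance", cycle, None, schedule).sum()
    )


def stratify_control_plates(
    control_tracks,
    *,
    alpha: float = 0.01,
    cycle: int = 2,
    schedule: AssaySchedule | None = None,
    unit: str = "larva",
) -> dict[str, dict[Phase, ActivityState]]:
    """Classify each plate's controls as hypo/normal/hyperactive per phase.

    Each plate's control movement is K-S-tested against the pooled controls
    of all *other* plates.  A plate is NORMAL when p >= alpha; otherwise it
    is HYPERACTIVE when its mean per-frame distance exceeds the pooled mean,
    else HYPOACTIVE.

    ``unit`` controls the K-S sample: ``"larva"`` (default) compares
    per-larva mean per-frame distances, so the test operates at the level
    the heterogeneity lives at; ``"frame"`` pools raw per-frame values.
    """
    schedule = schedule or AssaySchedule()
    by_plate: dict[str, list[LarvaTrack]] = {}
    for t in control_tracks:
        by_plate.setdefault(t.plate_id, []).append(t)
    if len(by_plate) < 2:
        raise ValueError("need controls from at least 2 plates to stratify")
    for plate, ts in by_plate.items():
        if len(ts) < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 control larvae")

    out: dict[str, dict[Phase, ActivityState]] = {}
    for phase in (Phase.LIGHT, Phase.DARK):
        samples = {
            plate: cycle_window_values(
                ts, "distance", cycle=cycle, phase=phase, schedule=schedule, unit=unit
            )
            for plate, ts in by_plate.items()
        }
        means = {
            plate: cycle_window_values(
                ts, "distance", cycle=cycle, phase=phase, schedule=schedule, unit="frame"
            ).mean()
            for plate, ts in by_plate.items()
        }
        for plate in sorted(by_plate):
            pooled = np.concatenate([v for p, v in sorted(samples.items()) if p != plate])
            pooled_mean = np.mean(
                [m for p, m in means.items() if p != plate]
            )
            res = ks_two_sample(samples[plate], pooled)
            if res.p >= alpha:
                state = ActivityState.NORMAL
            elif means[plate] > pooled_mean:
                state = ActivityState.HYPERACTIVE
            else:
                state = ActivityState.HYPOACTIVE
            out.setdefault(plate, {})[phase] = state
    return out


def _split_by_treatment(tracks, treatments):
    """-> (combo -> tracks, plate -> control tracks)."""
    combos: dict[tuple[str, float], list[LarvaTrack]] = {}
    controls: dict[str, list[LarvaTrack]] = {}
    for t in tracks:
        trt = treatments[t.subject_id]
        if trt.is_control:
            controls.setdefault(t.plate_id, []).append(t)
        else:
            combos.setdefault((trt.chemical, trt.concentration), []).append(t)
    return combos, controls


def _matched_controls(combo_tracks, controls_by_plate):
    plates = sorted({t.plate_id for t in combo_tracks})
    out = []
    for p in plates:
        out.extend(controls_by_plate.get(p, []))
    return out


def screen_combinations(
    tracks,
    treatments,
    *,
    metric: str = "distance",
    alpha: float = 0.05,
    cycle: int = 2,
    schedule: AssaySchedule | None = None,
    ks_unit: str = "frame",
) -> pd.DataFrame:
    """K-S screen of every chemical-concentration combination.

    Each combo's pooled cycle-2 per-frame metric is compared to its
    same-plate controls; significant means p < alpha.  No multiplicity
    adjustment is applied.  Combos without same-plate controls are skipped
    with a warning.

    Returns a DataFrame (chemical, concentration, n_treated, n_control,
    D, p, significant), one row per combo with controls.
    """
    schedule = schedule or AssaySchedule()
    combos, controls = _split_by_treatment(tracks, treatments)
    rows = []
    for (chemical, conc), combo_tracks in sorted(combos.items()):
        ctrl = _matched_controls(combo_tracks, controls)
        if not ctrl:
            log.warning(
                "combo (%s, %g μM) has no same-plate controls; skipped", chemical, conc
            )
            continue
        a = cycle_window_values(
            combo_tracks, metric, cycle=cycle, schedule=schedule, unit=ks_unit
        )
        b = cycle_window_values(ctrl, metric, cycle=cycle, schedule=schedule, unit=ks_unit)
        res = ks_two_sample(a, b)
        rows.append(
            {
                "chemical": chemical,
                "concentration": conc,
                "metric": metric,
                "n_treated": len(combo_tracks),
                "n_control": len(ctrl),
                "D": res.D,
                "p": res.p,
                "significant": res.p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chemical", "concentration", "metric",
            "n_treated", "n_control", "D", "p", "significant",
        ],
    )


def label_abnormal_larvae(
    screen: pd.DataFrame,
    tracks,
    treatments,
    *,
    lower_pct: float = 30.0,
    upper_pct: float = 70.0,
    cycle: int = 2,
    schedule: AssaySchedule | None = None,
) -> AbnormalLabelSet:
    """Label abnormal larvae within the significant combinations.

    The per-larva metric is total distance moved over cycle 2.  Thresholds
    are the matched (same-plate) controls' ``lower_pct`` and ``upper_pct``
    percentiles (linear interpolation); treated larvae at or below the lower
    or at or above the upper threshold are labeled abnormal.  Larvae from
    non-significant combos are never labeled.
    """
    schedule = schedule or AssaySchedule()
    combos, controls = _split_by_treatment(tracks, treatments)
    sig = {
        (r.chemical, r.concentration)
        for r in screen.itertuples()
        if r.significant
    }
    labeled: set[str] = set()
    used: list[tuple[str, float]] = []
    for key in sorted(sig):
        combo_tracks = combos.get(key, [])
        ctrl = _matched_controls(combo_tracks, controls)
        if not ctrl:
            raise ValueError(f"significant combo {key} has no matched controls")
        ctrl_metric = np.array(
            [total_cycle_distance(t, cycle, schedule) for t in ctrl]
        )
        lo = np.percentile(ctrl_metric, lower_pct)
        hi = np.percentile(ctrl_metric, upper_pct)
        used.append(key)
        for t in combo_tracks:
            m = total_cycle_distance(t, cycle, schedule)
            if m <= lo or m >= hi:
                labeled.add(t.subject_id)
    return AbnormalLabelSet(
        subjects=frozenset(labeled),
        metric="total_cycle_distance",
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        combos=tuple(used),
    )
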