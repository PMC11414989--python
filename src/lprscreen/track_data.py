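"""Domain types and tabular I/O for larval photomotor response (LPR) tracking data.

The unit of observation is one larva in one well of a 96-well plate, tracked
at a fixed frame rate through a light/dark cycling assay.  Tracking exports
arrive as long-format tables (one row per larva per frame); this module turns
them into :class:`LarvaTrack` objects and back, and handles the plate map
(which chemical and concentration each well received) and the morphology
table (larvae with physical malformations, which are excluded from any
behavioral analysis).

Distances are stored in millimetres internally.  Tracking software commonly
exports distance moved in micrometres while velocity is already mm/s; the
readers take an explicit unit flag rather than guessing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL",
    "FRAME_COLUMNS",
    "DEFAULT_SCHEMA",
    "Phase",
    "Treatment",
    "AssaySchedule",
    "LarvaTrack",
    "SchemaError",
    "read_tracks",
    "write_tracks",
    "read_plate_map",
    "write_plate_map",
    "read_morphology",
    "write_morphology",
    "filter_morphology",
]

CONTROL = "CONTROL"

#: canonical per-frame feature order used everywhere downstream
FRAME_COLUMNS = ["t", "x", "y", "dist", "vel"]

#: logical name -> column name in a tracking export
DEFAULT_SCHEMA = {
    "subject": "subject",
    "plate": "plate",
    "well": "well",
    "time": "t",
    "x": "x",
    "y": "y",
    "dist": "dist",
    "vel": "vel",
}


class SchemaError(ValueError):
    """A required column is missing or cannot be parsed."""


class Phase(enum.Enum):
    """Illumination phase of the assay. Acclimation is dark."""

    LIGHT = "light"
    DARK = "dark"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Treatment:
    """Chemical exposure of one larva. Controls have concentration 0 μM."""

    chemical: str = CONTROL
    concentration: float = 0.0  # μM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration: {self.concentration}")
        if (self.chemical == CONTROL) != (self.concentration == 0):
            raise ValueError(
                f"control flag inconsistent: chemical={self.chemical!r} "
                f"concentration={self.concentration}"
            )

    @property
    def is_control(self) -> bool:
        return self.concentration == 0


@dataclass(frozen=True)
class AssaySchedule:
    """Timing of the light/dark cycling assay.

    The default is a 6 min dark acclimation followed by 3 cycles of
    3 min light : 3 min dark (24 min total).
    """

    acclimation: float = 360.0  # s, dark
    cycle_light: float = 180.0  # s
    cycle_dark: float = 180.0  # s
    n_cycles: int = 3

    def __post_init__(self) -> None:
        if min(self.acclimation, self.cycle_light, self.cycle_dark) <= 0:
            raise ValueError("all schedule durations must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def total_duration(self) -> float:
        return self.acclimation + self.n_cycles * (self.cycle_light + self.cycle_dark)

    def phase_window(self, cycle: int, phase: Phase) -> tuple[float, float]:
        """Half-open time window [start, end) of one phase of one cycle."""
        if not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"cycle {cycle} out of range 1..{self.n_cycles}")
        start = self.acclimation + (cycle - 1) * (self.cycle_light + self.cycle_dark)
        if phase is Phase.LIGHT:
            return (start, start + self.cycle_light)
        return (start + self.cycle_light, start + self.cycle_light + self.cycle_dark)

    def phase_at(self, t: float) -> Phase:
        """Illumination phase at assay time ``t`` (s)."""
        if t < self.acclimation:
            return Phase.DARK
        u = (t - self.acclimation) % (self.cycle_light + self.cycle_dark)
        return Phase.LIGHT if u < self.cycle_light else Phase.DARK


@dataclass
class LarvaTrack:
    """One larva's ordered per-frame behavioral record.

    ``frames`` is a DataFrame with columns ``t`` (s from assay start),
    ``x``/``y`` (mm, well-centered after preprocessing), ``dist``
    (mm moved since previous frame) and ``vel`` (mm/s).
    """

    subject_id: str
    plate_id: str
    well: str
    treatment: Treatment = field(default_factory=Treatment)
    frames: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FRAME_COLUMNS))
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"track frames missing columns {missing}")
        t = self.frames["t"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def copy(self) -> "LarvaTrack":
        return replace(self, frames=self.frames.copy())


def _require_columns(df: pd.DataFrame, cols: dict[str, str], where: str) -> None:
    missing = {k: v for k, v in cols.items() if v not in df.columns}
    if missing:
        names = ", ".join(f"{k!r} (column {v!r})" for k, v in missing.items())
        raise SchemaError(f"{where}: missing required column(s): {names}")


def _to_numeric(df: pd.DataFrame, col: str, where: str) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{where}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row}"
        )
    return out.to_numpy(dtype=float)


def read_tracks(
    path,
    schema: dict[str, str] | None = None,
    *,
    distance_unit: str = "mm",
    frame_rate: float = 25.0,
    sep: str = ",",
) -> list[LarvaTrack]:
    """Read a long-format tracking export into a list of :class:`LarvaTrack`.

    Parameters
    ----------
    path
        CSV/TSV file, optionally gzip-compressed (by extension).
    schema
        Map of logical names (``subject``, ``plate``, ``well``, ``time``,
        ``x``, ``y``, ``dist``, ``vel``) to column names in the file.
        ``well`` may be absent, in which case the subject id doubles as the
        well label.
    distance_unit
        ``"mm"`` or ``"um"``; the ``dist`` column is converted to mm
        internally (positions and velocity are taken as mm and mm/s).

    Every input row lands in exactly one track; frames are ordered by time.
    """
    if distance_unit not in ("mm", "um"):
        raise ValueError(f"distance_unit must be 'mm' or 'um', got {distance_unit!r}")
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep)
    required = {k: schema[k] for k in ("subject", "plate", "time", "x", "y", "dist", "vel")}
    _require_columns(df, required, str(path))
    if df.empty:
        return []

    dist_scale = 1e-3 if distance_unit == "um" else 1.0
    num = {
        "t": _to_numeric(df, schema["time"], str(path)),
        "x": _to_numeric(df, schema["x"], str(path)),
        "y": _to_numeric(df, schema["y"], str(path)),
        "dist": _to_numeric(df, schema["dist"], str(path)) * dist_scale,
        "vel": _to_numeric(df, schema["vel"], str(path)),
    }
    flat = pd.DataFrame(num)
    flat["subject"] = df[schema["subject"]].astype(str)
    flat["plate"] = df[schema["plate"]].astype(str)
    well_col = schema.get("well")
    if well_col is not None and well_col in df.columns:
        flat["well"] = df[well_col].astype(str)
    else:
        flat["well"] = flat["subject"]

    tracks: list[LarvaTrack] = []
    for (plate, subject), grp in flat.groupby(["plate", "subject"], sort=True):
        grp = grp.sort_values("t", kind="mergesort")
        frames = grp[FRAME_COLUMNS].reset_index(drop=True)
        tracks.append(
            LarvaTrack(
                subject_id=str(subject),
                plate_id=str(plate),
                well=str(grp["well"].iloc[0]),
                frames=frames,
                frame_rate=frame_rate,
            )
        )
    return tracks


def write_tracks(tracks, path, *, sep: str = ",") -> None:
    """Write tracks back to the long format `read_tracks` accepts (mm units)."""
    parts = []
    for tr in tracks:
        part = tr.frames.copy()
        part.insert(0, "well", tr.well)
        part.insert(0, "plate", tr.plate_id)
        part.insert(0, "subject", tr.subject_id)
        parts.append(part)
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["subject", "plate", "well", *FRAME_COLUMNS])
    out.to_csv(path, sep=sep, index=False)


def read_plate_map(path) -> dict[str, Treatment]:
    """Read a plate map CSV (columns subject, chemical, concentration_um).

    Returns a map subject_id -> :class:`Treatment`; every subject appears
    exactly once.
    """
    df = pd.read_csv(path)
    cols = {"subject": "subject", "chemical": "chemical", "concentration": "concentration_um"}
    _require_columns(df, cols, str(path))
    subjects = df["subject"].astype(str)
    dup = subjects[subjects.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate subject(s) in plate map: {dup}")
    conc = _to_numeric(df, "concentration_um", str(path))
    if (conc < 0).any():
        bad = subjects[conc < 0].tolist()
        raise ValueError(f"negative concentration for subject(s): {bad}")
    out: dict[str, Treatment] = {}
    for subj, chem, c in zip(subjects, df["chemical"].astype(str), conc):
        chem = CONTROL if c == 0 else chem
        out[subj] = Treatment(chemical=chem, concentration=float(c))
    return out


def write_plate_map(plate_map: dict[str, Treatment], path) -> None:
    rows = [
        {"subject": s, "chemical": t.chemical, "concentration_um": t.concentration}
        for s, t in plate_map.items()
    ]
    pd.DataFrame(rows, columns=["subject", "chemical", "concentration_um"]).to_csv(
        path, index=False
    )


def read_morphology(path) -> dict[str, bool]:
    """Read the morphology table (columns subject, abnormal as 0/1)."""
    df = pd.read_csv(path)
    _require_columns(df, {"subject": "subject", "abnormal": "abnormal"}, str(path))
    return {
        str(s): bool(int(a)) for s, a in zip(df["subject"], df["abnormal"])
    }


def write_morphology(morphology: dict[str, bool], path) -> None:
    rows = [{"subject": s, "abnormal": int(a)} for s, a in morphology.items()]
    pd.DataFrame(rows, columns=["subject", "abnormal"]).to_csv(path, index=False)


def filter_morphology(tracks, morphology: dict[str, bool]):
    """Drop tracks of larvae flagged with a physical malformation.

    Malformed larvae are excluded from all behavioral analysis because the
    malformation itself may alter movement.  Subjects absent from the
    morphology table are retained.
    """
    return [t for t in tracks if not morphology.get(t.subject_id, False)]
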