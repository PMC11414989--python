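"""Shared fixtures: a short assay schedule and a small multi-plate study.

The mini schedule (1 min acclimation + 2 cycles of 1 min light : 1 min
dark at 10 frames/s) keeps simulation and training fast while preserving
the assay's structure; tests of the exact full-scale geometry build their
own default-schedule tracks.
"""

import numpy as np
import pandas as pd
import pytest

from lprscreen.stats import ActivityState
from lprscreen.synthetic_data import (
    BehaviorParams,
    ComboSpec,
    PhenotypeSpec,
    StudyConfig,
    simulate_study,
)
from lprscreen.track_data import FRAME_COLUMNS, AssaySchedule, LarvaTrack, Treatment


@pytest.fixture(scope="session")
def mini_schedule() -> AssaySchedule:
    return AssaySchedule(acclimation=60, cycle_light=60, cycle_dark=60, n_cycles=2)


@pytest.fixture(scope="session")
def small_study(mini_schedule):
    """Six plates (two per activity state), six strong-phenotype combos."""
    combos = tuple(
        ComboSpec(
            chemical=f"chem{i}",
            concentration=10.0,
            phenotype=PhenotypeSpec(activity_scale=2.5 if i % 2 else 0.2),
            n_replicates=7,
        )
        for i in range(6)
    )
    config = StudyConfig(
        n_plates=6,
        wells_per_plate=18,
        controls_per_plate=8,
        combos=combos,
        plate_states=(
            ActivityState.HYPOACTIVE,
            ActivityState.NORMAL,
            ActivityState.HYPERACTIVE,
        )
        * 2,
        schedule=mini_schedule,
        frame_rate=10.0,
        seed=42,
    )
    return simulate_study(config)


def make_track(
    dist,
    subject_id="s1",
    plate_id="P1",
    well="A1",
    frame_rate=10.0,
    x=None,
    y=None,
    t=None,
    treatment=None,
) -> LarvaTrack:
    """Hand-build a track from a per-frame distance series."""
    dist = np.asarray(dist, dtype=float)
    n = len(dist)
    frames = pd.DataFrame(
        {
            "t": np.arange(n) / frame_rate if t is None else np.asarray(t, float),
            "x": np.zeros(n) if x is None else np.asarray(x, float),
            "y": np.zeros(n) if y is None else np.asarray(y, float),
            "dist": dist,
            "vel": dist * frame_rate,
        },
        columns=FRAME_COLUMNS,
    )
    return LarvaTrack(
        subject_id=subject_id,
        plate_id=plate_id,
        well=well,
        treatment=treatment or Treatment(),
        frames=frames,
        frame_rate=frame_rate,
    )


@pytest.fixture(scope="session")
def default_params() -> BehaviorParams:
    return BehaviorParams()
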