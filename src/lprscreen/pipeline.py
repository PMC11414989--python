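"""End-to-end orchestration: raw tracks -> trained bank -> chemical calls.

This is the glue the command-line interface and the acceptance checks run:
preprocess every track, stratify the control plates, run the K-S screen,
label abnormal larvae, train the six-model bank, classify every larva with
the model of its plate's stratum, and roll classifications up to
chemical-concentration calls with per-stratum performance metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import evaluation, preprocess, stats
from .autoencoder import AEConfig, ModelBank, TensorRecord, train_bank
from .preprocess import WellGeometry
from .stats import AbnormalLabelSet, ActivityState
from .track_data import AssaySchedule, LarvaTrack, Phase, Treatment

__all__ = ["PipelineResult", "prepare_records", "run_pipeline", "classify_records"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    stratification: dict[str, dict[Phase, ActivityState]]
    screen: pd.DataFrame
    labels: AbnormalLabelSet
    bank: ModelBank
    larva_calls: pd.DataFrame
    chemical_calls: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def prepare_records(
    tracks: list[LarvaTrack],
    treatments: dict[str, Treatment],
    *,
    geometry: WellGeometry | None = None,
    schedule: AssaySchedule | None = None,
    cycle: int = 2,
    cap: float | None = None,
    downsample: int = 1,
) -> tuple[list[LarvaTrack], list[TensorRecord]]:
    """Preprocess tracks and cut the cycle's light and dark phase tensors.

    Returns (preprocessed tracks, one TensorRecord per track per phase).
    """
    schedule = schedule or AssaySchedule()
    geometry = geometry or WellGeometry()
    pre = [
        preprocess.preprocess_track(t, geometry, schedule, cap=cap) for t in tracks
    ]
    records: list[TensorRecord] = []
    for t in pre:
        for phase in Phase:
            tensor = preprocess.extract_phase(t, cycle, phase, schedule)
            if downsample > 1:
                tensor = preprocess.downsample_tensor(tensor, downsample)
            records.append(
                TensorRecord(
                    subject_id=t.subject_id,
                    plate_id=t.plate_id,
                    phase=phase,
                    tensor=tensor,
                    is_control=treatments[t.subject_id].is_control,
                )
            )
    return pre, records


def classify_records(
    bank: ModelBank,
    records: list[TensorRecord],
    treatments: dict[str, Treatment],
    *,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify every record its stratum has a model for.

    A larva with tensors in both phases is called abnormal if either
    phase's model flags it.  Returns one row per larva: subject, plate,
    chemical, concentration, p_light, p_dark, abnormal.
    """
    per_subject: dict[str, dict] = {}
    for r in records:
        state = bank.stratification.get(r.plate_id, {}).get(r.phase)
        if state is None or (state, r.phase) not in bank.entries:
            continue
        p, label = bank.classify_record(r, threshold)
        trt = treatments[r.subject_id]
        row = per_subject.setdefault(
            r.subject_id,
            {
                "subject": r.subject_id,
                "plate": r.plate_id,
                "chemical": trt.chemical,
                "concentration": trt.concentration,
                "p_light": float("nan"),
                "p_dark": float("nan"),
                "abnormal": False,
            },
        )
        row[f"p_{r.phase.value}"] = p
        row["abnormal"] = bool(row["abnormal"] or label)
    return pd.DataFrame(per_subject.values())


def run_pipeline(
    tracks: list[LarvaTrack],
    treatments: dict[str, Treatment],
    config: AEConfig,
    *,
    geometry: WellGeometry | None = None,
    schedule: AssaySchedule | None = None,
    cycle: int = 2,
    downsample: int = 1,
    screen_alpha: float = 0.05,
    stratify_alpha: float = 0.01,
    min_controls: int = 10,
    head_folds: int = 100,
    threshold: float = 0.5,
) -> PipelineResult:
    """Run the full screening pipeline on (morphology-filtered) tracks."""
    schedule = schedule or AssaySchedule()
    pre, records = prepare_records(
        tracks, treatments, geometry=geometry, schedule=schedule,
        cycle=cycle, downsample=downsample,
    )
    controls = [t for t in pre if treatments[t.subject_id].is_control]
    stratification = stats.stratify_control_plates(
        controls, alpha=stratify_alpha, cycle=cycle, schedule=schedule
    )
    screen = stats.screen_combinations(
        pre, treatments, alpha=screen_alpha, cycle=cycle, schedule=schedule
    )
    labels = stats.label_abnormal_larvae(
        screen, pre, treatments, cycle=cycle, schedule=schedule
    )
    bank = train_bank(
        records, stratification, labels.subjects, config,
        min_controls=min_controls, head_folds=head_folds,
    )
    larva_calls = classify_records(bank, records, treatments, threshold=threshold)
    chemical_calls = (
        evaluation.call_chemicals(larva_calls) if not larva_calls.empty else pd.DataFrame()
    )

    metrics: dict = {}
    if not larva_calls.empty:
        treated = larva_calls[larva_calls["concentration"] > 0]
        if len(treated) and treated["abnormal"].any():
            actual = treated["subject"].isin(labels.subjects).to_numpy()
            if actual.any() and not actual.all():
                scores = treated[["p_light", "p_dark"]].max(axis=1).to_numpy()
                cm = evaluation.confusion_from_labels(
                    treated["abnormal"].to_numpy(), actual
                )
                metrics["overall"] = evaluation.metric_report(cm, scores, actual)
    return PipelineResult(
        stratification=stratification,
        screen=screen,
        labels=labels,
        bank=bank,
        larva_calls=larva_calls,
        chemical_calls=chemical_calls,
        metrics=metrics,
    )
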