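"""Classifier diagnostics, chemical-level calls, and variability measures.

Per-larva classifications roll up to chemical-concentration calls: a combo
is flagged abnormal when the exposed group's abnormal fraction exceeds its
matched controls' and at least 25% of exposed individuals are abnormal.
Classifier quality is reported as sensitivity / specificity / positive
predictive value plus the chance-corrected Cohen's kappa and AUROC;
permutation feature importance and coefficients of variation explain which
of the five tensor features carry the signal; replicate experiments are
compared through quartic dose-response fits and an extra-sum-of-squares
F test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .track_data import FRAME_COLUMNS

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ChemicalCall",
    "ImportanceReport",
    "confusion_from_labels",
    "cohens_kappa",
    "auroc",
    "metric_report",
    "call_chemicals",
    "permutation_importance",
    "coefficient_of_variation",
    "compare_replicates",
]

log = logging.getLogger(__name__)

CALL_MIN_FRACTION = 0.25  # a combo is called only if >= 25% of exposed are abnormal


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a binary classifier (positive class = abnormal)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_labels(predicted, actual) -> ConfusionMatrix:
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        tn=int(np.sum(~p & ~a)),
        fn=int(np.sum(~p & a)),
    )


@dataclass(frozen=True)
class MetricReport:
    """SE/SP/PPV in percent; kappa in [-1, 1]; AUROC in [0, 1].

    Ratios with a zero denominator are reported as NaN (missing), never 0.
    """

    SE: float
    SP: float
    PPV: float
    kappa: float
    auroc: float


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement, p_e the agreement expected from the
    marginals alone.  Equals 1 for perfect agreement even when p_e = 1.
    """
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def auroc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney concordance P(score_pos > score_neg) +
    0.5 * P(tie) over all positive/negative pairs.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels.astype(int), np.asarray(scores, dtype=float)))


def _ratio(num: int, den: int) -> float:
    if den == 0:
        log.warning("undefined ratio (zero denominator); reported as NaN")
        return float("nan")
    return 100.0 * num / den


def metric_report(cm: ConfusionMatrix, scores=None, labels=None) -> MetricReport:
    """Assemble SE, SP, PPV, kappa and (when scores are given) AUROC."""
    auc = float("nan")
    if scores is not None and labels is not None:
        auc = auroc(scores, labels)
    return MetricReport(
        SE=_ratio(cm.tp, cm.tp + cm.fn),
        SP=_ratio(cm.tn, cm.tn + cm.fp),
        PPV=_ratio(cm.tp, cm.tp + cm.fp),
        kappa=cohens_kappa(cm),
        auroc=auc,
    )


@dataclass(frozen=True)
class ChemicalCall:
    """Per chemical-concentration abnormality decision with its counts."""

    chemical: str
    concentration: float
    n_exposed: int
    n_abnormal_exposed: int
    control_abnormal_fraction: float
    exposed_abnormal_fraction: float
    flagged: bool


def call_chemicals(larva_calls: pd.DataFrame, *, min_fraction: float = CALL_MIN_FRACTION) -> pd.DataFrame:
    """Roll per-larva abnormality labels up to chemical-concentration calls.

    ``larva_calls`` needs columns subject, plate, chemical, concentration,
    abnormal (bool); controls are rows with concentration 0.  A combo is
    flagged when its exposed abnormal fraction strictly exceeds its matched
    (same-plate) controls' fraction AND is at least ``min_fraction``.
    Combos without matched controls are skipped with a warning.
    """
    df = larva_calls
    controls = df[df["concentration"] == 0]
    treated = df[df["concentration"] > 0]
    rows = []
    for (chem, conc), grp in sorted(treated.groupby(["chemical", "concentration"])):
        plates = sorted(grp["plate"].unique())
        ctrl = controls[controls["plate"].isin(plates)]
        if ctrl.empty:
            log.warning("combo (%s, %g μM) has no matched controls; skipped", chem, conc)
            continue
        n_exp = len(grp)
        n_abn = int(grp["abnormal"].sum())
        f_exp = n_abn / n_exp
        f_ctrl = float(ctrl["abnormal"].mean())
        rows.append(
            ChemicalCall(
                chemical=chem,
                concentration=float(conc),
                n_exposed=n_exp,
                n_abnormal_exposed=n_abn,
                control_abnormal_fraction=f_ctrl,
                exposed_abnormal_fraction=f_exp,
                flagged=(f_exp > f_ctrl) and (f_exp >= min_fraction),
            ).__dict__
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chemical", "concentration", "n_exposed", "n_abnormal_exposed",
            "control_abnormal_fraction", "exposed_abnormal_fraction", "flagged",
        ],
    )


@dataclass(frozen=True)
class ImportanceReport:
    """Mean ± SEM performance drop per permuted feature."""

    features: tuple[str, ...]
    baseline_kappa: float
    baseline_auroc: float
    delta_kappa_mean: np.ndarray
    delta_kappa_sem: np.ndarray
    delta_auroc_mean: np.ndarray
    delta_auroc_sem: np.ndarray
    n_shuffles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "delta_kappa_mean": self.delta_kappa_mean,
                "delta_kappa_sem": self.delta_kappa_sem,
                "delta_auroc_mean": self.delta_auroc_mean,
                "delta_auroc_sem": self.delta_auroc_sem,
            }
        )


def permutation_importance(
    score_fn,
    tensors: np.ndarray,
    labels,
    *,
    n_shuffles: int = 1000,
    seed: int = 0,
    within_subject: bool = False,
    threshold: float = 0.5,
    features: tuple[str, ...] | None = None,
) -> ImportanceReport:
    """Permutation feature importance against a fitted scoring function.

    ``score_fn`` maps a (n_subjects, n_frames, n_features) array to
    per-subject abnormality scores in [0, 1]; ``labels`` are the reference
    abnormal flags.  One feature column at a time is shuffled (jointly
    across frames and subjects by default; per subject when
    ``within_subject``), the set is re-scored, and the drop in kappa and
    AUROC relative to the unpermuted baseline is averaged over
    ``n_shuffles`` with its standard error.  Positive deltas mean the
    feature mattered.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 (SEM undefined otherwise)")
    X = np.asarray(tensors, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"tensors must be (subjects, frames, features), got {X.shape}")
    y = np.asarray(labels, dtype=bool)
    n, f_count = X.shape[0], X.shape[2]
    features = features or tuple(FRAME_COLUMNS[:f_count])
    rng = np.random.default_rng(seed)

    def _metrics(scores: np.ndarray) -> tuple[float, float]:
        cm = confusion_from_labels(scores >= threshold, y)
        return cohens_kappa(cm), auroc(scores, y)

    base_kappa, base_auroc = _metrics(np.asarray(score_fn(X), dtype=float))
    dk = np.empty((f_count, n_shuffles))
    da = np.empty((f_count, n_shuffles))
    for j in range(f_count):
        for s in range(n_shuffles):
            Xp = X.copy()
            if within_subject:
                for i in range(n):
                    Xp[i, :, j] = Xp[i, rng.permutation(X.shape[1]), j]
            else:
                flat = Xp[:, :, j].reshape(-1)
                Xp[:, :, j] = rng.permutation(flat).reshape(n, -1)
            k, a = _metrics(np.asarray(score_fn(Xp), dtype=float))
            dk[j, s] = base_kappa - k
            da[j, s] = base_auroc - a
    sem = lambda m: m.std(axis=1, ddof=1) / np.sqrt(n_shuffles)
    return ImportanceReport(
        features=features,
        baseline_kappa=base_kappa,
        baseline_auroc=base_auroc,
        delta_kappa_mean=dk.mean(axis=1),
        delta_kappa_sem=sem(dk),
        delta_auroc_mean=da.mean(axis=1),
        delta_auroc_sem=sem(da),
        n_shuffles=n_shuffles,
    )


def coefficient_of_variation(values) -> float:
    """Population standard deviation divided by the mean (NaN if mean is 0)."""
    values = np.asarray(values, dtype=float)
    if values.mean() == 0:
        log.warning("coefficient of variation undefined for zero-mean series")
        return float("nan")
    return float(sps.variation(values, ddof=0))


def _quartic_rss(x: np.ndarray, y: np.ndarray) -> float:
    # standardize x for conditioning; RSS is invariant to the affine reparam
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    V = np.vander(xs, 5)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ coef
    return float(resid @ resid)


def compare_replicates(curve_a, curve_b, *, alpha: float = 0.05) -> tuple[float, bool]:
    """Are two dose-response curves replicates of the same relationship?

    Each curve is a sequence of (concentration, abnormal fraction) points
    (at least 6 distinct concentrations each, as a quartic has 5
    coefficients).  A shared quartic fit to the pooled points is compared
    to separate per-curve quartics with the extra-sum-of-squares F test;
    the curves are "the same" when p >= alpha.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    for name, c in (("curve_a", a), ("curve_b", b)):
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"{name} must be (n, 2) points")
        if len(np.unique(c[:, 0])) < 6:
            raise ValueError(f"{name} needs >= 6 distinct concentrations")
    pooled = np.vstack([a, b])
    n_total = len(pooled)
    k = 5  # quartic coefficients
    df_sep = n_total - 2 * k
    if df_sep <= 0:
        raise ValueError("not enough points for separate quartic fits")
    rss_shared = _quartic_rss(pooled[:, 0], pooled[:, 1])
    rss_sep = _quartic_rss(a[:, 0], a[:, 1]) + _quartic_rss(b[:, 0], b[:, 1])
    if rss_sep <= 0:
        # separate fits are exact; any shared-fit excess is decisive
        p = 1.0 if rss_shared <= 1e-12 else 0.0
    else:
        F = ((rss_shared - rss_sep) / k) / (rss_sep / df_sep)
        p = float(sps.f.sf(max(F, 0.0), k, df_sep))
    return p, p >= alpha
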