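"""Stratified deep autoencoders with logistic-regression heads.

The anomaly-detection model is a fully connected autoencoder trained on
*control* larvae only, so the bottleneck learns a compressed representation
of quintessential normal behavior.  A logistic-regression head on the
bottleneck then separates normal from abnormal encodings, where "abnormal"
is the K-S-labeled set produced by :mod:`lprscreen.stats`.  Because control
behavior differs systematically between plates, one (autoencoder, head)
pair is trained per (activity state, phase) stratum — six models in a
complete bank.

The network is implemented directly in numpy: tanh hidden layers with
normal kernel initialization, inverted dropout, L1+L2 weight penalties,
full-batch backpropagation under mean-squared-error loss, and an adadelta
optimizer (accumulated squared gradients and updates with decay rho).
Training is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .preprocess import FeatureScaler, PhaseTensor, apply_scaler, fit_scaler
from .stats import ActivityState
from .track_data import Phase

__all__ = [
    "AEConfig",
    "Autoencoder",
    "ClassifierHead",
    "TensorRecord",
    "BankEntry",
    "ModelBank",
    "build_autoencoder",
    "train_autoencoder",
    "encode",
    "reconstruction_error",
    "train_head",
    "classify",
    "train_bank",
    "save_bank",
    "load_bank",
]

log = logging.getLogger(__name__)

#: encoder/decoder widths used at full scale (bottleneck 250 on 22500 inputs)
FULL_ENCODER = [7500, 3000, 1500, 1000, 750, 500, 375, 250]
FULL_DECODER = [375, 500, 750, 1500, 3000, 7500]


@dataclass(frozen=True)
class AEConfig:
    """Architecture and optimization settings for one autoencoder.

    Defaults mirror the full-scale model: a 22500-long input (4500 frames x
    5 features), eight encoder layers narrowing to a 250-unit bottleneck,
    six mirrored decoder layers, tanh activations, dropout 0.2, L1 = L2 =
    1e-5, adadelta (learning_rate 0.001, rho 0.95, epsilon 1e-7) under MSE
    loss.  ``epochs`` is deliberately configurable: full-scale training runs
    to 1e5+ epochs; desk-scale configurations use far fewer with a larger
    adadelta learning rate.
    """

    input_dim: int = 22500
    encoder_layers: tuple[int, ...] = tuple(FULL_ENCODER)
    decoder_layers: tuple[int, ...] = tuple(FULL_DECODER)
    activation: str = "tanh"
    dropout: float = 0.2
    l1: float = 1e-5
    l2: float = 1e-5
    learning_rate: float = 0.001
    rho: float = 0.95
    epsilon: float = 1e-7
    epochs: int = 500
    init_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        enc = tuple(self.encoder_layers)
        if len(enc) == 0 or any(e <= 0 for e in enc):
            raise ValueError("encoder_layers must be non-empty and positive")
        if len(enc) > 1 and not all(b < a for a, b in zip(enc[:-1], enc[1:])):
            raise ValueError(f"encoder_layers must be strictly decreasing: {enc}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        object.__setattr__(self, "encoder_layers", enc)
        object.__setattr__(self, "decoder_layers", tuple(self.decoder_layers))

    @property
    def bottleneck(self) -> int:
        return self.encoder_layers[-1]

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.encoder_layers, *self.decoder_layers, self.input_dim]


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else z


def _act_grad(h: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - h * h if kind == "tanh" else np.ones_like(h)


class Autoencoder:
    """A fully connected autoencoder; see module docstring for the design."""

    def __init__(self, config: AEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = config.layer_dims
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(0.0, config.init_std, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self.loss_history: list[float] = []
        self.val_loss_history: list[float] = []
        self.stratum: tuple[ActivityState, Phase] | None = None
        self._rng = rng

    # ---- shapes ----------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_encoder_layers(self) -> int:
        return len(self.config.encoder_layers)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    # ---- forward passes --------------------------------------------------
    def _forward(self, X: np.ndarray, *, train: bool = False):
        """One pass through all layers. Output layer is linear.

        Returns (acts, raw, masks): ``acts[i]`` is the input actually fed to
        layer i (post-dropout), ``acts[-1]`` the reconstruction; ``raw[i]``
        is layer i's pre-dropout activation (needed for the tanh gradient);
        ``masks[i]`` the inverted-dropout mask or None.
        """
        cfg = self.config
        acts: list[np.ndarray] = [X]
        raw: list[np.ndarray | None] = []
        masks: list[np.ndarray | None] = []
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < self.n_layers - 1:
                a = _act(z, cfg.activation)
                raw.append(a)
                if train and cfg.dropout > 0:
                    mask = (
                        self._rng.random(a.shape) >= cfg.dropout
                    ).astype(a.dtype) / (1.0 - cfg.dropout)
                    h = a * mask
                    masks.append(mask)
                else:
                    h = a
                    masks.append(None)
            else:
                h = z
                raw.append(None)
                masks.append(None)
            acts.append(h)
        return acts, raw, masks

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Dropout-free reconstruction of a (batch, input_dim) array."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_dim(X)
        acts, _, _ = self._forward(X, train=False)
        return acts[-1]

    def encode_array(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck representation of a (batch, input_dim) array."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_dim(X)
        h = X
        for i in range(self.n_encoder_layers):
            h = _act(h @ self.weights[i] + self.biases[i], self.config.activation)
        return h

    def _check_dim(self, X: np.ndarray) -> None:
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has {X.shape[1]} features; model expects {self.config.input_dim}"
            )

    def mse(self, X: np.ndarray) -> float:
        R = self.reconstruct(X)
        return float(np.mean((R - np.atleast_2d(X)) ** 2))

    # ---- training --------------------------------------------------------
    def fit(self, X: np.ndarray, X_val: np.ndarray | None = None) -> "Autoencoder":
        """Full-batch adadelta training under MSE + L1/L2 weight penalties.

        ``loss_history`` records the dropout-free training MSE each epoch
        (and ``val_loss_history`` the validation MSE when given).
        """
        cfg = self.config
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_dim(X)
        n, d = X.shape
        acc_g_w = [np.zeros_like(w) for w in self.weights]
        acc_d_w = [np.zeros_like(w) for w in self.weights]
        acc_g_b = [np.zeros_like(b) for b in self.biases]
        acc_d_b = [np.zeros_like(b) for b in self.biases]
        eps, rho, lr = cfg.epsilon, cfg.rho, cfg.learning_rate

        for epoch in range(cfg.epochs):
            self.loss_history.append(self.mse(X))
            if X_val is not None:
                self.val_loss_history.append(self.mse(X_val))
            acts, raw, masks = self._forward(X, train=True)
            out = acts[-1]
            delta = 2.0 * (out - X) / (n * d)  # dL/dz of the linear output layer
            if not np.isfinite(out).all():
                raise FloatingPointError(f"non-finite reconstruction at epoch {epoch}")
            for i in range(self.n_layers - 1, -1, -1):
                gW = acts[i].T @ delta
                gW += cfg.l1 * np.sign(self.weights[i]) + 2.0 * cfg.l2 * self.weights[i]
                gb = delta.sum(axis=0)
                if i > 0:
                    back = delta @ self.weights[i].T  # dL/d(post-dropout act of i-1)
                    if masks[i - 1] is not None:
                        back = back * masks[i - 1]
                    delta = back * _act_grad(raw[i - 1], cfg.activation)
                # adadelta update
                for g, p, acc_g, acc_d in (
                    (gW, self.weights[i], acc_g_w[i], acc_d_w[i]),
                    (gb, self.biases[i], acc_g_b[i], acc_d_b[i]),
                ):
                    acc_g *= rho
                    acc_g += (1 - rho) * g * g
                    step = g * np.sqrt(acc_d + eps) / np.sqrt(acc_g + eps)
                    acc_d *= rho
                    acc_d += (1 - rho) * step * step
                    p -= lr * step
        return self


def build_autoencoder(config: AEConfig) -> Autoencoder:
    """Construct an untrained autoencoder with seeded normal initialization."""
    return Autoencoder(config)


def _stack(tensors) -> np.ndarray:
    rows = []
    for t in tensors:
        rows.append(t.flatten() if isinstance(t, PhaseTensor) else np.ravel(t))
    return np.vstack(rows)


def train_autoencoder(
    tensors,
    config: AEConfig,
    *,
    validation=None,
    stratum: tuple[ActivityState, Phase] | None = None,
) -> Autoencoder:
    """Train one autoencoder on (scaled) control tensors.

    Tensors must all come from one phase; mixing phases across one model is
    an error because the model is stratum-specific.
    """
    tensors = list(tensors)
    if not tensors:
        raise ValueError("no training tensors")
    phases = {t.phase for t in tensors if isinstance(t, PhaseTensor)}
    if len(phases) > 1:
        raise ValueError(f"training tensors span multiple phases: {sorted(p.value for p in phases)}")
    X = _stack(tensors)
    cfg = config if config.input_dim == X.shape[1] else replace(config, input_dim=X.shape[1])
    model = Autoencoder(cfg)
    model.stratum = stratum
    X_val = _stack(validation) if validation is not None else None
    model.fit(X, X_val)
    if not model.loss_history or not np.isfinite(model.loss_history[-1]):
        raise FloatingPointError("training produced a non-finite loss")
    return model


def encode(model: Autoencoder, tensor) -> np.ndarray:
    """Bottleneck vector (length = config.bottleneck) for one tensor."""
    x = tensor.flatten() if isinstance(tensor, PhaseTensor) else np.ravel(tensor)
    return model.encode_array(x[None, :])[0]


def reconstruction_error(model: Autoencoder, tensor) -> float:
    """Dropout-free MSE between a tensor and its reconstruction."""
    x = tensor.flatten() if isinstance(tensor, PhaseTensor) else np.ravel(tensor)
    return model.mse(x[None, :])


@dataclass
class ClassifierHead:
    """Cross-validated logistic-regression head on bottleneck encodings."""

    estimator: LogisticRegression
    cv_scores: np.ndarray
    folds: int
    max_iter: int

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimator.coef_[0]

    @property
    def intercept(self) -> float:
        return float(self.estimator.intercept_[0])


def train_head(
    encoded_normals: np.ndarray,
    encoded_abnormals: np.ndarray,
    *,
    folds: int = 100,
    max_iter: int = 4000,
    seed: int = 0,
) -> ClassifierHead:
    """Train the logistic head: normal encodings vs abnormal encodings.

    Stratified k-fold cross-validated accuracy is recorded; the fold count
    is capped at the minority class size (with a warning) so every fold
    holds both classes.  The solver is LBFGS with an iteration cap.
    """
    Xn = np.atleast_2d(np.asarray(encoded_normals, dtype=float))
    Xa = np.atleast_2d(np.asarray(encoded_abnormals, dtype=float))
    if Xn.shape[0] == 0 or Xa.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([Xn, Xa])
    y = np.concatenate([np.zeros(len(Xn), dtype=int), np.ones(len(Xa), dtype=int)])
    min_class = min(len(Xn), len(Xa))
    folds_used = min(folds, min_class)
    if folds_used < folds:
        log.warning(
            "reducing CV folds from %d to %d (minority class has %d samples)",
            folds, folds_used, min_class,
        )
    est = LogisticRegression(solver="lbfgs", max_iter=max_iter)
    if folds_used >= 2:
        cv = StratifiedKFold(n_splits=folds_used, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
    else:
        scores = np.array([])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return ClassifierHead(estimator=est, cv_scores=scores, folds=folds_used, max_iter=max_iter)


def classify(
    model: Autoencoder,
    head: ClassifierHead,
    tensor,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """(p_abnormal, label) for one scaled tensor; abnormal iff p >= threshold."""
    z = encode(model, tensor)
    p = float(head.estimator.predict_proba(z[None, :])[0, 1])
    return p, p >= threshold


# ---------------------------------------------------------------------------
# model bank


@dataclass(frozen=True)
class TensorRecord:
    """One larva's phase tensor with the metadata the bank needs."""

    subject_id: str
    plate_id: str
    phase: Phase
    tensor: PhaseTensor
    is_control: bool


@dataclass
class BankEntry:
    model: Autoencoder
    head: ClassifierHead
    scaler: FeatureScaler
    n_controls: int
    n_abnormals: int


@dataclass
class ModelBank:
    """Six (autoencoder, head) pairs indexed by (ActivityState, Phase)."""

    entries: dict[tuple[ActivityState, Phase], BankEntry]
    stratification: dict[str, dict[Phase, ActivityState]]
    config: AEConfig
    missing: list[tuple[ActivityState, Phase]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def complete(self) -> bool:
        return len(self.entries) == 6

    def entry_for(self, plate_id: str, phase: Phase) -> BankEntry:
        state = self.stratification[plate_id][phase]
        key = (state, phase)
        if key not in self.entries:
            raise KeyError(f"no trained model for stratum {key}")
        return self.entries[key]

    def classify_record(self, record: TensorRecord, threshold: float = 0.5):
        """(p_abnormal, label) for one unscaled tensor record."""
        entry = self.entry_for(record.plate_id, record.phase)
        scaled = apply_scaler(entry.scaler, record.tensor)
        return classify(entry.model, entry.head, scaled, threshold)


def train_bank(
    records,
    stratification: dict[str, dict[Phase, ActivityState]],
    abnormal_ids,
    config: AEConfig,
    *,
    min_controls: int = 10,
    head_folds: int = 100,
    head_max_iter: int = 4000,
) -> ModelBank:
    """Train one (autoencoder, head) pair per populated (state, phase) stratum.

    Each autoencoder sees only its stratum's *control* tensors (z-scaled by
    a scaler fitted on those controls).  Each head sees the stratum's
    encoded controls (label normal) and the stratum's K-S-labeled abnormal
    larvae (label abnormal).  Strata without enough controls or without any
    abnormal larvae are recorded as missing with a warning.
    """
    records = list(records)
    abnormal_ids = set(abnormal_ids)
    entries: dict[tuple[ActivityState, Phase], BankEntry] = {}
    missing: list[tuple[ActivityState, Phase]] = []
    for si, state in enumerate(ActivityState):
        for pi, phase in enumerate(Phase):
            key = (state, phase)
            in_stratum = [
                r for r in records
                if r.phase == phase
                and stratification.get(r.plate_id, {}).get(phase) == state
            ]
            controls = [r for r in in_stratum if r.is_control]
            abnormals = [
                r for r in in_stratum
                if (not r.is_control) and r.subject_id in abnormal_ids
            ]
            if len(controls) < min_controls:
                log.warning(
                    "stratum (%s, %s): %d controls < required %d; skipped",
                    state.value, phase.value, len(controls), min_controls,
                )
                missing.append(key)
                continue
            if not abnormals:
                log.warning(
                    "stratum (%s, %s): no labeled abnormal larvae; skipped",
                    state.value, phase.value,
                )
                missing.append(key)
                continue
            scaler = fit_scaler([r.tensor for r in controls])
            ctrl_scaled = [apply_scaler(scaler, r.tensor) for r in controls]
            abn_scaled = [apply_scaler(scaler, r.tensor) for r in abnormals]
            stratum_seed = config.seed + 97 * si + 11 * pi
            model = train_autoencoder(
                ctrl_scaled,
                replace(config, seed=stratum_seed),
                stratum=key,
            )
            Zn = np.vstack([encode(model, t) for t in ctrl_scaled])
            Za = np.vstack([encode(model, t) for t in abn_scaled])
            head = train_head(
                Zn, Za, folds=head_folds, max_iter=head_max_iter, seed=stratum_seed
            )
            entries[key] = BankEntry(
                model=model,
                head=head,
                scaler=scaler,
                n_controls=len(controls),
                n_abnormals=len(abnormals),
            )
    return ModelBank(
        entries=entries, stratification=stratification, config=config, missing=missing
    )


# ---------------------------------------------------------------------------
# serialization


def save_bank(bank: ModelBank, directory) -> None:
    """Write a bank to ``directory``: one .npz per stratum + manifest.json."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(bank.config),
        "stratification": {
            plate: {ph.value: st.value for ph, st in per.items()}
            for plate, per in bank.stratification.items()
        },
        "strata": [],
        "missing": [[s.value, p.value] for s, p in bank.missing],
    }
    for (state, phase), entry in bank.entries.items():
        name = f"{state.value}_{phase.value}"
        arrays = {"scaler_mean": entry.scaler.mean, "scaler_scale": entry.scaler.scale,
                  "head_coef": entry.head.estimator.coef_,
                  "head_intercept": entry.head.estimator.intercept_,
                  "head_cv_scores": entry.head.cv_scores,
                  "loss_history": np.array(entry.model.loss_history)}
        for i, (w, b) in enumerate(zip(entry.model.weights, entry.model.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez_compressed(d / f"{name}.npz", **arrays)
        manifest["strata"].append(
            {
                "state": state.value,
                "phase": phase.value,
                "file": f"{name}.npz",
                "n_controls": entry.n_controls,
                "n_abnormals": entry.n_abnormals,
                "input_dim": entry.model.config.input_dim,
                "head_folds": entry.head.folds,
                "head_max_iter": entry.head.max_iter,
            }
        )
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bank(directory) -> ModelBank:
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["encoder_layers"] = tuple(cfg_dict["encoder_layers"])
    cfg_dict["decoder_layers"] = tuple(cfg_dict["decoder_layers"])
    config = AEConfig(**cfg_dict)
    stratification = {
        plate: {Phase(ph): ActivityState(st) for ph, st in per.items()}
        for plate, per in manifest["stratification"].items()
    }
    entries = {}
    for meta in manifest["strata"]:
        with np.load(d / meta["file"]) as z:
            cfg = replace(config, input_dim=int(meta["input_dim"]))
            model = Autoencoder(cfg)
            for i in range(model.n_layers):
                model.weights[i] = z[f"W{i}"]
                model.biases[i] = z[f"b{i}"]
            model.loss_history = list(z["loss_history"])
            scaler = FeatureScaler(mean=z["scaler_mean"], scale=z["scaler_scale"])
            est = LogisticRegression(solver="lbfgs", max_iter=meta["head_max_iter"])
            est.coef_ = z["head_coef"]
            est.intercept_ = z["head_intercept"]
            est.classes_ = np.array([0, 1])
            head = ClassifierHead(
                estimator=est,
                cv_scores=z["head_cv_scores"],
                folds=meta["head_folds"],
                max_iter=meta["head_max_iter"],
            )
        key = (ActivityState(meta["state"]), Phase(meta["phase"]))
        model.stratum = key
        entries[key] = BankEntry(
            model=model,
            head=head,
            scaler=scaler,
            n_controls=meta["n_controls"],
            n_abnormals=meta["n_abnormals"],
        )
    missing = [(ActivityState(s), Phase(p)) for s, p in manifest["missing"]]
    return ModelBank(
        entries=entries, stratification=stratification, config=config, missing=missing
    )
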