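"""The five frame-level classifiers and their training recipe.

DNN: three 200-unit relu layers + softmax head, applied frame-wise.
LSTM / GRU: two 50-cell recurrent layers with dropout 0.2 + linear/softmax
head over the whole sequence.  BiLSTM: two stacked bidirectional blocks,
each a forward and a backward 50-cell LSTM whose outputs are *summed*
(hidden width stays 50), + linear/softmax head.  RF: a 26-tree bootstrap
ensemble over single frames.

Neural members train by minimizing frame-level cross-entropy (every frame
inherits its utterance's diagnosis) with Adam; default learning rates are
0.001 for DNN/GRU and 0.0005 for LSTM/BiLSTM.  All training is
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from voicedx.nnet import (
    Adam, BiSumLayer, Dense, Dropout, GRULayer, LSTMLayer, Relu,
    masked_cross_entropy, softmax,
)

__all__ = [
    "ModelConfig", "TrainConfig", "UtteranceFeatures", "TrainResult",
    "UnsupportedModelError", "build_model", "train_model", "forward_frames",
    "extract_hidden_features", "n_parameters", "crossval_uar",
    "save_model", "load_model",
]

MODEL_KINDS = ("dnn", "lstm", "bilstm", "gru", "rf")
_DEFAULT_LR = {"dnn": 1e-3, "gru": 1e-3, "lstm": 5e-4, "bilstm": 5e-4}


class UnsupportedModelError(TypeError):
    """Raised when an operation does not apply to the model kind."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one classifier."""

    kind: str = "bilstm"
    n_classes: int = 4
    layer_sizes: tuple[int, ...] = (200, 200, 200)   # dnn
    n_layers: int = 2                                # recurrent depth
    cells: int = 50                                  # recurrent width
    dropout: float = 0.2
    n_trees: int = 26                                # rf

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2 or self.cells <= 0 or self.n_trees <= 0 \
                or self.n_layers <= 0 or any(s <= 0 for s in self.layer_sizes):
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe; ``learning_rate=None`` selects the per-kind
    default (0.001 dnn/gru, 0.0005 lstm/bilstm)."""

    learning_rate: Optional[float] = None
    epochs: int = 30
    batch_size: int = 16          # utterances per batch
    seed: int = 0
    folds: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def lr_for(self, kind: str) -> float:
        return self.learning_rate if self.learning_rate is not None \
            else _DEFAULT_LR[kind]


@dataclass
class UtteranceFeatures:
    """One training example: an MFCC sequence with its diagnosis."""

    mfcc: np.ndarray              # (T, 26)
    label: int
    speaker: Optional[str] = None


@dataclass
class TrainResult:
    model: "object"
    epoch_losses: list[float]
    fold_uars: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class _NeuralModel:
    """Common scaffolding: feature standardization + parameter plumbing."""

    def __init__(self, cfg: ModelConfig, input_dim: int):
        self.cfg = cfg
        self.input_dim = input_dim
        self.feat_mean = np.zeros(input_dim, dtype=np.float32)
        self.feat_std = np.ones(input_dim, dtype=np.float32)

    def set_scaler(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.feat_mean = mean.astype(np.float32)
        self.feat_std = np.maximum(std, 1e-6).astype(np.float32)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.feat_mean) / self.feat_std).astype(np.float32)

    def parameters(self):
        raise NotImplementedError


class DnnModel(_NeuralModel):
    def __init__(self, cfg: ModelConfig, input_dim: int, rng: np.random.Generator):
        super().__init__(cfg, input_dim)
        self.hidden = []
        d = input_dim
        for size in cfg.layer_sizes:
            self.hidden.append(Dense(d, size, rng))
            self.hidden.append(Relu())
            d = size
        self.head = Dense(d, cfg.n_classes, rng)

    def parameters(self):
        out = []
        for layer in self.hidden:
            out += layer.params()
        return out + self.head.params()

    def forward_seq(self, x, lengths, training=False, rng=None):
        h = self._scale(x)
        for layer in self.hidden:
            h = layer.forward(h)
        self._last_hidden = h
        return self.head.forward(h)

    def backward_seq(self, dlogits):
        d = self.head.backward(dlogits)
        for layer in reversed(self.hidden):
            d = layer.backward(d)


class RecurrentModel(_NeuralModel):
    def __init__(self, cfg: ModelConfig, input_dim: int, rng: np.random.Generator):
        super().__init__(cfg, input_dim)
        self.blocks = []
        self.dropouts = []
        d = input_dim
        for _ in range(cfg.n_layers):
            if cfg.kind == "bilstm":
                self.blocks.append(BiSumLayer(d, cfg.cells, rng, cell="lstm"))
            elif cfg.kind == "lstm":
                self.blocks.append(LSTMLayer(d, cfg.cells, rng))
            else:
                self.blocks.append(GRULayer(d, cfg.cells, rng))
            self.dropouts.append(Dropout(cfg.dropout))
            d = cfg.cells
        self.head = Dense(d, cfg.n_classes, rng)

    def parameters(self):
        out = []
        for blk in self.blocks:
            out += blk.params()
        return out + self.head.params()

    def hidden_seq(self, x, lengths, training=False, rng=None):
        h = self._scale(x)
        for blk, drop in zip(self.blocks, self.dropouts):
            if isinstance(blk, BiSumLayer):
                h = blk.forward(h, lengths)
            else:
                h = blk.forward(h)
            h = drop.forward(h, training, rng)
        return h

    def forward_seq(self, x, lengths, training=False, rng=None):
        h = self.hidden_seq(x, lengths, training, rng)
        self._last_hidden = h
        return self.head.forward(h)

    def backward_seq(self, dlogits):
        d = self.head.backward(dlogits)
        for blk, drop in zip(reversed(self.blocks), reversed(self.dropouts)):
            d = drop.backward(d)
            d = blk.backward(d)


class RfModel:
    """Frame-wise random forest (bootstrap, Gini, unpruned)."""

    def __init__(self, cfg: ModelConfig, input_dim: int, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier

        self.cfg = cfg
        self.input_dim = input_dim
        self.forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, bootstrap=True, criterion="gini",
            random_state=seed, n_jobs=1)
        self._fitted = False

    def fit(self, frames: np.ndarray, labels: np.ndarray) -> None:
        self.forest.fit(frames, labels)
        self._fitted = True

    def predict_proba_frames(self, frames: np.ndarray) -> np.ndarray:
        raw = self.forest.predict_proba(frames)
        out = np.zeros((frames.shape[0], self.cfg.n_classes))
        for j, cls in enumerate(self.forest.classes_):
            out[:, int(cls)] = raw[:, j]
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig, input_dim: int = 26, seed: int = 0):
    """Construct an untrained classifier of the configured kind."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 913])))
    if cfg.kind == "dnn":
        return DnnModel(cfg, input_dim, rng)
    if cfg.kind in ("lstm", "bilstm", "gru"):
        return RecurrentModel(cfg, input_dim, rng)
    if cfg.kind == "rf":
        return RfModel(cfg, input_dim, seed=seed)
    raise ValueError(f"unknown model kind {cfg.kind!r}")


def n_parameters(model) -> int:
    """Trainable parameter count (neural kinds)."""
    if isinstance(model, RfModel):
        raise UnsupportedModelError("parameter count applies to neural kinds")
    return int(sum(p.value.size for p in model.parameters()))


def _coerce(data) -> list[UtteranceFeatures]:
    out = []
    for item in data:
        if isinstance(item, UtteranceFeatures):
            out.append(item)
        else:
            mfcc, label = item[0], item[1]
            spk = item[2] if len(item) > 2 else None
            out.append(UtteranceFeatures(np.asarray(mfcc), int(label), spk))
    return out


def _pad_batch(batch: list[UtteranceFeatures]):
    lengths = np.array([u.mfcc.shape[0] for u in batch])
    T = int(lengths.max())
    D = batch[0].mfcc.shape[1]
    x = np.zeros((len(batch), T, D), dtype=np.float32)
    for i, u in enumerate(batch):
        x[i, :u.mfcc.shape[0]] = u.mfcc
    labels = np.array([u.label for u in batch])
    mask = np.arange(T)[None, :] < lengths[:, None]
    return x, lengths, labels, mask


def train_model(model, data, tc: TrainConfig,
                cross_validate: bool = False) -> TrainResult:
    """Fit a classifier on labeled MFCC sequences.

    Neural kinds minimize masked frame-level cross-entropy with Adam over
    length-bucketed utterance batches; the RF fits on the stacked frames.
    Feature standardization statistics are computed from the training
    frames and stored on the model.  With ``cross_validate=True`` the
    speaker-disjoint k-fold UARs (``tc.folds`` folds) are computed first
    and returned alongside the final fit.
    """
    data = _coerce(data)
    labels_present = sorted({u.label for u in data})
    if len(labels_present) < 2:
        raise ValueError("training data contains a single class")

    fold_uars = crossval_uar(model.cfg, data, tc) if cross_validate else []

    all_frames = np.vstack([u.mfcc for u in data])
    if isinstance(model, RfModel):
        frame_labels = np.concatenate(
            [np.full(u.mfcc.shape[0], u.label) for u in data])
        model.fit(all_frames, frame_labels)
        return TrainResult(model=model, epoch_losses=[], fold_uars=fold_uars)

    model.set_scaler(all_frames.mean(axis=0), all_frames.std(axis=0))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([tc.seed, 5501])))
    opt = Adam(model.parameters(), lr=tc.lr_for(model.cfg.kind))
    order_by_len = sorted(range(len(data)), key=lambda i: data[i].mfcc.shape[0])
    batches_idx = [order_by_len[i:i + tc.batch_size]
                   for i in range(0, len(data), tc.batch_size)]
    losses = []
    for _ in range(tc.epochs):
        rng.shuffle(batches_idx)
        epoch_loss, n_batches = 0.0, 0
        for idx in batches_idx:
            batch = [data[i] for i in idx]
            x, lengths, labels, mask = _pad_batch(batch)
            logits = model.forward_seq(x, lengths, training=True, rng=rng)
            loss, dlogits = masked_cross_entropy(logits, labels, mask)
            opt.zero_grad()
            model.backward_seq(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return TrainResult(model=model, epoch_losses=losses, fold_uars=fold_uars)


def forward_frames(model, mfcc: np.ndarray) -> np.ndarray:
    """Per-frame class posteriors (frames x K); dropout disabled."""
    mfcc = np.atleast_2d(np.asarray(mfcc))
    if mfcc.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim}-column input, "
                         f"got {mfcc.shape[1]}")
    if isinstance(model, RfModel):
        return model.predict_proba_frames(mfcc)
    x = mfcc[None, :, :].astype(np.float32)
    lengths = np.array([mfcc.shape[0]])
    logits = model.forward_seq(x, lengths, training=False)
    return softmax(np.asarray(logits[0], dtype=np.float64), axis=-1)


def extract_hidden_features(model, mfcc: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Last-hidden-layer activations and their frame mean (recurrent kinds).

    The pooled vector is the utterance-level representation used for PCA
    visualization (width = number of cells, 50 by default).
    """
    if not isinstance(model, RecurrentModel):
        raise UnsupportedModelError(
            "hidden-feature extraction applies to recurrent models")
    mfcc = np.atleast_2d(np.asarray(mfcc))
    x = mfcc[None, :, :].astype(np.float32)
    lengths = np.array([mfcc.shape[0]])
    h = model.hidden_seq(x, lengths, training=False)[0]
    return np.asarray(h, float), np.asarray(h.mean(axis=0), float)


def crossval_uar(cfg: ModelConfig, data, tc: TrainConfig) -> list[float]:
    """Speaker-disjoint k-fold validation UARs for one architecture."""
    from voicedx.inference import compute_metrics, confusion_matrix, majority_vote

    data = _coerce(data)
    groups: dict[str, list[int]] = {}
    for i, u in enumerate(data):
        groups.setdefault(u.speaker if u.speaker is not None else f"u{i}",
                          []).append(i)
    keys = sorted(groups)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([tc.seed, 77])))
    rng.shuffle(keys)
    fold_of = {k: j % tc.folds for j, k in enumerate(keys)}
    uars = []
    for fold in range(tc.folds):
        val_idx = [i for k, idxs in groups.items() if fold_of[k] == fold
                   for i in idxs]
        train_idx = [i for k, idxs in groups.items() if fold_of[k] != fold
                     for i in idxs]
        if not val_idx or not train_idx:
            continue
        m = build_model(cfg, data[0].mfcc.shape[1], seed=tc.seed + fold)
        train_model(m, [data[i] for i in train_idx], tc)
        preds = [majority_vote(forward_frames(m, data[i].mfcc)).label
                 for i in val_idx]
        truths = [data[i].label for i in val_idx]
        present = sorted(set(truths))
        remap = {c: j for j, c in enumerate(present)}
        cm = confusion_matrix([remap.get(p, 0) for p in preds],
                              [remap[t] for t in truths], len(present))
        uars.append(compute_metrics(cm).uar)
    return uars


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(path: str | Path, model) -> None:
    """Serialize a fitted model (single .npz for neural, joblib for RF)."""
    path = Path(path)
    cfg_json = json.dumps(model.cfg.__dict__ | {"input_dim": model.input_dim})
    if isinstance(model, RfModel):
        import joblib

        joblib.dump({"config": cfg_json, "forest": model.forest}, path)
        return
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, config=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             feat_mean=model.feat_mean, feat_std=model.feat_std, **arrays)


def load_model(path: str | Path):
    path = Path(path)
    try:
        data = np.load(path, allow_pickle=False)
    except Exception:
        import joblib

        blob = joblib.load(path)
        cfg_d = json.loads(blob["config"])
        input_dim = cfg_d.pop("input_dim")
        cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
        model = RfModel(ModelConfig(**cfg_d), input_dim)
        model.forest = blob["forest"]
        model._fitted = True
        return model
    cfg_d = json.loads(bytes(data["config"]).decode())
    input_dim = cfg_d.pop("input_dim")
    cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
    model = build_model(ModelConfig(**cfg_d), input_dim)
    for i, p in enumerate(model.parameters()):
        p.value = data[f"p{i}"].astype(np.float32)
    model.set_scaler(data["feat_mean"], data["feat_std"])
    return model
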