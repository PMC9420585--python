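"""Bidirectional-LSTM per-sample phase segmentation.

The model maps a preprocessed, per-record z-scored pulse signal to one
class distribution per sample (background / systole / diastole).  Two
stacked bidirectional LSTM layers form the feature extractor: the first
acts as an encoder producing a hidden feature sequence, the second as a
decoder consuming it; a shared per-timestep affine layer then emits class
logits.  The architecture is length-agnostic — any record length yields
an equally long label sequence.

Training minimizes mean per-sample cross-entropy with Adam (initial
learning rate 0.001) and early-stops on validation loss.  Everything is
seeded: initialization, dropout, and batch order, so a configuration
reproduces bit-identical models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    init_lstm_params,
    lstm_backward,
    lstm_forward,
    softmax,
    softmax_xent,
)
from .sequences import BACKGROUND, LabelSequence, runs_from_classes
from .synthgen import PulseRecord

log = logging.getLogger("pulseseg")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters of the segmenter."""

    hidden_size: int = 64  # units per direction
    num_bilstm_layers: int = 2
    num_classes: int = 3
    dropout: float = 0.2  # between BiLSTM layers, training only
    lr: float = 0.001  # Adam initial learning rate
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 10
    min_run_s: float = 0.05  # post-processing: shorter runs are absorbed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_bilstm_layers < 1 or self.num_classes < 2:
            raise ValueError("invalid architecture sizes")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be positive and batch_size >= 1")


@dataclass
class SegmentationResult:
    """Predicted per-sample classes with probabilities and derived segments."""

    classes: np.ndarray  # (n,) int8
    probs: np.ndarray  # (n, num_classes), rows sum to 1
    segments: list[tuple[int, int, int]] = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [r for r in runs_from_classes(self.classes) if r[2] != BACKGROUND]

    def labels(self, fs: float = 720.0) -> LabelSequence:
        return LabelSequence(self.classes, fs=fs)


def zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


class BiLSTMSegmenter:
    """Stacked-BiLSTM sequence labeler with seeded initialization."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        H, C = cfg.hidden_size, cfg.num_classes
        self.params: dict[str, np.ndarray] = {}
        in_size = 1
        for layer in range(cfg.num_bilstm_layers):
            for direction in ("f", "r"):
                p = init_lstm_params(in_size, H, rng, dtype)
                for name, arr in p.items():
                    self.params[f"l{layer}_{direction}_{name}"] = arr
            in_size = 2 * H
        k = 1.0 / np.sqrt(in_size)
        self.params["out_W"] = rng.uniform(-k, k, (in_size, C)).astype(dtype)
        self.params["out_b"] = np.zeros(C, dtype=dtype)

    # -- forward / backward -------------------------------------------------

    def _layer_params(self, layer: int, direction: str) -> dict[str, np.ndarray]:
        return {
            name: self.params[f"l{layer}_{direction}_{name}"] for name in ("Wx", "Wh", "b")
        }

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """x: (B, T) z-scored input -> logits (T, B, C) and backprop caches."""
        B, T = x.shape
        inp = x.T[:, :, None].astype(self.dtype)  # (T, B, 1)
        caches = []
        for layer in range(self.cfg.num_bilstm_layers):
            hs = []
            layer_caches = []
            for direction, reverse in (("f", False), ("r", True)):
                h, cache = lstm_forward(inp, self._layer_params(layer, direction), reverse)
                hs.append(h)
                layer_caches.append(cache)
            out = np.concatenate(hs, axis=-1)
            mask = None
            if train and self.cfg.dropout > 0 and layer < self.cfg.num_bilstm_layers - 1:
                keep = 1.0 - self.cfg.dropout
                mask = (rng.random(out.shape) < keep).astype(self.dtype) / keep
                out = out * mask
            caches.append((layer_caches, mask))
            inp = out
        logits = inp @ self.params["out_W"] + self.params["out_b"]
        caches.append(inp)  # final features for the output-layer gradient
        return logits, caches

    def backward(self, dlogits: np.ndarray, caches: list) -> dict[str, np.ndarray]:
        H = self.cfg.hidden_size
        feats = caches[-1]
        T, B, _ = dlogits.shape
        grads = {
            "out_W": feats.reshape(T * B, -1).T @ dlogits.reshape(T * B, -1),
            "out_b": dlogits.sum(axis=(0, 1)),
        }
        dout = dlogits @ self.params["out_W"].T
        for layer in range(self.cfg.num_bilstm_layers - 1, -1, -1):
            layer_caches, mask = caches[layer]
            if mask is not None:
                dout = dout * mask
            dinp = None
            for k, (direction, _) in enumerate((("f", False), ("r", True))):
                dh = dout[:, :, k * H : (k + 1) * H]
                dx, g = lstm_backward(dh, self._layer_params(layer, direction), layer_caches[k])
                for name, arr in g.items():
                    grads[f"l{layer}_{direction}_{name}"] = arr
                dinp = dx if dinp is None else dinp + dx
            dout = dinp
        return grads

    # -- inference ----------------------------------------------------------

    def predict(self, record: PulseRecord) -> SegmentationResult:
        """Segment one record into per-sample phase classes.

        The record is expected to be preprocessed; whether it was is
        recorded in the result flags, not enforced.
        """
        if not np.isfinite(record.samples).all():
            raise ValueError("record contains non-finite samples")
        x = zscore(record.samples)[None, :]
        logits, _ = self.forward(x)
        probs = softmax(logits.astype(np.float64))[:, 0, :]  # (T, C)
        raw = np.argmax(probs, axis=-1).astype(np.int8)
        classes = postprocess(raw, record.fs, self.cfg.min_run_s)
        return SegmentationResult(
            classes=classes,
            probs=probs,
            flags={"preprocessed": bool(record.meta.get("preprocessed", False))},
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) plus a JSON sidecar with the config."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"model_config": asdict(self.cfg)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMSegmenter":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        cfg = ModelConfig(**json.loads(sidecar.read_text())["model_config"])
        model = cls(cfg)
        with np.load(path) as data:
            model.params = {k: data[k] for k in data.files}
        return model


def build_model(cfg: ModelConfig) -> BiLSTMSegmenter:
    """Construct a seeded, untrained segmenter."""
    return BiLSTMSegmenter(cfg)


def _as_xy(dataset: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Stack (record, labels) pairs into (N, T) arrays; validate lengths."""
    xs, ys = [], []
    for item in dataset:
        record, labels = item[0], item[-1]
        if len(record) != len(labels):
            raise ValueError(
                f"record {record.record_id!r}: signal length {len(record)} != "
                f"label length {len(labels)}"
            )
        xs.append(zscore(record.samples))
        ys.append(np.asarray(labels.classes, dtype=np.int64))
    return np.stack(xs), np.stack(ys)


def _eval_loss_acc(model: BiLSTMSegmenter, x: np.ndarray, y: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    losses, correct, total = [], 0, 0
    for lo in range(0, x.shape[0], batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits, _ = model.forward(xb)
        loss, _ = softmax_xent(logits, yb.T)
        losses.append(loss * xb.shape[0])
        pred = np.argmax(logits, axis=-1).T
        correct += int((pred == yb).sum())
        total += yb.size
    return float(np.sum(losses) / x.shape[0]), correct / total


def train(
    model: BiLSTMSegmenter,
    train_set: Sequence,
    val_set: Sequence,
    cfg: ModelConfig | None = None,
) -> tuple[BiLSTMSegmenter, dict[str, list]]:
    """Train with Adam + early stopping; returns the best-validation model.

    `train_set` / `val_set` are sequences of (PulseRecord, ..., LabelSequence)
    tuples (the record first, its labels last).  History holds per-epoch
    train/val loss and per-sample accuracy.
    """
    cfg = cfg or model.cfg
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    if cfg.max_epochs == 0:
        return model, history
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")

    x_tr, y_tr = _as_xy(train_set)
    x_va, y_va = _as_xy(val_set)
    rng = np.random.default_rng(cfg.seed + 1)  # data order + dropout stream
    opt = Adam(model.params, lr=cfg.lr)

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    patience_left = cfg.early_stop_patience
    n = x_tr.shape[0]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits, caches = model.forward(xb, train=True, rng=rng)
            loss, dlogits = softmax_xent(logits, yb.T)
            grads = model.backward(dlogits, caches)
            opt.step(model.params, grads)
            ep_loss += loss * xb.shape[0]
            ep_correct += int((np.argmax(logits, axis=-1).T == yb).sum())
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / y_tr.size)

        val_loss, val_acc = _eval_loss_acc(model, x_va, y_va, cfg.batch_size)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        log.info(
            "epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
            epoch + 1, history["train_loss"][-1], history["train_acc"][-1],
            val_loss, val_acc,
        )

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.params = best_params
    return model, history


def postprocess(classes: np.ndarray, fs: float = 720.0, min_run_s: float = 0.05) -> np.ndarray:
    """Clean a raw argmax sequence into plausible phase runs.

    Runs shorter than `min_run_s` are merged into the longer neighboring
    run (repeatedly, shortest first); then consecutive same-phase runs
    separated only by a short background gap are fused, so within the
    labeled region systole and diastole alternate.
    """
    classes = np.asarray(classes, dtype=np.int8).copy()
    min_run = max(int(round(min_run_s * fs)), 1)

    while True:
        runs = runs_from_classes(classes)
        if len(runs) <= 1:
            break
        short = [
            (end - start, idx)
            for idx, (start, end, _) in enumerate(runs)
            if end - start < min_run
        ]
        if not short:
            break
        _, idx = min(short)
        start, end, _ = runs[idx]
        left = runs[idx - 1] if idx > 0 else None
        right = runs[idx + 1] if idx < len(runs) - 1 else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            target = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        classes[start:end] = target[2]

    # fuse same-phase runs separated by a short background gap
    runs = runs_from_classes(classes)
    nonbg = [r for r in runs if r[2] != BACKGROUND]
    for (s1, e1, c1), (s2, e2, c2) in zip(nonbg, nonbg[1:]):
        if c1 == c2 and 0 < s2 - e1 < min_run and (classes[e1:s2] == BACKGROUND).all():
            classes[e1:s2] = c1
    return classes
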