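"""Utterance-level prediction and evaluation metrics.

An utterance's diagnosis is the majority vote over its frame-level argmax
predictions (ties: highest mean posterior, then lowest class index).
Evaluation reduces a truth x prediction confusion matrix to overall
accuracy (trace/total), per-class sensitivity TP/(TP+FN), and UAR — the
unweighted mean of the K per-class sensitivities (K=4 for the full label
set, K=3 for the challenge-style subset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from voicedx.features import FramingConfig, featurize
from voicedx.models import forward_frames
from voicedx.synth import Waveform

__all__ = [
    "UnvoicedInputError", "UtterancePrediction", "MetricsReport",
    "majority_vote", "predict_utterance", "confusion_matrix",
    "compute_metrics",
]


class UnvoicedInputError(ValueError):
    """No speech frames survive voice activity detection."""


@dataclass(frozen=True)
class UtterancePrediction:
    label: int
    vote_counts: np.ndarray
    mean_posterior: np.ndarray


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale scores; ``uar`` is the mean of ``sensitivity``."""

    accuracy: float
    sensitivity: np.ndarray     # per class, truth order
    uar: float
    k: int
    accuracy_macro_ovr: float   # TN-inclusive one-vs-rest average (alt form)


def majority_vote(probs: np.ndarray) -> UtterancePrediction:
    """Aggregate frame posteriors into one utterance label.

    Tallies per-frame argmax votes; the most frequent class wins.  A vote
    tie falls back to the higher mean posterior, a residual tie to the
    lowest class index (np.argmax order).
    """
    probs = np.atleast_2d(np.asarray(probs, float))
    if probs.shape[0] == 0:
        raise ValueError("no frames to vote on")
    k = probs.shape[1]
    votes = np.bincount(np.argmax(probs, axis=1), minlength=k)
    mean_post = probs.mean(axis=0)
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    label = int(tied[0]) if len(tied) == 1 else int(tied[np.argmax(mean_post[tied])])
    return UtterancePrediction(label=label, vote_counts=votes,
                               mean_posterior=mean_post)


def predict_utterance(model, w: Waveform,
                      vad_threshold: float = 0.9,
                      feat_cfg: Optional[FramingConfig] = None,
                      fb=None) -> UtterancePrediction:
    """Full pipeline for one waveform: VAD -> MFCC -> model -> vote."""
    try:
        mfcc = featurize(w, cfg=feat_cfg, fb=fb, vad_threshold=vad_threshold)
    except ValueError as exc:
        if "no voiced content" in str(exc):
            raise UnvoicedInputError("unvoiced input: VAD kept no frames") from exc
        raise
    return majority_vote(forward_frames(model, mfcc))


def confusion_matrix(preds: Sequence[int], truths: Sequence[int],
                     k: int) -> np.ndarray:
    """K x K integer counts; rows = truth, columns = prediction."""
    from sklearn.metrics import confusion_matrix as _sk_cm

    preds = np.asarray(preds, int)
    truths = np.asarray(truths, int)
    if preds.shape != truths.shape:
        raise ValueError("prediction/truth length mismatch")
    if preds.size == 0:
        raise ValueError("empty label sequences")
    for arr, name in ((preds, "prediction"), (truths, "truth")):
        if arr.min() < 0 or arr.max() >= k:
            raise ValueError(f"{name} label out of range 0..{k - 1}")
    return _sk_cm(truths, preds, labels=np.arange(k)).astype(int)


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy, per-class sensitivity, and UAR from a confusion matrix.

    Accuracy is 100 * trace / total (the multiclass reduction of the
    binary TP+TN form); ``accuracy_macro_ovr`` additionally reports the
    one-vs-rest TN-inclusive average for reference.  Sensitivity of class
    c is 100 * TP_c / (TP_c + FN_c); a class with no true examples makes
    sensitivity undefined and raises.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        empty = np.flatnonzero(row_sums == 0).tolist()
        raise ValueError(f"sensitivity undefined: no true examples for "
                         f"class(es) {empty}")
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    sensitivity = 100.0 * tp / row_sums
    accuracy = 100.0 * tp.sum() / total
    tn = total - row_sums - cm.sum(axis=0) + tp
    acc_ovr = float(np.mean(100.0 * (tp + tn) / total))
    return MetricsReport(accuracy=float(accuracy),
                         sensitivity=sensitivity,
                         uar=float(sensitivity.mean()),
                         k=k, accuracy_macro_ovr=acc_ovr)
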