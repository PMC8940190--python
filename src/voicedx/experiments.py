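"""Experiment harnesses on synthetic corpora.

Three designs: (1) condition comparison — every classifier kind trained
and tested on matched continuous-speech and sustained-vowel corpora;
(2) sentence selection — one BiLSTM system trained and tested per script
item, ranked; (3) PCA projection of pooled last-hidden-layer features
(50 -> 2) for visualizing class separation at the feature level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from voicedx.features import FramingConfig, featurize, mel_filterbank
from voicedx.inference import compute_metrics, confusion_matrix, majority_vote
from voicedx.models import (
    ModelConfig, TrainConfig, UtteranceFeatures, build_model,
    extract_hidden_features, forward_frames, train_model,
)
from voicedx.synth import (
    Corpus, CorpusConfig, DisorderProfile, UtteranceSpec, generate_corpus,
)

__all__ = [
    "PcaProjection", "featurize_corpus", "train_on_corpus", "evaluate_split",
    "run_condition_comparison", "run_sentence_selection", "pca_project",
    "pooled_hidden_features", "plot_pca",
]


def _filterbank_for(corpus: Corpus, cfg: FramingConfig):
    return mel_filterbank(corpus.config.fs, cfg.fft_size_for(corpus.config.fs))


def featurize_corpus(corpus: Corpus, which: Optional[str] = None,
                     cfg: Optional[FramingConfig] = None,
                     vad_threshold: float = 0.9) -> list[UtteranceFeatures]:
    """VAD-gated MFCC features for a corpus (or one split of it)."""
    cfg = cfg or FramingConfig()
    fb = _filterbank_for(corpus, cfg)
    utts = corpus.utterances if which is None else corpus.split(which)
    out = []
    for u in utts:
        mfcc = featurize(u.waveform, cfg=cfg, fb=fb, vad_threshold=vad_threshold)
        out.append(UtteranceFeatures(mfcc.astype(np.float32), u.label_idx,
                                     u.speaker_id))
    return out


def train_on_corpus(corpus: Corpus, model_cfg: ModelConfig, tc: TrainConfig,
                    cfg: Optional[FramingConfig] = None):
    """Train one classifier on a corpus's training split.

    Returns (model, train_features, test_features).
    """
    train_feats = featurize_corpus(corpus, "train", cfg)
    test_feats = featurize_corpus(corpus, "test", cfg)
    model = build_model(model_cfg, input_dim=26, seed=tc.seed)
    train_model(model, train_feats, tc)
    return model, train_feats, test_feats


def evaluate_split(model, feats: Sequence[UtteranceFeatures], k: int):
    """Majority-vote metrics of a model over featurized utterances."""
    preds = [majority_vote(forward_frames(model, u.mfcc)).label for u in feats]
    truths = [u.label for u in feats]
    cm = confusion_matrix(preds, truths, k)
    return compute_metrics(cm)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _default_model_cfg(kind: str, n_classes: int) -> ModelConfig:
    return ModelConfig(kind=kind, n_classes=n_classes)

TrainerFn = Callable[[str, list[UtteranceFeatures], TrainConfig], Callable]


def run_condition_comparison(corpora: dict[str, Corpus],
                             model_kinds: Sequence[str],
                             tc: TrainConfig,
                             model_cfgs: Optional[dict[str, ModelConfig]] = None,
                             trainer: Optional[TrainerFn] = None,
                             feat_cfg: Optional[FramingConfig] = None,
                             ) -> pd.DataFrame:
    """Train/evaluate each model kind under each recording condition.

    ``corpora`` maps condition name ("continuous", "vowel") to a corpus;
    the corpora must share the same label set.  Returns a table with one
    row per (model_kind, condition) holding test accuracy and UAR in
    percent.  ``trainer`` may replace the default fit for harness tests:
    it receives (kind, train_features, tc) and returns a callable
    ``predict(features: UtteranceFeatures) -> class index``.
    """
    label_sets = {name: c.labels for name, c in corpora.items()}
    if len({tuple(v) for v in label_sets.values()}) != 1:
        raise ValueError(f"corpora have mismatched class sets: {label_sets}")
    k = len(next(iter(corpora.values())).labels)
    rows = []
    for name, corpus in corpora.items():
        train_feats = featurize_corpus(corpus, "train", feat_cfg)
        test_feats = featurize_corpus(corpus, "test", feat_cfg)
        for kind in model_kinds:
            if trainer is not None:
                predict = trainer(kind, train_feats, tc)
                preds = [predict(u) for u in test_feats]
            else:
                cfg = (model_cfgs or {}).get(kind) or _default_model_cfg(kind, k)
                model = build_model(cfg, input_dim=26, seed=tc.seed)
                train_model(model, train_feats, tc)
                preds = [majority_vote(forward_frames(model, u.mfcc)).label
                         for u in test_feats]
            report = compute_metrics(
                confusion_matrix(preds, [u.label for u in test_feats], k))
            rows.append({"model_kind": kind, "condition": name,
                         "accuracy": report.accuracy, "uar": report.uar})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sentence selection
# ---------------------------------------------------------------------------

def run_sentence_selection(script_variants: Sequence[int] | dict,
                           profiles: dict[str, DisorderProfile],
                           tc: TrainConfig,
                           corpus_config: Optional[CorpusConfig] = None,
                           model_cfg: Optional[ModelConfig] = None,
                           feat_cfg: Optional[FramingConfig] = None,
                           ) -> pd.DataFrame:
    """Rank script items by the test performance of a per-item classifier.

    ``script_variants`` is a sequence of script ids (1-7), or a mapping
    id -> profile set to let variants differ in class separation.  For
    each variant a fresh corpus of single-item continuous utterances is
    generated, a BiLSTM (or ``model_cfg``) is trained on its training
    split and evaluated on its test split.  Rows are ranked by UAR, then
    accuracy, then script id; the best row is flagged.
    """
    if isinstance(script_variants, dict):
        variant_profiles = dict(script_variants)
    else:
        variant_profiles = {sid: profiles for sid in script_variants}
    if len(variant_profiles) < 2:
        raise ValueError("need at least two script variants to rank")
    corpus_config = corpus_config or CorpusConfig()
    k = len(corpus_config.class_counts)
    model_cfg = model_cfg or ModelConfig(kind="bilstm", n_classes=k)
    rows = []
    for sid, prof in sorted(variant_profiles.items()):
        spec = UtteranceSpec(mode="continuous", script_id=sid)
        corpus = generate_corpus(corpus_config, prof, spec)
        model, _, test_feats = train_on_corpus(corpus, model_cfg, tc, feat_cfg)
        report = evaluate_split(model, test_feats, k)
        rows.append({"script_id": sid, "accuracy": report.accuracy,
                     "uar": report.uar})
    table = pd.DataFrame(rows).sort_values(
        by=["uar", "accuracy", "script_id"],
        ascending=[False, False, True]).reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table


# ---------------------------------------------------------------------------
# PCA feature visualization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaProjection:
    """Two-dimensional projection of pooled hidden features."""

    coords: np.ndarray                 # (n, 2)
    labels: np.ndarray
    explained_variance_ratio: np.ndarray


def pooled_hidden_features(model, feats: Sequence[UtteranceFeatures]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Utterance-mean last-hidden-layer vectors and their labels."""
    pooled = np.stack([extract_hidden_features(model, u.mfcc)[1] for u in feats])
    labels = np.array([u.label for u in feats])
    return pooled, labels


def pca_project(features: np.ndarray, labels: Sequence[int],
                n_components: int = 2) -> PcaProjection:
    """Mean-centered projection onto the top principal axes (no whitening)."""
    from sklearn.decomposition import PCA

    features = np.asarray(features, float)
    if features.shape[0] < 3:
        raise ValueError("need at least 3 utterance vectors for PCA")
    if features.shape[1] < n_components:
        raise ValueError("feature dimension below the projection dimension")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(features)
    return PcaProjection(coords=coords, labels=np.asarray(labels),
                         explained_variance_ratio=pca.explained_variance_ratio_)


def plot_pca(proj: PcaProjection, path: str,
             label_names: Optional[Sequence[str]] = None) -> None:
    """Scatter plot of the projection, one color per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(proj.labels):
        sel = proj.labels == cls
        name = label_names[cls] if label_names is not None else str(cls)
        ax.scatter(proj.coords[sel, 0], proj.coords[sel, 1], s=12, label=name)
    ax.set_xlabel(f"PC1 ({100 * proj.explained_variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * proj.explained_variance_ratio[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
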