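import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import voicedx as vx
from voicedx.experiments import evaluate_split, featurize_corpus, run_condition_comparison
from voicedx.models import ModelConfig, TrainConfig, build_model, train_model


@pytest.fixture(scope="session")
def profiles():
    return vx.default_profiles()


@pytest.fixture(scope="session")
def e2e_bundle(profiles):
    """A trained end-to-end BiLSTM pipeline on a well-separated continuous
    corpus (40 utterances per class, fixed seed) with its test metrics."""
    cfg = vx.CorpusConfig(class_counts={l: 40 for l in vx.DISORDER_LABELS},
                          seed=11)
    spec = vx.UtteranceSpec(mode="continuous", script_id=2)
    corpus = vx.generate_corpus(cfg, profiles, spec)
    train_feats = featurize_corpus(corpus, "train")
    test_feats = featurize_corpus(corpus, "test")
    model = build_model(ModelConfig(kind="bilstm", n_classes=4), seed=11)
    result = train_model(model, train_feats, TrainConfig(epochs=15, seed=11))
    report = evaluate_split(model, test_feats, 4)
    return {"corpus": corpus, "model": model, "train": train_feats,
            "test": test_feats, "report": report, "result": result}


@pytest.fixture(scope="session")
def condition_gaps(profiles):
    """BiLSTM continuous-vs-vowel UAR gaps over three seeds (40 utt/class)."""
    gaps = []
    tables = []
    for seed in (0, 1, 2):
        cc = vx.CorpusConfig(class_counts={l: 40 for l in vx.DISORDER_LABELS},
                             seed=seed)
        cont = vx.generate_corpus(cc, profiles,
                                  vx.UtteranceSpec(mode="continuous", script_id=2))
        vow = vx.generate_corpus(cc, profiles,
                                 vx.UtteranceSpec(mode="sustained_vowel"))
        tc = TrainConfig(epochs=15, seed=seed)
        tab = run_condition_comparison({"continuous": cont, "vowel": vow},
                                       ["bilstm"], tc)
        cu = float(tab.query("condition=='continuous'").uar.iloc[0])
        vu = float(tab.query("condition=='vowel'").uar.iloc[0])
        gaps.append(cu - vu)
        tables.append(tab)
    return {"gaps": gaps, "tables": tables}


@pytest.fixture()
def tiny_vowel_spec():
    return vx.UtteranceSpec(mode="sustained_vowel", duration_s=0.6)
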