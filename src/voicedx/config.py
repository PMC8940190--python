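"""YAML configuration loading for corpora and disorder profiles."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from voicedx.synth import (
    CorpusConfig, DisorderProfile, TransitionParams, UtteranceSpec,
    default_profiles,
)

__all__ = ["load_corpus_setup"]


def load_corpus_setup(path: str | Path):
    """Read (CorpusConfig, profiles, UtteranceSpec) from a YAML file.

    Recognized top-level keys: ``corpus`` (CorpusConfig fields),
    ``utterance`` (UtteranceSpec fields), and ``profiles`` — a mapping of
    label to overrides of the default profile fields (nested
    ``transition`` overrides are applied to TransitionParams).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = CorpusConfig(**data.get("corpus", {}))
    spec = UtteranceSpec(**data.get("utterance", {}))
    profiles = default_profiles(tuple(cfg.class_counts))
    for label, overrides in (data.get("profiles") or {}).items():
        if label not in profiles:
            raise KeyError(f"profile overrides for unknown label {label!r}")
        overrides = dict(overrides)
        tr = overrides.pop("transition", None)
        prof = replace(profiles[label], **overrides)
        if tr:
            prof = replace(prof, transition=replace(prof.transition, **tr))
        profiles[label] = prof
    return cfg, profiles, spec
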