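"""Synthetic corpus generator: perturbation calibration, corpus contracts."""

import numpy as np
import pytest

import voicedx as vx
from voicedx.synth import (
    ConfigurationError, InvalidParameterError, SynthesisError,
    VocalTractParams, profiles_with_separation,
)
from oracles import (
    autocorr_at_lag, centroid_variance, measure_hnr_db, measure_jitter_pct,
    measure_shimmer_db,
)

FS = 44100


def _source(f0=150.0, duration=2.0, seed=0, **kw):
    p = vx.GlottalSourceParams(f0_mean=f0, **kw)
    return vx.synth_glottal_source(p, duration, FS, np.random.default_rng(seed))


class TestGlottalSource:
    def test_clean_source_is_periodic(self):
        w = _source(duration=1.0, seed=4)
        assert autocorr_at_lag(w.samples, FS // 150) >= 0.99

    def test_jitter_measured_matches_configured(self):
        w = _source(jitter_pct=3.0, seed=3)
        assert abs(measure_jitter_pct(w.samples, FS, 150.0) - 3.0) <= 0.5

    def test_no_aspiration_gives_high_hnr(self):
        w = _source(duration=1.0, seed=4)
        assert measure_hnr_db(w.samples, FS, 150.0) >= 40.0

    def test_shimmer_measured_matches_configured(self):
        w = _source(shimmer_db=1.5, seed=5)
        assert abs(measure_shimmer_db(w.samples, FS, 150.0) - 1.5) <= 0.3

    def test_aspiration_gain_sets_hnr(self):
        w = _source(duration=1.0, seed=6, aspiration_gain=10 ** (-15 / 20))
        assert abs(measure_hnr_db(w.samples, FS, 150.0) - 15.0) <= 2.0

    @pytest.mark.parametrize("kwargs", [
        dict(duration_s=0.0), dict(duration_s=-1.0)])
    def test_bad_duration_raises(self, kwargs):
        p = vx.GlottalSourceParams(f0_mean=150.0)
        with pytest.raises(InvalidParameterError):
            vx.synth_glottal_source(p, kwargs["duration_s"], FS,
                                    np.random.default_rng(0))

    def test_bad_f0_raises(self):
        with pytest.raises(InvalidParameterError):
            vx.GlottalSourceParams(f0_mean=0.0)
        p = vx.GlottalSourceParams(f0_mean=30000.0)
        with pytest.raises(InvalidParameterError):
            vx.synth_glottal_source(p, 1.0, FS, np.random.default_rng(0))

    @pytest.mark.parametrize("measure,param,grid", [
        (measure_jitter_pct, "jitter_pct", (0.5, 1.5, 3.0)),
        (measure_shimmer_db, "shimmer_db", (0.3, 0.8, 1.5)),
    ])
    def test_perturbation_monotonicity(self, measure, param, grid):
        """Measured jitter/shimmer tracks the configured value over a grid."""
        vals = []
        for g in grid:
            per_seed = [measure(_source(seed=s, **{param: g}).samples, FS, 150.0)
                        for s in (0, 1, 2)]
            vals.append(np.median(per_seed))
        assert vals[0] <= vals[1] + 0.1 and vals[1] <= vals[2] + 0.1

    def test_hnr_monotone_in_aspiration(self):
        hnrs = [measure_hnr_db(_source(duration=1.0, seed=7,
                                       aspiration_gain=g).samples, FS, 150.0)
                for g in (10 ** (-25 / 20), 10 ** (-15 / 20), 10 ** (-8 / 20))]
        assert hnrs[0] > hnrs[1] > hnrs[2]


class TestUtterance:
    def test_vowel_duration_sample_count(self, profiles):
        spec = vx.UtteranceSpec(mode="sustained_vowel", duration_s=3.0)
        w = vx.synth_utterance(spec, profiles["FD"], np.random.default_rng(0))
        voiced = int(round(3.0 * FS))
        pad = int(round(0.12 * FS)) + int(round(0.06 * FS))
        assert len(w.samples) == voiced + pad

    def test_peak_normalized(self, profiles):
        for mode, kw in (("sustained_vowel", {"duration_s": 1.0}),
                         ("continuous", {"script_id": 1})):
            spec = vx.UtteranceSpec(mode=mode, **kw)
            w = vx.synth_utterance(spec, profiles["vocal_palsy"],
                                   np.random.default_rng(1))
            assert np.max(np.abs(w.samples)) <= 1.0

    def test_continuous_has_larger_centroid_variance(self, profiles):
        rng = np.random.default_rng(2)
        vowel = vx.synth_utterance(
            vx.UtteranceSpec(mode="sustained_vowel", duration_s=1.5),
            profiles["FD"], rng, f0_base=160.0)
        cont = vx.synth_utterance(
            vx.UtteranceSpec(mode="continuous", script_id=2),
            profiles["FD"], np.random.default_rng(2), f0_base=160.0)
        assert centroid_variance(cont.samples, FS) \
            > centroid_variance(vowel.samples, FS)

    def test_unstable_tract_raises(self):
        with pytest.raises(InvalidParameterError):
            VocalTractParams(formant_freqs=(700.0, 600.0, 2600.0))
        with pytest.raises(InvalidParameterError):
            VocalTractParams(formant_bandwidths=(80.0, -1.0, 120.0))
        from voicedx.synth import _apply_tract
        with pytest.raises(SynthesisError):
            _apply_tract(np.zeros(512), FS, np.array([[700.0, 1220.0, 90000.0]]),
                         (80.0, 100.0, 120.0))


class TestProfiles:
    def test_defaults_pairwise_distinct(self, profiles):
        keys = ("jitter_pct", "shimmer_db", "hnr_db", "tremor_depth")
        labs = list(profiles)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                a, b = profiles[labs[i]], profiles[labs[j]]
                assert any(getattr(a, k) != getattr(b, k) for k in keys)

    def test_separation_scaling_identity(self, profiles):
        scaled = profiles_with_separation(1.0)
        for lab in profiles:
            assert scaled[lab].transition.f0_glide_st == pytest.approx(
                profiles[lab].transition.f0_glide_st)


class TestCorpus:
    def test_replica_counts(self):
        cfg_c, spec_c = vx.femh_replica_continuous_config()
        cfg_v, spec_v = vx.femh_replica_vowel_config()
        cfg_ch, spec_ch = vx.challenge_replica_config()
        profs4 = vx.default_profiles()
        profs3 = vx.default_profiles(vx.CHALLENGE_LABELS)
        assert len(vx.generate_corpus(cfg_c, profs4, spec_c)) == 1045
        assert len(vx.generate_corpus(cfg_v, profs4, spec_v)) == 1061
        assert len(vx.generate_corpus(cfg_ch, profs3, spec_ch)) == 150

    def test_class_counts_exact(self, profiles, tiny_vowel_spec):
        counts = {"FD": 3, "neoplasm": 5, "phonotrauma": 7, "vocal_palsy": 2}
        corpus = vx.generate_corpus(
            vx.CorpusConfig(class_counts=counts, seed=1), profiles,
            tiny_vowel_spec)
        assert corpus.class_counts() == counts

    def test_speaker_disjoint_split(self, profiles, tiny_vowel_spec):
        cfg = vx.CorpusConfig(class_counts={l: 10 for l in vx.DISORDER_LABELS},
                              seed=2, speakers_per_class=5)
        corpus = vx.generate_corpus(cfg, profiles, tiny_vowel_spec)
        train_spk = {u.speaker_id for u in corpus.split("train")}
        test_spk = {u.speaker_id for u in corpus.split("test")}
        assert train_spk and test_spk
        assert not (train_spk & test_spk)

    def test_same_seed_byte_identical(self, profiles, tiny_vowel_spec):
        cfg = vx.CorpusConfig(class_counts={"FD": 2, "neoplasm": 2}, seed=9)
        h1 = vx.generate_corpus(cfg, profiles, tiny_vowel_spec).content_hash()
        h2 = vx.generate_corpus(cfg, profiles, tiny_vowel_spec).content_hash()
        assert h1 == h2

    def test_too_few_speakers_raises(self, profiles, tiny_vowel_spec):
        cfg = vx.CorpusConfig(class_counts={"FD": 4, "neoplasm": 4},
                              speakers_per_class=1)
        with pytest.raises(ConfigurationError):
            vx.generate_corpus(cfg, profiles, tiny_vowel_spec)

    def test_full_script_spec_carries_seven_items(self):
        _, spec = vx.femh_replica_continuous_config()
        assert spec.script_ids == (1, 2, 3, 4, 5, 6, 7)

    def test_yaml_config_roundtrip(self, tmp_path):
        from voicedx.config import load_corpus_setup

        path = tmp_path / "setup.yaml"
        path.write_text(
            "corpus:\n  class_counts: {FD: 3, neoplasm: 4}\n  seed: 12\n"
            "utterance:\n  mode: continuous\n  script_id: 2\n"
            "profiles:\n  FD:\n    jitter_pct: 0.9\n"
            "    transition: {f0_glide_st: 1.5}\n")
        cfg, profiles, spec = load_corpus_setup(path)
        assert cfg.class_counts == {"FD": 3, "neoplasm": 4} and cfg.seed == 12
        assert spec.script_id == 2
        assert profiles["FD"].jitter_pct == 0.9
        assert profiles["FD"].transition.f0_glide_st == 1.5
        assert profiles["neoplasm"].jitter_pct == 3.0

    def test_wav_write_and_manifest(self, profiles, tiny_vowel_spec, tmp_path):
        import pandas as pd
        from scipy.io import wavfile

        cfg = vx.CorpusConfig(class_counts={"FD": 2, "phonotrauma": 2}, seed=3)
        corpus = vx.generate_corpus(cfg, profiles, tiny_vowel_spec)
        manifest = corpus.write(tmp_path)
        df = pd.read_csv(manifest)
        assert set(df.columns) == {"path", "label", "speaker_id", "mode", "split"}
        fs, data = wavfile.read(tmp_path / df.iloc[0]["path"])
        assert fs == 44100 and data.dtype == np.int16
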