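"""Synthetic dysphonic-voice corpus generation.

Source-filter synthesis of sustained-vowel and continuous (multi-syllable)
utterances with disorder-dependent perturbations of the glottal source:
jitter (cycle-to-cycle period perturbation), shimmer (cycle-to-cycle
amplitude perturbation), aspiration noise (reduced harmonics-to-noise
ratio) and slow f0 tremor.  Four default disorder profiles emulate the
acoustic phenotypes of functional dysphonia (FD), glottic neoplasm,
phonotraumatic lesions and vocal-fold palsy; the parameters are invented
stand-ins for clinical recordings and are documented as such.

The glottal source is a Rosenberg-style pulse train (flow derivative)
plus high-pass-filtered aspiration noise; the vocal tract is a cascade of
second-order formant resonators whose targets can move syllable-to-
syllable in continuous mode.  Continuous mode additionally encodes
class-discriminative *transition dynamics* (syllable-onset formant/f0
glide speed, syllable rate, inter-syllable amplitude dips) so that the
benefit of modelling syllable transitions is testable in synthesis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, lfilter

__all__ = [
    "InvalidParameterError", "SynthesisError", "ConfigurationError",
    "DISORDER_LABELS", "CHALLENGE_LABELS", "VOWEL_FORMANTS",
    "SCRIPT_ITEMS",
    "GlottalSourceParams", "VocalTractParams", "TransitionParams",
    "DisorderProfile", "UtteranceSpec", "CorpusConfig", "Waveform",
    "Utterance", "Corpus",
    "default_profiles", "profiles_with_separation",
    "synth_glottal_source", "synth_utterance", "generate_corpus",
    "femh_replica_continuous_config", "femh_replica_vowel_config",
    "challenge_replica_config",
]


class InvalidParameterError(ValueError):
    """Raised for physically meaningless synthesis parameters."""


class SynthesisError(RuntimeError):
    """Raised when a filter configuration would be unstable."""


class ConfigurationError(ValueError):
    """Raised for inconsistent corpus configurations."""


#: Four-class label set (full corpus) and three-class subset (the smaller
#: balanced challenge-style corpus).
DISORDER_LABELS: tuple[str, ...] = ("FD", "neoplasm", "phonotrauma", "vocal_palsy")
CHALLENGE_LABELS: tuple[str, ...] = ("neoplasm", "phonotrauma", "vocal_palsy")

#: Reference formant targets (F1, F2, F3 in Hz).  /a/ uses the standard
#: phonetics textbook values; the others are generic vowel targets used to
#: build multi-syllable scripts.
VOWEL_FORMANTS: dict[str, tuple[float, float, float]] = {
    "a": (700.0, 1220.0, 2600.0),
    "i": (300.0, 2300.0, 3000.0),
    "u": (320.0, 800.0, 2500.0),
    "e": (500.0, 1800.0, 2500.0),
    "o": (450.0, 900.0, 2600.0),
}

_FORMANT_BANDWIDTHS = (80.0, 100.0, 120.0)

#: Seven script items standing in for a seven-sentence reading passage.
#: Syllable counts mirror a realistic short-sentence script (7-14
#: syllables); vowel sequences differ in transition richness.
SCRIPT_ITEMS: dict[int, tuple[str, ...]] = {
    1: ("o", "i", "a", "o", "e", "a", "e"),
    2: ("a", "a", "e", "o", "e", "i", "e", "i", "i", "a"),
    3: ("e", "a", "e", "o", "a", "i", "e", "e", "i", "e", "e"),
    4: ("o", "a", "e", "e", "i", "i", "i", "a", "e", "e", "i", "i"),
    5: ("a", "o", "i", "e", "i", "a", "e", "e", "a"),
    6: ("a", "a", "a", "a", "e", "e", "a", "i", "i", "i", "a", "e", "a", "u"),
    7: ("e", "a", "o", "e", "a", "e", "i", "e", "i", "a", "a", "u", "u"),
}

# E|x - y| for iid standard normals x, y is 2/sqrt(pi); dividing the
# configured perturbation by this constant makes the *expected measured*
# cycle-to-cycle (local) jitter/shimmer equal the configured value.
_LOCAL_PERT_CAL = 2.0 / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlottalSourceParams:
    """Parameters of the glottal (voice-source) model.

    f0_mean          mean fundamental frequency, Hz
    f0_contour       optional relative f0 multiplier per syllable
    jitter_pct       expected local cycle-to-cycle period perturbation, %
    shimmer_db       expected local cycle-to-cycle amplitude perturbation, dB
    aspiration_gain  aspiration-noise RMS relative to voiced RMS (linear);
                     a target HNR of h dB corresponds to 10**(-h/20)
    tremor_hz        slow f0 modulation rate, Hz (0 disables)
    tremor_depth     relative depth of the f0 modulation
    """

    f0_mean: float
    f0_contour: Optional[tuple[float, ...]] = None
    jitter_pct: float = 0.0
    shimmer_db: float = 0.0
    aspiration_gain: float = 0.0
    tremor_hz: float = 0.0
    tremor_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise InvalidParameterError(f"f0_mean must be > 0, got {self.f0_mean}")
        for name in ("jitter_pct", "shimmer_db", "aspiration_gain",
                     "tremor_hz", "tremor_depth"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class VocalTractParams:
    """Formant resonator cascade; ``trajectory`` holds per-syllable targets."""

    formant_freqs: tuple[float, ...] = VOWEL_FORMANTS["a"]
    formant_bandwidths: tuple[float, ...] = _FORMANT_BANDWIDTHS
    trajectory: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.formant_freqs, dtype=float)
        b = np.asarray(self.formant_bandwidths, dtype=float)
        if f.size < 3 or f.size != b.size:
            raise InvalidParameterError("need >= 3 formants with matching bandwidths")
        if np.any(np.diff(f) <= 0):
            raise InvalidParameterError("formant_freqs must be strictly increasing")
        if np.any(b <= 0):
            raise InvalidParameterError("formant bandwidths must be > 0")


@dataclass(frozen=True)
class TransitionParams:
    """Continuous-mode articulation dynamics (class-discriminative).

    onset_time_s   formant/f0 transition time at each syllable onset
    f0_glide_st    signed f0 onset glide, semitones relative to the base
    syllable_dur_s steady-state syllable duration
    dip_depth      inter-syllable amplitude dip depth in [0, 1)
    loudness_var   depth of slow utterance-level loudness modulation
    """

    onset_time_s: float = 0.08
    f0_glide_st: float = 0.0
    syllable_dur_s: float = 0.18
    dip_depth: float = 0.7
    loudness_var: float = 0.1


@dataclass(frozen=True)
class DisorderProfile:
    """Acoustic phenotype of one diagnosis class.

    Scalar attributes are per-speaker *means*; ``spread`` gives the
    half-width of the uniform range each speaker's value is drawn from
    (relative for jitter/shimmer, absolute dB for HNR).  The four default
    profiles are invented emulations chosen so the classes are separable
    but overlapping; they are not clinical measurements.
    """

    label: str
    jitter_pct: float
    shimmer_db: float
    hnr_db: float
    tremor_hz: float = 0.0
    tremor_depth: float = 0.0
    jitter_spread: float = 0.6     # relative
    shimmer_spread: float = 0.6    # relative
    hnr_spread_db: float = 8.0     # absolute dB
    transition: TransitionParams = field(default_factory=TransitionParams)

    def sample_source(self, rng: np.random.Generator, f0_mean: float,
                      f0_contour: Optional[tuple[float, ...]] = None,
                      ) -> GlottalSourceParams:
        """Draw one utterance's source parameters around the class means."""
        u = rng.uniform
        jit = max(self.jitter_pct * (1.0 + u(-self.jitter_spread, self.jitter_spread)), 0.0)
        shim = max(self.shimmer_db * (1.0 + u(-self.shimmer_spread, self.shimmer_spread)), 0.0)
        hnr = self.hnr_db + u(-self.hnr_spread_db, self.hnr_spread_db)
        return GlottalSourceParams(
            f0_mean=f0_mean,
            f0_contour=f0_contour,
            jitter_pct=jit,
            shimmer_db=shim,
            aspiration_gain=10.0 ** (-hnr / 20.0),
            tremor_hz=self.tremor_hz,
            tremor_depth=self.tremor_depth * (1.0 + u(-0.3, 0.3)) if self.tremor_depth else 0.0,
        )


def default_profiles(labels: Sequence[str] = DISORDER_LABELS) -> dict[str, DisorderProfile]:
    """The four default disorder phenotypes (overridable, invented).

    FD: near-normal perturbations, reduced loudness variation, crisp fast
    syllable onsets.  Neoplasm: high jitter, moderate noise, slow falling
    onsets.  Phonotrauma: high shimmer and breathiness, deep inter-
    syllable dips.  Vocal palsy: strong aspiration, f0 tremor, slow
    syllables with falling glides.
    """
    table = {
        "FD": DisorderProfile(
            label="FD", jitter_pct=0.5, shimmer_db=0.4, hnr_db=25.0,
            transition=TransitionParams(onset_time_s=0.05, f0_glide_st=3.0,
                                        syllable_dur_s=0.16, dip_depth=0.75,
                                        loudness_var=0.02)),
        "neoplasm": DisorderProfile(
            label="neoplasm", jitter_pct=3.0, shimmer_db=0.8, hnr_db=18.0,
            transition=TransitionParams(onset_time_s=0.16, f0_glide_st=-3.0,
                                        syllable_dur_s=0.18, dip_depth=0.55,
                                        loudness_var=0.10)),
        "phonotrauma": DisorderProfile(
            label="phonotrauma", jitter_pct=1.5, shimmer_db=1.5, hnr_db=15.0,
            transition=TransitionParams(onset_time_s=0.10, f0_glide_st=0.5,
                                        syllable_dur_s=0.17, dip_depth=0.92,
                                        loudness_var=0.15)),
        "vocal_palsy": DisorderProfile(
            label="vocal_palsy", jitter_pct=2.0, shimmer_db=1.0, hnr_db=8.0,
            tremor_hz=4.0, tremor_depth=0.04,
            transition=TransitionParams(onset_time_s=0.20, f0_glide_st=-6.0,
                                        syllable_dur_s=0.22, dip_depth=0.45,
                                        loudness_var=0.12)),
    }
    return {lab: table[lab] for lab in labels}


def profiles_with_separation(scale: float,
                             labels: Sequence[str] = DISORDER_LABELS,
                             ) -> dict[str, DisorderProfile]:
    """Rescale inter-class differences of the transition dynamics.

    ``scale=1`` returns the defaults; larger values move each class's
    transition parameters away from the across-class mean, making classes
    easier to separate from continuous speech (used for separation-
    monotonicity experiments).
    """
    base = default_profiles(labels)
    keys = ("onset_time_s", "f0_glide_st", "syllable_dur_s", "dip_depth")
    means = {k: float(np.mean([getattr(p.transition, k) for p in base.values()]))
             for k in keys}
    out = {}
    for lab, prof in base.items():
        tr = prof.transition
        new = {k: means[k] + scale * (getattr(tr, k) - means[k]) for k in keys}
        new["onset_time_s"] = float(np.clip(new["onset_time_s"], 0.02, 0.35))
        new["syllable_dur_s"] = float(np.clip(new["syllable_dur_s"], 0.10, 0.40))
        new["dip_depth"] = float(np.clip(new["dip_depth"], 0.0, 0.97))
        out[lab] = replace(prof, transition=replace(tr, **new))
    return out


@dataclass(frozen=True)
class UtteranceSpec:
    """What to say: sustained vowel or a multi-syllable script item.

    ``script_id`` selects one of the seven script items (1-7); ``None`` in
    continuous mode means the full seven-item script (items concatenated
    with short pauses), matching a whole-passage recording.
    """

    mode: str = "continuous"
    duration_s: float = 3.0
    n_syllables: Optional[int] = None
    script_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("sustained_vowel", "continuous"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be > 0")
        if self.mode == "continuous":
            if self.script_id is None and self.n_syllables is not None \
                    and self.n_syllables < 2:
                raise InvalidParameterError("continuous mode needs >= 2 syllables")
            if self.script_id is not None and self.script_id not in SCRIPT_ITEMS:
                raise InvalidParameterError(f"script_id must be in 1..7")

    @property
    def script_ids(self) -> tuple[int, ...]:
        """Script items carried by this spec (continuous mode)."""
        if self.mode != "continuous":
            return ()
        if self.script_id is not None:
            return (self.script_id,)
        if self.n_syllables is not None:
            return ()
        return tuple(sorted(SCRIPT_ITEMS))


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus size, audio format, and partitioning."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: {lab: 25 for lab in DISORDER_LABELS})
    fs: int = 44100
    bit_depth: int = 16
    seed: int = 0
    split_fraction: float = 0.8
    speakers_per_class: Optional[int] = None   # None -> one speaker per utterance

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError("class counts must be >= 0")
        if not (0.0 < self.split_fraction < 1.0):
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if self.fs <= 0 or self.bit_depth not in (16, 32):
            raise ConfigurationError("invalid audio format")


@dataclass
class Waveform:
    """Mono audio with metadata; samples are float in [-1, 1]."""

    samples: np.ndarray
    fs: int
    label: Optional[str] = None
    speaker_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def to_int16(self) -> np.ndarray:
        return np.clip(np.round(self.samples * 32767.0), -32768, 32767).astype(np.int16)

    def write(self, path: str | Path) -> None:
        wavfile.write(str(path), self.fs, self.to_int16())


# ---------------------------------------------------------------------------
# glottal source
# ---------------------------------------------------------------------------

def _rosenberg_pulse(n_period: int) -> np.ndarray:
    """Rosenberg glottal flow derivative over one period (peak-normalized)."""
    n_open = max(int(round(0.40 * n_period)), 2)
    n_close = max(int(round(0.16 * n_period)), 1)
    flow = np.zeros(n_period + 1)
    t_o = np.arange(n_open)
    flow[:n_open] = 0.5 * (1.0 - np.cos(np.pi * t_o / n_open))
    t_c = np.arange(n_close)
    flow[n_open:n_open + n_close] = np.cos(np.pi * t_c / (2.0 * n_close))
    dflow = np.diff(flow)
    peak = np.max(np.abs(dflow))
    return dflow / peak if peak > 0 else dflow


def _source_from_f0_env(f0_env: np.ndarray, fs: float,
                        jitter_pct: float, shimmer_db: float,
                        aspiration_gain: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Pulse train following a per-sample f0 envelope, plus aspiration."""
    n = len(f0_env)
    out = np.zeros(n)
    sigma_j = (jitter_pct / 100.0) / _LOCAL_PERT_CAL
    sigma_s = shimmer_db / _LOCAL_PERT_CAL
    pos = 0.0
    while pos < n:
        i = int(pos)
        f0_here = f0_env[min(i, n - 1)]
        period = fs / f0_here
        # pulse shape follows the *unjittered* local period so that jitter
        # perturbs only the cycle spacing (keeps measured jitter calibrated)
        n_period = int(round(period))
        if sigma_j > 0:
            period *= 1.0 + np.clip(rng.normal(0.0, sigma_j), -3 * sigma_j, 3 * sigma_j)
        amp = 10.0 ** (rng.normal(0.0, sigma_s) / 20.0) if sigma_s > 0 else 1.0
        if n_period < 4:
            raise InvalidParameterError("f0 too high for sampling rate")
        pulse = amp * _rosenberg_pulse(n_period)
        start = int(round(pos))
        end = min(start + len(pulse), n)
        if end > start:
            out[start:end] += pulse[:end - start]
        pos += period
    if aspiration_gain > 0:
        noise = rng.standard_normal(n)
        b, a = butter(2, 1000.0 / (fs / 2.0), btype="highpass")
        noise = lfilter(b, a, noise)
        voiced_rms = np.sqrt(np.mean(out ** 2))
        noise_rms = np.sqrt(np.mean(noise ** 2))
        if noise_rms > 0:
            out = out + noise * (aspiration_gain * voiced_rms / noise_rms)
    return out


def synth_glottal_source(params: GlottalSourceParams, duration_s: float,
                         fs: float, rng: np.random.Generator) -> Waveform:
    """Synthesize the unfiltered glottal source signal.

    The pulse train follows ``f0_mean`` modulated by the per-syllable
    contour (piecewise-constant over equal time segments) and the tremor
    sinusoid; cycle periods and amplitudes carry the configured jitter and
    shimmer; aspiration noise is added at the configured relative gain.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    if fs <= 2.0 * params.f0_mean:
        raise InvalidParameterError("fs must exceed 2 * f0_mean")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f0_env = np.full(n, params.f0_mean)
    if params.f0_contour:
        seg = np.minimum((t / duration_s * len(params.f0_contour)).astype(int),
                         len(params.f0_contour) - 1)
        f0_env = f0_env * np.asarray(params.f0_contour, dtype=float)[seg]
    if params.tremor_hz > 0 and params.tremor_depth > 0:
        f0_env = f0_env * (1.0 + params.tremor_depth
                           * np.sin(2 * np.pi * params.tremor_hz * t))
    samples = _source_from_f0_env(f0_env, fs, params.jitter_pct,
                                  params.shimmer_db, params.aspiration_gain, rng)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples * (0.95 / peak)
    return Waveform(samples=samples, fs=int(fs))


# ---------------------------------------------------------------------------
# vocal tract and utterance assembly
# ---------------------------------------------------------------------------

_TRACT_BLOCK = 256  # samples per coefficient-update block


def _apply_tract(source: np.ndarray, fs: float,
                 formant_env: np.ndarray,
                 bandwidths: Sequence[float]) -> np.ndarray:
    """Filter through a cascade of 2nd-order resonators.

    ``formant_env`` is (n_blocks, n_formants) of center frequencies; the
    coefficients update every ``_TRACT_BLOCK`` samples with carried filter
    state, approximating a smoothly time-varying tract.
    """
    n = len(source)
    n_formants = formant_env.shape[1]
    if np.any(formant_env >= fs / 2.0) or np.any(formant_env <= 0):
        raise SynthesisError("formant frequency outside (0, fs/2)")
    if any(b <= 0 for b in bandwidths):
        raise SynthesisError("non-positive formant bandwidth")
    out = source.copy()
    for j in range(n_formants):
        r = np.exp(-np.pi * bandwidths[j] / fs)
        y = np.empty(n)
        zi = np.zeros(2)
        for blk in range(formant_env.shape[0]):
            lo = blk * _TRACT_BLOCK
            hi = min(lo + _TRACT_BLOCK, n)
            if lo >= hi:
                break
            theta = 2 * np.pi * formant_env[blk, j] / fs
            a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
            b = np.array([np.sum(a)])  # unity gain at DC
            y[lo:hi], zi = lfilter(b, a, out[lo:hi], zi=zi)
        out = y
    return out


def _block_env(values: np.ndarray, n_samples: int) -> np.ndarray:
    """Resample a per-sample envelope to per-block values."""
    n_blocks = int(np.ceil(n_samples / _TRACT_BLOCK))
    idx = np.minimum(np.arange(n_blocks) * _TRACT_BLOCK + _TRACT_BLOCK // 2,
                     n_samples - 1)
    return values[idx]


def _ramped_track(targets: np.ndarray, onsets_s: np.ndarray, ramp_s: float,
                  n: int, fs: float) -> np.ndarray:
    """Piecewise track holding ``targets`` with linear ramps at onsets."""
    t = np.arange(n) / fs
    track = np.full(n, targets[0], dtype=float)
    for k in range(1, len(targets)):
        t0 = onsets_s[k]
        ramp = np.clip((t - t0) / max(ramp_s, 1e-3), 0.0, 1.0)
        track = track * (1.0 - ramp) + targets[k] * ramp
    return track


_LEAD_SILENCE_S = 0.12   # keeps the first VAD frames speech-free
_TAIL_SILENCE_S = 0.06
_FLOOR_DB = -55.0        # recording-room noise floor re voiced RMS


def _finalize(voiced: np.ndarray, fs: float, rng: np.random.Generator,
              label: Optional[str], speaker_id: Optional[str]) -> Waveform:
    lead = int(round(_LEAD_SILENCE_S * fs))
    tail = int(round(_TAIL_SILENCE_S * fs))
    sig = np.concatenate([np.zeros(lead), voiced, np.zeros(tail)])
    rms = np.sqrt(np.mean(voiced ** 2))
    if rms > 0:
        sig = sig + rng.standard_normal(len(sig)) * rms * 10 ** (_FLOOR_DB / 20.0)
    peak = np.max(np.abs(sig))
    if peak > 0:
        sig = sig * (0.95 / peak)
    return Waveform(samples=sig, fs=int(fs), label=label, speaker_id=speaker_id)


def synth_utterance(spec: UtteranceSpec, profile: DisorderProfile,
                    rng: np.random.Generator, *, fs: float = 44100.0,
                    f0_base: Optional[float] = None, tract_scale: float = 1.0,
                    speaker_id: Optional[str] = None) -> Waveform:
    """Synthesize one labeled utterance under a disorder profile.

    Sustained-vowel mode renders a static /a/ of ``spec.duration_s``;
    continuous mode renders the requested script item(s) (or a generic
    ``n_syllables`` sequence) with formant/f0 transitions at syllable
    onsets and inter-syllable amplitude dips.  Output is peak-normalized
    below 1 with a short leading/trailing silence at the noise floor.
    """
    if f0_base is None:
        f0_base = rng.uniform(110.0, 220.0)
    if spec.mode == "sustained_vowel":
        src = profile.sample_source(rng, f0_mean=f0_base)
        n = int(round(spec.duration_s * fs))
        t = np.arange(n) / fs
        # mild natural declination plus class-dependent loudness variation
        f0_env = f0_base * (1.02 - 0.04 * t / spec.duration_s)
        if src.tremor_hz > 0 and src.tremor_depth > 0:
            f0_env *= 1.0 + src.tremor_depth * np.sin(2 * np.pi * src.tremor_hz * t)
        voiced = _source_from_f0_env(f0_env, fs, src.jitter_pct, src.shimmer_db,
                                     src.aspiration_gain, rng)
        freqs = np.asarray(VOWEL_FORMANTS["a"]) * tract_scale
        env = np.tile(freqs, (int(np.ceil(n / _TRACT_BLOCK)), 1))
        voiced = _apply_tract(voiced, fs, env, _FORMANT_BANDWIDTHS)
        lv = profile.transition.loudness_var
        amp = 1.0 + lv * np.sin(2 * np.pi * 0.8 * t + rng.uniform(0, 2 * np.pi))
        fade = int(round(0.05 * fs))
        ramp = np.ones(n)
        ramp[:fade] = np.linspace(0, 1, fade)
        ramp[-fade:] = np.linspace(1, 0, fade)
        return _finalize(voiced * amp * ramp, fs, rng, profile.label, speaker_id)

    # continuous mode
    if spec.script_ids and len(spec.script_ids) > 1:
        parts = []
        for sid in spec.script_ids:
            item = replace(spec, script_id=sid)
            parts.append(synth_utterance(item, profile, rng, fs=fs,
                                         f0_base=f0_base, tract_scale=tract_scale,
                                         speaker_id=speaker_id).samples)
            parts.append(np.zeros(int(round(0.25 * fs))))
        sig = np.concatenate(parts[:-1])
        return Waveform(samples=sig, fs=int(fs), label=profile.label,
                        speaker_id=speaker_id)

    if spec.script_id is not None:
        vowels = SCRIPT_ITEMS[spec.script_id]
    else:
        seq = ("a", "e", "i", "o", "u", "e", "a", "i")
        n_syl = spec.n_syllables or 8
        vowels = tuple(seq[k % len(seq)] for k in range(n_syl))
    if len(vowels) < 2:
        raise InvalidParameterError("continuous mode needs >= 2 syllables")

    tr = profile.transition
    syl_dur = tr.syllable_dur_s * rng.uniform(0.93, 1.07)
    n_syl = len(vowels)
    total_s = n_syl * syl_dur
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    onsets = np.arange(n_syl) * syl_dur

    # f0: declination + per-syllable onset glide + tremor
    glide = tr.f0_glide_st * rng.uniform(0.8, 1.2)
    f0_mult = np.full(n, 1.0)
    for k in range(n_syl):
        rel = (t - onsets[k]) / max(tr.onset_time_s, 1e-3)
        in_syl = (t >= onsets[k]) & (t < onsets[k] + syl_dur)
        decay = np.clip(1.0 - rel, 0.0, 1.0)
        f0_mult[in_syl] *= 2.0 ** (glide * decay[in_syl] / 12.0)
    declin = 1.04 - 0.12 * t / total_s
    src = profile.sample_source(rng, f0_mean=f0_base)
    f0_env = f0_base * declin * f0_mult
    if src.tremor_hz > 0 and src.tremor_depth > 0:
        f0_env *= 1.0 + src.tremor_depth * np.sin(2 * np.pi * src.tremor_hz * t)

    voiced = _source_from_f0_env(f0_env, fs, src.jitter_pct, src.shimmer_db,
                                 src.aspiration_gain, rng)

    # formant tracks ramped at syllable onsets
    targets = np.array([VOWEL_FORMANTS[v] for v in vowels]) * tract_scale
    tracks = np.stack([_ramped_track(targets[:, j], onsets, tr.onset_time_s, n, fs)
                       for j in range(3)], axis=1)
    env = np.stack([_block_env(tracks[:, j], n) for j in range(3)], axis=1)
    voiced = _apply_tract(voiced, fs, env, _FORMANT_BANDWIDTHS)

    # inter-syllable amplitude dips + slow loudness modulation
    amp = np.ones(n)
    dip_len = int(round(0.045 * fs))
    win = 0.5 * (1 - np.cos(2 * np.pi * np.arange(dip_len) / dip_len))  # raised cosine
    for k in range(1, n_syl):
        c = int(round(onsets[k] * fs))
        lo, hi = max(c - dip_len // 2, 0), min(c + dip_len // 2, n)
        amp[lo:hi] *= 1.0 - tr.dip_depth * win[:hi - lo]
    amp *= 1.0 + tr.loudness_var * np.sin(2 * np.pi * 1.1 * t + rng.uniform(0, 2 * np.pi))
    fade = int(round(0.04 * fs))
    amp[:fade] *= np.linspace(0, 1, fade)
    amp[-fade:] *= np.linspace(1, 0, fade)

    return _finalize(voiced * amp, fs, rng, profile.label, speaker_id)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

@dataclass
class Utterance:
    """One corpus entry; audio is synthesized lazily and cached."""

    index: int
    label: str
    label_idx: int
    speaker_id: str
    split: str                    # "train" | "test"
    spec: UtteranceSpec
    _seed: tuple[int, ...] = field(repr=False, default=())
    _profile: DisorderProfile = field(repr=False, default=None)
    _fs: int = field(repr=False, default=44100)
    _f0_base: float = field(repr=False, default=150.0)
    _tract_scale: float = field(repr=False, default=1.0)
    _cache: Optional[Waveform] = field(repr=False, default=None)

    @property
    def waveform(self) -> Waveform:
        if self._cache is None:
            rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(self._seed)))
            self._cache = synth_utterance(
                self.spec, self._profile, rng, fs=self._fs,
                f0_base=self._f0_base, tract_scale=self._tract_scale,
                speaker_id=self.speaker_id)
        return self._cache


@dataclass
class Corpus:
    """A labeled synthetic corpus with a speaker-disjoint partition."""

    config: CorpusConfig
    labels: tuple[str, ...]
    utterances: list[Utterance]

    def __len__(self) -> int:
        return len(self.utterances)

    def split(self, which: str) -> list[Utterance]:
        return [u for u in self.utterances if u.split == which]

    def class_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in self.labels}
        for u in self.utterances:
            out[u.label] += 1
        return out

    def content_hash(self) -> str:
        """SHA-256 over the 16-bit PCM streams of every utterance in order."""
        h = hashlib.sha256()
        for u in self.utterances:
            h.update(u.waveform.to_int16().tobytes())
        return h.hexdigest()

    def write(self, out_dir: str | Path) -> Path:
        """Write WAV files and a manifest CSV; returns the manifest path."""
        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for u in self.utterances:
            name = f"utt{u.index:05d}_{u.label}.wav"
            u.waveform.write(out_dir / name)
            rows.append({"path": name, "label": u.label,
                         "speaker_id": u.speaker_id, "mode": u.spec.mode,
                         "split": u.split})
        manifest = out_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest


def generate_corpus(config: CorpusConfig,
                    profiles: dict[str, DisorderProfile],
                    spec_template: UtteranceSpec) -> Corpus:
    """Generate a labeled corpus with a speaker-disjoint train/test split.

    Each class emits exactly ``class_counts[label]`` utterances spread
    round-robin over ``speakers_per_class`` speakers (default: one speaker
    per utterance); the 80/20-style partition is made at the speaker
    level, so no speaker crosses the train/test boundary.  The same seed
    yields a byte-identical corpus.
    """
    labels = tuple(config.class_counts)
    missing = [lab for lab in labels if lab not in profiles]
    if missing:
        raise ConfigurationError(f"profiles missing for labels: {missing}")
    utterances: list[Utterance] = []
    index = 0
    for label_idx, label in enumerate(labels):
        n_utt = config.class_counts[label]
        if n_utt == 0:
            continue
        n_spk = config.speakers_per_class or n_utt
        if n_spk < 2:
            raise ConfigurationError(
                f"class {label!r}: need >= 2 speakers for a disjoint split")
        n_spk = min(n_spk, n_utt) if n_utt >= 2 else n_spk
        split_rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([config.seed, 42, label_idx])))
        order = split_rng.permutation(n_spk)
        n_train = int(np.clip(round(config.split_fraction * n_spk), 1, n_spk - 1))
        train_speakers = set(order[:n_train].tolist())
        for k in range(n_utt):
            spk = k % n_spk
            spk_rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([config.seed, 7701, label_idx, spk])))
            f0_base = spk_rng.uniform(110.0, 220.0)
            tract_scale = spk_rng.uniform(0.92, 1.08)
            utterances.append(Utterance(
                index=index, label=label, label_idx=label_idx,
                speaker_id=f"{label}-s{spk:04d}",
                split="train" if spk in train_speakers else "test",
                spec=spec_template,
                _seed=(config.seed, label_idx, spk, k),
                _profile=profiles[label], _fs=config.fs,
                _f0_base=f0_base, _tract_scale=tract_scale))
            index += 1
    return Corpus(config=config, labels=labels, utterances=utterances)


# ---------------------------------------------------------------------------
# replica configurations
# ---------------------------------------------------------------------------

def femh_replica_continuous_config(seed: int = 0) -> tuple[CorpusConfig, UtteranceSpec]:
    """Full-corpus continuous-speech replica: 100/103/718/124 = 1,045."""
    cfg = CorpusConfig(class_counts={"FD": 100, "neoplasm": 103,
                                     "phonotrauma": 718, "vocal_palsy": 124},
                       seed=seed)
    return cfg, UtteranceSpec(mode="continuous", script_id=None)


def femh_replica_vowel_config(seed: int = 0) -> tuple[CorpusConfig, UtteranceSpec]:
    """Full-corpus sustained-/a/ replica: 100/102/735/124 = 1,061."""
    cfg = CorpusConfig(class_counts={"FD": 100, "neoplasm": 102,
                                     "phonotrauma": 735, "vocal_palsy": 124},
                       seed=seed)
    return cfg, UtteranceSpec(mode="sustained_vowel", duration_s=3.0)


def challenge_replica_config(seed: int = 0) -> tuple[CorpusConfig, UtteranceSpec]:
    """Balanced three-class challenge replica: 40/60/50 = 150 vowels."""
    cfg = CorpusConfig(class_counts={"neoplasm": 40, "phonotrauma": 60,
                                     "vocal_palsy": 50},
                       seed=seed)
    return cfg, UtteranceSpec(mode="sustained_vowel", duration_s=3.0)
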