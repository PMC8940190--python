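"""MFCC front end: 13 static + 13 delta coefficients per frame.

Chain: pre-emphasis -> 32 ms Hamming frames at 16 ms hop -> magnitude/
power spectrum (2048-point FFT at 44.1 kHz) -> 26 triangular mel filters
-> natural log (floored) -> orthonormal DCT-II keeping coefficients 0-12
-> regression deltas (window N=2, edge replication) appended, giving a
frames x 26 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import dct

from voicedx.synth import Waveform

__all__ = [
    "FramingConfig", "MelFilterbank", "hz_to_mel", "mel_to_hz",
    "frame_signal", "preprocess_frames", "mel_filterbank", "extract_mfcc",
    "delta", "featurize",
]

_LOG_FLOOR = 1e-10
N_STATIC = 13
N_MELS = 26


@dataclass(frozen=True)
class FramingConfig:
    """Frame geometry shared by the VAD and the MFCC front end."""

    frame_ms: float = 32.0
    hop_ms: float = 16.0
    preemph_coeff: float = 0.97
    fft_size: Optional[int] = None   # None: next power of two >= frame length

    def __post_init__(self) -> None:
        if not (self.frame_ms > self.hop_ms > 0):
            raise ValueError("require frame_ms > hop_ms > 0")

    def frame_len(self, fs: float) -> int:
        return int(round(self.frame_ms * fs / 1000.0))

    def hop_len(self, fs: float) -> int:
        return int(round(self.hop_ms * fs / 1000.0))

    def fft_size_for(self, fs: float) -> int:
        if self.fft_size is not None:
            if self.fft_size < self.frame_len(fs):
                raise ValueError("fft_size smaller than frame length")
            return self.fft_size
        return int(2 ** np.ceil(np.log2(self.frame_len(fs))))


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """m(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def frame_signal(x: np.ndarray, fs: float, cfg: FramingConfig,
                 preemphasis: bool = True, window: bool = True) -> np.ndarray:
    """Split a signal into (optionally pre-emphasized, windowed) frames.

    Frame count is ``1 + floor((N - frame_len) / hop_len)``; a signal
    shorter than one frame raises.
    """
    x = np.asarray(x, float)
    flen, hop = cfg.frame_len(fs), cfg.hop_len(fs)
    if len(x) < flen:
        raise ValueError(f"signal shorter than one frame ({len(x)} < {flen})")
    if preemphasis and cfg.preemph_coeff > 0:
        x = np.concatenate([[x[0] * (1.0 - cfg.preemph_coeff)],
                            x[1:] - cfg.preemph_coeff * x[:-1]])
    n_frames = 1 + (len(x) - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    if window:
        frames = frames * np.hamming(flen)
    return frames


def preprocess_frames(w: Waveform, cfg: FramingConfig | None = None) -> np.ndarray:
    """Pre-emphasized, Hamming-windowed frame matrix of a waveform."""
    if cfg is None:
        cfg = FramingConfig()
    return frame_signal(np.asarray(w.samples, float), w.fs, cfg)


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular mel filterbank (n_filters x (1 + fft_size/2))."""

    weights: np.ndarray
    center_freqs: np.ndarray
    fs: float
    fft_size: int

    def apply(self, power_spectra: np.ndarray) -> np.ndarray:
        return power_spectra @ self.weights.T


def mel_filterbank(fs: float, fft_size: int, n_filters: int = N_MELS) -> MelFilterbank:
    """Triangular filters with centers equally spaced on the mel scale.

    Band edges span 0 Hz to fs/2; filter ``i`` rises over
    [edge_i, edge_{i+1}] and falls over [edge_{i+1}, edge_{i+2}].
    """
    n_bins = 1 + fft_size // 2
    edges_mel = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_filters + 2)
    edges_hz = mel_to_hz(edges_mel)
    bin_freqs = np.arange(n_bins) * fs / fft_size
    edge_bins = np.round(edges_hz / fs * fft_size).astype(int)
    if np.any(np.diff(edge_bins[1:-1]) < 1):
        raise ValueError("n_filters too large for the FFT resolution")
    weights = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, ctr, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (bin_freqs - lo) / (ctr - lo)
        falling = (hi - bin_freqs) / (hi - ctr)
        weights[i] = np.maximum(0.0, np.minimum(rising, falling))
    return MelFilterbank(weights=weights, center_freqs=edges_hz[1:-1],
                         fs=fs, fft_size=fft_size)


def extract_mfcc(w: Waveform, cfg: FramingConfig | None = None,
                 fb: MelFilterbank | None = None,
                 speech_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """26-column MFCC matrix (13 static + 13 delta) of a waveform.

    If ``speech_mask`` is given (from the VAD), non-speech frames are
    dropped *before* the delta computation, so deltas describe the kept
    speech stream.  An all-false mask raises, signalling unvoiced input.
    """
    if cfg is None:
        cfg = FramingConfig()
    if fb is None:
        fb = mel_filterbank(w.fs, cfg.fft_size_for(w.fs))
    frames = preprocess_frames(w, cfg)
    if speech_mask is not None:
        speech_mask = np.asarray(speech_mask, bool)
        if speech_mask.shape[0] != frames.shape[0]:
            raise ValueError("speech mask length differs from frame count")
        if not speech_mask.any():
            raise ValueError("no voiced content: speech mask is empty")
        frames = frames[speech_mask]
    spectra = np.abs(np.fft.rfft(frames, n=fb.fft_size, axis=1)) ** 2
    mel_energy = fb.apply(spectra)
    log_mel = np.log(np.maximum(mel_energy, _LOG_FLOOR))
    static = dct(log_mel, type=2, norm="ortho", axis=1)[:, :N_STATIC]
    return np.hstack([static, delta(static)])


def delta(static: np.ndarray, n: int = 2) -> np.ndarray:
    """Regression deltas d_t = sum_k k (c_{t+k} - c_{t-k}) / (2 sum k^2).

    Edges are padded by replication; a single frame yields zeros.
    """
    static = np.atleast_2d(np.asarray(static, float))
    if static.shape[0] < 1:
        raise ValueError("need at least one frame")
    padded = np.vstack([static[:1]] * n + [static] + [static[-1:]] * n)
    denom = 2.0 * sum(k * k for k in range(1, n + 1))
    out = np.zeros_like(static)
    for k in range(1, n + 1):
        out += k * (padded[n + k:n + k + static.shape[0]]
                    - padded[n - k:n - k + static.shape[0]])
    return out / denom


def featurize(w: Waveform, cfg: FramingConfig | None = None,
              fb: MelFilterbank | None = None,
              vad_threshold: float = 0.9) -> np.ndarray:
    """VAD-gated MFCC matrix of one waveform (the standard pipeline)."""
    from voicedx.vad import detect_speech

    decision = detect_speech(w, threshold=vad_threshold, cfg=cfg)
    return extract_mfcc(w, cfg, fb, speech_mask=decision.speech_mask)
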