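"""Statistical-model voice activity detection.

Frames are modeled with complex-Gaussian speech and noise hypotheses; the
per-bin likelihood ratio is

    Lambda_k = exp(gamma_k * xi_k / (1 + xi_k)) / (1 + xi_k)

with a-posteriori SNR ``gamma_k = |X_k|^2 / lambda_N,k`` and
decision-directed a-priori SNR ``xi_k``.  The frame statistic is the
geometric mean of Lambda over bins; its logarithm is smoothed across
frames and compared against the detection threshold (default 0.9 on the
log statistic).  The decision-directed recursion uses the MMSE
short-time spectral-amplitude gain for the previous frame's clean-speech
amplitude estimate.

Framing (32 ms Hamming frames, 16 ms hop) matches the MFCC front end so
the speech mask indexes feature frames one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from voicedx.features import FramingConfig, frame_signal
from voicedx.synth import Waveform

__all__ = [
    "NoiseModel", "SnrEstimates", "VadDecision",
    "spectral_frames", "estimate_noise", "frame_likelihood_ratio",
    "detect_speech",
]

_VAR_FLOOR = 1e-12      # noise-variance floor epsilon
_XI_FLOOR = 1e-3        # a-priori SNR floor
_ALPHA_DD = 0.98        # decision-directed weight
_LLR_SMOOTH = 0.9       # first-order smoothing of the log-LR track
_HANGOVER = 3           # frames held after a speech run
_N_INIT_FRAMES = 6      # leading frames assumed speech-free


@dataclass
class NoiseModel:
    """Per-bin noise variance estimate with recursive smoothing."""

    lambda_noise: np.ndarray
    update_rate: float = 0.95

    def __post_init__(self) -> None:
        self.lambda_noise = np.maximum(np.asarray(self.lambda_noise, float),
                                       _VAR_FLOOR)

    def update(self, power: np.ndarray) -> None:
        """Recursive update on a frame judged speech-free."""
        self.lambda_noise = np.maximum(
            self.update_rate * self.lambda_noise
            + (1.0 - self.update_rate) * power, _VAR_FLOOR)


@dataclass
class SnrEstimates:
    """Per-bin SNR estimates for one or more frames."""

    posterior_gamma: np.ndarray    # (frames, bins) or (bins,)
    prior_xi: np.ndarray
    alpha_dd: float = _ALPHA_DD

    def __post_init__(self) -> None:
        self.posterior_gamma = np.asarray(self.posterior_gamma, float)
        self.prior_xi = np.asarray(self.prior_xi, float)
        if np.any(self.posterior_gamma < 0) or np.any(self.prior_xi < 0):
            raise ValueError("SNR estimates must be non-negative")


@dataclass
class VadDecision:
    """Per-frame speech decision.

    ``log_likelihood_ratio`` is the smoothed (and hangover-held) log of
    the geometric-mean likelihood ratio; the mask satisfies
    ``speech_mask[i] == (log_likelihood_ratio[i] >= threshold)`` exactly.
    """

    speech_mask: np.ndarray
    log_likelihood_ratio: np.ndarray
    threshold: float = 0.9
    raw_log_lr: np.ndarray = field(default=None, repr=False)

    @property
    def n_speech_frames(self) -> int:
        return int(np.sum(self.speech_mask))


def spectral_frames(w: Waveform, cfg: FramingConfig | None = None) -> np.ndarray:
    """Short-time power spectra, (frames, 1 + fft_size/2).

    Uses the MFCC framing geometry (Hamming window) without pre-emphasis.
    """
    if cfg is None:
        cfg = FramingConfig()
    frames = frame_signal(np.asarray(w.samples, float), w.fs, cfg,
                          preemphasis=False, window=True)
    fft_size = cfg.fft_size_for(w.fs)
    spec = np.fft.rfft(frames, n=fft_size, axis=1)
    return np.abs(spec) ** 2


def estimate_noise(frames: np.ndarray, n_init_frames: int = _N_INIT_FRAMES,
                   update_rate: float = 0.95) -> NoiseModel:
    """Initialize the noise model from the leading frames.

    ``frames`` holds per-frame power spectra; the first ``n_init_frames``
    are averaged per bin (assumed speech-free) and floored at epsilon.
    """
    frames = np.atleast_2d(np.asarray(frames, float))
    if frames.shape[0] == 0:
        raise ValueError("empty spectral frame sequence")
    if not (1 <= n_init_frames <= frames.shape[0]):
        raise ValueError("need frames >= n_init_frames >= 1")
    lam = frames[:n_init_frames].mean(axis=0)
    return NoiseModel(lambda_noise=lam, update_rate=update_rate)


def frame_likelihood_ratio(snr: SnrEstimates) -> np.ndarray:
    """Geometric-mean likelihood ratio per frame.

    Per bin, ``Lambda_k = exp(gamma_k xi_k / (1+xi_k)) / (1+xi_k)``; the
    frame value is ``exp(mean_k log Lambda_k)``.  For ``xi = 0`` the
    ratio is exactly 1 regardless of gamma.
    """
    gamma = np.atleast_2d(snr.posterior_gamma)
    xi = np.atleast_2d(snr.prior_xi)
    log_lam = gamma * xi / (1.0 + xi) - np.log1p(xi)
    out = np.exp(log_lam.mean(axis=1))
    return out[0] if snr.posterior_gamma.ndim == 1 else out


def _mmse_stsa_gain(xi: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """MMSE short-time spectral-amplitude gain (Ephraim-Malah)."""
    v = np.clip(xi * gamma / (1.0 + xi), 1e-10, 700.0)
    # exp(-v/2) * [(1+v) I0(v/2) + v I1(v/2)]  via exponentially scaled Bessels
    bessel = (1.0 + v) * i0e(v / 2.0) + v * i1e(v / 2.0)
    gain = (np.sqrt(np.pi) / 2.0) * (np.sqrt(v) / np.maximum(gamma, 1e-10)) * bessel
    return np.minimum(gain, 10.0)


def detect_speech(w: Waveform, threshold: float = 0.9,
                  cfg: FramingConfig | None = None,
                  n_init_frames: int = _N_INIT_FRAMES) -> VadDecision:
    """Flag speech-present frames of a waveform.

    Runs the decision-directed likelihood-ratio detector frame by frame:
    noise variances start from the leading frames and adapt on frames
    judged speech-free; the smoothed log-LR is held high for a short
    hangover and thresholded (default 0.9, log domain).
    """
    if len(w.samples) == 0:
        raise ValueError("empty waveform")
    power = spectral_frames(w, cfg)
    n_frames, n_bins = power.shape
    noise = estimate_noise(power, min(n_init_frames, n_frames))

    raw_llr = np.empty(n_frames)
    smoothed = np.empty(n_frames)
    prev_amp2 = np.zeros(n_bins)         # |A-hat|^2 of the previous frame
    s = 0.0
    for t in range(n_frames):
        lam = noise.lambda_noise
        gamma = power[t] / lam
        xi_inst = np.maximum(gamma - 1.0, 0.0)
        xi = np.maximum(_ALPHA_DD * prev_amp2 / lam
                        + (1.0 - _ALPHA_DD) * xi_inst, _XI_FLOOR)
        log_lam = gamma * xi / (1.0 + xi) - np.log1p(xi)
        llr = float(log_lam.mean())
        raw_llr[t] = llr
        s = llr if t == 0 else _LLR_SMOOTH * s + (1.0 - _LLR_SMOOTH) * llr
        smoothed[t] = s
        gain = _mmse_stsa_gain(xi, gamma)
        prev_amp2 = (gain ** 2) * power[t]
        if llr < threshold:              # instantaneous decision drives adaptation
            noise.update(power[t])

    # hangover: hold the decision statistic at its recent maximum
    stat = smoothed.copy()
    for t in range(n_frames):
        lo = max(t - _HANGOVER, 0)
        stat[t] = smoothed[lo:t + 1].max()
    mask = stat >= threshold
    return VadDecision(speech_mask=mask, log_likelihood_ratio=stat,
                       threshold=threshold, raw_log_lr=raw_llr)
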