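"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
loops, closed-form matrices, direct recursions) and kept independent of
the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks


# ---------------------------------------------------------------------------
# acoustic measurement oracles
# ---------------------------------------------------------------------------

def cycle_peaks(x: np.ndarray, fs: float, f0: float) -> np.ndarray:
    """Glottal-cycle landmark positions via peak picking on |x|."""
    ax = np.abs(x)
    peaks, _ = find_peaks(ax, height=0.3 * ax.max(),
                          distance=int(0.6 * fs / f0))
    return peaks


def measure_jitter_pct(x: np.ndarray, fs: float, f0: float) -> float:
    """Local jitter: mean |T_i - T_{i+1}| / mean T, percent."""
    periods = np.diff(cycle_peaks(x, fs, f0))
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)


def measure_shimmer_db(x: np.ndarray, fs: float, f0: float) -> float:
    """Local shimmer: mean |20 log10(A_{i+1}/A_i)| over cycle peaks, dB."""
    peaks = cycle_peaks(x, fs, f0)
    amps = np.abs(x)[peaks]
    return float(np.mean(np.abs(20.0 * np.log10(amps[1:] / amps[:-1]))))


def measure_hnr_db(x: np.ndarray, fs: float, f0: float) -> float:
    """Comb-average harmonic/noise decomposition HNR in dB."""
    period = int(round(fs / f0))
    n_cycles = len(x) // period
    mat = x[:n_cycles * period].reshape(n_cycles, period)
    harmonic = mat.mean(axis=0)
    residual = mat - harmonic
    p_h = np.sum(harmonic ** 2) * n_cycles
    p_n = np.sum(residual ** 2)
    return float(10.0 * np.log10(p_h / max(p_n, 1e-300)))


def autocorr_at_lag(x: np.ndarray, lag: int) -> float:
    """Normalized autocorrelation at one lag (unbiased normalization)."""
    a, b = x[:-lag], x[lag:]
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def centroid_variance(x: np.ndarray, fs: float, frame: int = 1024,
                      hop: int = 512) -> float:
    """Variance of the spectral centroid over STFT frames (energy-gated)."""
    n_frames = 1 + (len(x) - frame) // hop
    win = np.hanning(frame)
    freqs = np.fft.rfftfreq(frame, 1.0 / fs)
    cents, energies = [], []
    for i in range(n_frames):
        seg = x[i * hop:i * hop + frame] * win
        mag = np.abs(np.fft.rfft(seg))
        e = mag.sum()
        energies.append(e)
        cents.append(np.sum(freqs * mag) / e if e > 0 else 0.0)
    cents = np.array(cents)
    energies = np.array(energies)
    keep = energies > 0.1 * np.median(energies[energies > 0])
    return float(np.var(cents[keep]))


# ---------------------------------------------------------------------------
# reference MFCC chain (independent of voicedx.features)
# ---------------------------------------------------------------------------

def reference_mfcc_static(x: np.ndarray, fs: float, frame_ms: float = 32.0,
                          hop_ms: float = 16.0, preemph: float = 0.97,
                          n_mels: int = 26, n_ceps: int = 13,
                          fft_size: int | None = None,
                          log_floor: float = 1e-10) -> np.ndarray:
    """Static MFCCs computed with explicit loops and closed-form matrices."""
    x = np.asarray(x, float)
    y = np.empty_like(x)
    y[0] = x[0] * (1.0 - preemph)
    for n in range(1, len(x)):
        y[n] = x[n] - preemph * x[n - 1]
    flen = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    if fft_size is None:
        fft_size = 1
        while fft_size < flen:
            fft_size *= 2
    m = np.arange(flen)
    hamming = 0.54 - 0.46 * np.cos(2.0 * np.pi * m / (flen - 1))
    n_frames = 1 + (len(y) - flen) // hop
    n_bins = fft_size // 2 + 1

    # triangular mel weights, evaluated on bin frequencies
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(v):
        return 700.0 * (10.0 ** (v / 2595.0) - 1.0)

    edges = [imel(mel(0.0) + (mel(fs / 2.0) - mel(0.0)) * i / (n_mels + 1))
             for i in range(n_mels + 2)]
    bin_freq = [k * fs / fft_size for k in range(n_bins)]
    weights = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        for k in range(n_bins):
            f = bin_freq[k]
            w = min((f - lo) / (ctr - lo), (hi - f) / (hi - ctr))
            weights[i, k] = max(w, 0.0)

    # orthonormal DCT-II matrix, closed form
    dct_mat = np.zeros((n_ceps, n_mels))
    for i in range(n_ceps):
        scale = np.sqrt((1.0 if i == 0 else 2.0) / n_mels)
        for j in range(n_mels):
            dct_mat[i, j] = scale * np.cos(np.pi * i * (2 * j + 1) / (2 * n_mels))

    out = np.zeros((n_frames, n_ceps))
    for t in range(n_frames):
        seg = y[t * hop:t * hop + flen] * hamming
        power = np.abs(np.fft.rfft(seg, n=fft_size)) ** 2
        logmel = np.log(np.maximum(weights @ power, log_floor))
        out[t] = dct_mat @ logmel
    return out


# ---------------------------------------------------------------------------
# likelihood-ratio and metric oracles
# ---------------------------------------------------------------------------

def lr_oracle(xi: float, gamma: float) -> float:
    """Single-bin Gaussian likelihood ratio, direct evaluation."""
    return float(np.exp(gamma * xi / (1.0 + xi)) / (1.0 + xi))


def brute_force_metrics(cm: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Accuracy / per-class sensitivity / UAR by explicit TP/FN tallies."""
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = cm.sum()
    correct = sum(cm[i, i] for i in range(k))
    sens = np.empty(k)
    for c in range(k):
        tp = cm[c, c]
        fn = sum(cm[c, j] for j in range(k) if j != c)
        sens[c] = 100.0 * tp / (tp + fn)
    return 100.0 * correct / total, sens, float(np.mean(sens))


def brute_force_confusion(preds, truths, k) -> np.ndarray:
    out = np.zeros((k, k), dtype=int)
    for p, t in zip(preds, truths):
        out[t, p] += 1
    return out


# ---------------------------------------------------------------------------
# hand-rolled LSTM / BiLSTM recursion
# ---------------------------------------------------------------------------

def _sig(v):
    return 1.0 / (1.0 + np.exp(-v))


def lstm_reference(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                   b: np.ndarray) -> np.ndarray:
    """Explicit gate-equation LSTM recursion (gate order i, f, g, o)."""
    T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.zeros((T, H))
    for t in range(T):
        a = x[t] @ Wx + h @ Wh + b
        i = _sig(a[:H])
        f = _sig(a[H:2 * H])
        g = np.tanh(a[2 * H:3 * H])
        o = _sig(a[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        out[t] = h
    return out


def bilstm_head_reference(x: np.ndarray, fwd_w, bwd_w, head_W, head_b
                          ) -> np.ndarray:
    """One bidirectional-sum block + softmax head, from the gate equations."""
    y_f = lstm_reference(x, *fwd_w)
    y_b = lstm_reference(x[::-1], *bwd_w)[::-1]
    z = y_f + y_b
    logits = z @ head_W + head_b
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)
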