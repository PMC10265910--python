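"""Shared signal-processing primitives.

All filters here are zero-phase: event timing downstream is compared against a
reference with a 0.25 s half-tolerance, so any systematic group delay would
directly bias the validation statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

G_MPS2 = 9.80665

__all__ = [
    "G_MPS2",
    "zero_phase_fir_lowpass",
    "zero_phase_butter",
    "cwt_gauss",
    "moving_average",
    "moving_sum",
    "positive_peaks_between_zero_crossings",
    "merge_close_events",
    "dominant_frequency",
    "cumtrapz",
]


def _reflect_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with reflected edges so output length == input length.

    The kernel is applied centred; for (anti)symmetric kernels this is exactly
    zero-phase.
    """
    x = np.asarray(x, dtype=float)
    m = len(kernel)
    if len(x) == 0:
        return x.copy()
    half = m // 2
    pad = min(half, max(len(x) - 1, 1))
    xp = np.pad(x, half, mode="reflect") if len(x) > 1 else np.pad(x, half, mode="edge")
    y = np.convolve(xp, kernel, mode="same")
    return y[half: half + len(x)]


def zero_phase_fir_lowpass(x: np.ndarray, fs: float, cutoff_hz: float,
                           numtaps: int | None = None) -> np.ndarray:
    """Linear-phase windowed-sinc low-pass applied centred (zero phase).

    Default order is ~1 s of signal (``ceil(fs)`` taps, forced odd).
    """
    x = np.asarray(x, dtype=float)
    if numtaps is None:
        numtaps = int(np.ceil(fs)) | 1
    # keep the kernel shorter than the data to avoid pure edge content
    if numtaps >= len(x):
        numtaps = max(3, (len(x) // 2) * 2 - 1)
    b = signal.firwin(numtaps, cutoff_hz, fs=fs)
    return _reflect_convolve(x, b)


def zero_phase_butter(x: np.ndarray, fs: float, cutoff_hz, order: int = 2,
                      btype: str = "lowpass") -> np.ndarray:
    """Butterworth filter applied forward-backward (``sosfiltfilt``)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        return x.copy()
    sos = signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_pad, len(x) - 2)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def _gauss_kernel(scale: float, order: int) -> np.ndarray:
    """Sampled derivative-of-Gaussian wavelet at the given (sample-domain) scale.

    order=1: first derivative (antisymmetric); order=2: second derivative
    (symmetric, negative centre).  Support is +-5 scale units.
    """
    half = max(int(np.ceil(5.0 * scale)), 1)
    u = np.arange(-half, half + 1, dtype=float) / scale
    g = np.exp(-(u ** 2))
    if order == 1:
        k = -2.0 * u * g
    elif order == 2:
        k = (4.0 * u ** 2 - 2.0) * g
    else:
        raise ValueError(f"unsupported wavelet order {order}")
    return k / np.sqrt(scale)


def cwt_gauss(x: np.ndarray, scale: float, order: int) -> np.ndarray:
    """Single-scale continuous wavelet transform with a Gaussian-derivative wavelet.

    Returns one coefficient per sample (reflected edges).  ``scale`` is in
    samples, as in the usual sample-domain CWT convention.
    """
    return _reflect_convolve(np.asarray(x, dtype=float), _gauss_kernel(scale, order))


def moving_average(x: np.ndarray, win_samples: int) -> np.ndarray:
    win = max(int(win_samples), 1)
    return _reflect_convolve(x, np.full(win, 1.0 / win))


def moving_sum(x: np.ndarray, win_samples: int) -> np.ndarray:
    win = max(int(win_samples), 1)
    return _reflect_convolve(x, np.full(win, 1.0))


def cumtrapz(x: np.ndarray, fs: float) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid
    return cumulative_trapezoid(np.asarray(x, dtype=float), dx=1.0 / fs, initial=0.0)


def positive_peaks_between_zero_crossings(y: np.ndarray) -> np.ndarray:
    """Indices of the maximum within every positive excursion of ``y``.

    An excursion is a maximal run of strictly positive samples; runs touching
    the array ends are kept (their maximum is still well defined).
    """
    y = np.asarray(y, dtype=float)
    pos = y > 0
    if not pos.any():
        return np.array([], dtype=int)
    edges = np.flatnonzero(np.diff(pos.astype(np.int8)))
    starts = list(edges[~pos[edges]] + 1)
    ends = list(edges[pos[edges]] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(len(y))
    return np.array([s + int(np.argmax(y[s:e])) for s, e in zip(starts, ends)],
                    dtype=int)


def merge_close_events(times: np.ndarray, min_gap_s: float = 0.2) -> np.ndarray:
    """Drop events closer than ``min_gap_s`` to their predecessor (keep the earlier)."""
    times = np.sort(np.asarray(times, dtype=float))
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_gap_s:
            kept.append(t)
    return np.array(kept)


def dominant_frequency(x: np.ndarray, fs: float, band_hz=(0.5, 3.0)) -> float:
    """Frequency of the power-spectrum maximum inside ``band_hz`` (zero-padded FFT)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    nfft = max(4096, int(2 ** np.ceil(np.log2(max(len(x), 2)))))
    freqs, pxx = signal.periodogram(x, fs=fs, nfft=nfft)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not sel.any() or not np.any(pxx[sel] > 0):
        return float((band_hz[0] + band_hz[1]) / 2.0)
    return float(freqs[sel][np.argmax(pxx[sel])])
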