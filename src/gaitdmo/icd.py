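"""Initial-contact detection within gait sequences.

Four detectors sharing a common contract: given a recording and a gait
sequence they return the IC event times (seconds from recording start).
Detectors may read up to ``margin_s`` (default 1 s) beyond the sequence, the
same margin used by the refinement rule.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from . import _dsp
from .exceptions import BoundsError, InsufficientEventsError, UndefinedSymmetryError
from .io import GaitSequence, ImuRecording

__all__ = [
    "InitialContactList", "RefinedSequence",
    "detect_icd_a", "detect_icd_b", "detect_icd_c", "detect_icd_d",
    "symmetry_index", "refine_sequence", "detect",
]

#: sample-domain CWT scale quoted for a 100 Hz stream; rescaled for other rates
CWT_SCALE_AT_100HZ = 9.0
#: approximate centre frequency (cycles/sample at scale 1) of the gaus1 wavelet
GAUS1_CENTER_FREQ = 0.2
#: moving-average window for the impaired-gait smoothing passes; below the
#: 0.2 s stride-validity floor so true events survive
SMOOTH_WIN_S = 0.15


class InitialContactList:
    """Ordered IC times within (the margin of) one gait sequence."""

    def __init__(self, ic_times_s, source_sequence: GaitSequence):
        times = _dsp.merge_close_events(np.asarray(ic_times_s, dtype=float))
        lo = source_sequence.start_s - 1.0
        hi = source_sequence.end_s + 1.0
        self.ic_times_s = times[(times >= lo) & (times <= hi)]
        self.source_sequence = source_sequence

    def __len__(self) -> int:
        return len(self.ic_times_s)

    def __iter__(self):
        return iter(self.ic_times_s)

    def __repr__(self) -> str:
        return f"InitialContactList(n={len(self)}, gs={self.source_sequence})"


class RefinedSequence(GaitSequence):
    """Gait sequence re-anchored to the detected ICs (+-1 s)."""


def _slice_bounds(rec: ImuRecording, gs: GaitSequence, margin_s: float) -> tuple[int, int]:
    if gs.start_s > rec.duration_s or gs.end_s < 0:
        raise BoundsError(f"gait sequence {gs} outside recording of "
                          f"{rec.duration_s:.2f} s")
    i0 = max(rec.index_of(gs.start_s - margin_s), 0)
    i1 = min(rec.index_of(gs.end_s + margin_s), len(rec))
    return i0, i1


def _cwt_scale(fs: float) -> float:
    return CWT_SCALE_AT_100HZ * fs / 100.0


def _icd_a_transform(rec: ImuRecording, gs: GaitSequence, margin_s: float,
                     smooth_passes: int = 0) -> tuple[np.ndarray, int]:
    fs = rec.sampling_rate_hz
    i0, i1 = _slice_bounds(rec, gs, margin_s)
    x = rec.acc_v[i0:i1]
    if len(x) < 4:
        return np.zeros(len(x)), i0
    x = signal.detrend(x, type="linear")
    x = _dsp.zero_phase_fir_lowpass(x, fs, 3.2)
    y = _dsp.cumtrapz(x, fs)
    # the chain (integrate, then second-derivative wavelet) differentiates the
    # smoothed signal once; heel-strike features come out as positive maxima
    w = _dsp.cwt_gauss(y, _cwt_scale(fs), order=2)
    for _ in range(smooth_passes):
        w = _dsp.moving_average(w, int(round(SMOOTH_WIN_S * fs)))
    return w, i0


def detect_icd_a(rec: ImuRecording, gs: GaitSequence,
                 margin_s: float = 1.0) -> InitialContactList:
    """CWT detector on the vertical axis.

    Detrend, zero-phase FIR low-pass at 3.2 Hz, cumulative trapezoidal
    integration, then differentiation by a second-derivative-of-Gaussian CWT at
    scale 9 (for 100 Hz).  ICs are the positive maxima between zero-crossings.
    """
    w, i0 = _icd_a_transform(rec, gs, margin_s)
    idx = _dsp.positive_peaks_between_zero_crossings(w)
    fs = rec.sampling_rate_hz
    return InitialContactList((i0 + idx) / fs, gs)


def detect_icd_b(rec: ImuRecording, gs: GaitSequence,
                 margin_s: float = 1.0) -> InitialContactList:
    """CWT detector on the AP axis with a signal-adapted wavelet scale.

    Butterworth order-2 low-pass at 10 Hz (zero phase), integration, then a
    first-derivative-of-Gaussian CWT whose scale follows the dominant gait
    frequency of the pre-processed signal; ICs from peak detection.
    """
    fs = rec.sampling_rate_hz
    i0, i1 = _slice_bounds(rec, gs, margin_s)
    x = rec.acc_ap[i0:i1]
    if len(x) < 8:
        return InitialContactList([], gs)
    x = signal.detrend(x, type="linear")
    x = _dsp.zero_phase_butter(x, fs, 10.0, order=2)
    if not np.any(np.abs(x) > 1e-12):
        return InitialContactList([], gs)
    y = _dsp.cumtrapz(x, fs)
    f_dom = _dsp.dominant_frequency(x, fs)
    scale = max(GAUS1_CENTER_FREQ * fs / f_dom, 2.0)
    w = _dsp.cwt_gauss(y, scale, order=1)
    idx, _ = signal.find_peaks(w, distance=max(int(0.2 * fs), 1),
                               height=0.2 * np.max(np.abs(w)))
    return InitialContactList((i0 + idx) / fs, gs)


def symmetry_index(rec: ImuRecording, gs: GaitSequence) -> float:
    """Step-to-stride regularity ratio from the unbiased autocorrelation
    of the detrended vertical acceleration, clipped to [0, 1].

    Raises :class:`UndefinedSymmetryError` for degenerate or too-short
    sequences; callers fall back to a symmetric default.
    """
    fs = rec.sampling_rate_hz
    if gs.duration_s < 3.0:
        raise UndefinedSymmetryError("sequence shorter than 3 s")
    sl = rec.slice_samples(gs.start_s, gs.end_s)
    x = rec.acc_v[sl]
    x = x - np.mean(x)
    n = len(x)
    if n < int(fs) or float(np.std(x)) < 1e-9:
        raise UndefinedSymmetryError("signal has no structure")
    ac = signal.correlate(x, x, mode="full")[n - 1:]
    ac = ac / (n - np.arange(n))          # unbiased
    ac = ac / ac[0]
    lo = int(0.2 * fs)
    hi = min(int(3.0 * fs), n - 1)
    if hi <= lo + 2:
        raise UndefinedSymmetryError("sequence too short for autocorrelation")
    peaks, _ = signal.find_peaks(ac[lo:hi])
    if len(peaks) == 0:
        raise UndefinedSymmetryError("no periodic structure")
    step_lag = lo + peaks[0]
    stride_target = 2 * step_lag
    cand = peaks[np.argmin(np.abs((lo + peaks) - stride_target))] + lo
    a_step, a_stride = float(ac[step_lag]), float(ac[cand])
    if a_stride <= 0:
        raise UndefinedSymmetryError("non-positive stride regularity")
    return float(np.clip(a_step / a_stride, 0.0, 1.0))


def detect_icd_c(rec: ImuRecording, gs: GaitSequence,
                 margin_s: float = 1.0) -> InitialContactList:
    """Impairment-adaptive variant of the vertical-axis CWT detector.

    Dispatches on the symmetry index: > 0.5 uses the plain pipeline; 0.25-0.5
    adds one moving-average pass after the CWT; < 0.25 adds two.
    """
    try:
        si = symmetry_index(rec, gs)
    except UndefinedSymmetryError:
        si = 1.0
    if si > 0.5:
        passes = 0
    elif si >= 0.25:
        passes = 1
    else:
        passes = 2
    w, i0 = _icd_a_transform(rec, gs, margin_s, smooth_passes=passes)
    idx = _dsp.positive_peaks_between_zero_crossings(w)
    return InitialContactList((i0 + idx) / rec.sampling_rate_hz, gs)


def detect_icd_d(rec: ImuRecording, gs: GaitSequence,
                 margin_s: float = 1.0,
                 sum_win_s: float = 0.1,
                 hysteresis_frac: float = 0.5) -> InitialContactList:
    """Zero-crossing detector on the acceleration norm.

    Sliding-window moving sum for denoising, first difference to drop the
    gravity baseline, then upward zero-crossings mark the ICs.  A crossing
    only counts once the slope has swung below/above ``hysteresis_frac`` times
    the median |slope| (small-amplitude noise wiggles produce sign changes but
    never a full swing).
    """
    fs = rec.sampling_rate_hz
    i0, i1 = _slice_bounds(rec, gs, margin_s)
    x = rec.acc_norm[i0:i1]
    if len(x) < 4:
        return InitialContactList([], gs)
    s = _dsp.moving_sum(x, int(round(sum_win_s * fs)))
    d = np.diff(s)
    eps = hysteresis_frac * float(np.median(np.abs(d)))
    if eps <= 1e-12:
        return InitialContactList([], gs)
    events = []
    armed = False
    cross = None
    for j in range(1, len(d)):
        if d[j] < -eps:
            armed = True
            cross = None
        elif armed:
            if cross is None and d[j] >= 0 and d[j - 1] < 0:
                cross = j
            if cross is not None and d[j] > eps:
                events.append(cross)
                armed = False
    return InitialContactList((i0 + np.asarray(events)) / fs if events else [], gs)


def refine_sequence(ics: InitialContactList, rec: ImuRecording) -> RefinedSequence:
    """Re-anchor a sequence to [first IC - 1 s, last IC + 1 s], clipped to
    the recording."""
    if len(ics) == 0:
        raise InsufficientEventsError("cannot refine a sequence with no ICs")
    start = max(float(ics.ic_times_s[0]) - 1.0, 0.0)
    end = min(float(ics.ic_times_s[-1]) + 1.0, rec.duration_s)
    return RefinedSequence(start, end)


_DETECTORS = {"a": detect_icd_a, "b": detect_icd_b, "c": detect_icd_c,
              "d": detect_icd_d}


def detect(rec: ImuRecording, gs: GaitSequence, algo: str,
           margin_s: float = 1.0) -> InitialContactList:
    """Dispatch by algorithm letter: ``a`` | ``b`` | ``c`` | ``d``."""
    try:
        fn = _DETECTORS[algo.lower()]
    except KeyError:
        raise ValueError(f"unknown ICD algorithm {algo!r}") from None
    return fn(rec, gs, margin_s=margin_s)
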