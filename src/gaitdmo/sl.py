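"""Stride length estimation per gait sequence.

Four estimators: two inverted-pendulum variants differing only in the
calibration constant ``k`` (with a cohort-specific value for MS in the B
variant), an acceleration-intensity model, and a hybrid combining an AP
double-integration displacement with a geometric intensity model.

All integrations run in SI units (g inputs converted to m/s^2); drift is
handled by the stated zero-phase high-pass cutoffs only (0.1 Hz on
acceleration, 1 Hz on velocity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _dsp
from ._dsp import G_MPS2
from .exceptions import InsufficientEventsError
from .io import ImuRecording, SubjectInfo

__all__ = ["SlParams", "StrideLengthResult", "vertical_displacement",
           "sl_pendulum", "sl_intensity", "sl_hybrid", "params_for",
           "estimate_stride_length"]

K_PENDULUM_A = 4.739
K_PENDULUM_B = 4.99
K_PENDULUM_B_MS = 4.587
T_INTENSITY_C = 0.93
T_INTENSITY_D = 0.85

HP_ACC_HZ = 0.1
HP_VEL_HZ = 1.0
_HP_ORDER = 4


@dataclass(frozen=True)
class SlParams:
    k: float = K_PENDULUM_A   # pendulum calibration factor
    t: float = T_INTENSITY_C  # intensity calibration factor
    p: float = 0.0            # additive offset, metres (foot length/size)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.t <= 0 or self.p < 0:
            raise ValueError("need k > 0, t > 0, p >= 0")


def params_for(algo: str, subject: SubjectInfo) -> SlParams:
    """Calibration constants for an algorithm letter and subject."""
    algo = algo.lower()
    if algo == "a":
        return SlParams(k=K_PENDULUM_A)
    if algo == "b":
        k = K_PENDULUM_B_MS if subject.cohort == "MS" else K_PENDULUM_B
        return SlParams(k=k)
    if algo == "c":
        return SlParams(t=T_INTENSITY_C, p=subject.foot_length_m)
    if algo == "d":
        return SlParams(t=T_INTENSITY_D, p=subject.foot_length_m)
    raise ValueError(f"unknown SL algorithm {algo!r}")


@dataclass
class StrideLengthResult:
    start_s: float
    stop_s: float
    sl_per_sec: np.ndarray        # metres, one value per elapsed second
    sl_mean: float                # metres
    sl_std: float                 # metres
    distance_m: float             # sum of emitted per-step lengths
    step_lengths_m: np.ndarray    # per-step forward progress, metres
    warning: bool = False

    def to_dict(self) -> dict:
        return {"start_s": self.start_s, "stop_s": self.stop_s,
                "sl_per_sec": list(map(float, self.sl_per_sec)),
                "sl_mean": self.sl_mean, "sl_std": self.sl_std,
                "distance_m": self.distance_m, "warning": self.warning}


def _ic_array(ics) -> np.ndarray:
    t = np.asarray(getattr(ics, "ic_times_s", ics), dtype=float)
    if len(t) < 2:
        raise InsufficientEventsError("need >= 2 ICs for stride length")
    return t


def _double_integrate(acc_g: np.ndarray, fs: float) -> np.ndarray:
    """Acceleration (g) -> drift-corrected position (m)."""
    a = np.asarray(acc_g, dtype=float) * G_MPS2
    a = a - np.mean(a)
    a = _dsp.zero_phase_butter(a, fs, HP_ACC_HZ, order=_HP_ORDER, btype="highpass")
    v = _dsp.cumtrapz(a, fs)
    v = _dsp.zero_phase_butter(v, fs, HP_VEL_HZ, order=_HP_ORDER, btype="highpass")
    return _dsp.cumtrapz(v, fs)


def _hp_gain(f_hz: float, fs: float) -> float:
    """Combined forward-backward amplitude response of the two drift filters
    at frequency ``f_hz``.

    The 1 Hz velocity high-pass halves the excursion of a 60 steps/min walker
    exactly (its step frequency sits on the cutoff); dividing the known
    response back out removes that systematic bias without touching the drift
    rejection.
    """
    from scipy import signal as _sig
    gain = 1.0
    for cutoff in (HP_ACC_HZ, HP_VEL_HZ):
        sos = _sig.butter(_HP_ORDER, cutoff, btype="highpass", fs=fs, output="sos")
        _, h = _sig.sosfreqz(sos, worN=[f_hz], fs=fs)
        gain *= float(np.abs(h[0])) ** 2   # filtfilt applies |H| twice
    return max(gain, 0.05)


def _per_step(rec: ImuRecording, ic_t: np.ndarray, series: np.ndarray, i0: int,
              reducer) -> tuple[np.ndarray, bool]:
    """Apply ``reducer`` to ``series`` restricted to each step interval."""
    fs = rec.sampling_rate_hz
    out = []
    skipped = False
    for a, b in zip(ic_t, ic_t[1:]):
        if b - a < 0.2:
            warnings.warn(f"step of {b - a:.3f} s skipped (< 0.2 s)", stacklevel=3)
            skipped = True
            continue
        ja = max(rec.index_of(a) - i0, 0)
        jb = min(rec.index_of(b) - i0 + 1, len(series))
        seg = series[ja:jb]
        out.append(reducer(seg) if len(seg) else 0.0)
    return np.asarray(out, dtype=float), skipped


def vertical_displacement(rec: ImuRecording, ics, pad_s: float = 1.0
                          ) -> np.ndarray:
    """Per-step vertical centre-of-mass excursion ``h`` (metres).

    Double integration of the vertical acceleration with zero-phase high-pass
    drift correction; ``h`` for a step is the position range between its two
    bounding ICs.
    """
    ic_t = _ic_array(ics)
    fs = rec.sampling_rate_hz
    i0 = max(rec.index_of(ic_t[0] - pad_s), 0)
    i1 = min(rec.index_of(ic_t[-1] + pad_s), len(rec))
    pos = _double_integrate(rec.acc_v[i0:i1], fs)
    h, _ = _per_step(rec, ic_t, pos, i0, lambda seg: float(np.ptp(seg)))
    # compensate the known zero-phase filter attenuation at the step frequency
    f_step = 1.0 / float(np.median(np.diff(ic_t)))
    return h / _hp_gain(f_step, fs)


def _aggregate(ic_t: np.ndarray, stride_est: np.ndarray, warning: bool
               ) -> StrideLengthResult:
    """Common result assembly from per-step stride-length estimates."""
    start, stop = float(ic_t[0]), float(ic_t[-1])
    steps = np.asarray(stride_est, dtype=float)
    step_lengths = steps / 2.0           # forward progress per step
    n_tiles = max(int(np.ceil(stop - start)), 1)
    # mean stride-length estimate of the steps overlapping each 1 s tile
    sl_sec = np.empty(n_tiles)
    mids = (ic_t[:-1] + ic_t[1:]) / 2.0
    mids = mids[:len(steps)] if len(mids) != len(steps) else mids
    for i in range(n_tiles):
        lo, hi = start + i, start + i + 1
        sel = (ic_t[1:][:len(steps)] > lo) & (ic_t[:-1][:len(steps)] < hi)
        sl_sec[i] = float(np.mean(steps[sel])) if sel.any() else 0.0
    return StrideLengthResult(
        start_s=start, stop_s=stop, sl_per_sec=sl_sec,
        sl_mean=float(np.mean(steps)) if len(steps) else 0.0,
        sl_std=float(np.std(steps)) if len(steps) else 0.0,
        distance_m=float(np.sum(step_lengths)),
        step_lengths_m=step_lengths, warning=warning)


def sl_pendulum(rec: ImuRecording, ics, subject: SubjectInfo,
                params: SlParams | None = None) -> StrideLengthResult:
    """Inverted-pendulum stride length: ``k * sqrt(2 l h - h^2)`` per step."""
    params = params or SlParams(k=K_PENDULUM_A)
    ic_t = _ic_array(ics)
    h = vertical_displacement(rec, ics)
    ell = subject.leg_length_m
    warning = False
    if np.any(h >= 2 * ell):
        warnings.warn("vertical excursion >= 2 x leg length; clipping", stacklevel=2)
        warning = True
    inner = np.clip(2.0 * ell * h - h ** 2, 0.0, None)
    stride_est = params.k * np.sqrt(inner)
    stride_est[stride_est < 1e-9] = 0.0
    if np.any(stride_est == 0):
        warning = True
    return _aggregate(ic_t, stride_est, warning)


def sl_intensity(rec: ImuRecording, ics, subject: SubjectInfo,
                 params: SlParams | None = None) -> StrideLengthResult:
    """Acceleration-intensity stride length: ``t * cbrt(mean|a_v|) + p``.

    ``a_v`` is the gravity-removed vertical acceleration in m/s^2; the additive
    offset ``p`` defaults to the subject's foot length.
    """
    params = params or SlParams(t=T_INTENSITY_C, p=subject.foot_length_m)
    ic_t = _ic_array(ics)
    fs = rec.sampling_rate_hz
    i0 = max(rec.index_of(ic_t[0]), 0)
    i1 = min(rec.index_of(ic_t[-1]) + 1, len(rec))
    av = (rec.acc_v[i0:i1] - np.median(rec.acc_v[i0:i1])) * G_MPS2
    a_mean, skipped = _per_step(rec, ic_t, np.abs(av), i0,
                                lambda seg: float(np.mean(seg)))
    stride_est = params.t * np.cbrt(a_mean) + params.p
    return _aggregate(ic_t, stride_est, skipped)


def sl_hybrid(rec: ImuRecording, ics, subject: SubjectInfo,
              params: SlParams | None = None) -> StrideLengthResult:
    """Hybrid stride length: mean of an AP double-integration displacement and
    the geometric model ``t * (a_v range)^(1/4) + p`` per step."""
    params = params or SlParams(t=T_INTENSITY_D, p=subject.foot_length_m)
    ic_t = _ic_array(ics)
    fs = rec.sampling_rate_hz
    pad = 1.0
    i0 = max(rec.index_of(ic_t[0] - pad), 0)
    i1 = min(rec.index_of(ic_t[-1] + pad), len(rec))
    pos_ap = _double_integrate(rec.acc_ap[i0:i1], fs)
    disp, skipped = _per_step(rec, ic_t, pos_ap, i0, lambda seg: float(np.ptp(seg)))

    av = (rec.acc_v[i0:i1] - np.median(rec.acc_v[i0:i1])) * G_MPS2
    a_range, _ = _per_step(rec, ic_t, av, i0, lambda seg: float(np.ptp(seg)))
    geometric = params.t * np.power(np.clip(a_range, 0.0, None), 0.25) + params.p
    n = min(len(disp), len(geometric))
    stride_est = (disp[:n] + geometric[:n]) / 2.0
    return _aggregate(ic_t, stride_est, skipped)


_ESTIMATORS = {"a": sl_pendulum, "b": sl_pendulum, "c": sl_intensity,
               "d": sl_hybrid}


def estimate_stride_length(rec: ImuRecording, ics, subject: SubjectInfo,
                           algo: str, params: SlParams | None = None
                           ) -> StrideLengthResult:
    """Dispatch by algorithm letter: ``a`` | ``b`` | ``c`` | ``d``."""
    algo = algo.lower()
    if algo not in _ESTIMATORS:
        raise ValueError(f"unknown SL algorithm {algo!r}")
    params = params or params_for(algo, subject)
    return _ESTIMATORS[algo](rec, ics, subject, params)
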