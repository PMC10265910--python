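"""Gait sequence detection from raw lower-back acceleration.

Three detectors are provided: a frequency-domain one working on the vertical
and anterior-posterior axes (``detect_gsd_a``) and a time-domain step-grouping
one on the acceleration norm with two peak thresholds
(``detect_gsd_peaks`` -- 0.1 g and 0.15 g variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from . import _dsp
from .io import GaitSequence, ImuRecording

__all__ = ["GsdParams", "detect_gsd_a", "detect_gsd_peaks", "detect"]


@dataclass(frozen=True)
class GsdParams:
    win_s: float = 3.0
    overlap_s: float = 1.5
    activity_thresh: float = 0.01       # g, std of band-passed signal in a window
    peak_thresh_g: float = 0.1          # 0.1 for the B variant, 0.15 for C
    band_hz: tuple[float, float] = (0.5, 3.0)
    lp_cut_hz: float = 3.2
    max_break_s: float = 3.0
    min_steps: int = 4                  # a bout needs >= 2 strides per foot

    def __post_init__(self) -> None:
        if not (0 < self.overlap_s < self.win_s):
            raise ValueError("need 0 < overlap_s < win_s")
        if self.peak_thresh_g <= 0:
            raise ValueError("peak_thresh_g must be > 0")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band lower edge must be below upper edge")


def _merge_sequences(seqs: list[GaitSequence], max_break_s: float) -> list[GaitSequence]:
    if not seqs:
        return []
    seqs = sorted(seqs)
    merged = [seqs[0]]
    for s in seqs[1:]:
        if s.start_s - merged[-1].end_s < max_break_s:
            merged[-1] = GaitSequence(merged[-1].start_s, max(merged[-1].end_s, s.end_s))
        else:
            merged.append(s)
    return merged


def detect_gsd_a(rec: ImuRecording, params: GsdParams | None = None) -> list[GaitSequence]:
    """Frequency-based detector on the vertical and AP axes.

    Band-passes both axes to the gait band, convolves with a one-cycle 2 Hz
    sine template, and flags windows of ``win_s`` (hop ``win_s - overlap_s``)
    whose band-passed activity exceeds ``activity_thresh`` and whose convolved
    signal shows repeated gait-band maxima.  Flagged windows are merged and
    the merged intervals are trimmed to the sample-level activity envelope.
    """
    params = params or GsdParams()
    fs = rec.sampling_rate_hz
    if rec.duration_s < params.win_s:
        warnings.warn("recording shorter than one analysis window", stacklevel=2)
        return []

    bp_v = _dsp.zero_phase_butter(rec.acc_v - np.mean(rec.acc_v), fs, params.band_hz,
                                  order=2, btype="bandpass")
    bp_ap = _dsp.zero_phase_butter(rec.acc_ap - np.mean(rec.acc_ap), fs, params.band_hz,
                                   order=2, btype="bandpass")

    # one gait-cycle template: a single cycle of a 2 Hz sine
    n_template = max(int(round(fs / 2.0)), 2)
    template = np.sin(2 * np.pi * np.arange(n_template) / n_template)
    conv = (np.convolve(bp_v, template, mode="same")
            + np.convolve(bp_ap, template, mode="same")) / n_template

    win = int(round(params.win_s * fs))
    hop = int(round((params.win_s - params.overlap_s) * fs))
    n = len(rec)
    flagged: list[GaitSequence] = []
    for i0 in range(0, max(n - win + 1, 1), hop):
        seg_v = bp_v[i0:i0 + win]
        seg_ap = bp_ap[i0:i0 + win]
        activity = max(float(np.std(seg_v)), float(np.std(seg_ap)))
        if activity <= params.activity_thresh:
            continue
        seg_conv = conv[i0:i0 + win]
        peaks, _ = signal.find_peaks(seg_conv, prominence=0.5 * np.std(seg_conv),
                                     distance=max(int(fs / params.band_hz[1]), 1))
        # repeated maxima at a gait-band rate
        lo = params.band_hz[0] * params.win_s
        hi = params.band_hz[1] * params.win_s + 1
        if lo <= len(peaks) <= hi:
            flagged.append(GaitSequence(i0 / fs, min(i0 + win, n) / fs))

    merged = _merge_sequences(flagged, params.max_break_s)
    return [s for s in (_trim_to_activity(s, bp_v, bp_ap, fs, params) for s in merged)
            if s is not None]


def _trim_to_activity(seq: GaitSequence, bp_v: np.ndarray, bp_ap: np.ndarray,
                      fs: float, params: GsdParams) -> GaitSequence | None:
    """Tighten window-quantised boundaries to the sample-level envelope."""
    i0, i1 = int(seq.start_s * fs), int(seq.end_s * fs)
    env_win = max(int(0.5 * fs), 2)
    seg = np.abs(bp_v[i0:i1]) + np.abs(bp_ap[i0:i1])
    env = _dsp.moving_average(seg, env_win)
    # absolute floor plus a relative gate against filter ringing at the edges
    gate = max(params.activity_thresh, 0.25 * float(np.max(env, initial=0.0)))
    active = np.flatnonzero(env > gate)
    if active.size == 0:
        return None
    start = (i0 + active[0]) / fs
    end = (i0 + active[-1] + 1) / fs
    if end - start < 2.0 / params.band_hz[1]:  # shorter than two fast steps
        return None
    return GaitSequence(start, end)


def detect_gsd_peaks(rec: ImuRecording, params: GsdParams | None = None) -> list[GaitSequence]:
    """Step-grouping detector on the acceleration norm.

    Low-passes the norm, removes the gravity offset (recording-median norm),
    finds peaks above ``peak_thresh_g`` and groups consecutive peaks whose
    spacing stays below an adaptive step-duration threshold
    (``max(1.5 x running median of the last 5 intervals, 0.5 s)``, capped at
    3 s).  Groups of at least ``min_steps`` peaks become gait sequences.
    """
    params = params or GsdParams()
    fs = rec.sampling_rate_hz
    if rec.duration_s < params.win_s:
        warnings.warn("recording shorter than one analysis window", stacklevel=2)
        return []

    norm = rec.acc_norm
    lp = _dsp.zero_phase_fir_lowpass(norm, fs, params.lp_cut_hz)
    lp = lp - np.median(lp)  # gravity offset: the at-rest norm is ~1 g

    min_dist = max(int(0.2 * fs), 1)
    peak_idx, _ = signal.find_peaks(lp, height=params.peak_thresh_g, distance=min_dist)
    if len(peak_idx) == 0:
        return []
    peak_t = peak_idx / fs

    groups: list[list[float]] = [[peak_t[0]]]
    history: list[float] = []
    for prev, cur in zip(peak_t, peak_t[1:]):
        gap = cur - prev
        if history:
            thresh = max(1.5 * float(np.median(history[-5:])), 0.5)
        else:
            thresh = 3.0
        thresh = min(thresh, 3.0)
        if gap <= thresh:
            groups[-1].append(cur)
            history.append(gap)
        else:
            groups.append([cur])
    seqs = []
    for g in groups:
        if len(g) < params.min_steps:
            continue
        step = float(np.median(np.diff(g)))
        seqs.append(GaitSequence(max(g[0] - step / 2, 0.0),
                                 min(g[-1] + step / 2, rec.duration_s)))
    return _merge_sequences(seqs, params.max_break_s)


_ALGOS = {"a": ("detect_gsd_a", 0.1), "b": ("detect_gsd_peaks", 0.1),
          "c": ("detect_gsd_peaks", 0.15)}


def detect(rec: ImuRecording, algo: str, params: GsdParams | None = None) -> list[GaitSequence]:
    """Dispatch by algorithm letter: ``a`` | ``b`` | ``c``."""
    algo = algo.lower()
    if algo not in _ALGOS:
        raise ValueError(f"unknown GSD algorithm {algo!r}")
    params = params or GsdParams()
    if algo == "a":
        return detect_gsd_a(rec, params)
    params = replace(params, peak_thresh_g=_ALGOS[algo][1])
    return detect_gsd_peaks(rec, params)
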