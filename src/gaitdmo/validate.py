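"""Technical-validation framework: window classification, IC matching,
performance measures, agreement statistics and error-vs-covariate modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DataError
from .io import GaitSequence, WalkingBout

__all__ = [
    "ConfusionCounts", "AgreementStats", "BinnedErrorCurve", "MatchResult",
    "classify_gsd_windows", "match_ics", "confusion_measures",
    "agreement_stats", "binned_error_fit", "gsd_duration_agreement",
    "icc_2_1",
]

#: IC matching: 0.5 s tolerance window centred on the reference event
IC_TOL_S = 0.5


@dataclass
class ConfusionCounts:
    """Event counts; ``tn`` is None where true negatives are not defined
    (IC matching)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.tn is not None and self.tn < 0:
            raise DataError("tn must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + (self.tn or 0)


@dataclass
class MatchResult:
    counts: ConfusionCounts
    abs_errors_s: np.ndarray       # one per TP, seconds
    rel_errors_pct: np.ndarray     # abs error / mean reference step duration


@dataclass
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    abs_error_mean: float
    rel_error_pct: float | None
    rel_error_ci: tuple[float, float] | None
    icc: float
    icc_ci: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa_low": self.loa_low,
                "loa_high": self.loa_high, "abs_error_mean": self.abs_error_mean,
                "rel_error_pct": self.rel_error_pct,
                "rel_error_ci": self.rel_error_ci, "icc": self.icc,
                "icc_ci": list(self.icc_ci), "n": self.n}


@dataclass
class BinnedErrorCurve:
    bin_centers: np.ndarray
    median_rel_error_pct: np.ndarray
    weights: np.ndarray
    fit_params: tuple[float, float] | None   # (a, b) of y = a * exp(b * x)
    r2: float | None


# ---------------------------------------------------------------------------
# Window classification (gait sequence detection)
# ---------------------------------------------------------------------------

def _window_overlap(intervals, total_duration_s: float, window_s: float
                    ) -> np.ndarray:
    """Seconds of gait inside each tiling window, for non-overlapping
    intervals."""
    n_win = int(np.floor(total_duration_s / window_s + 1e-9))
    overlap = np.zeros(n_win)
    for iv in intervals:
        s = max(float(iv.start_s), 0.0)
        e = min(float(iv.end_s), n_win * window_s)
        if e <= s:
            continue
        j0 = int(np.floor(s / window_s))
        j1 = min(int(np.floor(e / window_s)), n_win - 1)
        if j0 == j1:
            overlap[j0] += e - s
            continue
        overlap[j0] += (j0 + 1) * window_s - s
        overlap[j1] += e - j1 * window_s
        if j1 > j0 + 1:
            overlap[j0 + 1:j1] += window_s
    return overlap


def classify_gsd_windows(detected: list[GaitSequence],
                         reference,
                         total_duration_s: float,
                         window_s: float = 0.1) -> ConfusionCounts:
    """Tile the recording into ``window_s`` windows and classify each one.

    A window counts as gait for a system when more than half of it overlaps
    that system's gait intervals (majority rule).  TP = both gait, TN = both
    non-gait, FP = device only, FN = reference only.
    """
    ref_intervals = [b.as_sequence() if isinstance(b, WalkingBout) else b
                     for b in reference]
    det_gait = _window_overlap(detected, total_duration_s, window_s) > window_s / 2
    ref_gait = _window_overlap(ref_intervals, total_duration_s, window_s) > window_s / 2
    tp = int(np.sum(det_gait & ref_gait))
    fp = int(np.sum(det_gait & ~ref_gait))
    fn = int(np.sum(~det_gait & ref_gait))
    tn = int(np.sum(~det_gait & ~ref_gait))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# IC matching
# ---------------------------------------------------------------------------

def match_ics(detected, reference, tol_s: float = IC_TOL_S) -> MatchResult:
    """Match detected to reference ICs within a centred tolerance window.

    Reference events are processed in time order; among the not-yet-consumed
    detected events within ``tol_s / 2`` the nearest wins (ties break toward
    the earlier detected event).  Unmatched reference events are FN, unmatched
    detected events FP; true negatives are not defined.
    """
    det = np.sort(np.asarray(getattr(detected, "ic_times_s", detected), dtype=float))
    ref = np.sort(np.asarray(getattr(reference, "ic_times_s", reference), dtype=float))
    half = tol_s / 2.0
    used = np.zeros(len(det), dtype=bool)
    errors = []
    tp = 0
    for r in ref:
        cand = np.flatnonzero(~used & (np.abs(det - r) <= half))
        if cand.size == 0:
            continue
        dists = np.abs(det[cand] - r)
        best = cand[int(np.argmin(dists))]  # argmin returns the first == earliest
        used[best] = True
        tp += 1
        errors.append(abs(det[best] - r))
    errors = np.asarray(errors)
    counts = ConfusionCounts(tp=tp, fp=int(len(det) - tp), fn=int(len(ref) - tp),
                             tn=None)
    if len(ref) >= 2 and errors.size:
        mean_step = float(np.mean(np.diff(ref)))
        rel = errors / mean_step * 100.0
    else:
        rel = np.array([])
    return MatchResult(counts=counts, abs_errors_s=errors, rel_errors_pct=rel)


# ---------------------------------------------------------------------------
# Performance measures
# ---------------------------------------------------------------------------

def confusion_measures(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity and PPV; undefined measures are
    ``None`` rather than 0."""
    tn = c.tn
    out: dict[str, float | None] = {}
    denom_acc = c.tp + c.fp + c.fn + (tn if tn is not None else 0)
    out["accuracy"] = ((c.tp + tn) / denom_acc
                       if tn is not None and denom_acc > 0 else None)
    out["sensitivity"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    out["specificity"] = (tn / (tn + c.fp)
                          if tn is not None and (tn + c.fp) > 0 else None)
    out["ppv"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    return out


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def icc_2_1(device: np.ndarray, reference: np.ndarray,
            alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Closed-form from the two-way ANOVA mean squares, with the standard
    F-based confidence interval.
    """
    x = np.column_stack([np.asarray(device, float), np.asarray(reference, float)])
    n, k = x.shape
    if n < 3:
        raise DataError("need >= 3 paired observations for ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    if mse <= 0:
        return float(icc), (float(icc), float(icc))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = ((n - 1) * (k * icc * fj) ** 2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def agreement_stats(device_values, reference_values) -> AgreementStats:
    """Bland-Altman bias/LoA, mean absolute error, relative error with 95% CI
    and ICC(2,1) for matched per-bout outcome lists."""
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if len(dev) != len(ref):
        raise DataError("device and reference lists must have equal length")
    if len(dev) < 3:
        raise DataError("need >= 3 paired observations")
    diffs = dev - ref
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    abs_error_mean = float(np.mean(np.abs(diffs)))

    nonzero = ref != 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} bouts with zero reference "
                      "value excluded from relative error", stacklevel=2)
    if nonzero.sum() >= 2:
        rel = (dev[nonzero] - ref[nonzero]) / ref[nonzero] * 100.0
        rel_mean = float(np.mean(rel))
        sem = stats.sem(rel)
        if sem > 0:
            ci = stats.t.interval(0.95, len(rel) - 1, loc=rel_mean, scale=sem)
            rel_ci = (float(ci[0]), float(ci[1]))
        else:
            rel_ci = (rel_mean, rel_mean)
    else:
        rel_mean, rel_ci = None, None

    icc, icc_ci = icc_2_1(dev, ref)
    return AgreementStats(bias=bias, loa_low=loa_low, loa_high=loa_high,
                          abs_error_mean=abs_error_mean, rel_error_pct=rel_mean,
                          rel_error_ci=rel_ci, icc=icc, icc_ci=icc_ci,
                          n=len(dev))


def gsd_duration_agreement(detected_per_recording, reference_per_recording
                           ) -> AgreementStats:
    """Agreement on total accumulated gait seconds, one pair per recording."""
    def total(seqs):
        return float(sum(s.duration_s for s in seqs))
    dev = [total(d) for d in detected_per_recording]
    ref = [total([b.as_sequence() if isinstance(b, WalkingBout) else b
                  for b in r]) for r in reference_per_recording]
    return agreement_stats(dev, ref)


# ---------------------------------------------------------------------------
# Error-vs-covariate modelling
# ---------------------------------------------------------------------------

def binned_error_fit(per_bout_rel_errors, covariate, bin_width: float
                     ) -> BinnedErrorCurve:
    """Median |relative error| per covariate bin plus a weighted exponential
    best fit ``y = a * exp(b * x)``.

    Weights are observation shares per bin; empty bins are skipped without
    shifting bin centres.  With fewer than 3 non-empty bins the fit is
    skipped (``fit_params is None``).
    """
    err = np.abs(np.asarray(per_bout_rel_errors, dtype=float))
    cov = np.asarray(covariate, dtype=float)
    if len(err) != len(cov) or len(err) == 0:
        raise DataError("errors and covariate must be equal-length, non-empty")
    lo = np.floor(cov.min() / bin_width) * bin_width
    idx = np.floor((cov - lo) / bin_width).astype(int)
    centers, medians, counts = [], [], []
    for j in range(idx.max() + 1):
        sel = idx == j
        if not sel.any():
            continue
        centers.append(lo + (j + 0.5) * bin_width)
        medians.append(float(np.median(err[sel])))
        counts.append(int(sel.sum()))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    weights = np.asarray(counts, dtype=float) / np.sum(counts)

    fit_params, r2 = None, None
    if len(centers) >= 3 and np.any(medians > 0):
        safe = np.clip(medians, 1e-9, None)
        # weighted log-linear start values
        coef = np.polyfit(centers, np.log(safe), 1, w=np.sqrt(weights))
        p0 = (float(np.exp(coef[1])), float(coef[0]))
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x), centers, medians,
                p0=p0, sigma=1.0 / np.sqrt(weights), maxfev=10000)
            yhat = popt[0] * np.exp(popt[1] * centers)
            ybar = np.sum(weights * medians)
            ss_res = np.sum(weights * (medians - yhat) ** 2)
            ss_tot = np.sum(weights * (medians - ybar) ** 2)
            fit_params = (float(popt[0]), float(popt[1]))
            r2 = float(1 - ss_res / ss_tot) if ss_tot > 0 else 1.0
        except RuntimeError:
            pass
    return BinnedErrorCurve(bin_centers=centers, median_rel_error_pct=medians,
                            weights=weights, fit_params=fit_params, r2=r2)
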