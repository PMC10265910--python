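"""End-to-end technical validation at desk scale.

Gait-sequence detectors receive the full recording; IC, cadence and stride
length estimators receive the reference walking bouts as their input
intervals (they may read at most 1 s beyond a bout, the refinement margin).
Per-algorithm statistics are aggregated across recordings and fed into the
ranking stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import cad as cad_mod
from . import gsd as gsd_mod
from . import icd as icd_mod
from . import rank as rank_mod
from . import sl as sl_mod
from . import validate as val_mod
from .exceptions import GaitDmoError, PairingError
from .io import ImuRecording, SubjectInfo, WalkingBout

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    gsd_algos: tuple[str, ...] = ("a", "b", "c")
    icd_algos: tuple[str, ...] = ("a", "b", "c", "d")
    cad_algos: tuple[str, ...] = ("a", "b", "c")
    sl_algos: tuple[str, ...] = ("a", "b", "c", "d")
    sl_k_override: float | None = None   # e.g. the generative pendulum constant
    inject_truth: bool = False           # oracle passthrough for smoke tests


def _gsd_block(recordings, references, algos, inject_truth=False):
    out = {}
    for algo in algos:
        counts = val_mod.ConfusionCounts(tn=0)
        det_all, ref_all = [], []
        for rec, bouts in zip(recordings, references):
            det = ([b.as_sequence() for b in bouts] if inject_truth
                   else gsd_mod.detect(rec, algo))
            c = val_mod.classify_gsd_windows(det, bouts, rec.duration_s)
            counts = val_mod.ConfusionCounts(tp=counts.tp + c.tp, fp=counts.fp + c.fp,
                                             fn=counts.fn + c.fn, tn=counts.tn + c.tn)
            det_all.append(det)
            ref_all.append(bouts)
        block = {"confusion": {"tp": counts.tp, "fp": counts.fp,
                               "fn": counts.fn, "tn": counts.tn},
                 "measures": val_mod.confusion_measures(counts)}
        if len(recordings) >= 3:
            block["duration_agreement"] = val_mod.gsd_duration_agreement(
                det_all, ref_all).to_dict()
        out[algo] = block
    return out


def _icd_block(recordings, references, algos, inject_truth=False):
    out = {}
    for algo in algos:
        tp = fp = fn = 0
        abs_err, rel_err = [], []
        for rec, bouts in zip(recordings, references):
            for bout in bouts:
                truth = bout.ic_times_s
                det = (truth if inject_truth
                       else icd_mod.detect(rec, bout.as_sequence(), algo).ic_times_s)
                m = val_mod.match_ics(det, truth)
                tp += m.counts.tp
                fp += m.counts.fp
                fn += m.counts.fn
                abs_err.extend(m.abs_errors_s)
                rel_err.extend(m.rel_errors_pct)
        counts = val_mod.ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=None)
        meas = val_mod.confusion_measures(counts)
        out[algo] = {
            "confusion": {"tp": tp, "fp": fp, "fn": fn},
            "sensitivity": meas["sensitivity"], "ppv": meas["ppv"],
            "abs_error_mean_s": float(np.mean(abs_err)) if abs_err else None,
            "rel_error_mean_pct": float(np.mean(rel_err)) if rel_err else None,
        }
    return out


def _per_bout_outcomes(recordings, references, algo, kind, subject, cfg):
    device, reference, speeds, durations = [], [], [], []
    for rec, bouts in zip(recordings, references):
        for bout in bouts:
            gs = bout.as_sequence()
            truth_ics = bout.ic_times_s
            if kind == "cad":
                ref_val = cad_mod.cadence_from_ics(
                    icd_mod.InitialContactList(truth_ics, gs)).cad_mean
            else:
                lengths = [s.length_m for s in bout.strides if s.length_m is not None]
                if not lengths:
                    continue
                ref_val = float(np.mean(lengths))
            if cfg.inject_truth:
                dev_val = ref_val
            else:
                try:
                    if kind == "cad":
                        dev_val = cad_mod.estimate_cadence(rec, gs, algo).cad_mean
                    else:
                        ics = icd_mod.detect_icd_a(rec, gs)
                        params = sl_mod.params_for(algo, subject)
                        if cfg.sl_k_override is not None and algo in ("a", "b"):
                            params = sl_mod.SlParams(k=cfg.sl_k_override)
                        dev_val = sl_mod.estimate_stride_length(
                            rec, ics, subject, algo, params).sl_mean
                except GaitDmoError as exc:
                    logger.debug("bout [%.1f, %.1f] %s_%s failed: %s",
                                 bout.start_s, bout.end_s, kind, algo, exc)
                    continue
            device.append(dev_val)
            reference.append(ref_val)
            speeds.append(bout.mean_speed_mps)
            durations.append(bout.duration_s)
    return device, reference, speeds, durations


def _outcome_block(recordings, references, algos, kind, subject, cfg):
    out = {}
    for algo in algos:
        dev, ref, speeds, durs = _per_bout_outcomes(
            recordings, references, algo, kind, subject, cfg)
        block = {"n_bouts": len(dev)}
        if len(dev) >= 3:
            block["agreement"] = val_mod.agreement_stats(dev, ref).to_dict()
            rel = [(d - r) / r * 100.0 for d, r in zip(dev, ref) if r != 0]
            block["abs_rel_error_median_pct"] = float(np.median(np.abs(rel)))
            block["_per_bout"] = {"device": dev, "reference": ref,
                                  "speed_mps": speeds, "duration_s": durs}
        out[algo] = block
    return out


def _rankings(report):
    rankings = {}
    # GSD: benefits accuracy/sensitivity/specificity/ppv (+ICC when present)
    rows, specs = {}, {}
    for algo, block in report["gsd"].items():
        row = {k: v for k, v in block["measures"].items() if v is not None}
        if "duration_agreement" in block:
            row["icc"] = block["duration_agreement"]["icc"]
            row["abs_error"] = block["duration_agreement"]["abs_error_mean"]
        rows[algo] = row
    if rows:
        cols = {c for r in rows.values() for c in r}
        specs = {c: rank_mod.MeasureSpec("cost" if c == "abs_error" else "benefit")
                 for c in cols}
        idx = rank_mod.rank_algorithms(rank_mod.DecisionMatrix.from_dict(rows, specs))
        rankings["gsd"] = {"index": idx.to_dict(), "order": list(idx.index)}
    # ICD: benefits sensitivity/ppv, costs errors
    rows = {}
    for algo, block in report["icd"].items():
        row = {}
        for key, spec_kind in (("sensitivity", "benefit"), ("ppv", "benefit"),
                               ("abs_error_mean_s", "cost"),
                               ("rel_error_mean_pct", "cost")):
            if block.get(key) is not None:
                row[key] = block[key]
        rows[algo] = row
    if rows:
        cols = {c for r in rows.values() for c in r}
        specs = {c: rank_mod.MeasureSpec(
            "cost" if "error" in c else "benefit") for c in cols}
        idx = rank_mod.rank_algorithms(rank_mod.DecisionMatrix.from_dict(rows, specs))
        rankings["icd"] = {"index": idx.to_dict(), "order": list(idx.index)}
    # CAD / SL: benefit ICC, costs abs+rel error
    for kind in ("cad", "sl"):
        rows = {}
        for algo, block in report[kind].items():
            if "agreement" not in block:
                continue
            ag = block["agreement"]
            row = {"icc": ag["icc"], "abs_error": ag["abs_error_mean"]}
            if ag["rel_error_pct"] is not None:
                row["rel_error"] = abs(ag["rel_error_pct"])
            rows[algo] = row
        if rows:
            cols = {c for r in rows.values() for c in r}
            specs = {c: rank_mod.MeasureSpec("benefit" if c == "icc" else "cost")
                     for c in cols}
            idx = rank_mod.rank_algorithms(
                rank_mod.DecisionMatrix.from_dict(rows, specs))
            rankings[kind] = {"index": idx.to_dict(), "order": list(idx.index)}
    return rankings


def run_technical_validation(recordings: list[ImuRecording],
                             references: list[list[WalkingBout]],
                             subject: SubjectInfo | None = None,
                             config: PipelineConfig | None = None) -> dict:
    """Run every configured algorithm over matched recording/reference pairs
    and aggregate the validation statistics into a JSON-serialisable report."""
    if len(recordings) != len(references):
        raise PairingError(
            f"{len(recordings)} recordings vs {len(references)} references")
    for i, (rec, bouts) in enumerate(zip(recordings, references)):
        for b in bouts:
            if b.end_s > rec.duration_s + 1e-6:
                raise PairingError(f"pair {i}: bout ends after the recording")
    subject = subject or SubjectInfo(leg_length_m=0.9, foot_length_m=0.25)
    cfg = config or PipelineConfig()
    report = {
        "schema_version": SCHEMA_VERSION,
        "n_recordings": len(recordings),
        "gsd": _gsd_block(recordings, references, cfg.gsd_algos, cfg.inject_truth),
        "icd": _icd_block(recordings, references, cfg.icd_algos, cfg.inject_truth),
        "cad": _outcome_block(recordings, references, cfg.cad_algos,
                              "cad", subject, cfg),
        "sl": _outcome_block(recordings, references, cfg.sl_algos,
                             "sl", subject, cfg),
    }
    report["ranking"] = _rankings(report)
    return report


def strip_private(report: dict) -> dict:
    """Drop the bulky per-bout payloads (keys starting with '_') for writing."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items() if not k.startswith("_")}
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj
    return clean(report)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(strip_private(report), fh, indent=1, sort_keys=True)


def format_report(report: dict) -> str:
    """Human-readable per-outcome summary table."""
    lines = []
    for kind in ("gsd", "icd", "cad", "sl"):
        lines.append(f"== {kind.upper()} ==")
        for algo, block in report.get(kind, {}).items():
            parts = [f"  {kind}_{algo}:"]
            if kind == "gsd":
                for k, v in block["measures"].items():
                    if v is not None:
                        parts.append(f"{k}={v:.3f}")
            elif kind == "icd":
                for k in ("sensitivity", "ppv", "abs_error_mean_s",
                          "rel_error_mean_pct"):
                    if block.get(k) is not None:
                        parts.append(f"{k}={block[k]:.3f}")
            elif "agreement" in block:
                ag = block["agreement"]
                parts.append(f"bias={ag['bias']:.3f}")
                parts.append(f"icc={ag['icc']:.3f}")
                parts.append(f"abs_err={ag['abs_error_mean']:.3f}")
            lines.append(" ".join(parts))
        order = report.get("ranking", {}).get(kind, {}).get("order")
        if order:
            lines.append(f"  ranking: {' > '.join(order)}")
    return "\n".join(lines)
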