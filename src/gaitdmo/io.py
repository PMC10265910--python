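"""Data model for recordings and reference annotations, plus on-disk formats.

Time base convention: all event times are seconds relative to the start of the
recording, stored as floats; the sample index of a time ``t`` is
``round(t * fs)`` (0-based).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError, FormatError
from ._dsp import G_MPS2

logger = logging.getLogger(__name__)

#: stride inclusion rules for reference data
STRIDE_MIN_DURATION_S = 0.2
STRIDE_MAX_DURATION_S = 3.0
STRIDE_MIN_LENGTH_M = 0.15
#: a rest of at least this long separates consecutive walking bouts
BOUT_BREAK_S = 3.0

_AXIS_ALIASES = {"acc_v": "acc_v", "acc_is": "acc_v",
                 "acc_ap": "acc_ap", "acc_pa": "acc_ap",
                 "acc_ml": "acc_ml"}


@dataclass
class ImuRecording:
    """Triaxial lower-back acceleration stream, axes in g units.

    ``acc_v``: vertical (positive up), ``acc_ap``: anterior-posterior
    (positive forward), ``acc_ml``: medio-lateral.
    """

    sampling_rate_hz: float
    acc_v: np.ndarray
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.acc_v = np.asarray(self.acc_v, dtype=float)
        self.acc_ap = np.asarray(self.acc_ap, dtype=float)
        self.acc_ml = np.asarray(self.acc_ml, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be > 0")
        n = len(self.acc_v)
        if n < 1 or len(self.acc_ap) != n or len(self.acc_ml) != n:
            raise DataError("axis series must have identical length >= 1")
        for name in ("acc_v", "acc_ap", "acc_ml"):
            bad = np.flatnonzero(~np.isfinite(getattr(self, name)))
            if bad.size:
                raise DataError(
                    f"non-finite samples in {name} at indices {bad[:10].tolist()}"
                )

    def __len__(self) -> int:
        return len(self.acc_v)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    @property
    def acc_norm(self) -> np.ndarray:
        """Euclidean norm of the three axes, in g."""
        return np.sqrt(self.acc_v ** 2 + self.acc_ap ** 2 + self.acc_ml ** 2)

    def index_of(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_rate_hz))

    def slice_samples(self, start_s: float, end_s: float) -> slice:
        i0 = max(self.index_of(start_s), 0)
        i1 = min(self.index_of(end_s), len(self))
        return slice(i0, max(i1, i0))


@dataclass(frozen=True, order=True)
class GaitSequence:
    """A detected (device) or annotated (reference) interval of gait."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise DataError(f"invalid gait sequence [{self.start_s}, {self.end_s}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Stride:
    start_s: float
    end_s: float
    length_m: float | None = None
    foot: str = "unknown"  # left | right | unknown

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def is_valid(self) -> bool:
        if not (STRIDE_MIN_DURATION_S <= self.duration_s <= STRIDE_MAX_DURATION_S):
            return False
        if self.length_m is not None and self.length_m < STRIDE_MIN_LENGTH_M:
            return False
        return True


@dataclass
class WalkingBout:
    """A reference walking interval with its per-stride annotation."""

    start_s: float
    end_s: float
    strides: list[Stride] = field(default_factory=list)
    mean_speed_mps: float | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def ic_times_s(self) -> np.ndarray:
        """Initial contacts implied by the stride boundaries (sorted, unique)."""
        times = {round(s.start_s, 9) for s in self.strides}
        times |= {round(s.end_s, 9) for s in self.strides}
        return np.array(sorted(times))

    def as_sequence(self) -> GaitSequence:
        return GaitSequence(self.start_s, self.end_s)

    def check_valid(self) -> None:
        feet = {s.foot for s in self.strides}
        if feet <= {"left", "right"} and feet:
            per_foot = {f: sum(1 for s in self.strides if s.foot == f) for f in feet}
            if len(feet) < 2 or min(per_foot.values()) < 2:
                raise DataError("bout needs at least two strides per foot")
        elif len(self.strides) < 4:
            raise DataError("bout with unlabeled feet needs at least 4 strides")
        starts = sorted(s.start_s for s in self.strides)
        gaps = np.diff(starts)
        if gaps.size and gaps.max() >= BOUT_BREAK_S:
            raise DataError("inter-stride gap >= 3 s inside a bout")


def _min_strides(strides: list[Stride]) -> bool:
    feet = {s.foot for s in strides}
    if feet <= {"left", "right"} and feet:
        return all(sum(1 for s in strides if s.foot == f) >= 2 for f in ("left", "right"))
    return len(strides) >= 4


@dataclass
class SubjectInfo:
    leg_length_m: float
    foot_length_m: float
    cohort: str = "HA"  # HA | PD | MS | COPD | CHF | PFF

    def __post_init__(self) -> None:
        if self.leg_length_m <= 0 or self.foot_length_m <= 0:
            raise DataError("subject lengths must be > 0")


# ---------------------------------------------------------------------------
# Recording CSV (+ optional YAML sidecar)
# ---------------------------------------------------------------------------

def load_recording(path, config: dict | None = None) -> ImuRecording:
    """Read a recording CSV (``time_s,acc_v,acc_ap,acc_ml`` or aliases).

    ``config`` keys (also read from a ``<path>.yaml`` sidecar if present):
    ``units`` ("g" or "m/s^2"), ``sampling_rate_hz`` (overrides the time
    column), ``axis_map`` (logical axis -> column name), ``axis_signs``
    (logical axis -> +-1).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    cfg = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        cfg.update(yaml.safe_load(sidecar.read_text()) or {})
    cfg.update(config or {})

    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    axis_map = cfg.get("axis_map") or {}
    columns: dict[str, str] = {}
    for logical in ("acc_v", "acc_ap", "acc_ml"):
        col = axis_map.get(logical)
        if col is None:
            for name, target in _AXIS_ALIASES.items():
                if target == logical and name in df.columns:
                    col = name
                    break
        if col is None or col not in df.columns:
            raise FormatError(f"missing column for axis {logical!r}")
        columns[logical] = col

    rate = cfg.get("sampling_rate_hz")
    if rate is None:
        if "time_s" not in df.columns:
            raise FormatError("missing column 'time_s' and no sampling_rate_hz given")
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or np.any(dt <= 0):
            raise DataError("time_s column is not strictly increasing")
        rate = 1.0 / float(np.median(dt))

    data = {}
    signs = cfg.get("axis_signs") or {}
    for logical, col in columns.items():
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise DataError(
                f"non-finite samples in column {col!r} at rows {bad[:10].tolist()}"
            )
        data[logical] = float(signs.get(logical, 1.0)) * vals

    units = str(cfg.get("units", "g")).lower()
    if units in ("m/s^2", "m/s2", "ms2", "mps2"):
        for k in data:
            data[k] = data[k] / G_MPS2
    elif units != "g":
        raise FormatError(f"unknown units {units!r} (use 'g' or 'm/s^2')")

    start = float(df["time_s"].iloc[0]) if "time_s" in df.columns else 0.0
    return ImuRecording(sampling_rate_hz=float(rate), start_time_s=start, **data)


def write_recording(rec: ImuRecording, path) -> None:
    t = rec.start_time_s + np.arange(len(rec)) / rec.sampling_rate_hz
    pd.DataFrame({"time_s": t, "acc_v": rec.acc_v, "acc_ap": rec.acc_ap,
                  "acc_ml": rec.acc_ml}).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Reference annotations (JSON)
# ---------------------------------------------------------------------------

def load_reference(path) -> list[WalkingBout]:
    """Read reference walking bouts, enforcing the stride/bout validity rules.

    Strides outside the 0.2-3 s / 0.15 m rules are dropped with a warning;
    bouts left without the minimum stride content are dropped entirely.
    Overlapping bouts raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"reference file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    if "bouts" not in payload:
        raise FormatError("reference JSON must contain a 'bouts' list")

    bouts: list[WalkingBout] = []
    for i, raw in enumerate(payload["bouts"]):
        strides = []
        for raw_stride in raw.get("strides", []):
            stride = Stride(start_s=float(raw_stride["start_s"]),
                            end_s=float(raw_stride["end_s"]),
                            length_m=(None if raw_stride.get("length_m") is None
                                      else float(raw_stride["length_m"])),
                            foot=raw_stride.get("foot", "unknown"))
            if stride.is_valid():
                strides.append(stride)
            else:
                warnings.warn(
                    f"bout {i}: dropping invalid stride "
                    f"[{stride.start_s:.3f}, {stride.end_s:.3f}] "
                    f"(duration {stride.duration_s:.3f} s, length {stride.length_m})",
                    stacklevel=2)
        if not _min_strides(strides):
            logger.warning("bout %d dropped: too few valid strides", i)
            continue
        bout = WalkingBout(start_s=float(raw["start_s"]),
                           end_s=float(raw["end_s"]),
                           strides=sorted(strides, key=lambda s: s.start_s),
                           mean_speed_mps=(None if raw.get("mean_speed_mps") is None
                                           else float(raw["mean_speed_mps"])))
        try:
            bout.check_valid()
        except DataError as exc:
            logger.warning("bout %d dropped: %s", i, exc)
            continue
        bouts.append(bout)

    bouts.sort(key=lambda b: b.start_s)
    for prev, cur in zip(bouts, bouts[1:]):
        if cur.start_s < prev.end_s:
            raise DataError(
                f"overlapping bouts: [{prev.start_s}, {prev.end_s}] and "
                f"[{cur.start_s}, {cur.end_s}]")
    return bouts


def write_reference(bouts: list[WalkingBout], path) -> None:
    payload = {"bouts": [
        {"start_s": b.start_s, "end_s": b.end_s, "mean_speed_mps": b.mean_speed_mps,
         "strides": [{"start_s": s.start_s, "end_s": s.end_s,
                      "length_m": s.length_m, "foot": s.foot} for s in b.strides]}
        for b in bouts]}
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Gait sequence lists (JSON) -- CLI plumbing
# ---------------------------------------------------------------------------

def write_sequences(seqs: list[GaitSequence], path) -> None:
    Path(path).write_text(json.dumps(
        [{"start_s": s.start_s, "end_s": s.end_s} for s in seqs], indent=1))


def load_sequences(path) -> list[GaitSequence]:
    raw = json.loads(Path(path).read_text())
    return [GaitSequence(float(d["start_s"]), float(d["end_s"])) for d in raw]


def load_subject(path) -> SubjectInfo:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return SubjectInfo(leg_length_m=float(cfg["leg_length_m"]),
                           foot_length_m=float(cfg["foot_length_m"]),
                           cohort=cfg.get("cohort", "HA"))
    except KeyError as exc:
        raise FormatError(f"subject file missing key {exc}") from exc
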