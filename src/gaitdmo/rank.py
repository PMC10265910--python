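"""Combine performance measures into a performance index and rank algorithms.

Measures are tagged benefit (larger is better) or cost (smaller is better);
costs are normalised by min-max inversion across algorithms and the index is
the weighted mean of the available normalised values, in [0, 1] for measures
in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MeasureSpec", "DecisionMatrix", "performance_index", "rank_algorithms"]


@dataclass(frozen=True)
class MeasureSpec:
    kind: str            # "benefit" | "cost"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("benefit", "cost"):
            raise ValueError(f"kind must be benefit or cost, got {self.kind!r}")
        if not (0 <= self.weight <= 1):
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class DecisionMatrix:
    """Algorithms x measures table with benefit/cost tags and weights."""

    values: pd.DataFrame                      # rows: algorithms, cols: measures
    specs: dict[str, MeasureSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.specs)
        if missing:
            raise ValueError(f"measures without a spec: {sorted(missing)}")

    @classmethod
    def from_dict(cls, rows: dict[str, dict[str, float]],
                  specs: dict[str, MeasureSpec]) -> "DecisionMatrix":
        return cls(values=pd.DataFrame.from_dict(rows, orient="index"), specs=specs)


def _normalise(matrix: DecisionMatrix) -> pd.DataFrame:
    out = matrix.values.astype(float).copy()
    for col in out.columns:
        if matrix.specs[col].kind == "cost":
            vals = out[col]
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            out[col] = 1.0 if hi == lo else (hi - vals) / (hi - lo)
    return out


def performance_index(matrix: DecisionMatrix) -> pd.Series:
    """Weighted mean of normalised measures per algorithm.

    Missing cells are excluded from both numerator and weight sum; algorithms
    with no measure at all are dropped with a warning.
    """
    norm = _normalise(matrix)
    weights = pd.Series({c: matrix.specs[c].weight for c in norm.columns})
    indices = {}
    for algo, row in norm.iterrows():
        ok = row.notna()
        if not ok.any():
            warnings.warn(f"algorithm {algo!r} has no measures; excluded",
                          stacklevel=2)
            continue
        w = weights[ok.index[ok]]
        if w.sum() == 0:
            warnings.warn(f"algorithm {algo!r} has zero total weight; excluded",
                          stacklevel=2)
            continue
        indices[algo] = float((row[ok] * w).sum() / w.sum())
    return pd.Series(indices, name="performance_index")


def rank_algorithms(matrix: DecisionMatrix) -> pd.Series:
    """Descending performance index; ties broken alphabetically."""
    idx = performance_index(matrix)
    order = sorted(idx.index, key=lambda a: (-idx[a], a))
    return idx.reindex(order)
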