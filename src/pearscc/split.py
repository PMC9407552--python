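"""SPXY calibration/validation partitioning.

SPXY (sample-set partitioning based on joint x-y distances) extends
Kennard-Stone sampling to be response-aware: pairwise distances are the sum
of the Euclidean spectral distance and the absolute SCC difference, each
normalized by its maximum.  Selection is fully deterministic: seed with the
pair at maximal joint distance, then greedily add the sample whose minimum
distance to the chosen set is largest (max-min), until the calibration set
reaches its target size.  Extremes of both spectra and SCC are thereby
pushed into the calibration set, so the calibration response range covers
the validation range by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datasets import (ReferenceSet, SetStatistics, SpectraSet,
                       anova_two_groups, summarize_reference)


@dataclass(frozen=True)
class DatasetSplit:
    """Index partition into calibration (Cs) and validation (Vs) sets."""

    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    ratio: tuple[int, int]

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_idx, dtype=int)
        val = np.asarray(self.validation_idx, dtype=int)
        object.__setattr__(self, "calibration_idx", cal)
        object.__setattr__(self, "validation_idx", val)
        if np.intersect1d(cal, val).size:
            raise ValueError("calibration and validation sets overlap")

    @property
    def n(self) -> int:
        return self.calibration_idx.size + self.validation_idx.size

    def to_dict(self) -> dict:
        return {"calibration_idx": self.calibration_idx.tolist(),
                "validation_idx": self.validation_idx.tolist(),
                "ratio": list(self.ratio)}


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, SpectraSet):
        if isinstance(y, ReferenceSet):
            y = y.aligned_to(X)
        X = X.reflectance
    X = np.asarray(X, dtype=float)
    y = np.asarray(getattr(y, "scc", y), dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    return X, y


def spxy_split(X, y, ratio: tuple[int, int] = (3, 1)) -> DatasetSplit:
    """Deterministic SPXY split at ``ratio`` = (calibration parts, validation
    parts); |Cs| = round(n * cal / (cal + val)).

    Distance ties are broken toward the sample whose id (or index, for bare
    arrays) sorts first, making the selected id sets invariant to row order.
    """
    ids = X.sample_ids if isinstance(X, SpectraSet) else None
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("SPXY needs at least 4 samples")
    cal_parts, val_parts = ratio
    if cal_parts <= 0 or val_parts < 0:
        raise ValueError("ratio parts must be positive (validation may be 0)")
    n_cal = int(np.floor(n * cal_parts / (cal_parts + val_parts) + 0.5))
    n_cal = min(max(n_cal, 2), n)

    # canonical tie-break rank: position in the sorted-id order
    if ids is not None:
        rank = np.empty(n, dtype=int)
        rank[np.argsort(np.asarray(ids))] = np.arange(n)
    else:
        rank = np.arange(n)

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0 and dy_max == 0:
        raise ValueError("all spectra and all responses identical: "
                         "SPXY distances degenerate")
    d = (dx / dx_max if dx_max > 0 else dx) + (dy / dy_max if dy_max > 0 else dy)

    # seed pair: maximal joint distance, ties to smallest rank pair
    best_pair, best_key = None, None
    dmax = d.max()
    for i, j in zip(*np.nonzero(d == dmax)):
        if i >= j:
            continue
        a, b = sorted((int(i), int(j)), key=lambda t: rank[t])
        key = (rank[a], rank[b])
        if best_key is None or key < best_key:
            best_key, best_pair = key, (a, b)
    selected = list(best_pair)
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True

    dmin = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        dmin_masked = np.where(in_set, -np.inf, dmin)
        top = dmin_masked.max()
        ties = np.flatnonzero(dmin_masked == top)
        nxt = int(ties[np.argmin(rank[ties])])
        selected.append(nxt)
        in_set[nxt] = True
        dmin = np.minimum(dmin, d[nxt])

    cal = np.array(sorted(selected))
    val = np.flatnonzero(~in_set)
    return DatasetSplit(cal, val, ratio)


@dataclass(frozen=True)
class SplitReport:
    """Coverage and distributional diagnostics of a split."""

    covers: bool
    calibration_stats: SetStatistics
    validation_stats: SetStatistics | None
    anova_f: float | None
    anova_p: float | None

    def to_dict(self) -> dict:
        return {"covers": self.covers,
                "calibration": self.calibration_stats.to_dict(),
                "validation": (self.validation_stats.to_dict()
                               if self.validation_stats else None),
                "anova_f": self.anova_f, "anova_p": self.anova_p}


def validate_split(split: DatasetSplit, y) -> SplitReport:
    """Report whether the calibration SCC range covers the validation range,
    the per-set statistics, and the two-group ANOVA.  Diagnostic only: a
    significant ANOVA does not gate the pipeline."""
    y = np.asarray(getattr(y, "scc", y), dtype=float).ravel()
    y_cal = y[split.calibration_idx]
    cal_stats = summarize_reference(y_cal)
    if split.validation_idx.size == 0:
        return SplitReport(True, cal_stats, None, None, None)
    y_val = y[split.validation_idx]
    val_stats = summarize_reference(y_val)
    covers = bool(cal_stats.min <= val_stats.min
                  and val_stats.max <= cal_stats.max)
    if y_cal.size >= 2 and y_val.size >= 2:
        res = anova_two_groups(y_cal, y_val)
        return SplitReport(covers, cal_stats, val_stats, res["F"], res["p"])
    return SplitReport(covers, cal_stats, val_stats, None, None)
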