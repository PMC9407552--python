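"""Spectral preprocessing: SNV, MSC, Savitzky-Golay, and their comparison.

Raw diffuse-reflectance spectra carry multiplicative scatter (sample size,
surface geometry), additive baseline drift and channel noise.  The three
standard corrections are provided as scikit-learn transformers so they can
be composed in pipelines, plus the grid-search procedure that picks the
best preprocessing by PLSR performance on a calibration/validation split.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import ReferenceSet, SpectraSet
from .plsr import PLSRegressor, choose_factors, correlation, rmse
from .split import DatasetSplit

VALID_FRAMES = (3, 5, 7, 9)


class SNVScaler(TransformerMixin, BaseEstimator):
    """Standard normal variate: each spectrum is centered and scaled to
    unit sample SD (n-1 denominator), removing per-sample gain and offset."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < 2:
            raise ValueError("SNV needs at least 2 channels")
        sd = X.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"constant spectrum (SD 0) at row(s) "
                             f"{bad.tolist()[:5]}")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class MSCCorrector(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference by OLS, x ~ a + b * ref,
    and corrected to (x - a) / b.  The reference defaults to the column-wise
    mean spectrum of the data passed to :meth:`fit`.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float).ravel()
        else:
            self.reference_ = X.mean(axis=0)
        if self.reference_.size < 2:
            raise ValueError("MSC needs at least 2 channels")
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ref = self.reference_
        if X.shape[1] != ref.size:
            raise ValueError("channel count differs from reference")
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        a = X.mean(axis=1) - b * ref.mean()
        bad = np.flatnonzero(np.abs(b) < 1e-12)
        if bad.size:
            raise ValueError(f"MSC slope numerically zero at row(s) "
                             f"{bad.tolist()[:5]}")
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing with window ``frame`` and polynomial
    ``order``.  Edges are handled by fitting the polynomial on the truncated
    window ("interp" mode), so output length equals input length."""

    def __init__(self, frame: int = 7, order: int = 5):
        self.frame = frame
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        _validate_savgol(self.frame, self.order)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.frame > X.shape[1]:
            raise ValueError("frame exceeds channel count")
        return savgol_filter(X, self.frame, self.order, axis=1, mode="interp")


def _validate_savgol(frame: int, order: int) -> None:
    if frame not in VALID_FRAMES:
        raise ValueError(f"frame must be odd in {VALID_FRAMES}, got {frame}")
    if not 1 <= order <= 7:
        raise ValueError(f"order must lie in [1, 7], got {order}")
    if order >= frame:
        raise ValueError(f"order {order} must be below frame {frame}")


# ---------------------------------------------------------------------------
# preprocessing specs: ordered step lists, e.g. "savgol:7:5,snv"
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered preprocessing steps from {none, snv, msc, savgol:f:o}."""

    steps: tuple[str, ...] = ("none",)

    def __post_init__(self) -> None:
        for step in self.steps:
            if step in ("none", "snv", "msc"):
                continue
            if step.startswith("savgol:"):
                frame, order = self._savgol_params(step)
                _validate_savgol(frame, order)
                continue
            raise ValueError(f"unknown preprocessing step {step!r}")

    @staticmethod
    def _savgol_params(step: str) -> tuple[int, int]:
        try:
            _, frame, order = step.split(":")
            return int(frame), int(order)
        except ValueError:
            raise ValueError(
                f"savgol step must look like 'savgol:7:5', got {step!r}"
            ) from None

    @classmethod
    def parse(cls, text: str) -> "PreprocessSpec":
        return cls(tuple(s.strip() for s in text.split(",") if s.strip()))

    @property
    def name(self) -> str:
        return "+".join(self.steps)


def _step_transformer(step: str):
    if step == "snv":
        return SNVScaler()
    if step == "msc":
        return MSCCorrector()
    if step.startswith("savgol:"):
        frame, order = PreprocessSpec._savgol_params(step)
        return SavitzkyGolaySmoother(frame, order)
    return None  # "none"


# SpectraSet-level wrappers ---------------------------------------------------

def snv(s: SpectraSet) -> SpectraSet:
    """SNV per spectrum; errors name the offending sample."""
    sd = s.reflectance.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum for sample(s) "
            f"{[s.sample_ids[i] for i in bad[:5]]}")
    return s.with_reflectance(SNVScaler().fit_transform(s.reflectance))


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    corr = MSCCorrector(reference=reference).fit(s.reflectance)
    try:
        out = corr.transform(s.reflectance)
    except ValueError as exc:
        raise _check_rows_msc(s, exc) from None
    return s.with_reflectance(out)


def _check_rows_msc(s: SpectraSet, exc: ValueError) -> ValueError:
    import re
    m = re.search(r"row\(s\) \[([0-9, ]+)\]", str(exc))
    if not m:
        return exc
    rows = [int(x) for x in m.group(1).split(",")]
    ids = [s.sample_ids[i] for i in rows]
    return ValueError(f"MSC slope numerically zero for sample(s) {ids}")


def savgol(s: SpectraSet, frame: int, order: int) -> SpectraSet:
    return s.with_reflectance(
        SavitzkyGolaySmoother(frame, order).fit_transform(s.reflectance))


def apply(spec: PreprocessSpec, s: SpectraSet) -> SpectraSet:
    """Apply the steps of ``spec`` in listed order; "none" is the identity."""
    out = s
    for step in spec.steps:
        if step == "none":
            continue
        elif step == "snv":
            out = snv(out)
        elif step == "msc":
            out = msc(out)
        else:
            frame, order = PreprocessSpec._savgol_params(step)
            out = savgol(out, frame, order)
    return out


# ---------------------------------------------------------------------------
# comparison of preprocessing candidates by PLSR performance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessRow:
    spec: PreprocessSpec
    n_factors: int
    r_c: float
    rmse_c: float
    r_v: float
    rmse_v: float

    def to_dict(self) -> dict:
        return {"preprocessing": self.spec.name, "n_factors": self.n_factors,
                "r_c": self.r_c, "rmse_c": self.rmse_c,
                "r_v": self.r_v, "rmse_v": self.rmse_v}


@dataclass(frozen=True)
class PreprocessComparison:
    rows: tuple[PreprocessRow, ...]
    chosen: int

    @property
    def winner(self) -> PreprocessRow:
        return self.rows[self.chosen]

    def to_dicts(self) -> list[dict]:
        out = []
        for i, row in enumerate(self.rows):
            d = row.to_dict()
            d["chosen"] = i == self.chosen
            out.append(d)
        return out


def _plsr_metrics(X: np.ndarray, y: np.ndarray, split: DatasetSplit,
                  max_factors: int) -> tuple[int, float, float, float, float]:
    cal, val = split.calibration_idx, split.validation_idx
    if cal.size < 4 or val.size < 2:
        raise ValueError("degenerate split: too few calibration or "
                         "validation samples")
    folds = min(10, cal.size // 2)
    nf = choose_factors(X[cal], y[cal], max_factors=max_factors, folds=folds)
    model = PLSRegressor(n_factors=nf).fit(X[cal], y[cal])
    pc, pv = model.predict(X[cal]), model.predict(X[val])
    return (nf, correlation(pc, y[cal]), rmse(pc, y[cal]),
            correlation(pv, y[val]), rmse(pv, y[val]))


def savgol_grid_search(s: SpectraSet, r: ReferenceSet, split: DatasetSplit,
                       max_factors: int = 10
                       ) -> tuple[tuple[int, int], list[dict]]:
    """Pick the (frame, order) pair maximizing validation R (tie: lower
    validation RMSE, then first in grid order) over frames {3,5,7,9} and
    orders 1..min(frame-1, 7)."""
    y = r.aligned_to(s)
    table = []
    best = None
    for frame in VALID_FRAMES:
        for order in range(1, min(frame, 8)):
            X = savgol(s, frame, order).reflectance
            nf, r_c, rmse_c, r_v, rmse_v = _plsr_metrics(X, y, split,
                                                         max_factors)
            table.append({"frame": frame, "order": order, "n_factors": nf,
                          "r_c": r_c, "rmse_c": rmse_c,
                          "r_v": r_v, "rmse_v": rmse_v})
            key = (-r_v, rmse_v)
            if best is None or key < best[0]:
                best = (key, (frame, order))
    return best[1], table


def default_candidates(best_savgol: tuple[int, int]) -> list[PreprocessSpec]:
    f, o = best_savgol
    sg = f"savgol:{f}:{o}"
    return [PreprocessSpec(("none",)), PreprocessSpec(("msc",)),
            PreprocessSpec(("snv",)), PreprocessSpec((sg,)),
            PreprocessSpec((sg, "msc")), PreprocessSpec((sg, "snv"))]


def compare_preprocessing(s: SpectraSet, r: ReferenceSet, split: DatasetSplit,
                          candidates: Sequence[PreprocessSpec] | None = None,
                          max_factors: int = 10) -> PreprocessComparison:
    """Fit a PLSR model per candidate preprocessing and rank them.

    Winner: highest validation R; ties broken by lowest validation RMSE,
    then by the smallest calibration/validation R gap (robustness), then by
    list position.  When ``candidates`` is None the default slate is used:
    none, MSC, SNV, the grid-search-optimal S-G filter, and S-G combined
    with MSC or SNV.
    """
    if candidates is None:
        best_sg, _ = savgol_grid_search(s, r, split, max_factors)
        candidates = default_candidates(best_sg)
    if not candidates:
        raise ValueError("no preprocessing candidates given")
    y = r.aligned_to(s)
    rows = []
    for spec in candidates:
        X = apply(spec, s).reflectance
        nf, r_c, rmse_c, r_v, rmse_v = _plsr_metrics(X, y, split, max_factors)
        rows.append(PreprocessRow(spec, nf, r_c, rmse_c, r_v, rmse_v))
    keys = [(-row.r_v, row.rmse_v, abs(row.r_c - row.r_v), i)
            for i, row in enumerate(rows)]
    chosen = min(range(len(rows)), key=lambda i: keys[i])
    return PreprocessComparison(tuple(rows), chosen)
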