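"""Characteristic-wavelength selection: SPA and MCUVE.

Two filter-type selectors reduce the ~1000-channel spectra to fewer than a
hundred informative wavelengths before the final SVR model is trained.

SPA (successive projections algorithm) runs in three phases:

1. for every starting channel, grow a chain of channels by repeatedly
   appending the one whose projection orthogonal to the span of the chain
   has the largest norm (minimal collinearity);
2. score every chain prefix by the RMSE of a PLSR model on the validation
   set (RMSEV) and keep the prefix with the smallest RMSEV;
3. rank the surviving channels by the correlation index
   |coefficient x channel SD|, refit on the top-j channels for growing j,
   and keep the smallest j whose RMSEV passes an F-test (alpha = 0.25,
   degrees of freedom Nval/Nval) against the minimum RMSEV.

MCUVE (Monte-Carlo uninformative variable elimination) fits PLSR models on
many random subsets of the calibration samples, forms the stability
C(k) = mean(beta_k) / SD(beta_k) of each channel's coefficient across runs,
orders channels by |C|, and keeps the top-j* channels where j* minimizes
the forward RMSEV trajectory.

Both selectors expose a scikit-learn-style estimator (``fit`` /
``transform`` / ``get_support``) over the functional phases.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .plsr import PLSRegressor, rmse

_EPS = 1e-12


@dataclass(frozen=True)
class SpaConfig:
    """SPA tuning knobs.  ``n_max`` of None means min(Ncal - 1, K, 100);
    the 100 cap keeps selections below the hundred-wavelength budget."""

    n_min: int = 5
    n_max: int | None = None
    alpha: float = 0.25
    max_factors: int = 10

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.n_max is not None and self.n_max < self.n_min:
            raise ValueError("n_max must be >= n_min")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    def resolved_n_max(self, n_cal: int, k: int) -> int:
        cap = min(n_cal - 1, k, 100)
        n_max = cap if self.n_max is None else min(self.n_max, cap)
        return max(n_max, 1)


@dataclass(frozen=True)
class McuveConfig:
    """MCUVE tuning knobs: number of Monte-Carlo runs, fraction of the
    calibration set drawn per run, PLSR factor cap, forward-trajectory
    length cap, and the capping value for degenerate stabilities."""

    n_runs: int = 500
    sample_fraction: float = 0.8
    max_factors: int = 10
    max_wavelengths: int = 100
    stability_cap: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.sample_fraction < 1:
            raise ValueError("sample_fraction must lie in (0, 1)")
        if self.max_wavelengths < 1:
            raise ValueError("max_wavelengths must be >= 1")


@dataclass(frozen=True)
class WavelengthSelection:
    """Result of a selector: ordered channel indices, the RMSEV trajectory
    that justified them, and per-channel diagnostics."""

    method: str
    selected: np.ndarray
    trajectory: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=int)
        object.__setattr__(self, "selected", sel)
        object.__setattr__(self, "trajectory",
                           np.asarray(self.trajectory, dtype=float))
        if sel.size == 0:
            raise ValueError("empty selection")
        if np.unique(sel).size != sel.size:
            raise ValueError("selected indices must be unique")


def _fit_prefix(Xcal, ycal, cols, max_factors) -> PLSRegressor:
    cols = np.asarray(cols, dtype=int)
    nf = max(1, min(max_factors, cols.size, Xcal.shape[0] - 1))
    return PLSRegressor(n_factors=nf).fit(Xcal[:, cols], ycal)


def _rmsev(model: PLSRegressor, Xval, yval, cols) -> float:
    return rmse(model.predict(Xval[:, np.asarray(cols, dtype=int)]), yval)


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_chains(Xcal: np.ndarray, cfg: SpaConfig) -> dict[int, np.ndarray]:
    """Phase 1: one projection chain per valid starting channel.

    Chains are grown on the column-centered calibration matrix by
    successive orthogonal projection; ties and exhausted (zero-projection)
    channels resolve to the lowest index, so an exact duplicate of a chain
    member is appended last.
    """
    X = np.asarray(Xcal, dtype=float)
    n, k = X.shape
    n_max = cfg.resolved_n_max(n, k)
    Xc = X - X.mean(axis=0)
    norms0 = np.linalg.norm(Xc, axis=0)
    scale = norms0.max()
    chains: dict[int, np.ndarray] = {}
    for start in range(k):
        if norms0[start] <= _EPS * max(scale, 1.0):
            warnings.warn(f"SPA: zero-norm starting column {start} skipped",
                          stacklevel=2)
            continue
        P = Xc.copy()
        chain = [start]
        chosen = np.zeros(k, dtype=bool)
        chosen[start] = True
        for _ in range(n_max - 1):
            v = P[:, chain[-1]]
            nv2 = v @ v
            if nv2 > _EPS ** 2:
                P = P - np.outer(v, (v @ P) / nv2)
            proj = np.linalg.norm(P, axis=0)
            proj[chosen] = -1.0
            nxt = int(np.argmax(proj))  # argmax takes the lowest tied index
            chain.append(nxt)
            chosen[nxt] = True
        chains[start] = np.array(chain)
    if not chains:
        raise ValueError("no valid SPA starting columns")
    return chains


def spa_evaluate(chains: dict[int, np.ndarray], Xcal, ycal, Xval, yval,
                 cfg: SpaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Phase 2: score every chain prefix of length n_min..n_max by RMSEV.

    Returns ``(best_subset, table)`` where ``table[start]`` holds RMSEV per
    prefix length (NaN where the start was skipped or the fit failed).
    Ties prefer the shorter prefix, then the lower starting channel.
    """
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    if Xval.shape[0] == 0:
        raise ValueError("SPA needs a non-empty validation set")
    k = Xcal.shape[1]
    n_max = cfg.resolved_n_max(Xcal.shape[0], k)
    n_min = min(cfg.n_min, n_max)
    table = np.full((k, n_max + 1), np.nan)  # column m = prefix length m
    best = None  # (rmsev, length, start)
    for start in sorted(chains):
        chain = chains[start]
        for m in range(n_min, n_max + 1):
            cols = chain[:m]
            try:
                model = _fit_prefix(Xcal, ycal, cols, cfg.max_factors)
                val = _rmsev(model, Xval, yval, cols)
            except (ValueError, np.linalg.LinAlgError):
                continue
            table[start, m] = val
            key = (val, m, start)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("every SPA subproblem was singular")
    _, m_best, start_best = best
    return chains[start_best][:m_best].copy(), table


def spa_eliminate(subset: np.ndarray, Xcal, ycal, Xval, yval,
                  cfg: SpaConfig) -> WavelengthSelection:
    """Phase 3: F-test elimination of uninformative channels.

    Channels are ranked by the correlation index |coefficient x channel SD|
    of a PLSR fit on the whole subset; RMSEV(j) is computed for the top-j
    channels and the smallest j with
    RMSEV(j) <= min RMSEV * sqrt(F^-1(1 - alpha; Nval, Nval)) is kept.
    """
    subset = np.asarray(subset, dtype=int)
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    if subset.size == 1:
        model = _fit_prefix(Xcal, ycal, subset, cfg.max_factors)
        traj = np.array([_rmsev(model, Xval, yval, subset)])
        return WavelengthSelection("spa", subset, traj,
                                   {"correlation_index": [1.0],
                                    "t_rmsev": float(traj[0]),
                                    "ratio": [1.0]})
    model = _fit_prefix(Xcal, ycal, subset, cfg.max_factors)
    index = np.abs(model.coef_ * Xcal[:, subset].std(axis=0, ddof=1))
    order = np.argsort(-index, kind="stable")
    ranked = subset[order]
    traj = np.empty(subset.size)
    for j in range(1, subset.size + 1):
        m = _fit_prefix(Xcal, ycal, ranked[:j], cfg.max_factors)
        traj[j - 1] = _rmsev(m, Xval, yval, ranked[:j])
    nval = len(np.asarray(yval).ravel())
    f_crit = stats.f.ppf(1.0 - cfg.alpha, nval, nval)
    t_rmsev = traj.min() * np.sqrt(f_crit)
    passing = np.flatnonzero(traj <= t_rmsev)
    j_star = int(passing[0] + 1) if passing.size else int(np.argmin(traj) + 1)
    floor = traj.min() if traj.min() > 0 else 1.0  # exact fits: ratio moot
    diagnostics = {"correlation_index": index[order].tolist(),
                   "ratio": (traj / floor).tolist(),
                   "t_rmsev": float(t_rmsev),
                   "f_critical": float(f_crit)}
    return WavelengthSelection("spa", ranked[:j_star], traj, diagnostics)


def spa_select(Xcal, ycal, Xval, yval,
               cfg: SpaConfig | None = None) -> WavelengthSelection:
    """All three SPA phases; see the module docstring."""
    cfg = cfg or SpaConfig()
    chains = spa_chains(Xcal, cfg)
    subset, table = spa_evaluate(chains, Xcal, ycal, Xval, yval, cfg)
    result = spa_eliminate(subset, Xcal, ycal, Xval, yval, cfg)
    per_size = np.array([np.nanmin(col) if np.isfinite(col).any() else np.nan
                         for col in table.T])
    diag = dict(result.diagnostics)
    diag["rmsev_by_subset_size"] = per_size.tolist()
    return WavelengthSelection("spa", result.selected, result.trajectory, diag)


# ---------------------------------------------------------------------------
# MCUVE
# ---------------------------------------------------------------------------

def mcuve_stability(Xcal, ycal, cfg: McuveConfig) -> np.ndarray:
    """Stability C(k) = mean over runs / SD over runs of each channel's PLSR
    coefficient, across seeded Monte-Carlo draws of the calibration set.

    Channels whose coefficient SD underflows get C = sign(mean) * cap (or 0
    for an identically-zero coefficient), with a warning.
    """
    X = np.asarray(Xcal, dtype=float)
    y = np.asarray(ycal, dtype=float).ravel()
    n, k = X.shape
    m = int(np.ceil(cfg.sample_fraction * n))
    if m < cfg.max_factors + 2:
        raise ValueError(
            f"subsample size {m} too small for max_factors={cfg.max_factors}")
    rng = np.random.default_rng(cfg.seed)
    betas = np.empty((k, cfg.n_runs))
    for run in range(cfg.n_runs):
        pick = rng.choice(n, size=m, replace=False)
        nf = max(1, min(cfg.max_factors, m - 1, k))
        model = PLSRegressor(n_factors=nf).fit(X[pick], y[pick])
        betas[:, run] = model.coef_
    mean = betas.mean(axis=1)
    sd = betas.std(axis=1, ddof=1)
    degenerate = sd < _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        c = mean / sd
    if degenerate.any():
        warnings.warn(
            f"MCUVE: {int(degenerate.sum())} channel(s) with degenerate "
            "coefficient SD; stability capped", stacklevel=2)
        c[degenerate] = np.sign(mean[degenerate]) * cfg.stability_cap
    return c


def mcuve_select(c: np.ndarray, Xcal, ycal, Xval, yval,
                 cfg: McuveConfig) -> WavelengthSelection:
    """Forward selection along the |C| ranking.

    Channels are ordered by descending |C| (ties to the lower index); for
    each j up to ``max_wavelengths`` a PLSR model on the top-j channels is
    scored by RMSEV, and the j* minimizing the trajectory (ties: smaller j)
    is returned.
    """
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("stability vector must be finite (cap degenerates)")
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    k = c.size
    order = np.argsort(-np.abs(c), kind="stable")
    j_max = min(k, cfg.max_wavelengths)
    traj = np.empty(j_max)
    for j in range(1, j_max + 1):
        cols = order[:j]
        model = _fit_prefix(Xcal, ycal, cols, cfg.max_factors)
        traj[j - 1] = _rmsev(model, Xval, yval, cols)
    # rounding makes numerically-tied minima resolve to the smaller j
    j_star = int(np.argmin(np.round(traj, 12)) + 1)
    return WavelengthSelection("mcuve", order[:j_star], traj,
                               {"stability": c.tolist(),
                                "ranking": order.tolist()})


def mcuve_run(Xcal, ycal, Xval, yval,
              cfg: McuveConfig | None = None) -> WavelengthSelection:
    cfg = cfg or McuveConfig()
    c = mcuve_stability(Xcal, ycal, cfg)
    return mcuve_select(c, Xcal, ycal, Xval, yval, cfg)


# ---------------------------------------------------------------------------
# estimator facades
# ---------------------------------------------------------------------------

class _BaseSelector(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing over the functional selector phases."""

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_]

    def get_support(self, indices: bool = False):
        if indices:
            return self.selected_.copy()
        mask = np.zeros(self.n_channels_, dtype=bool)
        mask[self.selected_] = True
        return mask


class SPASelector(_BaseSelector):
    """Successive projections algorithm as a transformer.

    ``fit(X, y, X_val=..., y_val=...)`` requires a held-out validation set
    (the RMSEV criterion is defined on it).  Fitted attributes:
    ``selected_`` (importance-ordered channel indices), ``trajectory_``,
    ``diagnostics_``, ``n_channels_``.
    """

    def __init__(self, n_min: int = 5, n_max: int | None = None,
                 alpha: float = 0.25, max_factors: int = 10):
        self.n_min = n_min
        self.n_max = n_max
        self.alpha = alpha
        self.max_factors = max_factors

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None or y_val is None:
            raise ValueError("SPASelector.fit requires X_val and y_val")
        cfg = SpaConfig(self.n_min, self.n_max, self.alpha, self.max_factors)
        result = spa_select(X, y, X_val, y_val, cfg)
        self.n_channels_ = np.asarray(X).shape[1]
        self.selected_ = result.selected
        self.trajectory_ = result.trajectory
        self.diagnostics_ = result.diagnostics
        self.result_ = result
        return self


class MCUVESelector(_BaseSelector):
    """Monte-Carlo UVE as a transformer; see :class:`SPASelector` for the
    fit signature.  Adds ``stability_`` (C per channel)."""

    def __init__(self, n_runs: int = 500, sample_fraction: float = 0.8,
                 max_factors: int = 10, max_wavelengths: int = 100,
                 seed: int = 0):
        self.n_runs = n_runs
        self.sample_fraction = sample_fraction
        self.max_factors = max_factors
        self.max_wavelengths = max_wavelengths
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None or y_val is None:
            raise ValueError("MCUVESelector.fit requires X_val and y_val")
        cfg = McuveConfig(self.n_runs, self.sample_fraction, self.max_factors,
                          self.max_wavelengths, seed=self.seed)
        c = mcuve_stability(X, y, cfg)
        result = mcuve_select(c, X, y, X_val, y_val, cfg)
        self.n_channels_ = np.asarray(X).shape[1]
        self.stability_ = c
        self.selected_ = result.selected
        self.trajectory_ = result.trajectory
        self.diagnostics_ = result.diagnostics
        self.result_ = result
        return self
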