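"""RBF-kernel support vector regression tuned by particle swarm optimization.

The final SCC model is an epsilon-SVR with Gaussian kernel
K(u, v) = exp(-g * ||u - v||^2) on the selected wavelengths.  Its two
hyperparameters — penalty C and kernel width g — are searched by a standard
global-best PSO in log10 space: each particle's fitness is the k-fold
cross-validated RMSE of the SVR on the calibration set, velocities follow
the usual inertia/cognitive/social update with linearly decaying inertia,
and positions are clipped to the bounds.  Everything is seeded.

Channels are standardized (training mean/SD) before the kernel so a single
g is meaningful across wavelengths; y is standardized too and predictions
are returned on the original % scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .plsr import correlation, rmse


@dataclass(frozen=True)
class SvrParams:
    c: float
    g: float
    epsilon: float = 0.01  # on the standardized-y scale

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0 or self.epsilon < 0:
            raise ValueError("require c > 0, g > 0, epsilon >= 0")


@dataclass(frozen=True)
class PsoConfig:
    swarm_size: int = 20
    iterations: int = 100
    inertia: tuple[float, float] = (0.9, 0.4)
    cognitive: float = 1.7
    social: float = 1.7
    c_bounds: tuple[float, float] = (0.01, 100.0)
    g_bounds: tuple[float, float] = (0.001, 10.0)
    folds: int = 5
    epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2 or self.iterations < 1:
            raise ValueError("swarm_size >= 2 and iterations >= 1 required")
        for lo, hi in (self.c_bounds, self.g_bounds):
            if lo <= 0 or hi < lo:
                raise ValueError("bounds must be positive with min <= max")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class RBFSVR(RegressorMixin, BaseEstimator):
    """Epsilon-SVR with RBF kernel on standardized inputs and response.

    ``g`` is the libsvm-style gamma of exp(-g * ||u - v||^2); ``epsilon``
    is the insensitive-tube width on the standardized-y scale.
    """

    def __init__(self, c: float = 1.0, g: float = 0.1,
                 epsilon: float = 0.01):
        self.c = c
        self.g = g
        self.epsilon = epsilon

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training inputs")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        SvrParams(self.c, self.g, self.epsilon)
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(y.mean())
        y_sd = float(y.std())
        self.y_sd_ = y_sd if y_sd > 0 else 1.0
        Xs = (X - self.x_mean_) / self.x_sd_
        ys = (y - self.y_mean_) / self.y_sd_
        self.svr_ = SVR(kernel="rbf", C=self.c, gamma=self.g,
                        epsilon=self.epsilon)
        self.svr_.fit(Xs, ys)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xs = (X - self.x_mean_) / self.x_sd_
        return self.svr_.predict(Xs) * self.y_sd_ + self.y_mean_


def train_svr(X, y, params: SvrParams) -> RBFSVR:
    return RBFSVR(c=params.c, g=params.g, epsilon=params.epsilon).fit(X, y)


def fitness(X, y, params: SvrParams, folds: int = 5, seed: int = 0) -> float:
    """k-fold cross-validated RMSE (% SCC) of the SVR on the calibration
    set; the PSO objective.  Deterministic given the seed (fold assignment
    is the only randomness)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if X.shape[0] < folds:
        raise ValueError(f"{X.shape[0]} samples cannot fill {folds} folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in kf.split(X):
        model = train_svr(X[train], y[train], params)
        pred[test] = model.predict(X[test])
    return rmse(pred, y)


def pso_optimize(X, y, cfg: PsoConfig | None = None
                 ) -> tuple[SvrParams, float, np.ndarray]:
    """Global-best PSO over (C, g), searched in log10 space.

    Returns ``(best_params, best_fitness, trajectory)`` with the
    best-so-far fitness per iteration (non-increasing by construction).
    """
    cfg = cfg or PsoConfig()
    lo = np.log10([cfg.c_bounds[0], cfg.g_bounds[0]])
    hi = np.log10([cfg.c_bounds[1], cfg.g_bounds[1]])
    span = hi - lo

    def evaluate(z: np.ndarray) -> float:
        params = SvrParams(10.0 ** z[0], 10.0 ** z[1], cfg.epsilon)
        return fitness(X, y, params, folds=cfg.folds, seed=cfg.seed)

    if np.all(span == 0):  # degenerate bounds: a single candidate
        best = evaluate(lo)
        return (SvrParams(10.0 ** lo[0], 10.0 ** lo[1], cfg.epsilon),
                best, np.array([best]))

    rng = np.random.default_rng(cfg.seed)
    pos = lo + span * rng.uniform(size=(cfg.swarm_size, 2))
    vel = 0.1 * span * rng.uniform(-1, 1, size=(cfg.swarm_size, 2))
    pbest_pos = pos.copy()
    pbest_fit = np.array([evaluate(p) for p in pos])
    g_idx = int(np.argmin(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g_idx].copy(), float(pbest_fit[g_idx])
    trajectory = [gbest_fit]

    w_start, w_end = cfg.inertia
    for it in range(1, cfg.iterations):
        w = w_start + (w_end - w_start) * it / max(cfg.iterations - 1, 1)
        r1 = rng.uniform(size=(cfg.swarm_size, 2))
        r2 = rng.uniform(size=(cfg.swarm_size, 2))
        vel = (w * vel + cfg.cognitive * r1 * (pbest_pos - pos)
               + cfg.social * r2 * (gbest_pos - pos))
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            f = evaluate(pos[i])
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest_pos[i] = pos[i]
                if f < gbest_fit:
                    gbest_fit = f
                    gbest_pos = pos[i].copy()
        trajectory.append(gbest_fit)
    params = SvrParams(10.0 ** gbest_pos[0], 10.0 ** gbest_pos[1],
                       cfg.epsilon)
    return params, gbest_fit, np.array(trajectory)


class PSOSVR(RegressorMixin, BaseEstimator):
    """SVR whose (C, g) are tuned by PSO at fit time.

    Fitted attributes: ``best_params_``, ``best_fitness_``, ``trajectory_``
    (best CV RMSE per PSO iteration) and ``model_`` (the final RBFSVR
    retrained on all fit data with the tuned parameters).
    """

    def __init__(self, config: PsoConfig | None = None):
        self.config = config

    def fit(self, X, y):
        cfg = self.config or PsoConfig()
        params, fit_val, traj = pso_optimize(X, y, cfg)
        self.best_params_ = params
        self.best_fitness_ = fit_val
        self.trajectory_ = traj
        self.model_ = train_svr(X, y, params)
        return self

    def predict(self, X):
        return self.model_.predict(X)


@dataclass(frozen=True)
class FinalMetrics:
    """Calibration/validation metrics of a fitted model, % SCC units.

    ``max_relative_error_*`` is max_i |pred_i - y_i| / y_i * 100, the
    worst-case evaluating error per set.
    """

    r_c: float
    rmse_c: float
    r_v: float
    rmse_v: float
    max_relative_error_c: float
    max_relative_error_v: float
    relative_errors_c: np.ndarray
    relative_errors_v: np.ndarray

    def to_dict(self) -> dict:
        return {"r_c": self.r_c, "rmse_c": self.rmse_c,
                "r_v": self.r_v, "rmse_v": self.rmse_v,
                "max_relative_error_c": self.max_relative_error_c,
                "max_relative_error_v": self.max_relative_error_v}


def _relative_errors(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.any(y == 0):
        raise ValueError("relative error undefined for y = 0")
    return np.abs(pred - y) / np.abs(y) * 100.0


def evaluate_final(model, split, X, y) -> FinalMetrics:
    """Score a trained model on a calibration/validation split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(getattr(y, "scc", y), dtype=float).ravel()
    cal, val = split.calibration_idx, split.validation_idx
    pc, pv = model.predict(X[cal]), model.predict(X[val])
    rel_c = _relative_errors(pc, y[cal])
    rel_v = _relative_errors(pv, y[val])
    return FinalMetrics(
        r_c=correlation(pc, y[cal]), rmse_c=rmse(pc, y[cal]),
        r_v=correlation(pv, y[val]), rmse_v=rmse(pv, y[val]),
        max_relative_error_c=float(rel_c.max()),
        max_relative_error_v=float(rel_v.max()),
        relative_errors_c=rel_c, relative_errors_v=rel_v)
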