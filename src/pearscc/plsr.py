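"""PLS1 regression (SIMPLS) and the R / RMSE metrics used everywhere.

Partial least squares regression projects the spectra onto a small number of
latent factors chosen to maximize covariance with SCC, then regresses on
those factors.  A single compact implementation is kept here because the
wavelength selectors fit thousands of small PLS models in their inner loops;
SIMPLS computes the full coefficient path (1..A factors) in one pass, which
the cross-validated factor chooser exploits.

X and y are mean-centered, not variance-scaled: SNV/MSC already condition
the spectra, and coefficient magnitudes stay interpretable per channel.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


def _simpls_path(X: np.ndarray, y: np.ndarray, n_factors: int
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """SIMPLS for a univariate response.

    Returns ``(B_path, x_mean, y_mean)`` where column ``a-1`` of ``B_path``
    is the coefficient vector of the a-factor model on centered data.  May
    return fewer columns than requested if the residual covariance is
    exhausted (exact fit reached early).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc                      # covariance direction
    R = np.zeros((k, n_factors))       # x-weights
    V = np.zeros((k, n_factors))       # orthonormal basis of loadings
    q = np.zeros(n_factors)            # y-loadings
    a_eff = 0
    for a in range(n_factors):
        r = s.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t)
        if t_norm < 1e-12 * max(1.0, np.linalg.norm(Xc)):
            break
        t /= t_norm
        r /= t_norm
        p = Xc.T @ t
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
        v_norm = np.linalg.norm(v)
        if v_norm < 1e-12:
            break
        v /= v_norm
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
        q[a] = yc @ t
        a_eff = a + 1
    if a_eff == 0:
        # y uncorrelated with X at machine precision: constant model
        return np.zeros((k, 1)), x_mean, y_mean
    B_path = np.cumsum(R[:, :a_eff] * q[:a_eff], axis=1)
    return B_path, x_mean, y_mean


class PLSRegressor(RegressorMixin, BaseEstimator):
    """PLS1 regression with ``n_factors`` latent variables.

    Attributes (after fit): ``coef_`` (per-channel coefficients),
    ``intercept_``, ``x_mean_``, ``y_mean_``, ``n_factors_`` (effective
    number of factors, which may be below the request if the fit became
    exact), ``coef_path_`` (channels x factors coefficient path).
    """

    def __init__(self, n_factors: int = 10):
        self.n_factors = n_factors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, k = X.shape
        if n != y.size:
            raise ValueError("X rows and y length differ")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if not 1 <= self.n_factors <= min(n - 1, k):
            raise ValueError(
                f"n_factors must lie in [1, min(n-1, K)] = "
                f"[1, {min(n - 1, k)}], got {self.n_factors}")
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")
        B_path, x_mean, y_mean = _simpls_path(X, y, self.n_factors)
        self.coef_path_ = B_path
        self.n_factors_ = B_path.shape[1]
        self.coef_ = B_path[:, -1]
        self.x_mean_ = x_mean
        self.y_mean_ = float(y_mean)
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef_.size:
            raise ValueError(
                f"model expects {self.coef_.size} channels, got {X.shape[1]}")
        return X @ self.coef_ + self.intercept_

    def predict_with_factors(self, X, a: int):
        """Prediction of the a-factor sub-model (a <= n_factors_)."""
        if not 1 <= a <= self.n_factors_:
            raise ValueError("factor count outside fitted path")
        b = self.coef_path_[:, a - 1]
        return np.asarray(X, dtype=float) @ b + (self.y_mean_ - self.x_mean_ @ b)

    def to_dict(self) -> dict:
        return {"n_factors": int(self.n_factors_),
                "coefficients": self.coef_.tolist(),
                "intercept": self.intercept_,
                "x_mean": self.x_mean_.tolist(),
                "y_mean": self.y_mean_}


def fit_plsr(X, y, n_factors: int) -> PLSRegressor:
    """Fit a PLS1 model; see :class:`PLSRegressor`."""
    return PLSRegressor(n_factors=n_factors).fit(X, y)


def predict(model: PLSRegressor, X) -> np.ndarray:
    return model.predict(X)


def rmse(pred, obs) -> float:
    """Root mean square error, 1/N convention."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ValueError("pred and obs lengths differ")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def correlation(pred, obs) -> float:
    """Pearson correlation coefficient."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ValueError("pred and obs lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("zero-variance input to correlation")
    return float(np.corrcoef(pred, obs)[0, 1])


def choose_factors(X, y, max_factors: int = 10, folds: int = 10) -> int:
    """Factor count minimizing venetian-blind cross-validated RMSE.

    Folds are assigned deterministically by index stride (sample i goes to
    fold ``i % folds``); ties prefer fewer factors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if folds < 2 or n < folds + 2:
        raise ValueError(f"n = {n} too small for {folds}-fold CV")
    a_max = min(max_factors, n - 1 - int(np.ceil(n / folds)), k)
    a_max = max(a_max, 1)
    press = np.zeros(a_max)
    counts = np.zeros(a_max)
    idx = np.arange(n)
    for f in range(folds):
        test = idx[idx % folds == f]
        train = idx[idx % folds != f]
        cap = min(a_max, train.size - 1, k)
        B_path, x_mean, y_mean = _simpls_path(X[train], y[train], cap)
        a_fit = B_path.shape[1]
        pred = (X[test] - x_mean) @ B_path + y_mean  # (n_test, a_fit)
        resid = pred - y[test][:, None]
        press[:a_fit] += (resid ** 2).sum(axis=0)
        counts[:a_fit] += test.size
        if a_fit < a_max:  # exact fit reached: higher counts behave the same
            press[a_fit:] += (resid[:, -1] ** 2).sum()
            counts[a_fit:] += test.size
    cv_rmse = np.sqrt(press / counts)
    return int(np.argmin(np.round(cv_rmse, 12)) + 1)
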