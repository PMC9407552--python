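"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (plain loops,
brute force) kept separate from the package code they check.
"""
from __future__ import annotations

import numpy as np
import pytest

from pearscc import (ReferenceSet, SpectraSet, SyntheticConfig, generate,
                     make_fixture)


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny-10x8")


@pytest.fixture(scope="session")
def paper_like():
    return make_fixture("paper-like-120")


@pytest.fixture
def small_spectra():
    rng = np.random.default_rng(42)
    wl = np.linspace(500.0, 900.0, 50)
    refl = 0.5 + 0.1 * rng.standard_normal((20, 50))
    ids = tuple(f"P{i:03d}" for i in range(20))
    return SpectraSet(wl, refl, ids)


@pytest.fixture
def small_synthetic():
    """Fast, modest-noise synthetic set for downstream-stage tests."""
    cfg = SyntheticConfig(n_samples=40, replicates_per_sample=1,
                          grid=(498.0, 1018.0, 8.0), seed=5)
    return generate(cfg)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def spxy_bruteforce(X: np.ndarray, y: np.ndarray, n_cal: int) -> list[int]:
    """Max-min joint-distance selection by exhaustive loops (no vector
    tricks); ties broken by lowest index, matching the documented rule for
    bare arrays."""
    n = X.shape[0]
    dx = np.zeros((n, n))
    dy = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dx[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
            dy[i, j] = abs(y[i] - y[j])
    d = dx / dx.max() + (dy / dy.max() if dy.max() > 0 else dy)
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    selected = list(pair)
    while len(selected) < n_cal:
        best_c, best_d = None, -1.0
        for c in range(n):
            if c in selected:
                continue
            dmin = min(d[c, s] for s in selected)
            if dmin > best_d:
                best_d, best_c = dmin, c
        selected.append(best_c)
    return selected


def spa_chain_bruteforce(X: np.ndarray, start: int, n_max: int) -> list[int]:
    """Sequential max-orthogonal-projection selection via explicit
    Gram-Schmidt on the centered columns."""
    Xc = X - X.mean(axis=0)
    k = Xc.shape[1]
    chain = [start]
    basis: list[np.ndarray] = []
    v = Xc[:, start].astype(float)
    while len(chain) < n_max:
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
        best_j, best_norm = None, -1.0
        for j in range(k):
            if j in chain:
                continue
            resid = Xc[:, j].astype(float)
            for b in basis:
                resid = resid - (b @ resid) * b
            norm = np.linalg.norm(resid)
            if norm > best_norm + 1e-12:
                best_norm, best_j = norm, j
        chain.append(best_j)
        resid = Xc[:, best_j].astype(float)
        for b in basis:
            resid = resid - (b @ resid) * b
        v = resid
    return chain
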