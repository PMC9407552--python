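"""SPA chain/evaluate/eliminate phases and MCUVE stability/selection."""
import numpy as np
import pytest

from pearscc import (McuveConfig, SpaConfig, mcuve_run, mcuve_select,
                     mcuve_stability, spa_chains, spa_eliminate,
                     spa_evaluate, spa_select)
from pearscc.selection import MCUVESelector, SPASelector
from conftest import spa_chain_bruteforce


def informative_noise_problem(n, n_inform, n_noise, seed, noise_sd=0.05):
    """y is a sparse linear function of the informative block; the noise
    block is pure standard normal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_inform + n_noise))
    beta = np.zeros(n_inform + n_noise)
    beta[:n_inform] = rng.uniform(0.5, 1.5, size=n_inform)
    y = X @ beta + noise_sd * rng.standard_normal(n)
    return X, y


class TestSpaChains:
    def test_orthogonal_columns_ordered_by_norm(self):
        # centered orthogonal columns of norms 3 > 2 > 1: projection leaves
        # the remaining columns untouched, so the chain orders by norm
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((12, 3))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = Q * np.array([1.0, 3.0, 2.0])
        chains = spa_chains(X, SpaConfig(n_min=1, n_max=3))
        assert chains[1].tolist() == [1, 2, 0]

    def test_duplicate_column_appended_last(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 4))
        X = np.column_stack([X, X[:, 0]])  # column 4 duplicates column 0
        chains = spa_chains(X, SpaConfig(n_min=1, n_max=5))
        assert chains[0][-1] == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gram_schmidt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((10, 6))
        chains = spa_chains(X, SpaConfig(n_min=1, n_max=6))
        for start in range(6):
            expected = spa_chain_bruteforce(X, start, 6)
            assert chains[start].tolist() == expected

    def test_chains_never_repeat_channels(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 8))
        chains = spa_chains(X, SpaConfig(n_min=1, n_max=8))
        for chain in chains.values():
            assert len(set(chain.tolist())) == len(chain)


class TestSpaEvaluate:
    def test_exact_two_channel_recovery(self):
        rng = np.random.default_rng(2)
        Xc = rng.standard_normal((30, 6))
        Xv = rng.standard_normal((12, 6))
        beta = np.array([0.0, 2.0, 0.0, -1.0, 0.0, 0.0])
        yc, yv = Xc @ beta, Xv @ beta
        cfg = SpaConfig(n_min=1, n_max=4)
        chains = spa_chains(Xc, cfg)
        subset, table = spa_evaluate(chains, Xc, yc, Xv, yv, cfg)
        assert {1, 3} <= set(subset.tolist())
        assert np.nanmin(table) < 1e-6

    def test_single_length_equals_univariate_argmin(self):
        rng = np.random.default_rng(3)
        Xc = rng.standard_normal((25, 5))
        Xv = rng.standard_normal((10, 5))
        beta = np.array([0.1, 0.2, 1.5, 0.0, 0.3])
        yc = Xc @ beta + 0.05 * rng.standard_normal(25)
        yv = Xv @ beta + 0.05 * rng.standard_normal(10)
        cfg = SpaConfig(n_min=1, n_max=1)
        chains = spa_chains(Xc, cfg)
        subset, _ = spa_evaluate(chains, Xc, yc, Xv, yv, cfg)
        # exhaustive univariate oracle
        best_k, best_err = None, np.inf
        for k in range(5):
            A = np.column_stack([np.ones(25), Xc[:, k]])
            coef, *_ = np.linalg.lstsq(A, yc, rcond=None)
            pred = coef[0] + coef[1] * Xv[:, k]
            err = np.sqrt(np.mean((pred - yv) ** 2))
            if err < best_err:
                best_err, best_k = err, k
        assert subset.tolist() == [best_k]

    def test_returned_minimum_is_table_minimum(self):
        rng = np.random.default_rng(4)
        Xc = rng.standard_normal((20, 6))
        Xv = rng.standard_normal((8, 6))
        yc = Xc @ np.array([1.0, 0, 0.5, 0, 0, -0.3])
        yv = Xv @ np.array([1.0, 0, 0.5, 0, 0, -0.3])
        cfg = SpaConfig(n_min=2, n_max=5)
        chains = spa_chains(Xc, cfg)
        subset, table = spa_evaluate(chains, Xc, yc, Xv, yv, cfg)
        start = [s for s, ch in chains.items()
                 if ch[:len(subset)].tolist() == subset.tolist()]
        assert start  # best subset is a prefix of one of the chains
        assert np.nanmin(table) == pytest.approx(
            np.nanmin(table[start[0]]))


class TestSpaEliminate:
    def test_singleton_identity(self):
        rng = np.random.default_rng(5)
        Xc, Xv = rng.standard_normal((20, 3)), rng.standard_normal((8, 3))
        yc, yv = Xc[:, 0], Xv[:, 0]
        out = spa_eliminate(np.array([0]), Xc, yc, Xv, yv, SpaConfig())
        assert out.selected.tolist() == [0]

    def test_drops_appended_noise_channel(self):
        rng = np.random.default_rng(6)
        Xc = rng.standard_normal((30, 2))
        Xv = rng.standard_normal((12, 2))
        yc, yv = 2.0 * Xc[:, 0], 2.0 * Xv[:, 0]  # channel 1 is pure noise
        out = spa_eliminate(np.array([0, 1]), Xc, yc, Xv, yv, SpaConfig())
        assert out.selected.tolist() == [0]

    def test_alpha_limits(self):
        rng = np.random.default_rng(8)
        Xc = rng.standard_normal((25, 4))
        Xv = rng.standard_normal((10, 4))
        beta = np.array([1.0, 0.5, 0.0, 0.0])
        yc = Xc @ beta + 0.1 * rng.standard_normal(25)
        yv = Xv @ beta + 0.1 * rng.standard_normal(10)
        subset = np.arange(4)
        # alpha -> 0: F quantile diverges, every prefix passes, j = 1 wins
        loose = spa_eliminate(subset, Xc, yc, Xv, yv, SpaConfig(alpha=1e-9))
        assert loose.selected.size == 1
        # alpha -> 1: threshold collapses onto the minimum, only the argmin
        # prefix survives
        tight = spa_eliminate(subset, Xc, yc, Xv, yv,
                              SpaConfig(alpha=1.0 - 1e-12))
        assert tight.selected.size == int(np.argmin(tight.trajectory) + 1)


class TestMcuve:
    def test_zero_channel_stability_is_zero_with_warning(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 5))
        X[:, 2] = 0.0
        y = X @ np.array([1.0, 0.5, 0.0, 0.2, 0.0]) + 0.05 * rng.standard_normal(30)
        with pytest.warns(UserWarning, match="degenerate"):
            c = mcuve_stability(X, y, McuveConfig(n_runs=20, max_factors=3,
                                                  seed=1))
        assert c[2] == 0.0

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((30, 8))
        y = X @ rng.standard_normal(8)
        cfg = McuveConfig(n_runs=30, max_factors=4, seed=3)
        np.testing.assert_array_equal(mcuve_stability(X, y, cfg),
                                      mcuve_stability(X, y, cfg))

    def test_informative_channels_outrank_noise(self):
        wins = 0
        for seed in range(20):
            X, y = informative_noise_problem(60, 10, 40, seed)
            c = mcuve_stability(X, y, McuveConfig(n_runs=100, seed=seed))
            inform = np.abs(c[:10]).min()
            noise = np.abs(c[10:]).max()
            wins += inform > noise
        assert wins >= 19

    def test_selects_exact_two_channel_solution(self):
        rng = np.random.default_rng(11)
        Xc, Xv = rng.standard_normal((40, 6)), rng.standard_normal((15, 6))
        beta = np.array([0.0, 1.5, 0.0, 0.0, -1.0, 0.0])
        yc, yv = Xc @ beta, Xv @ beta
        cfg = McuveConfig(n_runs=50, max_factors=4, seed=5)
        c = mcuve_stability(Xc, yc, cfg)
        assert set(np.argsort(-np.abs(c))[:2].tolist()) == {1, 4}
        out = mcuve_select(c, Xc, yc, Xv, yv, cfg)
        assert set(out.selected.tolist()) == {1, 4}
        assert out.trajectory[1] < 1e-6

    def test_selected_size_is_trajectory_argmin(self):
        X, y = informative_noise_problem(50, 5, 15, 12)
        Xv, yv_prob = informative_noise_problem(20, 5, 15, 13)
        cfg = McuveConfig(n_runs=40, seed=2)
        c = mcuve_stability(X, y, cfg)
        out = mcuve_select(c, X, y, Xv, yv_prob, cfg)
        assert out.selected.size == int(np.argmin(out.trajectory) + 1)

    def test_single_channel_input(self):
        rng = np.random.default_rng(13)
        Xc, Xv = rng.standard_normal((20, 1)), rng.standard_normal((8, 1))
        yc, yv = Xc[:, 0], Xv[:, 0]
        out = mcuve_select(np.array([2.0]), Xc, yc, Xv, yv,
                           McuveConfig(n_runs=10))
        assert out.selected.tolist() == [0]

    def test_ranking_invariant_under_positive_scaling(self):
        X, y = informative_noise_problem(40, 4, 8, 14)
        cfg = McuveConfig(n_runs=40, max_factors=5, seed=6)
        c1 = mcuve_stability(X, y, cfg)
        c2 = mcuve_stability(7.5 * X, y, cfg)
        np.testing.assert_array_equal(np.argsort(-np.abs(c1)),
                                      np.argsort(-np.abs(c2)))


class TestSelectorEstimators:
    def test_spa_selector_fit_transform(self):
        rng = np.random.default_rng(15)
        Xc, Xv = rng.standard_normal((30, 8)), rng.standard_normal((12, 8))
        beta = np.array([1.0, 0, 0, 0.5, 0, 0, 0, 0])
        yc, yv = Xc @ beta, Xv @ beta
        sel = SPASelector(n_min=1, n_max=4).fit(Xc, yc, X_val=Xv, y_val=yv)
        assert sel.get_support().sum() == sel.selected_.size
        assert sel.transform(Xc).shape == (30, sel.selected_.size)

    def test_mcuve_selector_requires_validation(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="X_val"):
            MCUVESelector().fit(X, X[:, 0])
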