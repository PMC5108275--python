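"""Redundancy analysis: preprocessing, fits, permutation tests, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markerdiv.rda import (
    fit_rda,
    forward_selection,
    marginal_contributions,
    pearson_correlations,
    permutation_test,
    preprocess,
)
from markerdiv.synthetic_data import simulate_env_linked_diversity


def _random_yx(seed, n=15, p=4, q=3):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    Y = pd.DataFrame(rng.standard_normal((n, p)), index=idx)
    X = pd.DataFrame(
        rng.standard_normal((n, q)), index=idx, columns=[f"x{j}" for j in range(q)]
    )
    return Y, X


class TestPreprocess:
    def test_log_and_centre(self):
        df = pd.DataFrame({"a": [0.0, np.e - 1]})
        out = preprocess(df, standardize=False)
        assert out["a"].tolist() == pytest.approx([-0.5, 0.5])

    def test_zero_maps_to_zero_before_centre(self):
        df = pd.DataFrame({"a": [0.0, 0.0]})
        out = preprocess(df, standardize=False)
        assert (out["a"] == 0).all()

    def test_constant_column_standardize_errors(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            preprocess(df, standardize=True)

    def test_values_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            preprocess(pd.DataFrame({"a": [-1.5, 0.0]}))


class TestFitRda:
    def test_perfect_fit(self):
        _, X = _random_yx(0)
        Y = X[["x0"]].rename(columns={"x0": "y"})
        res = fit_rda(Y, X)
        assert res.explained_fraction == pytest.approx(1.0)

    def test_orthogonal_response(self):
        rng = np.random.default_rng(1)
        n = 12
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        Xc = X - X.mean()
        y = rng.standard_normal(n)
        y = y - y.mean()
        y = y - Xc["x"].to_numpy() * (y @ Xc["x"]) / (Xc["x"] @ Xc["x"])
        res = fit_rda(pd.DataFrame({"y": y}), X)
        assert res.explained_fraction == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_projection_oracle(self, seed):
        """Explained fraction equals tr(Y'HY)/tr(Y'Y), H the hat matrix."""
        Y, X = _random_yx(seed)
        Ym = (Y - Y.mean()).to_numpy()
        Xm = (X - X.mean()).to_numpy()
        H = Xm @ np.linalg.inv(Xm.T @ Xm) @ Xm.T
        oracle = np.trace(Ym.T @ H @ Ym) / np.trace(Ym.T @ Ym)
        res = fit_rda(Y, X)
        assert res.explained_fraction == pytest.approx(oracle, abs=1e-12)
        assert res.axis_fractions.sum() == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_reparameterization_invariance(self, seed):
        Y, X = _random_yx(seed)
        rng = np.random.default_rng(100 + seed)
        A = rng.standard_normal((X.shape[1], X.shape[1]))
        while abs(np.linalg.det(A)) < 1e-3:
            A = rng.standard_normal((X.shape[1], X.shape[1]))
        X2 = pd.DataFrame(X.to_numpy() @ A, index=X.index, columns=X.columns)
        f1 = fit_rda(Y, X).explained_fraction
        f2 = fit_rda(Y, X2).explained_fraction
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_nested_monotonicity(self):
        Y, X = _random_yx(7, q=3)
        fracs = [
            fit_rda(Y, X.iloc[:, :k]).explained_fraction for k in (1, 2, 3)
        ]
        assert fracs[0] <= fracs[1] + 1e-12 <= fracs[2] + 2e-12

    def test_saturated_model_explains_everything(self):
        # n - 1 independent constraints span the centred row space
        Y, X = _random_yx(3, n=8, p=3, q=7)
        res = fit_rda(Y, X)
        assert res.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_collinear_columns_dropped(self):
        Y, X = _random_yx(9)
        X2 = X.copy()
        X2["dup"] = X2["x0"]
        res = fit_rda(Y, X2)
        assert res.dropped_columns == ["dup"]
        assert res.rank == 3

    def test_eigenvalue_accounting(self):
        Y, X = _random_yx(13)
        res = fit_rda(Y, X)
        assert np.all(np.diff(res.constrained_eigenvalues) <= 1e-12)
        total = res.constrained_eigenvalues.sum() + res.unconstrained_eigenvalues.sum()
        assert total == pytest.approx(res.total_variance, rel=1e-9)


class TestPermutationTest:
    def test_minimum_p(self):
        Y, X, _ = simulate_env_linked_diversity(effect_r2=0.8, seed=3)
        _, p = permutation_test(Y, X, "all", n_perm=999, seed=1)
        assert p == pytest.approx(0.001)

    def test_strong_signal_saturates_bound(self):
        Y, X, _ = simulate_env_linked_diversity(
            n_sites=20, effect_r2=0.8, seed=3
        )
        f, p = permutation_test(Y, X, "all", n_perm=999, seed=2)
        assert p == 0.001 and f > 1

    def test_type_i_error_calibrated(self):
        """Rejection rate at alpha = .05 under the null, binomial 95% band."""
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            Y, X, _ = simulate_env_linked_diversity(
                n_sites=20, n_env=3, effect_r2=0.0, seed=40000 + rep
            )
            _, p = permutation_test(Y, X, "all", n_perm=99, seed=rep)
            rej += p <= 0.05
        rate = rej / n_rep
        assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_rep) <= rate
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_single_term_conditioning(self):
        Y, X = _random_yx(21, n=20, q=3)
        f, p = permutation_test(Y, X, "x1", n_perm=99, seed=5)
        assert 0.01 <= p <= 1.0 and f >= 0

    def test_unknown_term(self):
        Y, X = _random_yx(22)
        with pytest.raises(KeyError):
            permutation_test(Y, X, "zz", n_perm=9, seed=0)


class TestForwardSelection:
    def test_informative_variable_found_first(self):
        """One real predictor among noise is picked first in >=95% of runs."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(50000 + rep)
            n = 20
            x1 = rng.standard_normal(n)
            noise = rng.standard_normal((n, 5))
            X = pd.DataFrame(
                np.column_stack([x1, noise]),
                columns=["signal"] + [f"n{j}" for j in range(5)],
            )
            Y = pd.DataFrame(
                {
                    "y1": 2 * x1 + 0.5 * rng.standard_normal(n),
                    "y2": -x1 + 0.5 * rng.standard_normal(n),
                }
            )
            tr = forward_selection(Y, X, alpha=0.05, n_perm=99, seed=rep)
            hits += bool(tr.selected) and tr.selected[0] == "signal"
        assert hits >= 95

    def test_all_noise_rarely_selects(self):
        picks = 0
        n_rep = 60
        for rep in range(n_rep):
            Y, X, _ = simulate_env_linked_diversity(
                n_sites=20, n_env=4, effect_r2=0.0, seed=70000 + rep
            )
            tr = forward_selection(Y, X, alpha=0.05, n_perm=99, seed=rep)
            picks += bool(tr.selected)
        # family error with 4 candidates at alpha=.05 stays well under 50%
        assert picks / n_rep < 0.5

    def test_duplicated_informative_column_selected_once(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.standard_normal(n)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(n)})
        Y = pd.DataFrame({"y": 3 * x + 0.1 * rng.standard_normal(n)})
        tr = forward_selection(Y, X, alpha=0.05, n_perm=199, seed=1)
        assert sum(v in ("a", "b") for v in tr.selected) == 1

    def test_trace_contributions_bounded(self):
        Y, X, _ = simulate_env_linked_diversity(effect_r2=0.6, seed=5)
        tr = forward_selection(Y, X, alpha=0.05, n_perm=99, seed=2)
        total = fit_rda(Y, X).explained_fraction
        sel = [s.conditional_fraction for s in tr.steps if s.selected]
        assert all(f > 0 for f in sel)
        assert sum(sel) <= total + 1e-9


class TestMarginalContributions:
    def test_proportional_response(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(15)
        X = pd.DataFrame({"x1": x, "x2": rng.standard_normal(15)})
        Y = pd.DataFrame({"y": 2.5 * x})
        marg = marginal_contributions(Y, X)
        assert marg["x1"] == pytest.approx(1.0)

    def test_orthogonal_variable_zero(self):
        rng = np.random.default_rng(9)
        n = 14
        y = rng.standard_normal(n)
        y -= y.mean()
        x = rng.standard_normal(n)
        x -= x.mean()
        x -= y * (x @ y) / (y @ y)
        marg = marginal_contributions(
            pd.DataFrame({"y": y}), pd.DataFrame({"x": x, "z": rng.standard_normal(n)})
        )
        assert marg["x"] == pytest.approx(0.0, abs=1e-12)


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        Y = pd.DataFrame({"up": x, "down": -2 * x + 7})
        X = pd.DataFrame({"x": x})
        r, p = pearson_correlations(Y, X)
        assert r.loc["up", "x"] == pytest.approx(1.0)
        assert r.loc["down", "x"] == pytest.approx(-1.0)
        assert (p < 1e-8).all().all()

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(500):
            y = pd.DataFrame({"y": rng.standard_normal(20)})
            x = pd.DataFrame({"x": rng.standard_normal(20)})
            r, _ = pearson_correlations(y, x)
            rs.append(r.iloc[0, 0])
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_flagged_nan(self):
        Y = pd.DataFrame({"y": [1.0, 1.0, 1.0]})
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        r, p = pearson_correlations(Y, X)
        assert np.isnan(r.iloc[0, 0]) and np.isnan(p.iloc[0, 0])

    def test_too_few_rows(self):
        Y = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pearson_correlations(Y, Y)


class TestRecovery:
    def test_explained_fraction_recovers_r2_at_large_n(self):
        Y, X, truth = simulate_env_linked_diversity(
            n_sites=200, effect_r2=0.8, seed=11
        )
        res = fit_rda(Y, X)
        assert res.explained_fraction == pytest.approx(0.8, abs=0.05)

    def test_null_fraction_near_rank_over_n(self):
        """With no signal the overfit fraction concentrates near q/(n-1)."""
        fracs = []
        for rep in range(40):
            Y, X, _ = simulate_env_linked_diversity(
                n_sites=30, n_env=5, effect_r2=0.0, seed=90000 + rep
            )
            fracs.append(fit_rda(Y, X).explained_fraction)
        assert np.mean(fracs) == pytest.approx(5 / 29, abs=0.04)
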