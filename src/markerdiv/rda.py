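"""Redundancy analysis (RDA) of diversity indices on environment.

RDA is the constrained ordination obtained by regressing every response
column on the explanatory matrix and eigen-decomposing the fitted
values: the explained fraction tr(Yhat'Yhat)/tr(Y'Y) is the multivariate
redundancy statistic, and the constrained axes are the principal axes of
the fitted values.  Significance is assessed with Monte Carlo
permutation tests of the pseudo-F statistic, and parsimonious models are
built by forward selection of explanatory variables gated by those
tests.  Variables and responses are log(x+1)-transformed and centred
(optionally standardized) before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RdaResult",
    "ForwardSelectionTrace",
    "preprocess",
    "fit_rda",
    "permutation_test",
    "forward_selection",
    "marginal_contributions",
    "pearson_correlations",
]

_RANK_TOL = 1e-9


@dataclass
class RdaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_variance: float
    explained_fraction: float
    axis_fractions: np.ndarray
    coefficients: pd.DataFrame  # explanatory variables x constrained axes
    rank: int
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class ForwardSelectionStep:
    variable: str
    conditional_fraction: float
    pseudo_F: float | None
    p_value: float | None
    selected: bool


@dataclass
class ForwardSelectionTrace:
    steps: list[ForwardSelectionStep]
    alpha: float

    @property
    def selected(self) -> list[str]:
        return [s.variable for s in self.steps if s.selected]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [s.variable for s in self.steps],
                "conditional_fraction": [s.conditional_fraction for s in self.steps],
                "pseudo_F": [s.pseudo_F for s in self.steps],
                "p_value": [s.p_value for s in self.steps],
                "selected": [s.selected for s in self.steps],
            }
        )


def preprocess(
    raw: pd.DataFrame, standardize: bool = True, log_transform: bool = True
) -> pd.DataFrame:
    """log(x+1)-transform, centre, and optionally standardize columns.

    Standardization divides by the sample SD (ddof=1); a zero-variance
    column under standardization is an error naming the column.
    """
    X = raw.astype(float)
    if log_transform:
        if (X <= -1).any().any():
            raise ValueError("log(x+1) needs all values > -1")
        X = np.log1p(X)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = sd[sd == 0].index.tolist()
        if dead:
            raise ValueError(f"zero-variance column(s) under standardization: {dead}")
        X = X / sd
    return X


def _independent_columns(X: np.ndarray, names: list[str]):
    """Greedy maximal linearly independent column subset (QR-based)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=None) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return keep, dropped


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (centred X assumed)."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((X.shape[0], 0))
    return U[:, s > s[0] * _RANK_TOL]


def _as_centred(M) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    return A - A.mean(axis=0)


def fit_rda(Y: pd.DataFrame, X: pd.DataFrame) -> RdaResult:
    """Fit the redundancy analysis of responses Y on constraints X.

    Y and X must share row order (checked via index when both are
    DataFrames).  Collinear explanatory columns are reduced to a maximal
    independent subset with a logged warning.
    """
    if isinstance(Y, pd.DataFrame) and isinstance(X, pd.DataFrame):
        if not Y.index.equals(X.index):
            raise ValueError("Y and X row labels differ")
    Ym = _as_centred(Y)
    Xm = _as_centred(X)
    n = Ym.shape[0]
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(Xm.shape[1])
    ]
    keep, dropped = _independent_columns(Xm, names)
    if dropped:
        logger.warning("dropping collinear explanatory column(s): %s", dropped)
    Xm = Xm[:, keep]
    names = [names[j] for j in keep]
    rank = Xm.shape[1]
    if rank < 1:
        raise ValueError("rank(X) must be >= 1")
    if n <= rank:
        # rank may legitimately reach n - 1 (saturated: explained = 1)
        raise ValueError(f"need n > rank(X); n={n}, rank={rank}")
    U = _orthobasis(Xm)
    Yhat = U @ (U.T @ Ym)
    resid = Ym - Yhat
    denom = n - 1
    total = float((Ym**2).sum()) / denom
    sv_fit = np.linalg.svd(Yhat, compute_uv=False)
    eig_c = (sv_fit**2) / denom
    eig_c = eig_c[eig_c > max(eig_c[0] if eig_c.size else 0.0, 1e-300) * _RANK_TOL]
    eig_c = eig_c[: min(rank, Ym.shape[1])]
    sv_res = np.linalg.svd(resid, compute_uv=False)
    eig_u = (sv_res**2) / denom
    eig_u = eig_u[eig_u > 1e-12 * max(total, 1.0)]
    explained = float((Yhat**2).sum() / (Ym**2).sum()) if total > 0 else 0.0
    axis_fractions = eig_c / total if total > 0 else eig_c * 0.0
    # canonical coefficients: regression of constrained site scores on X
    Uy, sy, Vty = np.linalg.svd(Yhat, full_matrices=False)
    k = len(eig_c)
    scores = Uy[:, :k] * sy[:k]
    coefs, *_ = np.linalg.lstsq(Xm, scores, rcond=None)
    coef_df = pd.DataFrame(
        coefs, index=names, columns=[f"RDA{i+1}" for i in range(k)]
    )
    return RdaResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_u,
        total_variance=total,
        explained_fraction=explained,
        axis_fractions=axis_fractions,
        coefficients=coef_df,
        rank=rank,
        dropped_columns=dropped,
    )


def _explained_ss(Ym: np.ndarray, U: np.ndarray) -> float:
    Yhat = U @ (U.T @ Ym)
    return float((Yhat**2).sum())


def permutation_test(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    term: str = "all",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte Carlo permutation test of the whole model or of one term.

    For term='all', rows of Y are freely permuted and the overall
    pseudo-F = (SS_fit/m) / (SS_res/(n-1-m)) is recomputed.  For a named
    term, the test conditions on the remaining variables: Y is first
    residualized on them and the residuals are permuted (reduced-model
    permutation).  p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Ym = _as_centred(Y)
    Xm = _as_centred(X)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(Xm.shape[1])
    ]
    n = Ym.shape[0]
    if term == "all":
        keep, _ = _independent_columns(Xm, names)
        Xm = Xm[:, keep]
        m = Xm.shape[1]
        if n - 1 - m < 1:
            raise ValueError("no residual degrees of freedom for pseudo-F")
        U = _orthobasis(Xm)
        tot = float((Ym**2).sum())
        f_obs = _pseudo_f(_explained_ss(Ym, U), tot, m, n)
        count = 0
        for _ in range(n_perm):
            Yp = Ym[rng.permutation(n)]
            if _pseudo_f(_explained_ss(Yp, U), tot, m, n) >= f_obs - 1e-12:
                count += 1
        return f_obs, (1 + count) / (n_perm + 1)
    if term not in names:
        raise KeyError(f"unknown term: {term!r}")
    j = names.index(term)
    others = [k for k in range(Xm.shape[1]) if k != j]
    U_red = _orthobasis(Xm[:, others]) if others else np.zeros((n, 0))
    keep, _ = _independent_columns(Xm, names)
    U_full = _orthobasis(Xm[:, keep])
    m_full = U_full.shape[1]
    if n - 1 - m_full < 1:
        raise ValueError("no residual degrees of freedom for pseudo-F")
    tot = float((Ym**2).sum())
    ss_red = _explained_ss(Ym, U_red)
    ss_full = _explained_ss(Ym, U_full)
    df_term = max(m_full - U_red.shape[1], 1)
    f_obs = ((ss_full - ss_red) / df_term) / (
        (tot - ss_full) / (n - 1 - m_full)
    )
    fitted_red = U_red @ (U_red.T @ Ym)
    resid_red = Ym - fitted_red
    count = 0
    for _ in range(n_perm):
        Yp = fitted_red + resid_red[rng.permutation(n)]
        ss_r = _explained_ss(Yp, U_red)
        ss_f = _explained_ss(Yp, U_full)
        tot_p = float((Yp**2).sum())
        f_p = ((ss_f - ss_r) / df_term) / ((tot_p - ss_f) / (n - 1 - m_full))
        if f_p >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (n_perm + 1)


def _pseudo_f(ss_fit: float, ss_tot: float, m: int, n: int) -> float:
    resid = max(ss_tot - ss_fit, 1e-300)
    return (ss_fit / m) / (resid / (n - 1 - m))


def forward_selection(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelectionTrace:
    """Stepwise forward selection of explanatory variables.

    Each step adds the candidate with the largest additional explained
    variance and tests the addition by reduced-model permutation; the
    procedure stops when the best candidate's p exceeds *alpha*.  Ties
    are broken by column order.  The trace lists the tested candidate of
    every step and, after stopping, the remaining candidates with their
    conditional contributions (untested, p = None).
    """
    if X.shape[1] < 2:
        raise ValueError("forward selection needs >=2 candidate variables")
    rng = np.random.default_rng(seed)
    Ym = _as_centred(Y)
    Xm = _as_centred(X)
    names = list(X.columns)
    n = Ym.shape[0]
    tot = float((Ym**2).sum())
    selected: list[int] = []
    steps: list[ForwardSelectionStep] = []
    remaining = list(range(Xm.shape[1]))
    while remaining:
        U_cur = (
            _orthobasis(Xm[:, selected]) if selected else np.zeros((n, 0))
        )
        ss_cur = _explained_ss(Ym, U_cur)
        gains = []
        for j in remaining:
            U_try = _orthobasis(Xm[:, selected + [j]])
            gains.append(_explained_ss(Ym, U_try) - ss_cur)
        best_pos = int(np.argmax(gains))  # argmax keeps first on ties
        j = remaining[best_pos]
        gain = gains[best_pos]
        if gain <= tot * 1e-12:
            # candidate adds nothing (e.g. duplicated column): record and stop
            for k in remaining:
                steps.append(
                    ForwardSelectionStep(names[k], gains[remaining.index(k)] / tot,
                                         None, None, False)
                )
            break
        sub = pd.DataFrame(
            Xm[:, selected + [j]], columns=[names[k] for k in selected + [j]],
            index=Y.index if isinstance(Y, pd.DataFrame) else None,
        )
        Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(Ym)
        f_obs, p = permutation_test(
            Ydf, sub, term=names[j], n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if p <= alpha:
            steps.append(
                ForwardSelectionStep(names[j], gain / tot, f_obs, p, True)
            )
            selected.append(j)
            remaining.remove(j)
        else:
            steps.append(
                ForwardSelectionStep(names[j], gain / tot, f_obs, p, False)
            )
            for k in remaining:
                if k != j:
                    steps.append(
                        ForwardSelectionStep(
                            names[k], gains[remaining.index(k)] / tot, None, None,
                            False,
                        )
                    )
            break
    return ForwardSelectionTrace(steps=steps, alpha=alpha)


def marginal_contributions(Y: pd.DataFrame, X: pd.DataFrame) -> pd.Series:
    """Explained fraction of a single-variable RDA, per variable."""
    out = {}
    for col in X.columns:
        res = fit_rda(Y, X[[col]])
        out[col] = res.explained_fraction
    return pd.Series(out, name="marginal_fraction")


def pearson_correlations(
    Y: pd.DataFrame, X: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Product-moment r and two-sided t-test p for every (index, variable) pair.

    Pairs where either column has zero variance get r = NaN, p = NaN.
    """
    if len(Y) < 3:
        raise ValueError("need >=3 paired observations")
    r = pd.DataFrame(index=Y.columns, columns=X.columns, dtype=float)
    p = pd.DataFrame(index=Y.columns, columns=X.columns, dtype=float)
    for yc in Y.columns:
        for xc in X.columns:
            y = Y[yc].to_numpy(dtype=float)
            x = X[xc].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                r.loc[yc, xc] = np.nan
                p.loc[yc, xc] = np.nan
                continue
            res = stats.pearsonr(y, x)
            r.loc[yc, xc] = res.statistic
            p.loc[yc, xc] = res.pvalue
    return r, p
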