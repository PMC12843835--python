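"""Fitting and selection of linear log FM models.

Ordinary least squares with the validation block QSAR reports expect
(R², adjusted R², RMSE, leave-one-out PRESS and Q², F, p), best-subset
search scored by Amemiya's prediction criterion, seeded random train/test
splitting and held-out evaluation.

Conventions (configurable where noted):

* RMSE = sqrt(SSE/n) by default; ``rmse_dof="n-p"`` divides by the
  residual degrees of freedom instead.
* PRESS uses the hat-matrix identity PRESS = Σ (eᵢ/(1−hᵢᵢ))²; Q² = 1 −
  PRESS/SStot. A leverage of one (a point that determines its own fit)
  raises :class:`~logfm.errors.LeverageError`.
* Amemiya PC = SSE·(n+p)/(n·(n−p)) with p counting the intercept by
  default (``count_intercept=False`` drops it).
* Subset ties are broken by fewer variables, then lexicographic
  descriptor order, so the search is deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import LeverageError, SingularityError, ValidationError
from .models import ModelCoefficients

__all__ = [
    "FitResult", "SubsetCandidate", "SubsetSearchResult",
    "ols_fit", "press_q2", "amemiya_pc", "best_subset_search",
    "split_train_test", "evaluate_on_test",
]

_LEVERAGE_TOL = 1e-10


@dataclass
class FitResult:
    """Coefficients plus the full validation-statistic block of one OLS fit."""

    coefficients: ModelCoefficients
    n_train: int
    R2: float
    R2_adj: float
    RMSE: float
    PRESS: float
    Q2: float
    F: float
    p_value: float
    residuals: np.ndarray
    column_names: tuple[str, ...]
    n_test: int | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.column_names)
        beta = np.array([self.coefficients.coefficients[c] for c in self.column_names])
        return self.coefficients.intercept + X @ beta


def _as_matrix(X, column_names=None):
    if isinstance(X, pd.DataFrame):
        if column_names is not None:
            X = X[list(column_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _column_names(X, p):
    if isinstance(X, pd.DataFrame):
        return tuple(map(str, X.columns))
    return tuple(f"x{i}" for i in range(p))


def _check_design(Xmat, names):
    if np.isnan(Xmat).any():
        raise ValidationError("design matrix contains missing cells")
    Z = np.column_stack([np.ones(len(Xmat)), Xmat])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns by greedy rank scan
        bad = []
        kept = [np.ones(len(Xmat))]
        for j in range(Xmat.shape[1]):
            trial = np.column_stack(kept + [Xmat[:, j]])
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(names[j])
            else:
                kept.append(Xmat[:, j])
        raise SingularityError(bad or list(names))


def ols_fit(X, y, model_id: str = "ols", rmse_dof: str = "n") -> FitResult:
    """Fit intercept + slopes by ordinary least squares.

    ``X`` is an (n, p) matrix or DataFrame, ``y`` the response. Requires
    n > p + 1, a full-rank design and a non-constant response. The returned
    :class:`FitResult` carries R², adjusted R², RMSE, PRESS/Q² (hat-matrix
    leave-one-out), the overall F statistic and its p-value.
    """
    y = np.asarray(y, dtype=float)
    Xmat = _as_matrix(X)
    n, p = Xmat.shape
    names = _column_names(X, p)
    if len(y) != n:
        raise ValidationError(f"X has {n} rows but y has {len(y)} values")
    if n <= p + 1:
        raise ValidationError(f"need more rows ({n}) than parameters ({p + 1})")
    if np.isnan(y).any():
        raise ValidationError("response contains missing values")
    if np.ptp(y) == 0:
        raise ValidationError("response is constant; nothing to fit")
    _check_design(Xmat, names)

    Z = sm.add_constant(Xmat, has_constant="add")
    res = sm.OLS(y, Z).fit()
    sse = float(res.ssr)
    denom = n if rmse_dof == "n" else n - p - 1
    rmse = float(np.sqrt(sse / denom))
    try:
        press, q2 = press_q2(Xmat, y)
    except LeverageError:
        # a unit-leverage point has no deleted residual; the fit itself is
        # still valid, so report the LOO block as undefined rather than fail
        press, q2 = float("nan"), float("nan")
    coeffs = ModelCoefficients(
        model_id,
        intercept=float(res.params[0]),
        coefficients={c: float(b) for c, b in zip(names, res.params[1:])},
        se={"intercept": float(res.bse[0]),
            **{c: float(s) for c, s in zip(names, res.bse[1:])}},
    )
    return FitResult(
        coefficients=coeffs,
        n_train=n,
        R2=float(res.rsquared),
        R2_adj=float(res.rsquared_adj),
        RMSE=rmse,
        PRESS=press,
        Q2=q2,
        F=float(res.fvalue),
        p_value=float(res.f_pvalue),
        residuals=np.asarray(res.resid),
        column_names=names,
    )


def press_q2(X, y) -> tuple[float, float]:
    """Leave-one-out PRESS and Q² via the hat-matrix identity.

    PRESS = Σᵢ (eᵢ/(1−hᵢᵢ))² where e are training residuals and h the
    leverages of the intercept-augmented design; Q² = 1 − PRESS/SStot.
    """
    y = np.asarray(y, dtype=float)
    Xmat = _as_matrix(X)
    Z = np.column_stack([np.ones(len(Xmat)), Xmat])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    e = y - Z @ beta
    # leverages via economical QR
    Q, _ = np.linalg.qr(Z)
    h = np.sum(Q * Q, axis=1)
    if np.any(h >= 1 - _LEVERAGE_TOL):
        idx = int(np.argmax(h))
        raise LeverageError(
            f"leverage of observation {idx} is {h[idx]:.12f}; the point "
            "determines its own fit and has no leave-one-out residual"
        )
    press = float(np.sum((e / (1 - h)) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValidationError("response is constant; Q2 undefined")
    return press, 1.0 - press / sstot


def amemiya_pc(sse: float, n: int, p: int) -> float:
    """Amemiya's prediction criterion PC = SSE·(n+p)/(n·(n−p)).

    ``p`` counts every estimated parameter (intercept included under the
    default convention used by :func:`best_subset_search`). The penalty is
    strictly increasing in p for fixed SSE and n, harsher than adjusted R².
    """
    if p < 1:
        raise ValidationError(f"p must be >= 1, got {p}")
    if n <= p:
        raise ValidationError(f"need n > p, got n={n}, p={p}")
    if sse < 0:
        raise ValidationError(f"SSE must be non-negative, got {sse}")
    return sse * (n + p) / (n * (n - p))


@dataclass
class SubsetCandidate:
    subset: tuple[str, ...]
    pc: float
    fit: FitResult | None = None


@dataclass
class SubsetSearchResult:
    ranked: list[SubsetCandidate]
    chosen: SubsetCandidate
    exhaustive: bool
    n_evaluated: int
    min_vars: int
    max_vars: int


def _sse(Z, y):
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ beta
    return float(r @ r)


def best_subset_search(X: pd.DataFrame, y, min_vars: int = 2, max_vars: int = 5,
                       budget: int = 200_000, allow_fallback: bool = True,
                       count_intercept: bool = True, keep: int = 10) -> SubsetSearchResult:
    """Best-subset selection scored by Amemiya's prediction criterion.

    Enumerates every descriptor subset with ``min_vars``–``max_vars``
    members when the candidate count fits the ``budget``; otherwise falls
    back to greedy forward selection (flagged via ``exhaustive=False``) or
    raises when the fallback is disabled. Ranking is ascending in PC with
    ties broken by (fewer variables, lexicographic order). Full
    :class:`FitResult` blocks are attached to the top ``keep`` candidates.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    cols = list(map(str, X.columns))
    ncol = len(cols)
    if not (1 <= min_vars <= max_vars <= ncol):
        raise ValidationError(
            f"need 1 <= min_vars <= max_vars <= n_columns, got "
            f"{min_vars}, {max_vars}, {ncol}")
    y = np.asarray(y, dtype=float)
    n = len(y)

    n_cand = sum(math.comb(ncol, k) for k in range(min_vars, max_vars + 1))

    exhaustive = n_cand <= budget
    if not exhaustive and not allow_fallback:
        raise ValidationError(
            f"{n_cand} candidate subsets exceed budget {budget} and the "
            "greedy fallback is disabled")

    Xfull = X.to_numpy(dtype=float)
    ones = np.ones((n, 1))
    scored: list[SubsetCandidate] = []

    def score(subset: tuple[str, ...]):
        idx = [cols.index(c) for c in subset]
        Z = np.hstack([ones, Xfull[:, idx]])
        k = len(subset)
        p = k + 1 if count_intercept else k
        sse = _sse(Z, y)
        return SubsetCandidate(tuple(subset), amemiya_pc(sse, n, p))

    if exhaustive:
        for k in range(min_vars, max_vars + 1):
            for subset in itertools.combinations(cols, k):
                scored.append(score(subset))
    else:
        # greedy forward selection: grow the best subset one variable at a
        # time, scoring every intermediate size in the window
        current: list[str] = []
        remaining = list(cols)
        while len(current) < max_vars:
            best = None
            for c in remaining:
                cand = score(tuple(sorted(current + [c])))
                if best is None or cand.pc < best.pc:
                    best = cand
                    best_col = c
            current.append(best_col)
            remaining.remove(best_col)
            if len(current) >= min_vars:
                scored.append(score(tuple(sorted(current))))

    scored.sort(key=lambda c: (c.pc, len(c.subset), c.subset))
    for cand in scored[:keep]:
        cand.fit = ols_fit(X[list(cand.subset)], y, model_id="+".join(cand.subset))
    return SubsetSearchResult(
        ranked=scored, chosen=scored[0], exhaustive=exhaustive,
        n_evaluated=len(scored), min_vars=min_vars, max_vars=max_vars,
    )


def split_train_test(ids: list, n_train: int, seed: int) -> tuple[list, list]:
    """Seeded random disjoint, exhaustive partition into train and test.

    Order within each half follows the original input order, so the split
    is a pure function of (ids, n_train, seed).
    """
    ids = list(ids)
    if not (0 < n_train < len(ids)):
        raise ValidationError(
            f"n_train must be in (0, {len(ids)}), got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train_idx = set(perm[:n_train].tolist())
    train = [x for i, x in enumerate(ids) if i in train_idx]
    test = [x for i, x in enumerate(ids) if i not in train_idx]
    return train, test


def evaluate_on_test(fit: FitResult, X_test, y_test,
                     rmse_dof: str = "n") -> dict:
    """Held-out statistics of a fitted model, without refitting.

    R² is computed about the test-set mean and reported as computed (it can
    be negative); R²_adj uses the test n and the model's p; F is the
    implied overall F at those degrees of freedom.
    """
    y = np.asarray(y_test, dtype=float)
    if len(y) == 0:
        raise ValidationError("test set is empty")
    pred = fit.predict(X_test)
    n = len(y)
    p = len(fit.column_names)
    sse = float(np.sum((y - pred) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else float("nan")
    r2_adj = (1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
              if n - p - 1 > 0 else float("nan"))
    denom = n if rmse_dof == "n" else max(n - p - 1, 1)
    rmse = float(np.sqrt(sse / denom))
    f = ((r2 / p) / ((1.0 - r2) / (n - p - 1))
         if n - p - 1 > 0 and r2 < 1.0 else float("inf"))
    fit.n_test = n
    return {"R2": r2, "R2_adj": r2_adj, "RMSE": rmse, "F": f, "n": n}
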