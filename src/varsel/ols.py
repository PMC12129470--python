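"""Post-selection OLS refitting."""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

__all__ = ["refit_ols", "ols_fit"]


def ols_fit(X: np.ndarray, Y: np.ndarray):
    """Full OLS fit with intercept; returns the statsmodels results object."""
    return sm.OLS(np.asarray(Y, float), sm.add_constant(np.asarray(X, float))).fit()


def refit_ols(X: np.ndarray, Y: np.ndarray, selected):
    """OLS of Y on the selected columns of the original X, with intercept.

    Returns ``(intercept, coef, stderr, dropped)`` where ``coef`` and
    ``stderr`` are full-length vectors (zeros / NaN for unselected
    predictors).  A rank-deficient selected submatrix is handled by dropping
    redundant columns with a warning; the dropped indices are reported.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N, M = X.shape
    selected = sorted(int(j) for j in selected)
    if len(selected) >= N - 1:
        raise ValueError(
            f"cannot refit {len(selected)} predictors with N={N} observations"
        )
    coef = np.zeros(M)
    stderr = np.full(M, np.nan)
    dropped: list[int] = []
    if not selected:
        return float(Y.mean()), coef, stderr, dropped

    keep = list(selected)
    Xs = X[:, keep]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(N), Xs]))
    if rank < len(keep) + 1:
        # drop columns until the design has full rank, keeping earlier ones
        kept: list[int] = []
        base = np.ones((N, 1))
        for j in keep:
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) > base.shape[1]:
                kept.append(j)
                base = cand
            else:
                dropped.append(j)
        warnings.warn(
            f"rank-deficient selected submatrix; dropped columns {dropped}",
            RuntimeWarning,
        )
        keep = kept
        Xs = X[:, keep]

    fit = sm.OLS(Y, sm.add_constant(Xs, has_constant="add")).fit()
    coef[keep] = fit.params[1:]
    stderr[keep] = fit.bse[1:]
    return float(fit.params[0]), coef, stderr, dropped
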