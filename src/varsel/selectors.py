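"""The comparison battery: backward elimination, penalized selectors and
sure-independence screening, all returning the common SelectionResult.

Method tags
-----------
``be-p`` / ``be-aic`` / ``be-bic``
    Backward elimination dropping predictors by t-test p-value (>0.05),
    AIC or BIC, backward-only.  Coefficients from the terminal OLS fit.
``lasso-min`` / ``lasso-1se``, ``alasso-min`` / ``alasso-1se``, ``enet``,
``scad``, ``mcp``
    Coordinate-descent penalized fits tuned by 10-fold CV (lambda_min or
    the one-standard-error rule; elastic net searches its mixing parameter
    jointly).  Coefficients are the penalized estimates themselves.
``isis``
    Iterative sure-independence screening with SCAD pruning; coefficients
    from a post-selection OLS refit.
``ssdci``
    The contrast-CI screener (see :mod:`varsel.ssd_ci`).
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .ols import refit_ols
from .penalized import PenaltySpec, alasso_weights, cd_fit, cross_validate
from .result import SelectionResult
from .ssd_ci import run_ssd_ci, standardize

__all__ = [
    "backward_eliminate",
    "sis_screen",
    "isis",
    "penalized_select",
    "get_selector",
    "METHOD_TAGS",
]


def _check_full_rank(X: np.ndarray) -> None:
    N, M = X.shape
    design = np.column_stack([np.ones(N), X])
    rank = np.linalg.matrix_rank(design)
    if rank < M + 1:
        # identify offending columns greedily for the error message
        bad = []
        base = np.ones((N, 1))
        for j in range(M):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) > base.shape[1]:
                base = cand
            else:
                bad.append(j)
        raise ValueError(f"design is rank deficient; collinear columns {bad}")


def backward_eliminate(
    X: np.ndarray, Y: np.ndarray, criterion: str = "pvalue", p_threshold: float = 0.05
) -> SelectionResult:
    """Backward-only stepwise elimination from the full model.

    ``criterion='pvalue'``: repeatedly drop the predictor with the largest
    coefficient p-value while it exceeds ``p_threshold``.
    ``criterion='aic'``/``'bic'``: at each step drop the single predictor
    whose removal most decreases the criterion; stop when no removal
    decreases it.
    """
    if criterion not in ("pvalue", "aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N, M = X.shape
    if N <= M + 1:
        raise ValueError(f"backward elimination needs N > M + 1 (N={N}, M={M})")
    _check_full_rank(X)

    def _crit(fit):
        return fit.aic if criterion == "aic" else fit.bic

    current = list(range(M))
    if criterion == "pvalue":
        while current:
            fit = sm.OLS(Y, sm.add_constant(X[:, current], has_constant="add")).fit()
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] <= p_threshold:
                break
            current.pop(worst)
    else:
        fit = sm.OLS(Y, sm.add_constant(X[:, current], has_constant="add")).fit()
        best = _crit(fit)
        while current:
            drop_scores = []
            for pos in range(len(current)):
                cols = current[:pos] + current[pos + 1:]
                Xsub = X[:, cols] if cols else np.empty((N, 0))
                f = sm.OLS(Y, sm.add_constant(Xsub, has_constant="add")).fit()
                drop_scores.append(_crit(f))
            pos = int(np.argmin(drop_scores))
            if drop_scores[pos] >= best:
                break
            best = drop_scores[pos]
            current.pop(pos)

    intercept, coef, se, _ = refit_ols(X, Y, current)
    return SelectionResult(
        selected=tuple(current), coef=coef, intercept=intercept,
        method_tag=f"be-{'p' if criterion == 'pvalue' else criterion}",
        stderr=se, extras={"criterion": criterion},
    )


def sis_screen(X: np.ndarray, Y: np.ndarray, d: int) -> np.ndarray:
    """Componentwise-regression screening: indices of the ``d`` predictors
    with the largest |omega_j|, omega = X_std' Y.  Ties by ascending index."""
    X = np.asarray(X, float)
    M = X.shape[1]
    if not (1 <= d <= M):
        raise ValueError(f"d={d} out of range 1..{M}")
    omega = standardize(X).T @ (Y - np.mean(Y))
    # stable sort on descending |omega|: negate, stable mergesort keeps index order
    order = np.argsort(-np.abs(omega), kind="stable")
    return np.sort(order[:d])


def _default_d(N: int, M: int) -> int:
    return min(M, max(1, int(np.floor(N / np.log(N)))))


def isis(
    X: np.ndarray, Y: np.ndarray, d: int | None = None,
    max_rounds: int = 5, seed: int = 0,
) -> SelectionResult:
    """Iterative SIS: screen residuals, prune with CV-tuned SCAD, pool the
    disjoint survivor sets, and finish with one SCAD fit on the pool.

    Reported coefficients come from an OLS refit on the final selection.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N, M = X.shape
    if d is None:
        d = _default_d(N, M)
    union: list[int] = []
    rounds: list[list[int]] = []
    residual = Y.copy()
    flagged = ""
    for r in range(max_rounds):
        candidates = np.setdiff1d(np.arange(M), union)
        if candidates.size == 0 or len(union) >= d:
            break
        budget = min(d - len(union), candidates.size)
        screened_local = sis_screen(X[:, candidates], residual, budget)
        screened = candidates[screened_local]
        Xsub = X[:, screened]
        cv = cross_validate(Xsub, residual, "scad", seed=seed + r)
        _, coef = cd_fit(Xsub, residual, PenaltySpec("scad", cv.lambda_min))
        survivors = screened[np.flatnonzero(coef != 0.0)]
        if survivors.size == 0:
            if r == 0:
                flagged = "empty-first-round"
            break
        rounds.append(survivors.tolist())
        union.extend(int(j) for j in survivors)
        icpt_u, fitted, _, _ = refit_ols(X, Y, union)
        residual = Y - (icpt_u + X @ fitted)

    if union:
        Xu = X[:, sorted(union)]
        cv = cross_validate(Xu, Y, "scad", seed=seed + 101)
        _, coef_u = cd_fit(Xu, Y, PenaltySpec("scad", cv.lambda_min))
        selected = tuple(np.asarray(sorted(union))[np.flatnonzero(coef_u != 0.0)].tolist())
    else:
        selected = ()
    intercept, coef, se, _ = refit_ols(X, Y, selected)
    return SelectionResult(
        selected=selected, coef=coef, intercept=intercept,
        method_tag="isis", stderr=se,
        extras={"rounds": rounds, "d": d, "flag": flagged},
    )


def penalized_select(
    X: np.ndarray, Y: np.ndarray, family: str, rule: str = "min", seed: int = 0
) -> SelectionResult:
    """CV-tuned penalized fit; the nonzero coefficients are the selection."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    weights = None
    tag = family
    if family == "alasso":
        weights = alasso_weights(X, Y, seed=seed)
    cv = cross_validate(X, Y, family, seed=seed, weights=weights)
    lam = cv.lambda_min if rule == "min" else cv.lambda_1se
    spec = PenaltySpec(
        family if family != "enet" else "enet", lam,
        alpha_mix=cv.alpha_mix, weights=weights,
    )
    intercept, coef = cd_fit(X, Y, spec)
    selected = tuple(np.flatnonzero(coef != 0.0).tolist())
    if family in ("lasso", "alasso"):
        tag = f"{family}-{rule}"
    return SelectionResult(
        selected=selected, coef=coef, intercept=intercept, method_tag=tag,
        extras={"lambda": lam, "rule": rule, "alpha_mix": cv.alpha_mix},
    )


METHOD_TAGS = (
    "be-p", "be-aic", "be-bic",
    "lasso-min", "lasso-1se", "alasso-min", "alasso-1se",
    "enet", "scad", "mcp", "isis", "ssdci",
)


def get_selector(tag: str):
    """Return a callable ``f(X, Y, seed) -> SelectionResult`` for a tag."""
    if tag == "be-p":
        return lambda X, Y, seed=0: backward_eliminate(X, Y, "pvalue")
    if tag == "be-aic":
        return lambda X, Y, seed=0: backward_eliminate(X, Y, "aic")
    if tag == "be-bic":
        return lambda X, Y, seed=0: backward_eliminate(X, Y, "bic")
    if tag == "ssdci":
        return lambda X, Y, seed=0: run_ssd_ci(X, Y)
    if tag == "isis":
        return lambda X, Y, seed=0: isis(X, Y, seed=seed)
    if tag in ("enet", "scad", "mcp"):
        return lambda X, Y, seed=0, f=tag: penalized_select(X, Y, f, "min", seed)
    for fam in ("lasso", "alasso"):
        for rule in ("min", "1se"):
            if tag == f"{fam}-{rule}":
                return (
                    lambda X, Y, seed=0, f=fam, r=rule: penalized_select(X, Y, f, r, seed)
                )
    raise ValueError(f"unknown method tag {tag!r}; known tags: {METHOD_TAGS}")
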