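"""Resampling stability analysis for real datasets.

When the true predictors are unknown, selection stability is judged
against a *global* full-model OLS fit on the complete data:

* inclusion frequencies (sub_VIF) and the model-selection frequency
  (sub_MSF) come from half-sample subsamples drawn without replacement;
* the relative conditional bias (RCB) and the RMSD ratio (RMSDR) come
  from full-size bootstrap resamples.

RCB compares the selection-conditional mean resample coefficient with the
global estimate, as a percentage; it is undefined (NA) for predictors that
are never selected.  RMSD imputes zeros for unselected resamples and its
ratio to the global coefficient's standard error (RMSDR) measures how much
variability selection adds on top of ordinary sampling noise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Dataset
from .ols import ols_fit
from .selectors import get_selector

__all__ = [
    "GlobalFit", "StabilityReport", "global_fit",
    "draw_subsample", "draw_bootstrap", "stability_run",
]


@dataclass(frozen=True)
class GlobalFit:
    """Full-model OLS on the complete dataset (all predictors)."""

    beta_global: np.ndarray
    se_global: np.ndarray
    intercept: float


def global_fit(data: Dataset) -> GlobalFit:
    fit = ols_fit(data.X, data.Y)
    return GlobalFit(
        beta_global=np.asarray(fit.params[1:]),
        se_global=np.asarray(fit.bse[1:]),
        intercept=float(fit.params[0]),
    )


def draw_subsample(data: Dataset, seed: int) -> Dataset:
    """floor(0.5 N) rows without replacement; seeded."""
    rng = np.random.default_rng(seed)
    n = data.n
    rows = rng.choice(n, size=n // 2, replace=False)
    return Dataset(X=data.X[rows], Y=data.Y[rows],
                   true_support=data.true_support, seed_used=seed)


def draw_bootstrap(data: Dataset, seed: int) -> Dataset:
    """N rows with replacement; seeded."""
    rng = np.random.default_rng(seed)
    n = data.n
    rows = rng.integers(0, n, size=n)
    return Dataset(X=data.X[rows], Y=data.Y[rows],
                   true_support=data.true_support, seed_used=seed)


@dataclass(frozen=True)
class StabilityReport:
    sub_vif_pct: np.ndarray
    sub_msf_model: tuple[int, ...]
    sub_msf_pct: float
    model_freqs: list[tuple[tuple[int, ...], int]]
    rcb_pct: np.ndarray          # NaN where undefined (never selected)
    rmsdr: np.ndarray
    rmsd: np.ndarray
    n_res: int
    method: str

    def to_frame(self, names=None) -> pd.DataFrame:
        M = self.sub_vif_pct.size
        if names is None:
            names = [f"x{j + 1}" for j in range(M)]
        return pd.DataFrame({
            "predictor": names,
            "sub_VIF": self.sub_vif_pct,
            "RCB_pct": self.rcb_pct,
            "RMSDR": self.rmsdr,
        })

    def model_freq_frame(self, names=None) -> pd.DataFrame:
        rows = []
        for model, count in self.model_freqs:
            label = ",".join(
                (names[j] if names is not None else f"x{j + 1}") for j in model
            ) or "(empty)"
            rows.append({"model": label, "count": count,
                         "pct": 100.0 * count / self.n_res})
        return pd.DataFrame(rows)


def stability_run(
    data: Dataset, method, n_res: int = 1000, seed: int = 0
) -> StabilityReport:
    """Run a selector over subsamples and bootstrap resamples.

    sub_VIF / sub_MSF use the ``n_res`` half-sample subsamples; RCB and
    RMSDR use ``n_res`` bootstrap resamples against the global OLS fit.
    ``method`` is a registry tag or any callable ``f(X, Y, seed) ->
    SelectionResult``.
    """
    if callable(method):
        select = method
        name = getattr(method, "__name__", "custom")
    else:
        select = get_selector(method)
        name = method
    gfit = global_fit(data)
    M = data.m
    method_key = sum(name.encode()) % (2 ** 16)
    ss = np.random.SeedSequence([seed, method_key])
    sub_seeds, boot_seeds = ss.spawn(2)
    sub_ints = sub_seeds.generate_state(n_res) % (2 ** 31)
    boot_ints = boot_seeds.generate_state(n_res) % (2 ** 31)

    sub_counts = np.zeros(M)
    models: Counter = Counter()
    for l in range(n_res):
        sub = draw_subsample(data, int(sub_ints[l]))
        res = select(sub.X, sub.Y, seed=int(sub_ints[l]))
        sub_counts[list(res.selected)] += 1
        models[res.selected] += 1
    sub_vif_pct = 100.0 * sub_counts / n_res
    msf_model, msf_count = models.most_common(1)[0]

    boot_coefs = np.zeros((n_res, M))
    boot_sel = np.zeros((n_res, M), dtype=bool)
    for l in range(n_res):
        boot = draw_bootstrap(data, int(boot_ints[l]))
        res = select(boot.X, boot.Y, seed=int(boot_ints[l]))
        boot_coefs[l] = res.coef
        boot_sel[l, list(res.selected)] = True

    sel_counts = boot_sel.sum(axis=0)
    rcb = np.full(M, np.nan)
    for j in range(M):
        if sel_counts[j] == 0 or gfit.beta_global[j] == 0.0:
            continue
        cond_mean = boot_coefs[boot_sel[:, j], j].mean()
        rcb[j] = (cond_mean / gfit.beta_global[j] - 1.0) * 100.0
    rmsd = np.sqrt(((boot_coefs - gfit.beta_global[None, :]) ** 2).mean(axis=0))
    rmsdr = rmsd / gfit.se_global

    return StabilityReport(
        sub_vif_pct=sub_vif_pct,
        sub_msf_model=msf_model,
        sub_msf_pct=100.0 * msf_count / n_res,
        model_freqs=sorted(models.items(), key=lambda kv: -kv[1]),
        rcb_pct=rcb, rmsdr=rmsdr, rmsd=rmsd,
        n_res=n_res, method=name,
    )
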