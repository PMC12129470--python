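"""Selection-performance measures over a suite of replicate results.

Given the known truth of a simulated design, a method's results over the
replicates are summarized by:

* FPR (type-I error): falsely selected non-predictors / number of true
  non-predictors, averaged over replicates;
* FNR (type-II error): missed true predictors / number of true predictors,
  averaged over replicates;
* average number of predictors selected, ignoring the true state;
* per-predictor variable inclusion frequency (VIF, a percentage — not the
  collinearity variance-inflation factor);
* per-predictor absolute bias |mean(estimate - truth)| and RMSE, with
  unselected predictors contributing an estimate of exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .result import SelectionResult

__all__ = [
    "TruthSpec", "MetricTable", "error_rates", "avg_selected", "vif",
    "vif_table", "bias_rmse", "epv", "metric_table",
]


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth of a simulated design."""

    true_support: tuple[int, ...]
    beta_true: np.ndarray

    def __post_init__(self):
        beta = np.asarray(self.beta_true, float)
        object.__setattr__(self, "beta_true", beta)
        object.__setattr__(self, "true_support", tuple(sorted(self.true_support)))
        if any(j < 0 or j >= beta.size for j in self.true_support):
            raise ValueError("true_support indices out of range")

    @property
    def M(self) -> int:
        return self.beta_true.size

    @property
    def false_support(self) -> tuple[int, ...]:
        return tuple(j for j in range(self.M) if j not in set(self.true_support))


def epv(n: int, m: int) -> float:
    """Events (observations) per candidate variable."""
    return n / m


def _check_nonempty(results: Sequence[SelectionResult]) -> None:
    if len(results) == 0:
        raise ValueError("empty result list")


def error_rates(results: Sequence[SelectionResult], truth: TruthSpec):
    """Mean (FPR, FNR) over replicates."""
    _check_nonempty(results)
    true_set = set(truth.true_support)
    false_set = set(truth.false_support)
    fprs, fnrs = [], []
    for r in results:
        sel = set(r.selected)
        fprs.append(len(sel & false_set) / len(false_set))
        fnrs.append(len(true_set - sel) / len(true_set))
    return float(np.mean(fprs)), float(np.mean(fnrs))


def avg_selected(results: Sequence[SelectionResult]) -> float:
    """Mean model size, ignoring the true state of the predictors."""
    _check_nonempty(results)
    return float(np.mean([r.n_selected for r in results]))


def vif(results: Sequence[SelectionResult], predictor: int) -> float:
    """Inclusion percentage of one predictor over the replicates."""
    _check_nonempty(results)
    hits = sum(1 for r in results if predictor in set(r.selected))
    return 100.0 * hits / len(results)


def vif_table(results: Sequence[SelectionResult]) -> np.ndarray:
    _check_nonempty(results)
    M = results[0].coef.size
    counts = np.zeros(M)
    for r in results:
        counts[list(r.selected)] += 1
    return 100.0 * counts / len(results)


def bias_rmse(results: Sequence[SelectionResult], truth: TruthSpec):
    """Per-predictor (absolute bias, RMSE) with zeros imputed for
    unselected predictors."""
    _check_nonempty(results)
    est = np.stack([r.coef for r in results])          # (L, M)
    diff = est - truth.beta_true[None, :]
    abs_bias = np.abs(diff.mean(axis=0))
    rmse = np.sqrt((diff ** 2).mean(axis=0))
    return abs_bias, rmse


@dataclass(frozen=True)
class MetricTable:
    """Tidy per-method summary of a replicate suite."""

    method: str
    n: int
    fpr: float
    fnr: float
    avg_selected: float
    vif_pct: np.ndarray
    abs_bias: np.ndarray
    rmse: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": self.method, "N": self.n, "metric": "fpr", "predictor": "", "value": self.fpr},
            {"method": self.method, "N": self.n, "metric": "fnr", "predictor": "", "value": self.fnr},
            {"method": self.method, "N": self.n, "metric": "avg_selected", "predictor": "", "value": self.avg_selected},
        ]
        for j in range(self.vif_pct.size):
            name = f"x{j + 1}"
            rows.append({"method": self.method, "N": self.n, "metric": "vif_pct", "predictor": name, "value": self.vif_pct[j]})
            rows.append({"method": self.method, "N": self.n, "metric": "abs_bias", "predictor": name, "value": self.abs_bias[j]})
            rows.append({"method": self.method, "N": self.n, "metric": "rmse", "predictor": name, "value": self.rmse[j]})
        return pd.DataFrame(rows)


def metric_table(
    results: Sequence[SelectionResult], truth: TruthSpec, method: str, n: int
) -> MetricTable:
    fpr, fnr = error_rates(results, truth)
    ab, rm = bias_rmse(results, truth)
    return MetricTable(
        method=method, n=n, fpr=fpr, fnr=fnr,
        avg_selected=avg_selected(results),
        vif_pct=vif_table(results), abs_bias=ab, rmse=rm,
    )
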