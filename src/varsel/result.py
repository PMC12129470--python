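"""Common selection-result container shared by every method."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SelectionResult"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one variable-selection run.

    ``selected`` holds the 0-based indices of the chosen predictors;
    ``coef`` is a full-length coefficient vector with exact zeros for the
    unselected positions.  Depending on the method the coefficients are
    either a post-selection OLS refit (screening and stepwise methods) or
    the penalized estimates themselves (shrinkage methods).
    """

    selected: tuple[int, ...]
    coef: np.ndarray
    intercept: float
    method_tag: str
    stderr: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "selected", tuple(sorted(int(j) for j in self.selected)))
        outside = np.setdiff1d(np.arange(coef.size), np.asarray(self.selected, int))
        if outside.size and not np.all(coef[outside] == 0.0):
            raise ValueError("coefficients of unselected predictors must be zero")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def selected_mask(self) -> np.ndarray:
        mask = np.zeros(self.coef.size, dtype=bool)
        mask[list(self.selected)] = True
        return mask

    def as_dict(self) -> dict:
        out = {
            "method": self.method_tag,
            "selected": list(self.selected),
            "intercept": float(self.intercept),
            "coef": self.coef.tolist(),
        }
        if self.stderr is not None:
            out["stderr"] = np.asarray(self.stderr, float).tolist()
        if "terminal_rule" in self.extras:
            out["terminal_rule"] = self.extras["terminal_rule"]
        return out
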