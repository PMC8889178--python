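"""Collinearity screening of continuous predictors by variance inflation.

VIF_j = 1/(1 − R²_j), with R²_j from the ordinary least-squares regression
of predictor j on all other predictors (with intercept).  The iterative
filter mirrors the correlation-threshold procedure standard in niche
modelling: repeatedly find the pair of predictors with the largest
absolute Pearson correlation; while that correlation strictly exceeds the
threshold (default 0.85), drop the member of the pair with the larger VIF
and recompute.  Ties remove the later variable in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Design matrix unsuitable for VIF (too few rows/columns, zero variance)."""


@dataclass
class RemovalStep:
    variable: str
    trigger_abs_corr: float
    vif_at_removal: float


@dataclass
class VifReport:
    vif: dict[str, float]
    steps: list[RemovalStep] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    threshold: float = 0.85

    def to_frame(self) -> pd.DataFrame:
        removed_at = {s.variable: i + 1 for i, s in enumerate(self.steps)}
        rows = []
        for name, v in self.vif.items():
            rows.append({
                "variable": name,
                "vif": v,
                "removed_at_step": removed_at.get(name, 0),
                "retained": name in self.retained,
            })
        return pd.DataFrame(rows)


def _check_design(X: pd.DataFrame) -> None:
    if X.shape[1] < 2:
        raise DegenerateInputError("need at least two variables")
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least three rows")
    variances = X.var(axis=0, ddof=0)
    zero = variances[variances == 0.0]
    if len(zero):
        raise DegenerateInputError(f"zero-variance columns: {list(zero.index)}")


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Per-variable variance inflation factors.

    Exact collinearity yields ``inf`` for the involved variables rather
    than an error, so the iterative filter can still rank them.
    """
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    _check_design(X)
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    out = {}
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = np.inf
        else:
            out[name] = max(1.0 / (1.0 - r2), 1.0)
    return pd.Series(out)


def vif_filter(X: pd.DataFrame, threshold: float = 0.85) -> VifReport:
    """Iterative pairwise-correlation elimination with VIF tie-breaking.

    Stops when the largest pairwise |r| is ≤ ``threshold`` (strict
    exceedance triggers removal).  The retained set is invariant to row
    order.  The last variable can never be removed: removal always acts
    on a *pair*.
    """
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    _check_design(X)
    current = list(X.columns)
    order = {name: i for i, name in enumerate(X.columns)}
    steps: list[RemovalStep] = []

    while len(current) >= 2:
        sub = X[current]
        corr = sub.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(abs_corr), abs_corr.shape)
        max_r = abs_corr[i, j]
        # strict exceedance, with a 1e-12 guard so a correlation equal to
        # the threshold up to floating-point rounding does not trigger removal
        if not max_r > threshold + 1e-12:
            break
        a, b = current[i], current[j]
        vifs = compute_vif(sub)
        va, vb = vifs[a], vifs[b]
        if va > vb:
            drop = a
        elif vb > va:
            drop = b
        else:
            drop = a if order[a] > order[b] else b
        steps.append(RemovalStep(variable=drop, trigger_abs_corr=float(max_r),
                                 vif_at_removal=float(vifs[drop])))
        current.remove(drop)

    final_vif = compute_vif(X[current]) if len(current) >= 2 else pd.Series(
        {current[0]: 1.0})
    return VifReport(vif=dict(final_vif), steps=steps,
                     retained=current, threshold=threshold)
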