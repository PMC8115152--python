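"""Ordinary least squares with the usual QSAR diagnostics, classical
stepwise descriptor selection, and the published skin-permeability equations
as frozen predictors.

The four frozen linear models predict log Kp (log10 cm/h) from up to three
descriptors: ``cos2_alogp``, ``x3v`` and ``neoplastic80``.  They are carried
exactly as printed, including the differing X3v/Neoplastic-80 coefficients
between the full-set and training-set three-descriptor fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "PublishedEquation",
    "PUBLISHED_EQUATIONS",
    "ols_fit",
    "stepwise_select",
    "predict_published",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit with per-coefficient and whole-model diagnostics.

    ``coef``/``se``/``t``/``p`` include the intercept first; ``vif`` covers
    the descriptors only (variance inflation factor 1/(1 - R_j^2) from
    regressing descriptor j on the others).
    """

    names: tuple
    coef: tuple
    se: tuple
    t: tuple
    p: tuple
    vif: tuple
    n: int
    r: float
    r2: float
    r2_adj: float
    se_estimate: float
    f_statistic: float

    @property
    def intercept(self) -> float:
        return self.coef[0]

    def coefficients(self) -> dict:
        return dict(zip(self.names[1:], self.coef[1:]))

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coef[0] + X @ np.asarray(self.coef[1:])

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "se": self.se_estimate,
            "f": self.f_statistic,
            "terms": [
                {
                    "name": nm,
                    "coefficient": c,
                    "std_error": s,
                    "t": t_,
                    "p_value": p_,
                    "vif": v,
                }
                for nm, c, s, t_, p_, v in zip(
                    self.names, self.coef, self.se, self.t, self.p,
                    (float("nan"),) + self.vif,
                )
            ],
        }


def _vif(X: np.ndarray) -> tuple:
    """VIF_j = 1/(1 - R_j^2), column j regressed on the remaining columns."""
    n, p = X.shape
    if p == 1:
        return (1.0,)
    out = []
    for j in range(p):
        others = np.delete(X, j, axis=1)
        res = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2j = min(res.rsquared, 1.0 - 1e-12)
        out.append(1.0 / (1.0 - r2j))
    return tuple(out)


def ols_fit(X, y, names: Optional[Sequence[str]] = None) -> RegressionFit:
    """Least-squares fit of y on X (with intercept) plus QSAR diagnostics.

    Raises on rank-deficient design, naming the collinear columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        bad = [names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) ==
               np.linalg.matrix_rank(design)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    r2 = float(res.rsquared)
    dof = n - p - 1
    f = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1.0 else float("inf")
    return RegressionFit(
        names=("intercept",) + tuple(names),
        coef=tuple(float(c) for c in res.params),
        se=tuple(float(s) for s in res.bse),
        t=tuple(float(t) for t in res.tvalues),
        p=tuple(float(v) for v in res.pvalues),
        vif=_vif(X),
        n=n,
        r=float(np.sqrt(r2)),
        r2=r2,
        r2_adj=float(res.rsquared_adj),
        se_estimate=float(np.sqrt(res.mse_resid)),
        f_statistic=float(f),
    )


def stepwise_select(
    X,
    y,
    names: Optional[Sequence[str]] = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple:
    """Classical forward-with-backward stepwise selection on partial-F (t) tests.

    At each step the candidate with the smallest entry p-value below
    ``p_enter`` joins the model; any included descriptor whose p-value rises
    above ``p_remove`` is then dropped.  Candidates that would make the
    design rank-deficient are ineligible, so exact copies of an included
    column are never co-selected.  Deterministic given the column order.

    Returns ``(selected column indices, RegressionFit or None)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    selected: list = []
    while True:
        changed = False
        # forward step
        best_j, best_p = None, p_enter
        for j in range(p):
            if j in selected:
                continue
            cols = selected + [j]
            design = sm.add_constant(X[:, cols], has_constant="add")
            if np.linalg.matrix_rank(design) < len(cols) + 1:
                continue
            pj = sm.OLS(y, design).fit().pvalues[-1]
            if pj < best_p:
                best_j, best_p = j, pj
        if best_j is not None:
            selected.append(best_j)
            changed = True
        # backward step
        if selected:
            design = sm.add_constant(X[:, selected], has_constant="add")
            pvals = sm.OLS(y, design).fit().pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            break
    if not selected:
        return [], None
    fit = ols_fit(X[:, selected], y, names=[names[j] for j in selected])
    return selected, fit


@dataclass(frozen=True)
class PublishedEquation:
    """A frozen published linear model: intercept plus descriptor coefficients."""

    eq_id: str
    intercept: float
    coefficients: Mapping[str, float]

    def predict(self, descriptors: Mapping[str, float]) -> float:
        try:
            return self.intercept + sum(
                c * float(descriptors[k]) for k, c in self.coefficients.items()
            )
        except KeyError as exc:
            raise KeyError(f"{self.eq_id} needs descriptor {exc.args[0]!r}") from None


# The printed equations, verbatim.  Fit statistics for context:
# one-descriptor (n=274, R=0.695), two-descriptor (R=0.918),
# three-descriptor full set (R=0.945), three-descriptor training set (R=0.949).
PUBLISHED_EQUATIONS: Mapping[str, PublishedEquation] = {
    "one_descriptor": PublishedEquation(
        "one_descriptor", 0.624, {"cos2_alogp": -5.178}
    ),
    "two_descriptor": PublishedEquation(
        "two_descriptor", 2.230, {"cos2_alogp": -6.643, "x3v": -0.245}
    ),
    "three_descriptor_full": PublishedEquation(
        "three_descriptor_full",
        2.209,
        {"cos2_alogp": -6.698, "x3v": -0.174, "neoplastic80": -0.704},
    ),
    "three_descriptor_train": PublishedEquation(
        "three_descriptor_train",
        2.068,
        {"cos2_alogp": -6.515, "x3v": -0.722, "neoplastic80": -0.168},
    ),
}


def predict_published(eq_id: str, descriptors: Mapping[str, float]) -> float:
    """Evaluate one of the frozen published equations."""
    try:
        eq = PUBLISHED_EQUATIONS[eq_id]
    except KeyError:
        raise KeyError(
            f"unknown equation {eq_id!r}; choose from {sorted(PUBLISHED_EQUATIONS)}"
        ) from None
    return eq.predict(descriptors)
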