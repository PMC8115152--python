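"""Model-quality metrics: rms error and R², leave-one-out and m-fold
cross-validation, and the Golbraikh-Tropsha external-validation battery.

The Golbraikh-Tropsha criteria declare an externally validated model
acceptable when q²_ext > 0.5, both through-origin regression slopes k
(predicted-on-observed) and k' (observed-on-predicted) lie in (0.85, 1.15),
and the through-origin determination coefficients R0² and R0'² stay within
10% (relative) of the test-set R².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "ValidationReport",
    "rms_r2",
    "loo_cv",
    "kfold_cv",
    "golbraikh_tropsha",
]


def rms_r2(y_obs, y_pred) -> tuple:
    """Root-mean-square error and squared Pearson correlation."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise ValueError("observed and predicted must share a non-zero length")
    rms = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    if np.std(y_obs) == 0.0 or np.std(y_pred) == 0.0:
        raise ValueError("R² undefined: zero variance in observed or predicted")
    r = stats.pearsonr(y_obs, y_pred).statistic
    return rms, float(r**2)


def loo_cv(trainer: Callable, X, y) -> tuple:
    """Leave-one-out cross-validation.

    ``trainer(X, y)`` must return an object with ``predict``.  Returns the
    per-point held-out predictions and their Pearson correlation with the
    observed values.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three points for leave-one-out")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = trainer(X[mask], y[mask])
            preds[i] = float(np.asarray(model.predict(X[i:i + 1])).ravel()[0])
        except Exception as exc:
            raise RuntimeError(f"leave-one-out refit failed at index {i}") from exc
    r = float(stats.pearsonr(y, preds).statistic)
    return preds, r


def kfold_cv(trainer: Callable, X, y, m: int, seed: int) -> float:
    """Mean held-out MSE over m folds with a seed-deterministic assignment."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if m > n:
        raise ValueError(f"m={m} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    errs = []
    for chunk in np.array_split(perm, m):
        mask = np.ones(n, dtype=bool)
        mask[chunk] = False
        model = trainer(X[mask], y[mask])
        pred = np.asarray(model.predict(X[chunk])).ravel()
        errs.append(float(np.mean((pred - y[chunk]) ** 2)))
    return float(np.mean(errs))


@dataclass(frozen=True)
class ValidationReport:
    """External-validation quantities with pass/fail flags."""

    rms: float
    r2: float
    q2_ext: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    rel_diff: float
    rel_diff_prime: float
    pass_q2: bool
    pass_k: bool
    pass_k_prime: bool
    pass_rel_diff: bool
    pass_rel_diff_prime: bool

    @property
    def all_pass(self) -> bool:
        return (self.pass_q2 and self.pass_k and self.pass_k_prime
                and self.pass_rel_diff and self.pass_rel_diff_prime)

    def as_dict(self) -> dict:
        return {
            "rms": self.rms,
            "r2": self.r2,
            "q2_ext": self.q2_ext,
            "k": self.k,
            "k_prime": self.k_prime,
            "r0_sq": self.r0_sq,
            "r0_prime_sq": self.r0_prime_sq,
            "rel_diff": self.rel_diff,
            "rel_diff_prime": self.rel_diff_prime,
            "pass": {
                "q2_ext_gt_0.5": self.pass_q2,
                "k_in_(0.85,1.15)": self.pass_k,
                "k_prime_in_(0.85,1.15)": self.pass_k_prime,
                "rel_diff_lt_0.1": self.pass_rel_diff,
                "rel_diff_prime_lt_0.1": self.pass_rel_diff_prime,
            },
            "all_pass": self.all_pass,
        }


def golbraikh_tropsha(y_obs_test, y_pred_test, y_train_mean: float) -> ValidationReport:
    """Golbraikh-Tropsha external-validation battery on test-set predictions.

    q²_ext = 1 - SS(obs - pred) / SS(obs - training mean);
    k = Σ y·ỹ / Σ ỹ² and k' = Σ y·ỹ / Σ y² are the through-origin slopes;
    R0² = 1 - Σ(ỹ - k·ỹ... through-origin residuals)² / Σ(ỹ - mean ỹ)² and
    R0'² the symmetric variant; the relative differences compare both with
    the test-set R² (squared Pearson correlation of observed vs predicted).
    """
    y = np.asarray(y_obs_test, dtype=float)
    yp = np.asarray(y_pred_test, dtype=float)
    if y.shape != yp.shape or len(y) < 3:
        raise ValueError("need equal-length vectors of at least three points")
    if np.std(y) == 0.0 or np.std(yp) == 0.0:
        raise ValueError("zero variance; validation statistics undefined")
    if np.sum(yp**2) == 0.0 or np.sum(y**2) == 0.0:
        raise ValueError("zero denominator in through-origin slope")
    rms, r2 = rms_r2(y, yp)
    q2_ext = 1.0 - np.sum((y - yp) ** 2) / np.sum((y - y_train_mean) ** 2)
    k = float(np.sum(y * yp) / np.sum(yp**2))
    k_prime = float(np.sum(y * yp) / np.sum(y**2))
    y_r0 = k * yp          # through-origin fit of observed on predicted
    yp_r0 = k_prime * y    # through-origin fit of predicted on observed
    r0_sq = float(1.0 - np.sum((yp - y_r0) ** 2) / np.sum((yp - yp.mean()) ** 2))
    r0_prime_sq = float(1.0 - np.sum((y - yp_r0) ** 2) / np.sum((y - y.mean()) ** 2))
    rel_diff = abs(r2 - r0_sq) / r2
    rel_diff_prime = abs(r2 - r0_prime_sq) / r2
    return ValidationReport(
        rms=rms,
        r2=r2,
        q2_ext=float(q2_ext),
        k=k,
        k_prime=k_prime,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        rel_diff=float(rel_diff),
        rel_diff_prime=float(rel_diff_prime),
        pass_q2=bool(q2_ext > 0.5),
        pass_k=bool(0.85 < k < 1.15),
        pass_k_prime=bool(0.85 < k_prime < 1.15),
        pass_rel_diff=bool(rel_diff < 0.1),
        pass_rel_diff_prime=bool(rel_diff_prime < 0.1),
    )
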