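"""Monte-Carlo resampling validation of the PLS component count.

The number of predictive components is selected from repeated random
half-splits: for each repetition the model is fitted on one half and the
other half is predicted; the median squared prediction error per repetition
is recorded for the mean-only model (A = 0) and for A = 1..A_max. The curve
aggregated over repetitions is the root-median-squared-error-of-prediction
(RMedSEP); the selected model is the largest A at or below the curve minimum
for which every incremental component still clearly lowers the prediction
error across repetitions.

Two step-acceptance rules are provided. The default, ``percentile-overlap``,
demands that the extra component improve the per-repetition error in at
least (1 - improvement_quantile) of repetitions (default: three quarters) —
a materiality criterion whose stringency does not change with the number of
repetitions. The alternative ``wilcoxon`` rule runs a paired one-sided
signed-rank test on the per-repetition errors; note that repetitions resample
the *same* cohort, so they are not independent and the test's nominal level
understates its real false-positive rate: with many repetitions it will
certify dataset-level chance correlations, which is why it is not the
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import RankError

RULES = ("percentile-overlap", "wilcoxon")

#: Fraction of repetitions in which an extra component may fail to improve
#: prediction under the default materiality rule (an improvement in at least
#: 75% of repetitions is required).
IMPROVEMENT_QUANTILE = 0.25


@dataclass
class ValidationCurve:
    """RMedSEP curve over A = 0..A_max with the per-repetition error matrix.

    ``rmedsep[A] = sqrt(median over reps of per_rep_medse[:, A])``; the raw
    ``per_rep_medse`` matrix is kept so alternative aggregations and the
    selection rule can be audited.
    """

    reps: int
    holdout_fraction: float
    rmedsep: np.ndarray
    per_rep_medse: np.ndarray
    selected_A: int
    seed: int
    alpha: float = 0.05
    rule: str = "percentile-overlap"
    step_pvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def a_max(self) -> int:
        return len(self.rmedsep) - 1

    def to_csv(self, path, full: bool = False) -> None:
        import pandas as pd

        passed = np.zeros(self.a_max + 1, dtype=bool)
        passed[1 : self.selected_A + 1] = True
        df = pd.DataFrame(
            {
                "A": np.arange(self.a_max + 1),
                "rmedsep": self.rmedsep,
                "step_pvalue": np.concatenate([[np.nan], self.step_pvalues]),
                "selected": passed,
            }
        )
        df.to_csv(path, index=False)
        if full:
            np.savetxt(str(path) + ".per_rep.csv", self.per_rep_medse, delimiter=",")

    def to_json(self, include_per_rep: bool = False) -> str:
        doc = {
            "reps": self.reps,
            "holdout_fraction": self.holdout_fraction,
            "rmedsep": self.rmedsep.tolist(),
            "selected_A": self.selected_A,
            "seed": self.seed,
            "alpha": self.alpha,
            "rule": self.rule,
            "step_pvalues": self.step_pvalues.tolist(),
        }
        if include_per_rep:
            doc["per_rep_medse"] = self.per_rep_medse.tolist()
        return json.dumps(doc)


def monte_carlo_curve(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    reps: int = 1000,
    holdout_fraction: float = 0.5,
    seed: int = 0,
    alpha: float = 0.05,
    rule: str = "percentile-overlap",
    improvement_quantile: float = IMPROVEMENT_QUANTILE,
) -> ValidationCurve:
    """Build the RMedSEP curve by repeated random half-splits.

    Each repetition draws a plain random holdout (without replacement,
    no stratification), centers the training half, fits PLS1 for
    A = 1..A_max by NIPALS, and predicts the holdout half via the deflation
    recursion (scores ``t = X_hold w_a`` accumulated as ``sum_a t q_a``).
    A = 0 is the training-mean predictor. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if A_max < 1:
        raise RankError("A_max must be >= 1")
    n_hold = int(round(n * holdout_fraction))
    n_train = n - n_hold
    if n_train < 2 or n_hold < 1:
        raise RankError(f"n={n} too small for holdout fraction {holdout_fraction}")
    if A_max > min(n_train - 1, m):
        raise RankError(
            f"A_max={A_max} infeasible for a training half of {n_train} samples "
            f"and {m} variables"
        )

    rng = np.random.default_rng(seed)
    medse = np.empty((reps, A_max + 1))
    for r in range(reps):
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        Xt = X[train]
        yt = y[train]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        Xa = Xt - x_mean
        ya = yt - y_mean
        Xh = X[hold] - x_mean
        yh = y[hold] - y_mean

        yhat = np.zeros(n_hold)
        medse[r, 0] = np.median(yh**2)
        for a in range(1, A_max + 1):
            w = Xa.T @ ya
            nw = np.linalg.norm(w)
            if nw <= 0 or not np.isfinite(nw):
                raise RankError(
                    f"repetition {r}: training half supports only {a - 1} "
                    f"components (A_max={A_max})"
                )
            w /= nw
            t = Xa @ w
            tt = float(t @ t)
            if tt <= 0:
                raise RankError(
                    f"repetition {r}: training half supports only {a - 1} "
                    f"components (A_max={A_max})"
                )
            p = Xa.T @ t / tt
            q = float(ya @ t) / tt
            Xa -= np.outer(t, p)
            th = Xh @ w
            Xh -= np.outer(th, p)
            yhat += th * q
            medse[r, a] = np.median((yh - yhat) ** 2)

    rmedsep = np.sqrt(np.median(medse, axis=0))
    curve = ValidationCurve(
        reps=reps,
        holdout_fraction=holdout_fraction,
        rmedsep=rmedsep,
        per_rep_medse=medse,
        selected_A=0,
        seed=seed,
        alpha=alpha,
        rule=rule,
    )
    curve.step_pvalues = _step_pvalues(medse, rule, improvement_quantile)
    curve.selected_A = select_components(curve, alpha)
    return curve


def _step_pvalues(
    medse: np.ndarray, rule: str, improvement_quantile: float = IMPROVEMENT_QUANTILE
) -> np.ndarray:
    """One-sided evidence that model A beats model A-1, per step A = 1..A_max."""
    if rule not in RULES:
        raise ValueError(f"unknown significance rule {rule!r}; options: {RULES}")
    a_max = medse.shape[1] - 1
    pvals = np.empty(a_max)
    for a in range(1, a_max + 1):
        d = medse[:, a - 1] - medse[:, a]  # > 0 where the extra component helps
        if np.allclose(d, 0):
            pvals[a - 1] = 1.0
        elif rule == "wilcoxon":
            pvals[a - 1] = stats.wilcoxon(
                d, alternative="greater", zero_method="wilcox"
            ).pvalue
        else:  # materiality: the lower quantile of the paired diff must be > 0
            pvals[a - 1] = 1.0 if np.quantile(d, improvement_quantile) <= 0 else 0.0
    return pvals


def select_components(curve: ValidationCurve, alpha: float | None = None) -> int:
    """Apply the minimum-plus-significance rule to a validation curve.

    Returns the largest ``A <= argmin(rmedsep)`` such that every incremental
    step ``1..A`` significantly lowers the per-repetition median prediction
    error; 0 if the one-component model does not beat the mean-only model.
    """
    if alpha is None:
        alpha = curve.alpha
    a_star = int(np.argmin(curve.rmedsep))
    selected = 0
    for a in range(1, a_star + 1):
        if curve.step_pvalues[a - 1] < alpha:
            selected = a
        else:
            break
    return selected
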