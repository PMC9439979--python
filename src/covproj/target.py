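"""Target projection (TP), selectivity ratios (SR), and VIP.

Target projection condenses a validated PLS1 model into a single predictive
component: the weight vector is the normalized regression vector
``w_tp = b / ||b||``, the score ``t_tp = X w_tp`` maximally correlates with
the predicted outcome, and the loading ``p_tp = X^T t_tp / (t_tp^T t_tp)``
describes how each variable projects on that predictive direction. The TP
component carries all the predictive information of the model:
``t_tp ||b|| == X b`` exactly.

The selectivity ratio of variable *i* is the ratio of its TP-explained to
TP-residual sum of squares, and ranks variables by predictive importance.
VIP is included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateError
from .pls import PLSModel

#: Sentinel selectivity ratio reported when a variable has (numerically) zero
#: residual around the target component.
SR_CAP = 1e12


@dataclass
class TPModel:
    """Single predictive target component distilled from a PLS1 model."""

    w_tp: np.ndarray
    t_tp: np.ndarray
    p_tp: np.ndarray
    b_norm: float
    explained_x_ss: np.ndarray
    residual_x_ss: np.ndarray
    explained_y_fraction: float
    variable_names: list[str] = field(default_factory=list)

    def fitted(self) -> np.ndarray:
        """Predicted outcome ``t_tp * ||b||`` (identical to ``X @ b``)."""
        return self.t_tp * self.b_norm

    @property
    def explained_x_fraction(self) -> float:
        """Fraction of the total X sum of squares captured by the component."""
        tot = float(self.explained_x_ss.sum() + self.residual_x_ss.sum())
        return float(self.explained_x_ss.sum()) / tot if tot > 0 else 0.0


def target_project(
    model: PLSModel, X: np.ndarray, y: np.ndarray | None = None
) -> TPModel:
    """Post-process a fitted PLS1 model into its target component.

    ``X`` must be the (centered) matrix the model was fitted on, or data
    centered compatibly with it. When ``y`` is given, the fraction of its sum
    of squares captured by the TP prediction is stored on the model.
    """
    X = np.asarray(X, dtype=float)
    b = model.b
    b_norm = float(np.linalg.norm(b))
    if b_norm <= 0:
        raise DegenerateError("regression vector is zero; no target direction")
    w_tp = b / b_norm
    t_tp = X @ w_tp
    tt = float(t_tp @ t_tp)
    if tt <= 0:
        raise DegenerateError("target score vector is zero")
    p_tp = X.T @ t_tp / tt
    explained = tt * p_tp**2  # ||t_tp p_i||^2 per variable
    residual = (X - np.outer(t_tp, p_tp)) ** 2
    residual_ss = residual.sum(axis=0)
    tp = TPModel(
        w_tp=w_tp,
        t_tp=t_tp,
        p_tp=p_tp,
        b_norm=b_norm,
        explained_x_ss=explained,
        residual_x_ss=residual_ss,
        explained_y_fraction=float("nan"),
        variable_names=[],
    )
    if y is not None:
        tp.explained_y_fraction = explained_y_fraction(tp, y)
    return tp


def explained_y_fraction(tp: TPModel, y: np.ndarray) -> float:
    """Fraction of the sum of squares of ``y`` captured by the TP prediction."""
    y = np.asarray(y, dtype=float).ravel()
    ss = float(y @ y)
    if ss <= 0:
        raise DegenerateError("response has zero sum of squares")
    yhat = tp.fitted()
    return float(yhat @ yhat) / ss


def selectivity_ratio(tp: TPModel) -> np.ndarray:
    """Per-variable SR: TP-explained over TP-residual sum of squares.

    A variable with (numerically) zero residual around the target component
    gets the documented cap :data:`SR_CAP` rather than infinity.
    """
    total = tp.explained_x_ss + tp.residual_x_ss
    sr = np.empty_like(tp.explained_x_ss)
    zero_resid = tp.residual_x_ss <= 1e-12 * np.maximum(total, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(zero_resid, SR_CAP, tp.explained_x_ss / np.where(
            tp.residual_x_ss > 0, tp.residual_x_ss, 1.0))
    sr[zero_resid & (tp.explained_x_ss <= 0)] = 0.0
    return sr


def signed_selectivity_ratio(tp: TPModel) -> np.ndarray:
    """SR with the sign of the TP loading attached, for directional SR plots."""
    return np.sign(tp.p_tp) * selectivity_ratio(tp)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection for a fitted PLS1 model.

    ``VIP_i = sqrt(m * sum_a SSY_a (w_ia / ||w_a||)^2 / sum_a SSY_a)`` with
    ``SSY_a = q_a^2 t_a^T t_a``; mean of VIP^2 over variables is 1.
    """
    m = model.W.shape[0]
    ssy = model.q**2 * np.einsum("na,na->a", model.T, model.T)
    wnorm2 = np.einsum("ma,ma->a", model.W, model.W)
    contrib = (model.W**2 / wnorm2) @ ssy
    return np.sqrt(m * contrib / ssy.sum())


def importance_table(
    model: PLSModel, tp: TPModel, variable_names: list[str]
) -> pd.DataFrame:
    """Assemble the exportable per-variable table (SR, signed SR, VIP, loadings)."""
    sr = selectivity_ratio(tp)
    return pd.DataFrame(
        {
            "variable": variable_names,
            "signed_sr": np.sign(tp.p_tp) * sr,
            "sr": sr,
            "vip": vip(model),
            "p_tp": tp.p_tp,
            "w_tp": tp.w_tp,
        }
    )
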