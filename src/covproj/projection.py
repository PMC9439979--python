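"""Sequential covariate projection (CP) on an augmented data matrix.

The central idea: collect the covariates Z, the outcome y and the
explanatory block X in one augmented, column-centered matrix and deflate it
by one rank-one projection per covariate (or, for a multicollinear /
linearly dependent covariate group, per standardized target-projection score
representing that group):

    [T_Z Z y X] = sum_a t_CP,a p_CP,a^T + E

Each projection zeroes the corresponding covariate column exactly and
removes the covariate's subspace from the outcome and explanatory variables
simultaneously, which equals residualizing each column on the covariate by
least squares. The running residual matrix after all steps holds the *net*
outcome and explanatory variables; the per-column sums of squares removed by
each step form the variance plot.

Sequential CP is order-dependent when covariates correlate: attribution is
first-come, each step claims what remains. The order is therefore an
explicit configuration (default: age, sex, adiposity, PA).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataTable, standardize_vector
from .errors import DegenerateError, UsageError
from .pls import PLSModel, fit_pls1
from .target import TPModel, target_project
from .validation import ValidationCurve, monte_carlo_curve

#: A residual column counts as zeroed once its SS falls below this fraction
#: of its original SS.
ZERO_TOL = 1e-12


@dataclass
class ValidationConfig:
    """Settings shared by every Monte-Carlo validated PLS model in a run."""

    reps: int = 1000
    holdout_fraction: float = 0.5
    alpha: float = 0.05
    rule: str = "percentile-overlap"
    a_max: int = 10
    seed: int = 0

    def model_seed(self, label: str) -> int:
        """Stable per-model seed derived from the run seed and a model label."""
        return int((self.seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31))


@dataclass
class CPStep:
    """One rank-one projection: standardized score, loadings, removed SS."""

    label: str
    score: np.ndarray
    loading: pd.Series
    removed_ss: pd.Series


@dataclass
class CPDecomposition:
    """Ordered CP steps plus the running residual augmented matrix."""

    residual: pd.DataFrame
    original_ss: pd.Series
    steps: list[CPStep] = field(default_factory=list)
    tp_models: dict[str, TPModel] = field(default_factory=dict)
    pls_models: dict[str, PLSModel] = field(default_factory=dict)
    curves: dict[str, ValidationCurve] = field(default_factory=dict)
    skipped_groups: list[str] = field(default_factory=list)

    @property
    def column_labels(self) -> list[str]:
        return list(self.residual.columns)

    def residual_ss(self) -> pd.Series:
        return (self.residual**2).sum(axis=0)

    def is_zeroed(self, label: str) -> bool:
        ss = float((self.residual[label] ** 2).sum())
        return ss <= ZERO_TOL * max(float(self.original_ss[label]), 1e-300)

    def net_column(self, label: str) -> np.ndarray:
        return self.residual[label].to_numpy(dtype=float)

    def net_matrix(self, labels: list[str]) -> np.ndarray:
        return self.residual[labels].to_numpy(dtype=float)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "columns": self.column_labels,
                "original_ss": self.original_ss.tolist(),
                "residual_ss": self.residual_ss().tolist(),
                "steps": [
                    {
                        "label": s.label,
                        "removed_ss": s.removed_ss.tolist(),
                    }
                    for s in self.steps
                ],
                "skipped_groups": self.skipped_groups,
            }
        )


def make_decomposition(table: DataTable) -> CPDecomposition:
    """Initialize the augmented matrix [Z y X] from a pretreated table.

    Columns are ordered covariates (in group order), outcome, explanatory.
    TP-score columns for multivariate groups are prepended as they are
    created during the sequence.
    """
    cols: list[str] = []
    for g in table.group_order:
        cols.extend(table.group_members(g))
    cols.append(table.outcome_name)
    cols.extend(table.explanatory_names)
    aug = table.frame[cols].astype(float).copy()
    original_ss = (aug**2).sum(axis=0)
    return CPDecomposition(residual=aug, original_ss=original_ss)


def cp_single(decomp: CPDecomposition, column_label: str) -> CPDecomposition:
    """Project one (univariate) column out of the augmented residual matrix.

    The weight vector selects the named column, so the CP score *is* that
    column's current residual (standardized for bookkeeping; residuals are
    invariant to the scaling). After the step the named column is exactly
    zero and every residual column is orthogonal to the step score.
    """
    if column_label not in decomp.residual.columns:
        raise UsageError(f"column {column_label!r} not in the augmented matrix")
    if decomp.is_zeroed(column_label):
        raise UsageError(f"column {column_label!r} is already zeroed")
    raw = decomp.residual[column_label].to_numpy(dtype=float)
    try:
        t = standardize_vector(raw)
    except DegenerateError as exc:
        raise DegenerateError(f"column {column_label!r}: {exc}") from exc
    E = decomp.residual.to_numpy(dtype=float)
    tt = float(t @ t)
    p = E.T @ t / tt
    removed = tt * p**2
    E = E - np.outer(t, p)
    E[:, decomp.residual.columns.get_loc(column_label)] = 0.0
    decomp.residual = pd.DataFrame(
        E, index=decomp.residual.index, columns=decomp.residual.columns
    )
    decomp.steps.append(
        CPStep(
            label=column_label,
            score=t,
            loading=pd.Series(p, index=decomp.residual.columns),
            removed_ss=pd.Series(removed, index=decomp.residual.columns),
        )
    )
    return decomp


def cp_multivariate(
    decomp: CPDecomposition,
    group_label: str,
    group_columns: list[str],
    y_column: str,
    validation_config: ValidationConfig,
) -> tuple[CPDecomposition, TPModel | None, ValidationCurve]:
    """Represent a multivariate covariate group by a TP score and project it.

    A PLS1 model of the *current residual* outcome on the group's current
    residual block is validated by Monte-Carlo resampling; its target
    component score is standardized, prepended to the augmented matrix as a
    ``tp_<group>`` column, and projected out with :func:`cp_single`. If the
    validation selects zero components the group is declared non-predictive
    and the decomposition is returned unchanged.
    """
    for c in group_columns:
        if c not in decomp.residual.columns:
            raise UsageError(f"group column {c!r} not in the augmented matrix")
    y = decomp.net_column(y_column)
    if float(y @ y) <= ZERO_TOL * max(float(decomp.original_ss[y_column]), 1e-300):
        raise UsageError(f"residual outcome {y_column!r} is zero; nothing to model")
    Z = decomp.net_matrix(group_columns)
    a_max = min(validation_config.a_max, len(group_columns))
    curve = monte_carlo_curve(
        Z,
        y,
        A_max=a_max,
        reps=validation_config.reps,
        holdout_fraction=validation_config.holdout_fraction,
        seed=validation_config.model_seed(group_label),
        alpha=validation_config.alpha,
        rule=validation_config.rule,
    )
    decomp.curves[group_label] = curve
    if curve.selected_A == 0:
        warnings.warn(
            f"covariate group {group_label!r} carries no validated predictive "
            "relation to the outcome; no projection performed",
            stacklevel=2,
        )
        decomp.skipped_groups.append(group_label)
        return decomp, None, curve

    model = fit_pls1(Z, y, curve.selected_A)
    tp = target_project(model, Z, y)
    tp.variable_names = list(group_columns)
    decomp.pls_models[group_label] = model
    decomp.tp_models[group_label] = tp

    score_label = f"tp_{group_label}"
    t_std = standardize_vector(tp.t_tp)
    decomp.residual.insert(0, score_label, t_std)
    decomp.original_ss = pd.concat(
        [pd.Series({score_label: float(t_std @ t_std)}), decomp.original_ss]
    )
    # earlier steps never touched the new column
    for s in decomp.steps:
        s.loading = s.loading.reindex(decomp.residual.columns, fill_value=0.0)
        s.removed_ss = s.removed_ss.reindex(decomp.residual.columns, fill_value=0.0)
    cp_single(decomp, score_label)
    return decomp, tp, curve


def cp_sequence(
    table: DataTable,
    group_order: list[str] | None = None,
    validation_config: ValidationConfig | None = None,
) -> CPDecomposition:
    """Run the full sequential CP over ordered covariate groups.

    Univariate groups are projected directly; multivariate groups through
    their validated TP score. The residual outcome and explanatory columns
    of the returned decomposition are the net data for subsequent modelling.
    """
    if group_order is None:
        group_order = table.group_order
    if validation_config is None:
        validation_config = ValidationConfig()
    decomp = make_decomposition(table)
    y_col = table.outcome_name
    for group in group_order:
        members = table.group_members(group)
        if len(members) == 1:
            cp_single(decomp, members[0])
        else:
            cp_multivariate(decomp, group, members, y_col, validation_config)
    return decomp


def pseudoinverse_adjust(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residualize ``M`` on the column space of ``Z`` via the Moore-Penrose inverse.

    ``M - Z Z^- M``; well-defined for rank-deficient ``Z`` and equal to OLS
    residuals when ``Z`` has full column rank.
    """
    Z = np.asarray(Z, dtype=float)
    M = np.asarray(M, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    resid = M - Z @ (np.linalg.pinv(Z) @ M)
    return resid[:, 0] if squeeze else resid


@dataclass
class VariancePartition:
    """Per-variable % of original SS removed by each CP step plus residual."""

    table: pd.DataFrame  # rows: variables; columns: step labels + 'residual'
    step_order: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True, index_label="variable")


def variance_partition(decomp: CPDecomposition) -> VariancePartition:
    """Tabulate the variance plot: % of each column's original SS per step.

    A TP-score column introduced mid-sequence gets zeros for earlier steps;
    percentages sum to 100 per variable.
    """
    cols = decomp.column_labels
    out = {}
    for s in decomp.steps:
        out[s.label] = 100.0 * s.removed_ss.reindex(cols).to_numpy() / (
            decomp.original_ss.reindex(cols).to_numpy()
        )
    out["residual"] = (
        100.0
        * decomp.residual_ss().reindex(cols).to_numpy()
        / decomp.original_ss.reindex(cols).to_numpy()
    )
    table = pd.DataFrame(out, index=cols)
    return VariancePartition(table=table, step_order=[s.label for s in decomp.steps])
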