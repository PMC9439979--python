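"""Orchestration of a full covariate-adjusted association analysis.

A *scenario* names an ordered subset of covariate groups to adjust for
(e.g. ``[age, sex]`` or ``[age, sex, adiposity, pa]``). For each scenario the
pipeline runs the sequential covariate projection, validates a PLS1 model of
the net outcome on the net explanatory block by Monte-Carlo resampling,
distills it to a target component, and reports:

* remaining variance of the outcome and the explanatory block after
  adjustment, as % of the original (pretreated, unadjusted) sums of squares;
* variance explained by the net-association target component, again as % of
  the *original* sums of squares, so numbers are comparable across scenarios;
* per-variable selectivity-ratio and VIP tables.

Two diagnostics accompany the scenarios: the relation between a covariate
group's target component and another multivariate group (how much of, say,
adiposity is accounted for by the physical-activity spectrum), and the
residual-covariate check, which refits the net model with the adjusted
covariate columns appended to the explanatory block — if the adjustment
removed all predictive covariate information, the appended columns gain no
selectivity and the explained outcome variance is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataTable, standardize_vector
from .errors import ConfigurationError
from .pls import fit_pls1
from .projection import (
    CPDecomposition,
    ValidationConfig,
    cp_multivariate,
    cp_sequence,
    variance_partition,
)
from .target import TPModel, importance_table, target_project
from .validation import ValidationCurve, monte_carlo_curve


@dataclass
class AdjustmentScenario:
    """Ordered covariate groups to adjust for, under a human-readable label."""

    label: str
    group_order: list[str]

    @classmethod
    def from_spec(cls, spec: str) -> "AdjustmentScenario":
        groups = [g.strip() for g in spec.split(",") if g.strip()]
        return cls(label=", ".join(groups) if groups else "none", group_order=groups)


@dataclass
class NetAssociationReport:
    """Summary of one scenario: variance bookkeeping plus importance tables."""

    scenario_label: str
    var_adj_outcome_pct: float
    var_adj_explanatory_pct: float
    r2_explanatory_pct: float
    r2_outcome_pct: float
    selected_A: int
    sr_table: pd.DataFrame
    curve: ValidationCurve | None
    decomposition: CPDecomposition
    tp: TPModel | None = None
    warnings: list[str] = field(default_factory=list)


def _check_groups(table: DataTable, groups: list[str]) -> None:
    known = set(table.group_order)
    bad = [g for g in groups if g not in known]
    if bad:
        raise ConfigurationError(f"scenario names unknown covariate groups: {bad}")


def run_scenario(
    table: DataTable,
    scenario: AdjustmentScenario,
    validation_config: ValidationConfig | None = None,
) -> NetAssociationReport:
    """Adjust for the scenario's groups, then model the net association."""
    vc = validation_config or ValidationConfig()
    _check_groups(table, scenario.group_order)
    decomp = cp_sequence(table, scenario.group_order, vc)

    y_col = table.outcome_name
    x_cols = table.explanatory_names
    ss_y0 = float(decomp.original_ss[y_col])
    ss_x0 = float(decomp.original_ss[x_cols].sum())
    y_net = decomp.net_column(y_col)
    X_net = decomp.net_matrix(x_cols)
    var_y = 100.0 * float(y_net @ y_net) / ss_y0
    var_x = 100.0 * float((X_net**2).sum()) / ss_x0

    curve = monte_carlo_curve(
        X_net,
        y_net,
        A_max=min(vc.a_max, len(x_cols)),
        reps=vc.reps,
        holdout_fraction=vc.holdout_fraction,
        seed=vc.model_seed(f"net::{scenario.label}"),
        alpha=vc.alpha,
        rule=vc.rule,
    )
    notes: list[str] = []
    if curve.selected_A == 0:
        msg = (
            f"scenario {scenario.label!r}: no validated predictive components "
            "remain between outcome and explanatory block"
        )
        warnings.warn(msg, stacklevel=2)
        return NetAssociationReport(
            scenario_label=scenario.label,
            var_adj_outcome_pct=var_y,
            var_adj_explanatory_pct=var_x,
            r2_explanatory_pct=0.0,
            r2_outcome_pct=0.0,
            selected_A=0,
            sr_table=pd.DataFrame(
                columns=["variable", "signed_sr", "sr", "vip", "p_tp", "w_tp"]
            ),
            curve=curve,
            decomposition=decomp,
            warnings=[msg],
        )

    model = fit_pls1(X_net, y_net, curve.selected_A)
    tp = target_project(model, X_net, y_net)
    tp.variable_names = list(x_cols)
    yhat = tp.fitted()
    r2_y = 100.0 * float(yhat @ yhat) / ss_y0
    r2_x = 100.0 * float(tp.explained_x_ss.sum()) / ss_x0
    return NetAssociationReport(
        scenario_label=scenario.label,
        var_adj_outcome_pct=var_y,
        var_adj_explanatory_pct=var_x,
        r2_explanatory_pct=r2_x,
        r2_outcome_pct=r2_y,
        selected_A=curve.selected_A,
        sr_table=importance_table(model, tp, list(x_cols)),
        curve=curve,
        decomposition=decomp,
        tp=tp,
        warnings=notes,
    )


def table1_report(
    table: DataTable,
    scenarios: list[AdjustmentScenario],
    validation_config: ValidationConfig | None = None,
) -> tuple[pd.DataFrame, list[NetAssociationReport]]:
    """One summary row per scenario (remaining and explained variances, in %)."""
    reports = [run_scenario(table, s, validation_config) for s in scenarios]
    rows = [
        {
            "adjusted_for": r.scenario_label,
            "remaining_outcome_pct": r.var_adj_outcome_pct,
            "remaining_explanatory_pct": r.var_adj_explanatory_pct,
            "r2_explanatory_pct": r.r2_explanatory_pct,
            "r2_outcome_pct": r.r2_outcome_pct,
            "selected_A": r.selected_A,
        }
        for r in reports
    ]
    cols = [
        "adjusted_for",
        "remaining_outcome_pct",
        "remaining_explanatory_pct",
        "r2_explanatory_pct",
        "r2_outcome_pct",
        "selected_A",
    ]
    return pd.DataFrame(rows, columns=cols), reports


@dataclass
class CovariateRelation:
    """PLS/TP summary of one covariate group modelled on another."""

    group_a: str
    group_b: str
    explained_pct: float
    selected_A: int
    sr_table: pd.DataFrame
    curve: ValidationCurve


def covariate_relation(
    table: DataTable,
    group_a: str,
    group_b: str,
    validation_config: ValidationConfig | None = None,
) -> CovariateRelation:
    """Model group_a's target component on group_b's block.

    Upstream groups (those configured before ``group_a``) are projected out
    first; group_b's block is taken at that same stage, so the relation is
    assessed net of the upstream covariates but before either group is
    removed.
    """
    vc = validation_config or ValidationConfig()
    _check_groups(table, [group_a, group_b])
    upstream = [g for g in table.group_order if g != group_b]
    upstream = upstream[: upstream.index(group_a)]
    decomp = cp_sequence(table, upstream, vc)

    b_cols = table.group_members(group_b)
    if len(b_cols) < 2:
        raise ConfigurationError(f"group_b {group_b!r} must be multivariate")
    Zb = decomp.net_matrix(b_cols)

    a_cols = table.group_members(group_a)
    if len(a_cols) == 1:
        t_a = standardize_vector(decomp.net_column(a_cols[0]))
    else:
        decomp, tp_a, _ = cp_multivariate(
            decomp, group_a, a_cols, table.outcome_name, vc
        )
        if tp_a is None:
            raise ConfigurationError(
                f"group {group_a!r} has no validated target component"
            )
        t_a = standardize_vector(tp_a.t_tp)

    curve = monte_carlo_curve(
        Zb,
        t_a,
        A_max=min(vc.a_max, len(b_cols)),
        reps=vc.reps,
        holdout_fraction=vc.holdout_fraction,
        seed=vc.model_seed(f"relation::{group_a}::{group_b}"),
        alpha=vc.alpha,
        rule=vc.rule,
    )
    if curve.selected_A == 0:
        return CovariateRelation(
            group_a=group_a,
            group_b=group_b,
            explained_pct=0.0,
            selected_A=0,
            sr_table=pd.DataFrame(
                columns=["variable", "signed_sr", "sr", "vip", "p_tp", "w_tp"]
            ),
            curve=curve,
        )
    model = fit_pls1(Zb, t_a, curve.selected_A)
    tp = target_project(model, Zb, t_a)
    tp.variable_names = list(b_cols)
    yhat = tp.fitted()
    explained = 100.0 * float(yhat @ yhat) / float(t_a @ t_a)
    return CovariateRelation(
        group_a=group_a,
        group_b=group_b,
        explained_pct=explained,
        selected_A=curve.selected_A,
        sr_table=importance_table(model, tp, list(b_cols)),
        curve=curve,
    )


@dataclass
class ResidualCovariateCheck:
    """Net model refitted with the adjusted covariate columns appended."""

    r2_outcome_pct_with: float
    r2_outcome_pct_without: float
    appended: list[str]
    sr_table: pd.DataFrame
    selected_A: int


def residual_covariate_check(
    table: DataTable,
    scenario: AdjustmentScenario,
    validation_config: ValidationConfig | None = None,
    base_report: NetAssociationReport | None = None,
) -> ResidualCovariateCheck:
    """Refit the net model with adjusted covariate variables as predictors.

    Covariates projected via a target component retain residual variance;
    appending their adjusted columns to the explanatory block probes whether
    any predictive covariate information survived the adjustment. The
    explained outcome variance should be essentially unchanged and the
    appended columns should not outrank the retained explanatory variables.
    """
    vc = validation_config or ValidationConfig()
    if base_report is None:
        base_report = run_scenario(table, scenario, vc)
    decomp = base_report.decomposition

    appended: list[str] = []
    for g in scenario.group_order:
        for c in table.group_members(g):
            if not decomp.is_zeroed(c):
                appended.append(c)
    x_cols = table.explanatory_names + appended
    X = decomp.net_matrix(x_cols)
    y_net = decomp.net_column(table.outcome_name)
    ss_y0 = float(decomp.original_ss[table.outcome_name])

    curve = monte_carlo_curve(
        X,
        y_net,
        A_max=min(vc.a_max, X.shape[1]),
        reps=vc.reps,
        holdout_fraction=vc.holdout_fraction,
        seed=vc.model_seed(f"residual-check::{scenario.label}"),
        alpha=vc.alpha,
        rule=vc.rule,
    )
    if curve.selected_A == 0:
        return ResidualCovariateCheck(
            r2_outcome_pct_with=0.0,
            r2_outcome_pct_without=base_report.r2_outcome_pct,
            appended=appended,
            sr_table=pd.DataFrame(
                columns=["variable", "signed_sr", "sr", "vip", "p_tp", "w_tp"]
            ),
            selected_A=0,
        )
    model = fit_pls1(X, y_net, curve.selected_A)
    tp = target_project(model, X, y_net)
    tp.variable_names = list(x_cols)
    yhat = tp.fitted()
    return ResidualCovariateCheck(
        r2_outcome_pct_with=100.0 * float(yhat @ yhat) / ss_y0,
        r2_outcome_pct_without=base_report.r2_outcome_pct,
        appended=appended,
        sr_table=importance_table(model, tp, list(x_cols)),
        selected_A=curve.selected_A,
    )


def export_reports(outdir, table1: pd.DataFrame, reports: list[NetAssociationReport]) -> None:
    """Write table1.csv, per-scenario SR/VIP tables, variance partitions, curves."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table1.to_csv(out / "table1.csv", index=False)
    for r in reports:
        slug = r.scenario_label.replace(", ", "_").replace(" ", "") or "none"
        r.sr_table.to_csv(out / f"sr_{slug}.csv", index=False)
        variance_partition(r.decomposition).to_csv(out / f"variance_partition_{slug}.csv")
        if r.curve is not None:
            r.curve.to_csv(out / f"validation_{slug}.csv")
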