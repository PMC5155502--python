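"""End-to-end benchmark studies on synthetic studbooks.

These drive the full pipeline — simulate a training population and an
independent holdout population, build design matrices, fit and prune
regression trees, validate externally, and run the group-structure
optimizer — under the frozen study conditions of the synthetic benchmarks.
The analysis scripts, the test suite and the acceptance script all call
these functions so every reported number comes from one code path.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import pandas as pd

from .covariates import (ModelSpec, ReproductiveSuccess, build_design_matrix,
                         select_focals, to_sigma_design)
from .optimizer import (ArrangementEvaluator, capacity_constraints, optimize)
from .pedigree import build_kdag
from .rprm import RegressionTree, cv_prune, external_validation, grow_tree
from .studbook_io import StudbookTable, monthly_residency
from .synthetic_data import (SimulationParams, make_benchmark_pair,
                             recovery_params, simulate_studbook)

#: model configuration of the split-vs-sigma recovery study: diameter-1 SIGs,
#: a 24-month outcome window, quarterly snapshots, and no descendant-class
#: predictors (they proxy the focal's own reproductive history)
RECOVERY_SPEC = ModelSpec(variable_set="split", d=1, horizon=24,
                          include_descendant_classes=False)
RECOVERY_MONTH_STEP = 3


def prepare_population(table: StudbookTable):
    """Graph, residency and cached r_III machinery for one population."""
    graph = build_kdag(table)
    residency = monthly_residency(table)
    rs = ReproductiveSuccess(graph, table)
    return graph, residency, rs


def build_split_design(table: StudbookTable, spec: ModelSpec = RECOVERY_SPEC,
                       month_step: int = RECOVERY_MONTH_STEP,
                       mode: str = "current") -> pd.DataFrame:
    graph, residency, rs = prepare_population(table)
    focals = select_focals(graph, table, spec.d)
    return build_design_matrix(graph, table, residency, spec, mode=mode,
                               month_step=month_step, focals=focals, rs=rs)


def fit_rprm(design: pd.DataFrame, seed: int, rule: str = "1se",
             variables: Optional[list[str]] = None) -> RegressionTree:
    """Grow with the standard stopping rules and prune by 10-fold CV."""
    tree = grow_tree(design, variables=variables,
                     minsplit=15, minbucket=15, cp=0.01)
    return cv_prune(design, tree, k=10, rng_seed=seed, rule=rule)


def split_vs_sigma_replicate(seed: int,
                             params: Optional[SimulationParams] = None) -> dict:
    """One train/holdout replicate of the kin-aware vs kin-blind comparison.

    Fits the split-spec model (local kin alpha and pseudo-kin gamma as
    separate variables) and the sigma-spec model (alpha + gamma merged per
    class) on the same training design, and scores both on the independent
    holdout population by signed predictive R-squared.
    """
    params = params or recovery_params()
    train, hold, train_truth, hold_truth = make_benchmark_pair(params, seed=seed)
    d_train = build_split_design(train)
    d_hold = build_split_design(hold)
    out = {"seed": seed,
           "n_train": train_truth["n_individuals"],
           "n_holdout": hold_truth["n_individuals"],
           "rows_train": len(d_train), "rows_holdout": len(d_hold)}
    for name, tr_design, ho_design in (
            ("split", d_train, d_hold),
            ("sigma", to_sigma_design(d_train), to_sigma_design(d_hold))):
        tree = fit_rprm(tr_design, seed=seed)
        scores = external_validation(tree, ho_design)
        out[name] = scores["predictive_r2"]
        out[name + "_pearson"] = scores["pearson_r2"]
        out[name + "_leaves"] = tree.n_leaves()
        if name == "split":
            out["first_split"] = tree.root.var
    out["split_wins"] = out["split"] > out["sigma"]
    return out


def split_vs_sigma_study(n_replicates: int = 20, seed: int = 0,
                         params: Optional[SimulationParams] = None) -> pd.DataFrame:
    """Replicated comparison; one row per replicate."""
    rows = [split_vs_sigma_replicate(seed + i, params)
            for i in range(n_replicates)]
    return pd.DataFrame(rows)


def optimizer_study(seed: int = 0, params: Optional[SimulationParams] = None,
                    n_seeds: int = 50, n_iter: int = 10, n_mutants: int = 5,
                    group_size: int = 20):
    """Scaled group-structure optimization on one synthetic population.

    Fits a sigma-spec current-conditions model with a 12-month outcome
    window plus a base-variables fallback,
    evaluates the status quo at the final simulated month, and hill-climbs
    ``n_seeds`` random rearrangements under historic capacity constraints.
    Returns (status-quo score, best score, trajectory, best arrangement).
    """
    params = params or dataclasses.replace(
        recovery_params(), n_zoos=10, months=180, id_prefix="OP")
    table, _ = simulate_studbook(params, seed=seed)
    graph, residency, rs = prepare_population(table)
    spec = ModelSpec(variable_set="sigma", d=1, horizon=12,
                     include_descendant_classes=False)
    focals = select_focals(graph, table, spec.d)
    # current-conditions model: the optimizer scores hypothetical
    # arrangements from social structure alone, so reproductive history
    # (prev_rs, arrangement-independent) stays out of the predictors
    design = build_design_matrix(graph, table, residency, spec,
                                 mode="current", month_step=4,
                                 focals=focals, rs=rs)
    # highest-mean-accuracy subtree selection: the optimizer needs the
    # richest validated predictor, not the most conservative one
    model = fit_rprm(design, seed=seed, rule="best")
    base_cols = [c for c in design.columns
                 if not c.startswith("s_") and c not in ("focal", "month", "y")]
    fallback = fit_rprm(design, seed=seed, rule="best", variables=base_cols)
    month = table.data_end
    evaluator = ArrangementEvaluator(graph, table, residency, month,
                                     model, spec, fallback=fallback, rs=rs)
    constraints = capacity_constraints(residency, month)
    status_quo = evaluator.score(evaluator.status_quo)
    best, trajectory = optimize(evaluator, constraints, n_seeds=n_seeds,
                                n_iter=n_iter, n_mutants=n_mutants,
                                group_size=group_size, rng=seed)
    return status_quo, evaluator.score(best), trajectory, best
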