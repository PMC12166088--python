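"""Experiment designs: repeated 80/10/10 hold-out and leave-one-out.

``run_holdout`` mirrors the large-screen study design: in each repeat the
cell lines are split into training/validation/test sets, the training matrix
is completed (held-out cells excluded from imputation), a probing panel and
historical cohort are chosen on the training set, and every test cell line
is recommended for from its panel measurements alone and scored against its
remaining measurements.

``run_leave_one_out`` mirrors the small ex vivo design: each drug's response
on each cell line is predicted from that cell line's other drugs (the panel)
and all other patients' profiles, yielding a full predicted profile per
cell line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._util import derive_seed
from .evaluation import (
    CellLineEvaluation,
    aggregate_repeats,
    evaluate_subsets,
    regression_metrics,
    summarise_cells,
)
from .imputation import impute
from .matrix_io import ResponseMatrix, call_hits, rank_drug_ids, selective_drug_mask
from .panel_selection import (
    DiversityParams,
    PanelSelection,
    fit_panel_to_size,
    select_random,
)
from .recommender import RecommenderConfig, recommend

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Settings for a full recommendation experiment.

    Defaults follow the prototype system: five repeated experiments on
    80/10/10 splits, TML-completed training data, a 30-drug diversity panel,
    100 randomly drawn historical cell lines, and a 50-tree random forest.
    """

    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_repeats: int = 5
    n_historical_cells: int = 100
    panel_size: int = 30
    panel_method: str = "diversity"
    imputation: str = "tml"
    learner: str = "random_forest"
    n_trees: int = 50
    top_ns: tuple[int, ...] = (10, 20, 30)
    hit_ks: tuple[int, ...] = (10,)
    selective_prevalence_limit: float = 0.2
    variance_keep_fraction: float = 0.5
    seed_base: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.split_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be ≥ 1")
        if self.panel_method not in ("diversity", "random"):
            raise ValueError(f"unknown panel method {self.panel_method!r}")


def split_dataset(
    cell_ids: Sequence[str],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], ...]:
    """Random disjoint, exhaustive partition of the cell lines.

    Split sizes use largest-remainder rounding so they always sum to the
    total (e.g. 809 cells at 80/10/10 gives 647/81/81). Raises if any split
    would be empty.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n = len(cell_ids)
    floors = [int(math.floor(f * n)) for f in fractions]
    remainders = [f * n - fl for f, fl in zip(fractions, floors)]
    for i in sorted(
        range(len(fractions)), key=lambda i: (-remainders[i], i)
    )[: n - sum(floors)]:
        floors[i] += 1
    if any(s == 0 for s in floors):
        raise ValueError(f"empty split with sizes {floors} for {n} cells")
    order = list(np.random.default_rng(seed).permutation(n))
    splits: list[list[str]] = []
    start = 0
    for size in floors:
        splits.append([str(cell_ids[i]) for i in order[start : start + size]])
        start += size
    return tuple(splits)


@dataclass
class RepeatResult:
    """Everything computed in one hold-out repeat."""

    seed: int
    train_cells: list[str]
    validation_cells: list[str]
    test_cells: list[str]
    panel: PanelSelection
    selective_drugs: list[str]
    predictions: dict[str, dict[str, float]]
    evaluations: dict[str, dict[str, CellLineEvaluation | None]]
    summary: dict[str, dict[str, float]]


@dataclass
class HoldoutReport:
    config: ExperimentConfig
    repeats: list[RepeatResult]
    aggregate: dict[str, dict[str, dict[str, float]]]


def _choose_panel(
    completed: ResponseMatrix, cfg: ExperimentConfig, seed: int
) -> list[str]:
    if cfg.panel_method == "random":
        return select_random(
            completed, "drugs", cfg.panel_size, derive_seed(seed, "panel")
        )
    return fit_panel_to_size(
        completed,
        DiversityParams(
            variance_keep_fraction=cfg.variance_keep_fraction,
            axis="drugs",
            target_size=cfg.panel_size,
        ),
    )


def run_holdout(matrix: ResponseMatrix, cfg: ExperimentConfig) -> HoldoutReport:
    """Repeated hold-out evaluation of the recommender on one dataset.

    ``matrix`` must already be pruned and on the activity scale. Every
    random draw is seeded from ``cfg.seed_base + repeat``; validation/test
    cell lines never enter imputation or panel selection.
    """
    repeats: list[RepeatResult] = []
    for r in range(cfg.n_repeats):
        seed_r = cfg.seed_base + r
        train, val, test = split_dataset(
            matrix.cell_ids, cfg.split_fractions, seed_r
        )
        train_m = matrix.subset(cells=train)
        completed = impute(train_m, cfg.imputation, seed=derive_seed(seed_r, "impute"))

        panel_drugs = _choose_panel(completed, cfg, seed_r)
        n_hist = min(cfg.n_historical_cells, len(train))
        historical_cells = select_random(
            completed, "cells", n_hist, derive_seed(seed_r, "historical")
        )
        panel = PanelSelection(panel_drugs, historical_cells, cfg.panel_method, seed_r)
        historical = completed.subset(cells=historical_cells)

        sel_mask = selective_drug_mask(
            call_hits(train_m), cfg.selective_prevalence_limit
        )
        selective = [d for d, m in zip(train_m.drug_ids, sel_mask) if m]

        predictions: dict[str, dict[str, float]] = {}
        evaluations: dict[str, dict[str, CellLineEvaluation | None]] = {}
        for cell in test:
            profile = matrix.cell_profile(cell)
            cell_panel = [d for d in panel_drugs if d in profile]
            if len(cell_panel) < len(panel_drugs):
                logger.warning(
                    "cell %r missing %d panel measurements; dropped from its panel",
                    cell,
                    len(panel_drugs) - len(cell_panel),
                )
            if len(cell_panel) < 2:
                logger.warning("cell %r has < 2 panel measurements; skipped", cell)
                continue
            rec = recommend(
                historical,
                PanelSelection(cell_panel, historical_cells, cfg.panel_method, seed_r),
                {d: profile[d] for d in cell_panel},
                RecommenderConfig(
                    learner=cfg.learner,
                    n_trees=cfg.n_trees,
                    seed=derive_seed(seed_r, "forest", cell),
                ),
                scheme=matrix.scheme,
                new_cell_id=cell,
            )
            panel_set = set(cell_panel)
            actual = {d: v for d, v in profile.items() if d not in panel_set}
            predictions[cell] = rec.predicted
            evaluations[cell] = evaluate_subsets(
                rec.predicted,
                actual,
                matrix.scheme,
                selective,
                cfg.top_ns,
                cfg.hit_ks,
                cell_id=cell,
            )

        summary = {
            subset: summarise_cells(
                [e[subset] for e in evaluations.values() if e[subset] is not None]
            )
            for subset in ("all_drugs", "selective_drugs")
        }
        repeats.append(
            RepeatResult(
                seed=seed_r,
                train_cells=train,
                validation_cells=val,
                test_cells=test,
                panel=panel,
                selective_drugs=selective,
                predictions=predictions,
                evaluations=evaluations,
                summary=summary,
            )
        )

    aggregate = {
        subset: aggregate_repeats([rep.summary[subset] for rep in repeats])
        for subset in ("all_drugs", "selective_drugs")
    }
    return HoldoutReport(config=cfg, repeats=repeats, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Leave-one-out (ex vivo style)
# ---------------------------------------------------------------------------

#: predictor(historical, panel, new_profile, seed, scheme, new_cell_id)
#: -> drug id → predicted activity for all non-panel drugs
Predictor = Callable[
    [ResponseMatrix, PanelSelection, Mapping[str, float], int, object, str],
    Mapping[str, float],
]


@dataclass
class LOOCellResult:
    """Per-cell-line leave-one-out summary (viability-style screens)."""

    cell_id: str
    n_drugs: int
    r_spearman: float
    library_mean_activity: float
    top5_mean_activity: float
    n_hits_available: int
    n_hits_predicted: int
    n_hits_identified: int
    predicted: dict[str, float]

    @property
    def hit_evaluable(self) -> bool:
        return self.n_hits_available > 0


@dataclass
class LOOReport:
    config: ExperimentConfig
    repeats: list[list[LOOCellResult]]
    aggregate: dict[str, dict[str, float]]


def _forest_predictor(
    historical: ResponseMatrix,
    panel: PanelSelection,
    new_profile: Mapping[str, float],
    seed: int,
    scheme,
    new_cell_id: str,
) -> Mapping[str, float]:
    rec = recommend(
        historical,
        panel,
        new_profile,
        RecommenderConfig(seed=seed),
        scheme=scheme,
        new_cell_id=new_cell_id,
    )
    return rec.predicted


def summarise_loo(rows: Sequence[LOOCellResult]) -> dict[str, float]:
    """Cohort means for one leave-one-out pass.

    ``hit_precision`` is hits identified / hits predicted and
    ``hit_recall`` hits identified / hits available, both averaged over the
    hit-evaluable cell lines (those with at least one hit available).
    """
    spearmans = [r.r_spearman for r in rows]
    out = {
        "n_cells": float(len(rows)),
        "n_drugs_available": float(np.mean([r.n_drugs for r in rows])),
        "r_spearman": (
            float(np.nanmean(spearmans))
            if np.any(np.isfinite(spearmans))
            else float("nan")
        ),
        "library_mean_activity": float(
            np.mean([r.library_mean_activity for r in rows])
        ),
        "top5_mean_activity": float(np.mean([r.top5_mean_activity for r in rows])),
        "n_hits_available": float(np.mean([r.n_hits_available for r in rows])),
        "n_hits_predicted": float(np.mean([r.n_hits_predicted for r in rows])),
        "n_hits_identified": float(np.mean([r.n_hits_identified for r in rows])),
    }
    evaluable = [r for r in rows if r.hit_evaluable]
    out["n_hit_evaluable_cells"] = float(len(evaluable))
    if evaluable:
        precisions = [
            r.n_hits_identified / r.n_hits_predicted
            for r in evaluable
            if r.n_hits_predicted > 0
        ]
        out["hit_precision"] = float(np.mean(precisions)) if precisions else 0.0
        out["hit_recall"] = float(
            np.mean([r.n_hits_identified / r.n_hits_available for r in evaluable])
        )
    else:
        out["hit_precision"] = float("nan")
        out["hit_recall"] = float("nan")
    return out


def run_leave_one_out(
    matrix: ResponseMatrix,
    cfg: ExperimentConfig,
    predictor: Predictor | None = None,
) -> LOOReport:
    """Leave-one-drug-out over every cell line of a small screen.

    For each cell line and each drug measured on it, the drug's response is
    predicted from the cell line's remaining measured drugs (the panel) and
    the completed profiles of all other cell lines. Cell lines with fewer
    than 3 measured drugs are skipped with a warning. Repeats vary only the
    stochastic components (imputation and forest seeds).
    """
    predictor = predictor or _forest_predictor
    repeats: list[list[LOOCellResult]] = []
    for r in range(cfg.n_repeats):
        seed_r = cfg.seed_base + r
        rows: list[LOOCellResult] = []
        for cell in matrix.cell_ids:
            profile = matrix.cell_profile(cell)
            measured = [d for d in matrix.drug_ids if d in profile]
            if len(measured) < 3:
                logger.warning(
                    "cell %r has only %d measured drugs; skipped",
                    cell,
                    len(measured),
                )
                continue
            others = [c for c in matrix.cell_ids if c != cell]
            completed = impute(
                matrix.subset(cells=others),
                cfg.imputation,
                seed=derive_seed(seed_r, "impute", cell),
            )
            predicted: dict[str, float] = {}
            for drug in measured:
                panel_drugs = [d for d in measured if d != drug]
                preds = predictor(
                    completed,
                    PanelSelection(panel_drugs, others, "loo", seed_r),
                    {d: profile[d] for d in panel_drugs},
                    derive_seed(seed_r, "forest", cell, drug),
                    matrix.scheme,
                    cell,
                )
                predicted[drug] = float(preds[drug])

            actual_vec = np.array([profile[d] for d in measured])
            pred_vec = np.array([predicted[d] for d in measured])
            _, r_s, _ = regression_metrics(pred_vec, actual_vec)
            ranked = rank_drug_ids(predicted, matrix.scheme)
            top5 = ranked[: min(5, len(ranked))]
            hits_avail = {d for d in measured if matrix.scheme.is_hit(profile[d])}
            hits_pred = {d for d in measured if matrix.scheme.is_hit(predicted[d])}
            rows.append(
                LOOCellResult(
                    cell_id=cell,
                    n_drugs=len(measured),
                    r_spearman=r_s,
                    library_mean_activity=float(np.mean(actual_vec)),
                    top5_mean_activity=float(
                        np.mean([profile[d] for d in top5])
                    ),
                    n_hits_available=len(hits_avail),
                    n_hits_predicted=len(hits_pred),
                    n_hits_identified=len(hits_avail & hits_pred),
                    predicted=predicted,
                )
            )
        repeats.append(rows)

    aggregate = aggregate_repeats([summarise_loo(rows) for rows in repeats])
    return LOOReport(config=cfg, repeats=repeats, aggregate=aggregate)
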