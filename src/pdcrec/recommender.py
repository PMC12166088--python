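"""Per-patient drug recommendation from a probing panel.

The learning setup inverts the usual drug-descriptor view: training SAMPLES
are the panel drugs, FEATURES are the historical cell lines (each drug is
fingerprinted by its measured activities across the cohort), and the TARGET
is the new culture's measured response to that drug. A tree ensemble fitted
on the panel rows then predicts the new culture's response to every other
library drug, and the library is ranked best-first under the dataset's
activity scheme. Forest feature importances quantify which historical cell
lines drive the predictions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .matrix_io import ActivityScheme, ResponseMatrix, rank_drug_ids
from .panel_selection import PanelSelection


class LeakageError(ValueError):
    """An operation would read data from the cell line being predicted."""


@dataclass
class RecommenderConfig:
    """Learner settings: a 50-tree random forest by default, with the
    implementation's default hyperparameters otherwise; gradient boosting is
    available as an alternative. ``learner_params`` passes extra keyword
    arguments straight through to the scikit-learn estimator."""

    learner: str = "random_forest"
    n_trees: int = 50
    seed: int = 0
    learner_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learner not in ("random_forest", "gradient_boosting"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be ≥ 1")


@dataclass
class TrainingTable:
    """Panel rows (with targets) and library rows sharing one feature layout:
    one column per historical cell line."""

    feature_cells: list[str]
    panel_drugs: list[str]
    X_train: np.ndarray
    y: np.ndarray
    pred_drugs: list[str]
    X_pred: np.ndarray


@dataclass
class RecommendationResult:
    """Predicted activities, ranking, hit calls and cohort importances for
    one new cell line."""

    new_cell_id: str | None
    predicted: dict[str, float]
    ranking: list[str]
    predicted_hits: list[str]
    importances: dict[str, float]
    low_confidence: bool = False
    hyperparameters: dict = field(default_factory=dict)


def build_training_table(
    historical: ResponseMatrix,
    panel: PanelSelection,
    new_profile: Mapping[str, float],
    new_cell_id: str | None = None,
) -> TrainingTable:
    """Assemble the drug × historical-cell feature table.

    ``historical`` must be complete (imputed) over the historical cells;
    ``new_profile`` must cover every panel drug and nothing outside the
    panel is ever read from it. Raises :class:`LeakageError` if the new cell
    also appears among the historical cells.
    """
    drug_set = set(historical.drug_ids)
    missing_drugs = [d for d in panel.panel_drugs if d not in drug_set]
    if missing_drugs:
        raise KeyError(f"panel drugs absent from historical matrix: {missing_drugs}")
    if new_cell_id is not None and new_cell_id in set(panel.historical_cells):
        raise LeakageError(
            f"new cell {new_cell_id!r} overlaps the historical cohort"
        )
    uncovered = [d for d in panel.panel_drugs if d not in new_profile]
    if uncovered:
        raise KeyError(f"new profile lacks panel drugs: {uncovered}")

    cohort = historical.subset(cells=panel.historical_cells)
    if cohort.missing_mask.any():
        raise ValueError(
            "historical matrix has missing entries over the cohort; impute first"
        )
    if len(panel.panel_drugs) == 1:
        warnings.warn("single-drug panel: degenerate training table", stacklevel=2)

    # rows = drugs, columns = historical cell lines
    by_drug = cohort.values.T
    dpos = {d: j for j, d in enumerate(cohort.drug_ids)}
    panel_idx = [dpos[d] for d in panel.panel_drugs]
    panel_set = set(panel.panel_drugs)
    pred_drugs = [d for d in cohort.drug_ids if d not in panel_set]
    pred_idx = [dpos[d] for d in pred_drugs]
    return TrainingTable(
        feature_cells=list(cohort.cell_ids),
        panel_drugs=list(panel.panel_drugs),
        X_train=by_drug[panel_idx],
        y=np.array([float(new_profile[d]) for d in panel.panel_drugs]),
        pred_drugs=pred_drugs,
        X_pred=by_drug[pred_idx],
    )


def _make_learner(config: RecommenderConfig):
    if config.learner == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.n_trees,
            random_state=config.seed,
            **config.learner_params,
        )
    return GradientBoostingRegressor(
        n_estimators=config.n_trees,
        random_state=config.seed,
        **config.learner_params,
    )


def fit_and_rank(
    table: TrainingTable,
    config: RecommenderConfig,
    scheme: ActivityScheme,
    new_cell_id: str | None = None,
) -> RecommendationResult:
    """Fit the ensemble on the panel rows and rank the rest of the library.

    Predicted hits reuse the scheme's measured-hit rule on predicted
    activities. Importances are per historical cell line and normalised to
    sum to 1 (uniform when the fitted ensemble assigns none, e.g. for a
    constant target, in which case the result is flagged low-confidence).
    """
    if table.X_train.shape[0] == 0:
        raise ValueError("empty training table")
    if not np.all(np.isfinite(table.X_train)) or not np.all(np.isfinite(table.y)):
        raise ValueError("training table contains non-finite values")

    model = _make_learner(config)
    model.fit(table.X_train, table.y)
    predictions = model.predict(table.X_pred) if table.X_pred.shape[0] else np.array([])
    predicted = {d: float(v) for d, v in zip(table.pred_drugs, predictions)}
    ranking = rank_drug_ids(predicted, scheme)
    predicted_hits = [d for d in ranking if bool(scheme.is_hit(predicted[d]))]

    raw = np.asarray(model.feature_importances_, dtype=float)
    total = raw.sum()
    low_confidence = bool(np.ptp(table.y) == 0 or total <= 0)
    if total > 0:
        weights = raw / total
    else:
        weights = np.full(len(table.feature_cells), 1.0 / len(table.feature_cells))
    importances = {c: float(w) for c, w in zip(table.feature_cells, weights)}

    return RecommendationResult(
        new_cell_id=new_cell_id,
        predicted=predicted,
        ranking=ranking,
        predicted_hits=predicted_hits,
        importances=importances,
        low_confidence=low_confidence,
        hyperparameters=model.get_params(),
    )


def recommend(
    historical: ResponseMatrix,
    panel: PanelSelection,
    new_profile: Mapping[str, float],
    config: RecommenderConfig,
    scheme: ActivityScheme | None = None,
    new_cell_id: str | None = None,
) -> RecommendationResult:
    """Convenience wrapper: build the table, fit, and rank."""
    table = build_training_table(historical, panel, new_profile, new_cell_id)
    return fit_and_rank(
        table, config, scheme or historical.scheme, new_cell_id=new_cell_id
    )


def tissue_composition(
    importances: Mapping[str, float],
    annotations: Mapping[str, str],
    top_k: int = 10,
) -> dict[str, int]:
    """Tissue-of-origin counts among the ``top_k`` most influential
    historical cell lines. Unannotated cells count as "unknown". Ties in
    importance are broken by cell id."""
    ranked = sorted(importances, key=lambda c: (-importances[c], c))
    top = ranked[: min(top_k, len(ranked))]
    counts = Counter(annotations.get(c, "unknown") for c in top)
    return dict(counts)
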