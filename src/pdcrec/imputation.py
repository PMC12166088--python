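"""Completion of missing entries in training response matrices.

Two strategies are provided. ``zero_fill`` replaces missing activities with
zero — on the pIC50 / inverse-log2 scales zero means "inactive", so this is
a conservative prior. ``tml_impute`` learns, for each drug with gaps, a
boosted-stump regression from the responses of all other (well-measured)
drugs across cell lines and predicts the missing values; the drug-response
profiles of other assays serve as the feature fingerprint.

Held-out cell lines (validation/test) must never inform imputation: they are
listed in :attr:`TMLConfig.excluded_cells`, their rows are neither used as
training samples nor filled in, and they are returned untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from ._util import derive_seed
from .matrix_io import ResponseMatrix

logger = logging.getLogger(__name__)


@dataclass
class TMLConfig:
    """Configuration for per-drug boosted-stump imputation.

    n_estimators, max_depth
        Boosted-ensemble size and tree depth; 50 depth-1 stumps give an
        additive model over feature drugs, robust at the small sample sizes
        typical of pruned screens.
    feature_missing_max
        A drug may serve as a feature only if it has strictly fewer than
        this many missing entries among the eligible (non-excluded) cells;
        its remaining gaps are zero-filled before fitting.
    excluded_cells
        Validation/test cell lines; never read and never filled.
    """

    n_estimators: int = 50
    max_depth: int = 1
    feature_missing_max: int = 20
    excluded_cells: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be ≥ 1")
        self.excluded_cells = frozenset(self.excluded_cells)


def zero_fill(matrix: ResponseMatrix) -> ResponseMatrix:
    """Replace every missing entry with 0 on the activity scale.

    Observed entries are untouched; the returned matrix's ``imputed_mask``
    records which entries were filled.
    """
    values = matrix.values.copy()
    values[matrix.missing_mask] = 0.0
    return ResponseMatrix(
        list(matrix.cell_ids),
        list(matrix.drug_ids),
        values,
        np.zeros_like(matrix.missing_mask),
        matrix.scheme,
        matrix.missing_mask.copy(),
    )


def tml_impute(
    matrix: ResponseMatrix, config: TMLConfig | None = None
) -> tuple[ResponseMatrix, dict]:
    """Impute missing entries drug-by-drug with boosted stumps.

    For each drug with missing values among eligible cells, a
    ``GradientBoostingRegressor`` is fitted on the eligible cells where that
    drug was measured, using as features all *other* drugs with fewer than
    ``feature_missing_max`` missing entries (their own gaps zero-filled).
    Each drug is modelled from the original matrix — freshly imputed columns
    are never chained as features. Drugs with no observed values or no
    eligible feature drugs fall back to zero-fill with a warning.

    Returns the completed matrix (rows of excluded cells unchanged) and a
    report dict with per-drug counts and the fallback list.
    """
    config = config or TMLConfig()
    unknown = config.excluded_cells - set(matrix.cell_ids)
    if unknown:
        raise KeyError(f"excluded cells not in matrix: {sorted(unknown)}")

    eligible = np.array(
        [c not in config.excluded_cells for c in matrix.cell_ids], dtype=bool
    )
    # Work only with eligible rows: excluded cell lines are never read.
    sub_values = matrix.values[eligible]
    sub_missing = matrix.missing_mask[eligible]
    missing_per_drug = sub_missing.sum(axis=0)

    features_filled = np.where(sub_missing, 0.0, sub_values)

    out_values = matrix.values.copy()
    out_missing = matrix.missing_mask.copy()
    imputed = np.zeros_like(matrix.missing_mask)
    eligible_rows = np.nonzero(eligible)[0]

    fallbacks: list[str] = []
    n_imputed = 0
    for j, drug in enumerate(matrix.drug_ids):
        gap_local = np.nonzero(sub_missing[:, j])[0]
        if gap_local.size == 0:
            continue
        obs_local = np.nonzero(~sub_missing[:, j])[0]
        feature_cols = np.array(
            [
                k
                for k in range(matrix.n_drugs)
                if k != j and missing_per_drug[k] < config.feature_missing_max
            ],
            dtype=int,
        )
        if obs_local.size == 0 or feature_cols.size == 0:
            logger.warning(
                "drug %r cannot be modelled (%d observed, %d feature drugs); "
                "falling back to zero-fill",
                drug,
                obs_local.size,
                feature_cols.size,
            )
            fallbacks.append(drug)
            predictions = np.zeros(gap_local.size)
        else:
            model = GradientBoostingRegressor(
                n_estimators=config.n_estimators,
                max_depth=config.max_depth,
                random_state=derive_seed(config.seed, drug),
            )
            model.fit(
                features_filled[np.ix_(obs_local, feature_cols)],
                sub_values[obs_local, j],
            )
            predictions = model.predict(
                features_filled[np.ix_(gap_local, feature_cols)]
            )
        rows = eligible_rows[gap_local]
        out_values[rows, j] = predictions
        out_missing[rows, j] = False
        imputed[rows, j] = True
        n_imputed += gap_local.size

    report = {
        "n_imputed": int(n_imputed),
        "n_fallback_drugs": len(fallbacks),
        "fallback_drugs": fallbacks,
        "n_excluded_cells": int((~eligible).sum()),
    }
    completed = ResponseMatrix(
        list(matrix.cell_ids),
        list(matrix.drug_ids),
        out_values,
        out_missing,
        matrix.scheme,
        imputed,
    )
    return completed, report


def impute(
    matrix: ResponseMatrix,
    method: str,
    excluded_cells: frozenset[str] | set[str] = frozenset(),
    seed: int = 0,
) -> ResponseMatrix:
    """Dispatch helper: ``method`` is ``zero`` or ``tml``."""
    if method == "zero":
        return zero_fill(matrix)
    if method == "tml":
        completed, _ = tml_impute(
            matrix, TMLConfig(excluded_cells=frozenset(excluded_cells), seed=seed)
        )
        return completed
    raise ValueError(f"unknown imputation method {method!r}")
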