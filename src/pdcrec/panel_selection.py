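"""Probing-panel and historical-cohort selection.

A probing panel is the small drug subset actually screened on a new
patient-derived culture; the historical cohort is the cell-line subset whose
response profiles become the model's features. Both can be chosen uniformly
at random or by a variance + median-correlation greedy diversity sweep that
removes redundant, highly inter-correlated entities:

1. drop the lowest-variance entities, keeping ``variance_keep_fraction``;
2. compute the Pearson correlation matrix over survivors
   (pairwise-complete observations);
3. rank survivors by their median correlation to the others, ascending;
4. take the lowest-ranked not-yet-excluded entity as a reference and
   exclude every remaining entity whose correlation with it reaches the
   threshold; repeat down the ranking until the list is exhausted.

The references visited in processing order form the selected panel; by
construction every selected pair correlates below the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import ResponseMatrix


@dataclass
class DiversityParams:
    """Knobs for the greedy diversity sweep.

    variance_keep_fraction
        Fraction of entities retained after the variance filter (0.5 drops
        the low-variance half).
    correlation_threshold
        In (0, 1]; entities correlating at or above this with a selected
        reference are excluded.
    axis
        ``drugs`` or ``cells`` — which axis is being panelled.
    target_size
        Optional; used by :func:`fit_panel_to_size` to bisect the threshold
        until the panel reaches this size.
    """

    variance_keep_fraction: float = 0.5
    correlation_threshold: float = 1.0
    axis: str = "drugs"
    target_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.variance_keep_fraction <= 1:
            raise ValueError("variance_keep_fraction must lie in (0, 1]")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must lie in (0, 1]")
        if self.axis not in ("cells", "drugs"):
            raise ValueError(f"unknown axis {self.axis!r}")


@dataclass
class PanelSelection:
    """A chosen probing drug panel plus historical cell-line cohort."""

    panel_drugs: list[str]
    historical_cells: list[str]
    method: str = "diversity"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.panel_drugs)) != len(self.panel_drugs):
            raise ValueError("duplicate drugs in panel")
        if len(set(self.historical_cells)) != len(self.historical_cells):
            raise ValueError("duplicate historical cells")


# -- internals ---------------------------------------------------------------

_MIN_COMMON_OBS = 3  # pairs with fewer common observations get r = 0


def _entity_rows(matrix: ResponseMatrix, axis: str) -> tuple[list[str], np.ndarray]:
    """Entities as rows (observations as columns) for the requested axis."""
    if axis == "cells":
        return list(matrix.cell_ids), matrix.values
    return list(matrix.drug_ids), matrix.values.T


def _variance_survivors(
    ids: list[str], data: np.ndarray, keep_fraction: float
) -> tuple[list[str], np.ndarray]:
    counts = np.sum(~np.isnan(data), axis=1)
    if np.any(counts < 2):
        bad = [i for i, c in zip(ids, counts) if c < 2]
        raise ValueError(
            f"entities with < 2 observations cannot be panelled: {bad[:5]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(data, axis=1)
    n_keep = max(1, math.ceil(keep_fraction * len(ids)))
    # ties in variance broken by lexicographic id for determinism
    order = sorted(range(len(ids)), key=lambda i: (-variances[i], ids[i]))
    keep = sorted(order[:n_keep], key=lambda i: ids[i])
    return [ids[i] for i in keep], data[keep]


def _pairwise_correlation(data: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows, pairwise-complete, undefined → 0."""
    if data.shape[0] == 1:
        return np.ones((1, 1))
    if not np.isnan(data).any():
        sd = data.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(data)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        corr[(sd == 0)[:, None] | (sd == 0)[None, :]] = 0.0
    else:
        frame = pd.DataFrame(data.T)
        corr = frame.corr(min_periods=_MIN_COMMON_OBS).to_numpy()
        corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _median_ranking(ids: list[str], corr: np.ndarray) -> list[int]:
    n = len(ids)
    if n == 1:
        return [0]
    medians = np.array(
        [np.median(np.delete(corr[i], i)) for i in range(n)]
    )
    return sorted(range(n), key=lambda i: (medians[i], ids[i]))


def _greedy_references(
    ids: list[str], corr: np.ndarray, ranking: list[int], threshold: float
) -> list[str]:
    excluded: set[int] = set()
    selected: list[str] = []
    for i in ranking:
        if i in excluded:
            continue
        selected.append(ids[i])
        for j in ranking:
            if j != i and j not in excluded and corr[i, j] >= threshold:
                excluded.add(j)
    return selected


def _diversity_state(
    matrix: ResponseMatrix, params: DiversityParams
) -> tuple[list[str], np.ndarray, list[int]]:
    ids, data = _entity_rows(matrix, params.axis)
    survivors, sub = _variance_survivors(ids, data, params.variance_keep_fraction)
    corr = _pairwise_correlation(sub)
    ranking = _median_ranking(survivors, corr)
    return survivors, corr, ranking


# -- public operations -------------------------------------------------------

def select_diverse(matrix: ResponseMatrix, params: DiversityParams) -> list[str]:
    """Greedy low-redundancy selection along one axis.

    Returns the selected entity ids in processing order (most "central"
    low-median-correlation references first). Warns when only a single
    entity survives.
    """
    survivors, corr, ranking = _diversity_state(matrix, params)
    selected = _greedy_references(
        survivors, corr, ranking, params.correlation_threshold
    )
    if len(selected) == 1 and len(survivors) > 1:
        warnings.warn(
            "correlation threshold left a single entity selected",
            stacklevel=2,
        )
    return selected


def select_random(
    matrix: ResponseMatrix, axis: str, n: int, seed: int
) -> list[str]:
    """Uniform sample of ``n`` entity ids without replacement."""
    ids, _ = _entity_rows(matrix, axis)
    if n > len(ids):
        raise ValueError(f"cannot sample {n} from {len(ids)} {axis}")
    rng = np.random.default_rng(seed)
    return [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]


def fit_panel_to_size(
    matrix: ResponseMatrix, params: DiversityParams
) -> list[str]:
    """Bisect the correlation threshold until the diversity sweep yields at
    least ``target_size`` entities, then truncate in processing order.

    If even a threshold of 1.0 cannot reach the target (duplicate entities
    force exclusions), the maximum achievable panel is returned with a
    warning.
    """
    if params.target_size is None:
        raise ValueError("target_size must be set")
    survivors, corr, ranking = _diversity_state(matrix, params)
    if params.target_size > len(survivors):
        raise ValueError(
            f"target_size {params.target_size} exceeds the "
            f"{len(survivors)} variance-surviving entities"
        )
    best = _greedy_references(survivors, corr, ranking, 1.0)
    if len(best) < params.target_size:
        warnings.warn(
            f"target size {params.target_size} unreachable; returning "
            f"{len(best)} entities",
            stacklevel=2,
        )
        return best
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        selected = _greedy_references(survivors, corr, ranking, mid)
        if len(selected) >= params.target_size:
            hi = mid
            best = selected
        else:
            lo = mid
    return best[: params.target_size]
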