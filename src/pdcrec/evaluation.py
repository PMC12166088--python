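"""Ranking and regression metrics for predicted vs measured drug responses.

All metrics operate on the *evaluable* drug set of a cell line: library
drugs outside the probing panel whose measured response is available.
Missing measurements enter no denominator. Rankings break activity ties by
drug id (see :func:`pdcrec.matrix_io.rank_drug_ids`), so every metric is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .matrix_io import ActivityScheme, rank_drug_ids


def topn_overlap(
    predicted_ranking: Sequence[str], actual_ranking: Sequence[str], n: int
) -> float:
    """Fraction of the predicted top-n found in the actual top-n.

    Set overlap, agnostic to positions within the top-n: 7 of the predicted
    top 10 appearing anywhere in the measured top 10 scores 0.7. Symmetric
    in its two arguments.
    """
    if set(predicted_ranking) != set(actual_ranking):
        raise ValueError("rankings must cover the same drug set")
    if n > len(predicted_ranking):
        raise ValueError(f"n={n} exceeds the {len(predicted_ranking)} evaluable drugs")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return len(set(predicted_ranking[:n]) & set(actual_ranking[:n])) / n


def hit_rate_topk(
    predicted_ranking: Sequence[str], hits: Iterable[str], k: int
) -> int:
    """Number of true hits among the k best-predicted drugs."""
    if k < 0:
        raise ValueError("k must be ≥ 0")
    return len(set(predicted_ranking[:k]) & set(hits))


def regression_metrics(
    predicted: np.ndarray, actual: np.ndarray
) -> tuple[float, float, float]:
    """(Pearson r, Spearman r, RMSE) over paired finite values.

    Requires ≥ 3 pairs. When either side has zero variance the correlations
    are undefined and reported as NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    ok = np.isfinite(predicted) & np.isfinite(actual)
    predicted, actual = predicted[ok], actual[ok]
    if predicted.size < 3:
        raise ValueError(f"need ≥ 3 paired values, got {predicted.size}")
    rmse = float(np.sqrt(np.mean((predicted - actual) ** 2)))
    if np.ptp(predicted) == 0 or np.ptp(actual) == 0:
        return float("nan"), float("nan"), rmse
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_p = float(stats.pearsonr(predicted, actual).statistic)
        r_s = float(stats.spearmanr(predicted, actual).statistic)
    return r_p, r_s, rmse


@dataclass
class CellLineEvaluation:
    """Metric battery for one cell line (one subset of its library).

    ``hit_rate_topk`` maps k → count of true hits among the top-k
    predictions; ``max_possible_hit_rate`` maps k → min(k, hits available),
    the theoretical ceiling. A cell line with no hits available is
    non-evaluable for hit analysis (``hit_evaluable`` False).
    """

    cell_id: str | None
    subset: str
    n_evaluable: int
    r_pearson: float
    r_spearman: float
    rmse: float
    topn_overlap: dict[int, float]
    hit_rate_topk: dict[int, int]
    n_hits_available: int
    max_possible_hit_rate: dict[int, int]
    baseline_hit_prevalence: float
    hit_evaluable: bool


def evaluate_cell(
    predicted: Mapping[str, float],
    actual: Mapping[str, float],
    scheme: ActivityScheme,
    top_ns: Sequence[int] = (10, 20, 30),
    hit_ks: Sequence[int] = (10,),
    cell_id: str | None = None,
    subset: str = "all_drugs",
) -> CellLineEvaluation:
    """Score one cell line's predictions against its measurements.

    The evaluable set is the intersection of predicted drugs and finite
    measured drugs. Top-n overlaps are computed only for n within the
    evaluable set size.
    """
    drugs = sorted(
        d
        for d in predicted
        if d in actual and np.isfinite(actual[d]) and np.isfinite(predicted[d])
    )
    if not drugs:
        raise ValueError("no evaluable drugs")
    pred_vec = np.array([predicted[d] for d in drugs])
    act_vec = np.array([actual[d] for d in drugs])
    if len(drugs) >= 3:
        r_p, r_s, rmse = regression_metrics(pred_vec, act_vec)
    else:
        r_p = r_s = rmse = float("nan")

    pred_rank = rank_drug_ids({d: predicted[d] for d in drugs}, scheme)
    act_rank = rank_drug_ids({d: actual[d] for d in drugs}, scheme)
    overlaps = {
        n: topn_overlap(pred_rank, act_rank, n) for n in top_ns if n <= len(drugs)
    }

    hit_flags = scheme.is_hit(act_vec)
    hit_set = {d for d, h in zip(drugs, hit_flags) if h}
    hit_counts = {k: hit_rate_topk(pred_rank, hit_set, k) for k in hit_ks}
    return CellLineEvaluation(
        cell_id=cell_id,
        subset=subset,
        n_evaluable=len(drugs),
        r_pearson=r_p,
        r_spearman=r_s,
        rmse=rmse,
        topn_overlap=overlaps,
        hit_rate_topk=hit_counts,
        n_hits_available=len(hit_set),
        max_possible_hit_rate={k: min(k, len(hit_set)) for k in hit_ks},
        baseline_hit_prevalence=len(hit_set) / len(drugs),
        hit_evaluable=len(hit_set) > 0,
    )


def evaluate_subsets(
    predicted: Mapping[str, float],
    actual: Mapping[str, float],
    scheme: ActivityScheme,
    selective_drugs: Iterable[str],
    top_ns: Sequence[int] = (10, 20, 30),
    hit_ks: Sequence[int] = (10,),
    cell_id: str | None = None,
) -> dict[str, CellLineEvaluation | None]:
    """Evaluate on the full evaluable library and again restricted to the
    selective drugs (those rarely active across the reference cohort). An
    empty selective subset is reported as None."""
    out: dict[str, CellLineEvaluation | None] = {
        "all_drugs": evaluate_cell(
            predicted, actual, scheme, top_ns, hit_ks, cell_id, "all_drugs"
        )
    }
    sel = set(selective_drugs)
    sel_pred = {d: v for d, v in predicted.items() if d in sel}
    sel_act = {d: v for d, v in actual.items() if d in sel}
    evaluable = [
        d
        for d in sel_pred
        if d in sel_act and np.isfinite(sel_act[d]) and np.isfinite(sel_pred[d])
    ]
    if evaluable:
        out["selective_drugs"] = evaluate_cell(
            sel_pred, sel_act, scheme, top_ns, hit_ks, cell_id, "selective_drugs"
        )
    else:
        out["selective_drugs"] = None
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _metric_rows(evaluation: CellLineEvaluation) -> dict[str, float]:
    row = {
        "r_pearson": evaluation.r_pearson,
        "r_spearman": evaluation.r_spearman,
        "rmse": evaluation.rmse,
        "baseline_hit_prevalence": evaluation.baseline_hit_prevalence,
        "n_hits_available": float(evaluation.n_hits_available),
    }
    for n, v in evaluation.topn_overlap.items():
        row[f"top{n}_overlap"] = v
    for k, c in evaluation.hit_rate_topk.items():
        row[f"hit_rate_top{k}"] = float(c)
    return row


def summarise_cells(
    evaluations: Sequence[CellLineEvaluation],
) -> dict[str, float]:
    """Mean of each metric over cell lines (NaN-ignoring).

    Hit-rate counts are additionally averaged over the hit-evaluable cells
    only (suffix ``_evaluable``), mirroring the practice of excluding cell
    lines with no hits available from hit analyses.
    """
    if not evaluations:
        return {}
    keys: list[str] = []
    for e in evaluations:
        for k in _metric_rows(e):
            if k not in keys:
                keys.append(k)
    out: dict[str, float] = {"n_cells": float(len(evaluations))}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in keys:
            vals = [_metric_rows(e).get(k, np.nan) for e in evaluations]
            out[k] = float(np.nanmean(vals))
        hit_keys = [k for k in keys if k.startswith("hit_rate_top")]
        evaluable = [e for e in evaluations if e.hit_evaluable]
        out["n_hit_evaluable_cells"] = float(len(evaluable))
        for k in hit_keys:
            vals = [_metric_rows(e).get(k, np.nan) for e in evaluable]
            out[f"{k}_evaluable"] = float(np.nanmean(vals)) if vals else float("nan")
    return out


def aggregate_repeats(
    repeat_summaries: Sequence[Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Mean/std of each summary metric across repeated experiments.

    Population std (ddof=0), so a single repeat reports std 0.
    """
    keys: list[str] = []
    for summary in repeat_summaries:
        for k in summary:
            if k not in keys:
                keys.append(k)
    out: dict[str, dict[str, float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in keys:
            vals = np.array(
                [s.get(k, np.nan) for s in repeat_summaries], dtype=float
            )
            out[k] = {
                "mean": float(np.nanmean(vals)),
                "std": float(np.nanstd(vals)),
            }
    return out
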