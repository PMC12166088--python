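"""Drug-response matrices: container, I/O, pruning, target transforms and hit calls.

The central object is :class:`ResponseMatrix`, a cell-line × drug numeric
matrix with an explicit missing mask and an :class:`ActivityScheme` tag that
says how raw assay values map to an activity scale, what counts as a hit,
and which direction of the scale is "better".

Three scheme families are supported:

``gdsc_pIC50``
    Raw IC50 values in molar units; transformed to pIC50 = log10(1/IC50).
    A drug is active on a cell line when pIC50 > 6 (i.e. IC50 ≤ 1 µM).
``prism_neglog2fc``
    Raw post/pre treatment fold-changes; transformed to −log2(fold-change).
    Active when the transformed value exceeds 1.7.
``viability_percent``
    Percent viability relative to DMSO control (identity transform).
    Active when viability drops to ≤ 30%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Strings (case-insensitive, after stripping) that mark a missing entry.
MISSING_SENTINELS = frozenset({"", "na", "nan", "null"})


class MatrixFormatError(ValueError):
    """A delimited-text matrix violates the expected format."""


class EmptyMatrixError(ValueError):
    """An operation removed every row or every column of a matrix."""


# ---------------------------------------------------------------------------
# Activity schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityScheme:
    """How a dataset family measures activity, calls hits and ranks drugs.

    Parameters
    ----------
    name : str
        Scheme identifier (``gdsc_pIC50``, ``prism_neglog2fc``,
        ``viability_percent``).
    transform : str
        Transform applied to raw values: ``neg_log10``, ``neg_log2`` or
        ``identity``.
    hit_threshold : float
        Threshold on the transformed activity scale.
    hit_direction : str
        ``greater`` (hit iff value > threshold) or ``less_equal``
        (hit iff value ≤ threshold).
    rank_direction : str
        ``descending_better`` (larger activity is better) or
        ``ascending_better`` (smaller value, e.g. viability, is better).
    """

    name: str
    transform: str
    hit_threshold: float
    hit_direction: str
    rank_direction: str

    def __post_init__(self) -> None:
        if self.transform not in ("neg_log10", "neg_log2", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.hit_direction not in ("greater", "less_equal"):
            raise ValueError(f"unknown hit_direction {self.hit_direction!r}")
        if self.rank_direction not in ("descending_better", "ascending_better"):
            raise ValueError(f"unknown rank_direction {self.rank_direction!r}")

    @property
    def better_is_higher(self) -> bool:
        return self.rank_direction == "descending_better"

    def is_hit(self, values: np.ndarray) -> np.ndarray:
        """Boolean hit calls for an array of transformed activities.

        NaN entries are never hits; use the missing mask to tell "non-hit"
        from "not measured".
        """
        values = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            if self.hit_direction == "greater":
                return values > self.hit_threshold
            return values <= self.hit_threshold


SCHEMES: dict[str, ActivityScheme] = {
    "gdsc_pIC50": ActivityScheme(
        "gdsc_pIC50", "neg_log10", 6.0, "greater", "descending_better"
    ),
    "prism_neglog2fc": ActivityScheme(
        "prism_neglog2fc", "neg_log2", 1.7, "greater", "descending_better"
    ),
    "viability_percent": ActivityScheme(
        "viability_percent", "identity", 30.0, "less_equal", "ascending_better"
    ),
}


def get_scheme(name: str) -> ActivityScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}"
        ) from None


def rank_drug_ids(values: Mapping[str, float], scheme: ActivityScheme) -> list[str]:
    """Sort drug ids best-first under the scheme's rank direction.

    Ties on the activity value are broken by lexicographic drug id so that
    rankings (and every metric derived from them) are deterministic.
    """
    sign = -1.0 if scheme.better_is_higher else 1.0
    return sorted(values, key=lambda d: (sign * values[d], d))


# ---------------------------------------------------------------------------
# ResponseMatrix
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Cell-line × drug response matrix with an explicit missing mask.

    ``values`` holds floats with rows = cell lines and columns = drugs;
    entries flagged in ``missing_mask`` are stored as NaN. ``imputed_mask``
    (optional) records which entries were filled in by an imputation step.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    scheme: ActivityScheme
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.values = np.asarray(self.values, dtype=float).copy()
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).copy()
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixFormatError("duplicate cell identifiers")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise MatrixFormatError("duplicate drug identifiers")
        if self.values.shape != (len(self.cell_ids), len(self.drug_ids)):
            raise MatrixFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.drug_ids)} drugs"
            )
        if self.missing_mask.shape != self.values.shape:
            raise MatrixFormatError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise MatrixFormatError("non-finite value in a non-missing entry")
        self.values[self.missing_mask] = np.nan
        if self.imputed_mask is not None:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool).copy()
            if self.imputed_mask.shape != self.values.shape:
                raise MatrixFormatError("imputed_mask shape mismatch")

    # -- basic accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if self.missing_mask.size else 0.0

    def cell_index(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            list(self.cell_ids),
            list(self.drug_ids),
            self.values,
            self.missing_mask,
            self.scheme,
            None if self.imputed_mask is None else self.imputed_mask,
        )

    def subset(
        self,
        cells: Sequence[str] | None = None,
        drugs: Sequence[str] | None = None,
    ) -> "ResponseMatrix":
        """Return a new matrix restricted to the given cells/drugs, in the
        given order. Unknown identifiers raise ``KeyError``."""
        cells = list(self.cell_ids) if cells is None else list(cells)
        drugs = list(self.drug_ids) if drugs is None else list(drugs)
        cpos = {c: i for i, c in enumerate(self.cell_ids)}
        dpos = {d: j for j, d in enumerate(self.drug_ids)}
        try:
            ri = np.array([cpos[c] for c in cells], dtype=int)
            cj = np.array([dpos[d] for d in drugs], dtype=int)
        except KeyError as exc:
            raise KeyError(f"identifier not in matrix: {exc.args[0]!r}") from None
        imputed = None
        if self.imputed_mask is not None:
            imputed = self.imputed_mask[np.ix_(ri, cj)]
        return ResponseMatrix(
            cells,
            drugs,
            self.values[np.ix_(ri, cj)],
            self.missing_mask[np.ix_(ri, cj)],
            self.scheme,
            imputed,
        )

    def cell_profile(self, cell_id: str, observed_only: bool = True) -> dict[str, float]:
        """Mapping drug id → value for one cell line."""
        i = self.cell_index(cell_id)
        out: dict[str, float] = {}
        for j, d in enumerate(self.drug_ids):
            if self.missing_mask[i, j]:
                if not observed_only:
                    out[d] = float("nan")
                continue
            out[d] = float(self.values[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.drug_ids
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, scheme: ActivityScheme
    ) -> "ResponseMatrix":
        values = frame.to_numpy(dtype=float)
        return cls(
            [str(c) for c in frame.index],
            [str(d) for d in frame.columns],
            values,
            np.isnan(values),
            scheme,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_response_matrix(
    path: str | Path,
    scheme: ActivityScheme | str | None = None,
    orientation: str = "cells_by_rows",
) -> ResponseMatrix:
    """Load a delimited-text response matrix.

    The file must be a rectangular table with one header row and one leading
    identifier column. Empty cells and the sentinels "NA"/"NaN"/"null"
    (case-insensitive) mark missing entries. Values are stored untransformed;
    apply :func:`transform_targets` to put them on the activity scale.

    Parameters
    ----------
    scheme : ActivityScheme, str or None
        The dataset's activity scheme. If None, a JSON sidecar written by
        :func:`save_response_matrix` (same stem, ``.json``) must name it.
    orientation : str
        ``cells_by_rows`` (default) or ``drugs_by_rows``; the matrix is
        always stored internally as cells × drugs.
    """
    path = Path(path)
    if scheme is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise MatrixFormatError(
                f"no scheme given and no sidecar found at {sidecar}"
            )
        scheme = json.loads(sidecar.read_text())["scheme"]
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if orientation not in ("cells_by_rows", "drugs_by_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    frame = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    row_ids = [str(r) for r in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if len(set(row_ids)) != len(row_ids):
        raise MatrixFormatError(f"duplicate row identifiers in {path}")
    if len(set(col_ids)) != len(col_ids):
        raise MatrixFormatError(f"duplicate column identifiers in {path}")

    values = np.empty(frame.shape, dtype=float)
    missing = np.zeros(frame.shape, dtype=bool)
    raw = frame.to_numpy(dtype=object)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in MISSING_SENTINELS:
                values[i, j] = np.nan
                missing[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric value {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                ) from None

    if orientation == "drugs_by_rows":
        values, missing = values.T, missing.T
        row_ids, col_ids = col_ids, row_ids
    matrix = ResponseMatrix(row_ids, col_ids, values, missing, scheme)
    logger.info(
        "loaded %s: %d cells × %d drugs, %.1f%% missing",
        path,
        matrix.n_cells,
        matrix.n_drugs,
        100 * matrix.missing_fraction(),
    )
    return matrix


def save_response_matrix(
    matrix: ResponseMatrix, path: str | Path, sidecar: bool = True
) -> None:
    """Write a matrix as delimited text (missing entries left empty), with an
    optional JSON sidecar recording the scheme and dimensions."""
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_delimiter_for(path), na_rep="")
    if sidecar:
        meta = {
            "scheme": matrix.scheme.name,
            "n_cells": matrix.n_cells,
            "n_drugs": matrix.n_drugs,
            "missing_fraction": matrix.missing_fraction(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_annotations(path: str | Path) -> dict[str, str]:
    """Read a (cell_id, tissue) CSV into a mapping."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise MatrixFormatError("annotation table needs ≥ 2 columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def save_annotations(annotations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(annotations), "tissue": list(annotations.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PruneParams:
    """Missingness limits for excluding cell lines and drugs.

    ``mode='fractional'`` interprets the limits as fractions of the relevant
    axis (a cell line is dropped when it is missing MORE THAN
    ``cell_missing_limit`` of the drugs); ``mode='absolute'`` interprets them
    as absolute counts (dropped when missing more than N entries).
    """

    cell_missing_limit: float
    drug_missing_limit: float
    mode: str = "fractional"

    def __post_init__(self) -> None:
        if self.mode not in ("fractional", "absolute"):
            raise ValueError(f"unknown prune mode {self.mode!r}")
        if self.mode == "fractional":
            for lim in (self.cell_missing_limit, self.drug_missing_limit):
                if not 0 <= lim <= 1:
                    raise ValueError("fractional limits must lie in [0, 1]")
        else:
            for lim in (self.cell_missing_limit, self.drug_missing_limit):
                if lim < 0 or lim != int(lim):
                    raise ValueError("absolute limits must be non-negative integers")


#: Conventional pruning presets: dense IC50 panels use 20%/20% fractional
#: limits, the sparser repurposing screen 10%/20%, and the small ex vivo
#: viability screen absolute limits of 5 missing entries per cell and drug.
PRUNE_PRESETS: dict[str, PruneParams] = {
    "gdsc": PruneParams(0.2, 0.2, "fractional"),
    "prism": PruneParams(0.1, 0.2, "fractional"),
    "rx": PruneParams(5, 5, "absolute"),
}


def prune_matrix(matrix: ResponseMatrix, params: PruneParams) -> ResponseMatrix:
    """Drop overly missing cell lines, then overly missing drugs.

    Cell lines are filtered first, against the full drug set; drugs are then
    filtered against the *remaining* cell lines. Returns a new matrix; the
    input is unchanged. Raises :class:`EmptyMatrixError` if either axis would
    be emptied.
    """
    if matrix.n_cells == 0 or matrix.n_drugs == 0:
        raise EmptyMatrixError("cannot prune an empty matrix")
    cell_missing = matrix.missing_mask.sum(axis=1)
    if params.mode == "fractional":
        keep_cells = cell_missing / matrix.n_drugs <= params.cell_missing_limit
    else:
        keep_cells = cell_missing <= params.cell_missing_limit
    if not keep_cells.any():
        raise EmptyMatrixError("cell pruning removed every cell line")

    remaining = matrix.missing_mask[keep_cells]
    drug_missing = remaining.sum(axis=0)
    n_remaining = int(keep_cells.sum())
    if params.mode == "fractional":
        keep_drugs = drug_missing / n_remaining <= params.drug_missing_limit
    else:
        keep_drugs = drug_missing <= params.drug_missing_limit
    if not keep_drugs.any():
        raise EmptyMatrixError("drug pruning removed every drug")

    cells = [c for c, k in zip(matrix.cell_ids, keep_cells) if k]
    drugs = [d for d, k in zip(matrix.drug_ids, keep_drugs) if k]
    return matrix.subset(cells=cells, drugs=drugs)


# ---------------------------------------------------------------------------
# Target transforms and hit calls
# ---------------------------------------------------------------------------

def transform_targets(matrix: ResponseMatrix) -> ResponseMatrix:
    """Map raw assay values onto the scheme's activity scale.

    gdsc_pIC50: pIC50 = log10(1 / IC50_molar); prism_neglog2fc:
    −log2(fold-change); viability_percent: identity. Non-positive values
    under a log transform are rejected with their locations; negative
    viabilities are likewise rejected.
    """
    values = matrix.values.copy()
    observed = ~matrix.missing_mask
    transform = matrix.scheme.transform
    if transform == "identity":
        bad = observed & (values < 0)
        if bad.any():
            raise MatrixFormatError(
                "negative viability at " + _describe_locations(matrix, bad)
            )
        out = values
    else:
        bad = observed & ~(values > 0)
        if bad.any():
            raise MatrixFormatError(
                "non-positive value under log transform at "
                + _describe_locations(matrix, bad)
            )
        with np.errstate(invalid="ignore"):
            out = -np.log10(values) if transform == "neg_log10" else -np.log2(values)
    return ResponseMatrix(
        list(matrix.cell_ids),
        list(matrix.drug_ids),
        out,
        matrix.missing_mask,
        matrix.scheme,
        matrix.imputed_mask,
    )


def inverse_transform_targets(matrix: ResponseMatrix) -> ResponseMatrix:
    """Undo :func:`transform_targets`, recovering raw-scale values."""
    transform = matrix.scheme.transform
    if transform == "identity":
        out = matrix.values.copy()
    elif transform == "neg_log10":
        out = np.power(10.0, -matrix.values)
    else:
        out = np.power(2.0, -matrix.values)
    return ResponseMatrix(
        list(matrix.cell_ids),
        list(matrix.drug_ids),
        out,
        matrix.missing_mask,
        matrix.scheme,
        matrix.imputed_mask,
    )


def _describe_locations(
    matrix: ResponseMatrix, bad: np.ndarray, limit: int = 5
) -> str:
    rows, cols = np.nonzero(bad)
    locs = [
        f"(cell {matrix.cell_ids[i]!r}, drug {matrix.drug_ids[j]!r})"
        for i, j in zip(rows[:limit], cols[:limit])
    ]
    extra = "" if len(rows) <= limit else f" and {len(rows) - limit} more"
    return ", ".join(locs) + extra


def call_hits(matrix: ResponseMatrix) -> np.ndarray:
    """Hit calls aligned with the matrix: 1.0 hit, 0.0 non-hit, NaN missing.

    Values must already be on the activity scale (:func:`transform_targets`).
    Missing entries are neither hits nor non-hits and must be excluded from
    every denominator; NaN encodes that directly.
    """
    hits = matrix.scheme.is_hit(matrix.values).astype(float)
    hits[matrix.missing_mask] = np.nan
    return hits


def drug_hit_prevalence(hits: np.ndarray) -> np.ndarray:
    """Per-drug hit fraction over non-missing measurements.

    Columns with no measurements at all are non-evaluable and come back NaN.
    """
    hits = np.asarray(hits, dtype=float)
    counts = np.sum(~np.isnan(hits), axis=0)
    prevalence = np.full(hits.shape[1], np.nan)
    ok = counts > 0
    if ok.any():
        prevalence[ok] = np.nansum(hits[:, ok], axis=0) / counts[ok]
    return prevalence


def selective_drug_mask(hits: np.ndarray, prevalence_limit: float = 0.2) -> np.ndarray:
    """Drugs active in strictly fewer than ``prevalence_limit`` of the
    measured cell lines. Non-evaluable drugs (no measurements) are excluded
    from the mask since their prevalence cannot be assessed."""
    prevalence = drug_hit_prevalence(hits)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(prevalence), False, prevalence < prevalence_limit)
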