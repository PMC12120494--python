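"""NODF and WNODF — nestedness metrics based on overlap and decreasing fill.

Both metrics score every ordered pair of rows and every ordered pair of
columns of a maximally packed matrix and average the paired terms on a 0–100
scale. A pair only contributes when its marginal totals *strictly* decrease:
under equal totals no nested subset relation can exist, so such pairs score 0.

* NODF (binary): for rows i (above) and j (below) with presence counts
  ``MT_i > MT_j > 0``, the paired term is ``100 * |overlap| / MT_j`` — the
  percentage of the poorer row's species that reoccur in the richer row.
  Columns are treated symmetrically.
* WNODF (quantitative): the paired term counts cells of the poorer
  row/column that are non-zero *and strictly smaller* than the matching cell
  of the richer one, divided by the poorer one's fill. On a strictly binary
  matrix no cell can be strictly smaller than a non-zero matching cell, so
  WNODF degenerates to 0.

Row terms average to the species-incidence component (NODFr/WNODFr), column
terms to the site-composition component (NODFc/WNODFc), and the overall value
is the mean over the union of both pair sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import CommunityMatrix, MatrixError, _desc_order

logger = logging.getLogger("parknest")


@dataclass(frozen=True)
class NestednessResult:
    metric: str  # "NODF" | "WNODF"
    overall: float
    row_component: float  # NODFr / WNODFr (species in rows)
    col_component: float  # NODFc / WNODFc (sites in columns)
    n_row_pairs: int
    n_col_pairs: int
    ordering_used: str

    def component(self, which: str) -> float:
        return {"overall": self.overall, "row": self.row_component, "col": self.col_component}[
            which
        ]


def _check_size(m: CommunityMatrix) -> None:
    if m.n_species < 2 or m.n_sites < 2:
        raise MatrixError(
            f"nestedness needs at least 2 species and 2 sites, got {m.n_species}x{m.n_sites}"
        )


def _pack(values: np.ndarray, ordering: str, metric: str) -> np.ndarray:
    """Sort rows and columns by decreasing marginal totals (stable)."""
    if ordering == "given":
        return values
    if ordering != "marginal_totals_desc":
        raise ValueError(
            f"{metric} ordering must be 'marginal_totals_desc' or 'given', got {ordering!r}"
        )
    values = values[_desc_order(values.sum(axis=1)), :]
    return values[:, _desc_order(values.sum(axis=0))]


def _nodf_axis_terms(B: np.ndarray) -> tuple[float, int]:
    """Sum of row-pair NODF terms of a binary matrix packed along axis 0."""
    totals = B.sum(axis=1)
    overlap = B @ B.T
    iu, il = np.triu_indices(B.shape[0], k=1)  # iu above il
    valid = (totals[iu] > totals[il]) & (totals[il] > 0)
    denom = np.where(totals[il] > 0, totals[il], 1)
    terms = np.where(valid, 100.0 * overlap[iu, il] / denom, 0.0)
    return float(terms.sum()), len(iu)


def _wnodf_axis_terms(X: np.ndarray) -> tuple[float, int]:
    """Sum of row-pair WNODF terms of a quantitative matrix packed along axis 0."""
    totals = X.sum(axis=1)
    fills = (X > 0).sum(axis=1)
    # counts[i, j] = #{cells c : X[j, c] > 0 and X[i, c] > X[j, c]}
    counts = ((X[:, None, :] > X[None, :, :]) & (X[None, :, :] > 0)).sum(axis=2)
    iu, il = np.triu_indices(X.shape[0], k=1)
    valid = (totals[iu] > totals[il]) & (fills[il] > 0)
    denom = np.where(fills[il] > 0, fills[il], 1)
    terms = np.where(valid, 100.0 * counts[iu, il] / denom, 0.0)
    return float(terms.sum()), len(iu)


def nodf(m: CommunityMatrix, ordering: str = "marginal_totals_desc") -> NestednessResult:
    """Binary NODF of a community matrix.

    The matrix is binarized (presence = abundance > 0), all-zero species rows
    dropped, then rows and columns are packed by decreasing presence totals
    (unless ``ordering="given"``).
    """
    _check_size(m)
    m = m.drop_empty_species()
    _check_size(m)
    B = _pack(m.binary(), ordering, "NODF")
    row_sum, n_row = _nodf_axis_terms(B)
    col_sum, n_col = _nodf_axis_terms(B.T)
    return NestednessResult(
        metric="NODF",
        overall=(row_sum + col_sum) / (n_row + n_col),
        row_component=row_sum / n_row,
        col_component=col_sum / n_col,
        n_row_pairs=n_row,
        n_col_pairs=n_col,
        ordering_used=ordering,
    )


def wnodf(m: CommunityMatrix, ordering: str = "marginal_totals_desc") -> NestednessResult:
    """Weighted NODF of a quantitative community matrix.

    Rows/columns are packed by decreasing *abundance* totals; fills enter only
    as paired-term denominators. Emits a warning on strictly binary input,
    where the metric is 0 by construction.
    """
    _check_size(m)
    m = m.drop_empty_species()
    _check_size(m)
    X = m.values
    if X.max(initial=0) <= 1:
        logger.warning("WNODF on a binary matrix degenerates to 0; use NODF instead")
    X = _pack(X, ordering, "WNODF")
    row_sum, n_row = _wnodf_axis_terms(X)
    col_sum, n_col = _wnodf_axis_terms(X.T)
    return NestednessResult(
        metric="WNODF",
        overall=(row_sum + col_sum) / (n_row + n_col),
        row_component=row_sum / n_row,
        col_component=col_sum / n_col,
        n_row_pairs=n_row,
        n_col_pairs=n_col,
        ordering_used=ordering,
    )


def compute_metric(m: CommunityMatrix, metric: str, ordering: str = "marginal_totals_desc"):
    """Dispatch by metric name ("NODF" or "WNODF")."""
    metric = metric.upper()
    if metric == "NODF":
        return nodf(m, ordering)
    if metric == "WNODF":
        return wnodf(m, ordering)
    raise ValueError(f"unknown metric {metric!r}")
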