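"""Thematic accuracy assessment of a classification against reference data.

Two class rasters (semi-automated prediction and manual reference) are
sampled on a regular point grid; each point contributes one count to a
square error matrix whose rows are the predicted class and whose columns
are the reference class. From the joint-proportion matrix p derive:

* overall accuracy      = 100 * trace(p)
* Cohen's kappa         = (p_o - p_e) / (1 - p_e),  p_e = sum_i p_i+ * p_+i
* conditional kappa_i   = (p_ii / p_i+ - p_+i) / (1 - p_+i)
  (the row-conditional, "user's" form, stated against the rows=predicted
  orientation; the column-conditional form is also exposed)
* omission error_i      = 100 * (1 - p_ii / p_+i)   (missed from class i)
* commission error_i    = 100 * (1 - p_ii / p_i+)   (wrongly put in class i)

Matrices may be entered in percent or proportion form; they are
normalized to proportions internally, so a printed percent matrix whose
cells are rounded to 2 dp is consumed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import PointGrid, sample_raster_at_points


class MatrixError(ValueError):
    """Error-matrix precondition failed (shape, schema, or mass)."""


@dataclass
class ErrorMatrix:
    """Square joint-proportion matrix: rows = predicted, columns = reference."""

    classes: list[str]
    p: np.ndarray          # proportions, sums to 1
    n_points: int = 0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        k = len(self.classes)
        if self.p.shape != (k, k):
            raise MatrixError(f"matrix shape {self.p.shape} does not match {k} classes")
        if np.any(self.p < 0):
            raise MatrixError("matrix entries must be non-negative")
        total = self.p.sum()
        if total <= 0:
            raise MatrixError("matrix has no mass")
        # accept percent-mode input; normalize to proportions
        self.p = self.p / total

    @property
    def row_totals(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.p.sum(axis=0)

    def index_of(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise MatrixError(f"class {cls!r} not in matrix classes {self.classes}") from None


def build_error_matrix(
    reference_map: np.ndarray,
    predicted_map: np.ndarray,
    grid: PointGrid | None = None,
    pixel_size: float = 1.0,
    classes: list | None = None,
) -> ErrorMatrix:
    """Cross-tabulate predicted vs reference class at grid points.

    Both rasters must share extent (shape) and class schema. Without a
    grid, every pixel contributes one point (spacing = pixel size). Class
    labels may be any integers; ``classes`` fixes the matrix ordering
    (defaults to the sorted union of labels seen at the sample points).
    """
    reference_map = np.asarray(reference_map)
    predicted_map = np.asarray(predicted_map)
    if reference_map.shape != predicted_map.shape:
        raise MatrixError(
            f"extent mismatch: reference {reference_map.shape} vs predicted {predicted_map.shape}"
        )
    if grid is None:
        ref = reference_map.ravel()
        pred = predicted_map.ravel()
    else:
        ref = sample_raster_at_points(reference_map, pixel_size, grid)
        pred = sample_raster_at_points(predicted_map, pixel_size, grid)
    if classes is None:
        classes = sorted(set(np.unique(ref)) | set(np.unique(pred)))
    lut = {c: i for i, c in enumerate(classes)}
    missing = (set(np.unique(ref)) | set(np.unique(pred))) - set(classes)
    if missing:
        raise MatrixError(f"labels {sorted(missing)} absent from the class list {classes}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    pi = np.vectorize(lut.get)(pred)
    ri = np.vectorize(lut.get)(ref)
    np.add.at(counts, (pi, ri), 1)
    n = int(counts.sum())
    return ErrorMatrix(classes=list(classes), p=counts / n, n_points=n)


def overall_accuracy(matrix: ErrorMatrix) -> float:
    """Percent of sample points on the matrix diagonal."""
    return 100.0 * float(np.trace(matrix.p))


def cohens_kappa(matrix: ErrorMatrix) -> float:
    """Chance-corrected overall agreement; NaN when expected agreement is 1."""
    p_o = float(np.trace(matrix.p))
    p_e = float(matrix.row_totals @ matrix.col_totals)
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def conditional_kappa(matrix: ErrorMatrix, cls: str, by: str = "row") -> float:
    """Per-class chance-corrected agreement.

    ``by="row"`` (default) conditions on the predicted row:
    (p_ii/p_i+ - p_+i) / (1 - p_+i); ``by="col"`` conditions on the
    reference column. NaN when the conditioning marginal is zero.
    """
    i = matrix.index_of(cls)
    p_ii = matrix.p[i, i]
    p_row = matrix.row_totals[i]
    p_col = matrix.col_totals[i]
    if by == "row":
        if p_row == 0 or p_col >= 1.0:
            return float("nan")
        return (p_ii / p_row - p_col) / (1.0 - p_col)
    if by == "col":
        if p_col == 0 or p_row >= 1.0:
            return float("nan")
        return (p_ii / p_col - p_row) / (1.0 - p_row)
    raise ValueError("by must be 'row' or 'col'")


def omission_commission(matrix: ErrorMatrix) -> pd.DataFrame:
    """Per-class omission and commission error percentages.

    Omission: share of the reference class missed by the prediction.
    Commission: share of the predicted class that is wrong. NaN where the
    corresponding marginal is zero.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        diag = np.diag(matrix.p)
        om = 100.0 * (1.0 - np.where(matrix.col_totals > 0, diag / matrix.col_totals, np.nan))
        co = 100.0 * (1.0 - np.where(matrix.row_totals > 0, diag / matrix.row_totals, np.nan))
    return pd.DataFrame(
        {"class": matrix.classes, "omission_pct": om, "commission_pct": co}
    ).set_index("class")


def accuracy_report(matrix: ErrorMatrix) -> pd.DataFrame:
    """Summary table: per-class omission, commission and conditional kappa."""
    oc = omission_commission(matrix)
    oc["conditional_kappa"] = [conditional_kappa(matrix, c) for c in matrix.classes]
    return oc


def accuracy_summary_text(matrix: ErrorMatrix) -> str:
    """Plain-text block with per-class errors and the overall statistics."""
    rep = accuracy_report(matrix)
    lines = [f"{'class':<16}{'omission':>10}{'commission':>12}{'cond. kappa':>13}"]
    for cls, row in rep.iterrows():
        om = "-" if np.isnan(row.omission_pct) else f"{row.omission_pct:.0f}%"
        co = "-" if np.isnan(row.commission_pct) else f"{row.commission_pct:.0f}%"
        ck = "-" if np.isnan(row.conditional_kappa) else f"{row.conditional_kappa:.2f}"
        lines.append(f"{cls:<16}{om:>10}{co:>12}{ck:>13}")
    lines.append(f"{'total accuracy':<16}{overall_accuracy(matrix):>9.0f}%")
    lines.append(f"{'total kappa':<16}{cohens_kappa(matrix):>10.2f}")
    return "\n".join(lines)


def save_matrix_csv(matrix: ErrorMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.p, index=matrix.classes, columns=matrix.classes)
    df.index.name = "predicted\\reference"
    df.to_csv(Path(path))


def load_matrix_csv(path: str | Path) -> ErrorMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise MatrixError("row and column class orders differ")
    return ErrorMatrix(classes=list(df.columns), p=df.to_numpy())
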