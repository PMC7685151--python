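"""SVD mode extraction from month-by-year anomaly matrices.

A regional monthly anomaly series is arranged into a 12 x n_years matrix
(rows Jan..Dec, columns years ascending) and decomposed with a thin SVD.
The left singular vectors are monthly patterns of interannual variability;
the fraction of overall variance explained by mode i is s_i^2 / sum_j s_j^2.
Modes are classified by the signs of their spring (Apr-Jun) and summer
(Jul-Sep) means: same sign = amplification-like, opposite = compensation-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridContractError, RegionSeries

__all__ = [
    "ModeDecomposition",
    "build_month_year_matrix",
    "svd_modes",
    "classify_mode",
]

_SPRING = slice(3, 6)  # Apr-Jun (0-based month rows)
_SUMMER = slice(6, 9)  # Jul-Sep


@dataclass
class ModeDecomposition:
    """Singular vectors/values of a month-by-year matrix, with labels."""

    month_vectors: np.ndarray  # (12, k) orthonormal columns
    year_loadings: np.ndarray  # (n_years, k) orthonormal columns
    singular_values: np.ndarray  # (k,) descending, >= 0
    variance_fractions: np.ndarray  # s_i^2 / sum s_j^2
    shape_labels: list[str]
    years: list[int] | None = None
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.singular_values.size):
            row = {
                "mode": i + 1,
                "singular_value": self.singular_values[i],
                "variance_fraction": self.variance_fractions[i],
                "label": self.shape_labels[i],
            }
            for m in range(12):
                row[f"m{m + 1:02d}"] = self.month_vectors[m, i]
            rows.append(row)
        return pd.DataFrame(rows)


def build_month_year_matrix(anoms: RegionSeries) -> tuple[np.ndarray, list[int]]:
    """Arrange a monthly anomaly series into a 12 x n_years matrix.

    Rows are Jan..Dec, columns years ascending.  Years without all twelve
    finite months are dropped.
    """
    by_year: dict[int, np.ndarray] = {}
    for y in sorted({yy for yy, _ in anoms.time}):
        col = np.full(12, np.nan)
        for m in range(1, 13):
            if (y, m) in anoms.time:
                col[m - 1] = anoms.values[anoms.time.index((y, m))]
        if np.all(np.isfinite(col)):
            by_year[y] = col
    if len(by_year) < 2:
        raise GridContractError("need at least two complete calendar years")
    years = sorted(by_year)
    return np.column_stack([by_year[y] for y in years]), years


def classify_mode(month_vector: np.ndarray, threshold: float = 0.05) -> str:
    """Label a monthly pattern by its spring/summer structure.

    With a = mean(Apr-Jun) and b = mean(Jul-Sep) of the (unit-norm) vector:
    same sign and both |.| > threshold -> "amplification"; opposite signs ->
    "compensation"; otherwise "other".
    """
    v = np.asarray(month_vector, dtype=float)
    a = v[_SPRING].mean()
    b = v[_SUMMER].mean()
    if min(abs(a), abs(b)) > threshold:
        if a * b > 0:
            return "amplification"
        if a * b < 0:
            return "compensation"
    return "other"


def svd_modes(matrix: np.ndarray, years: list[int] | None = None) -> ModeDecomposition:
    """Thin SVD of a 12 x n_years anomaly matrix.

    Sign convention: each month vector is oriented so its Apr-Jun mean is
    >= 0 (ties broken by the Jul-Sep mean), with year loadings flipped to
    match, so reconstruction is unaffected.  A zero matrix is flagged
    degenerate with undefined variance fractions.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != 12:
        raise GridContractError("matrix must have 12 month rows")
    if not np.all(np.isfinite(matrix)):
        raise GridContractError("matrix entries must be finite (drop missing years first)")

    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        k = s.size
        return ModeDecomposition(
            month_vectors=u,
            year_loadings=vt.T,
            singular_values=s,
            variance_fractions=np.full(k, np.nan),
            shape_labels=["other"] * k,
            years=years,
            degenerate=True,
        )
    fractions = s**2 / total

    v = vt.T.copy()
    u = u.copy()
    for i in range(s.size):
        a = u[_SPRING, i].mean()
        b = u[_SUMMER, i].mean()
        flip = a < 0 or (a == 0 and b < 0)
        if flip:
            u[:, i] *= -1
            v[:, i] *= -1
    labels = [classify_mode(u[:, i]) for i in range(s.size)]
    return ModeDecomposition(
        month_vectors=u,
        year_loadings=v,
        singular_values=s,
        variance_fractions=fractions,
        shape_labels=labels,
        years=years,
    )
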