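"""Correspondence analysis of RSCU matrices and Spearman correlation tables.

Correspondence analysis (CA) ordinates a non-negative table under the
chi-square metric: with correspondence matrix P = X / grand total, row
masses r and column masses c, the standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is decomposed by SVD; principal coordinates are the mass-rescaled
singular vectors times the singular values, and each axis explains a
fraction of the total inertia (= squared singular value / sum).  Total
inertia equals the table's Pearson chi-square statistic divided by the
grand total.  Here the table is strains x 59 RSCU values (the codon-usage
convention for "CA based on RSCU"); a raw-counts mode is available for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class COAResult:
    """Principal coordinates and inertia decomposition of one CA run."""

    row_coords: pd.DataFrame  # index: row labels, columns: axis1..k
    col_coords: pd.DataFrame  # index: column labels
    inertia_fractions: np.ndarray  # all non-trivial axes, sums to 1
    total_inertia: float


def correspondence_analysis(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 2,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> COAResult:
    """Standard correspondence analysis of a non-negative table.

    All-zero columns are dropped with a warning (a codon unused in every
    strain carries no chi-square information); an all-zero row raises.
    Axis signs are fixed by making the largest-magnitude column loading on
    each axis positive, so results do not depend on the SVD backend.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        row_labels = list(matrix.index) if row_labels is None else list(row_labels)
        col_labels = list(matrix.columns) if col_labels is None else list(col_labels)
    else:
        X = np.asarray(matrix, dtype=float)
        if row_labels is None:
            row_labels = [f"row{i}" for i in range(X.shape[0])]
        if col_labels is None:
            col_labels = [f"col{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if (X < 0).any() or np.isnan(X).any():
        raise ValueError("CA requires a finite non-negative table")
    keep = X.sum(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k_ in zip(col_labels, keep) if not k_]
        logger.warning("dropping %d all-zero column(s): %s", len(dropped), dropped[:5])
        X = X[:, keep]
        col_labels = [c for c, k_ in zip(col_labels, keep) if k_]
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero row in CA input")

    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    # non-trivial axes only (rank of the residual); S is scale-free, so an
    # absolute cutoff near machine epsilon separates structure from noise
    tol = max(S.shape) * np.finfo(float).eps
    nz = sv > tol
    n_axes = int(nz.sum())
    max_axes = min(X.shape[0], X.shape[1]) - 1
    n_axes = min(n_axes, max_axes)

    if n_axes == 0:
        logger.warning("rank-0 residual: rows are proportional, zero inertia")
        rows = pd.DataFrame(0.0, index=row_labels, columns=[f"axis{i+1}" for i in range(k)])
        cols = pd.DataFrame(0.0, index=col_labels, columns=[f"axis{i+1}" for i in range(k)])
        return COAResult(rows, cols, np.zeros(0), 0.0)

    U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes, :]
    # deterministic sign: largest-|loading| column coordinate positive per axis
    for a in range(n_axes):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    row_pc = (U / np.sqrt(r)[:, None]) * sv[None, :]
    col_pc = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]

    inertias = sv**2
    total_inertia = float(inertias.sum())
    fractions = inertias / total_inertia

    k_eff = min(k, n_axes)
    axis_names = [f"axis{i+1}" for i in range(k_eff)]
    rows = pd.DataFrame(row_pc[:, :k_eff], index=row_labels, columns=axis_names)
    cols = pd.DataFrame(col_pc[:, :k_eff], index=col_labels, columns=axis_names)
    return COAResult(rows, cols, fractions, total_inertia)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman correlations with two-sided p-values."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-form table (var1, var2, rho, p) over the upper triangle."""
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[i + 1:]:
                rows.append({
                    "var1": v1, "var2": v2,
                    "rho": self.rho.loc[v1, v2], "p": self.p.loc[v1, v2],
                })
        return pd.DataFrame(rows)


def spearman_matrix(
    feature_table: pd.DataFrame, bh_correct: bool = False
) -> CorrelationMatrix:
    """Spearman correlation matrix of a strains x variables table.

    Ties are handled by average ranks; p-values are two-sided and, by
    default, uncorrected (set ``bh_correct`` for Benjamini-Hochberg
    adjustment).  Constant variables yield nan correlations with a
    warning.
    """
    if feature_table.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    variables = list(feature_table.columns)
    n = len(variables)
    X = feature_table.to_numpy(dtype=float)
    constant = [v for v, col in zip(variables, X.T) if np.ptp(col) == 0]
    if constant:
        logger.warning("constant variable(s), correlations undefined: %s", constant)
    rho = np.eye(n)
    p = np.zeros((n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(n):
            for j in range(i + 1, n):
                if variables[i] in constant or variables[j] in constant:
                    rho[i, j] = rho[j, i] = np.nan
                    p[i, j] = p[j, i] = np.nan
                    continue
                r, pv = stats.spearmanr(X[:, i], X[:, j])
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = pv
    if bh_correct:
        iu = np.triu_indices(n, 1)
        pvals = p[iu]
        mask = ~np.isnan(pvals)
        if mask.any():
            adj = pvals.copy()
            adj[mask] = stats.false_discovery_control(pvals[mask], method="bh")
            p[iu] = adj
            p.T[iu] = adj
    rho_df = pd.DataFrame(rho, index=variables, columns=variables)
    p_df = pd.DataFrame(p, index=variables, columns=variables)
    return CorrelationMatrix(variables=variables, rho=rho_df, p=p_df)
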