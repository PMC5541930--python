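"""RLQ analysis: coupled ordination of the R, L, Q tables.

RLQ combines three separate ordinations — a correspondence analysis (CA)
of the abundance table L, and row-weighted, centred-and-normed principal
component analyses of R (plots x metrics, CA row weights) and Q
(species x traits, CA column weights) — into a single co-inertia
analysis that maximises the covariance between plot scores driven by the
environment (here, spatial configuration) and species scores driven by
traits, linked through L.

Writing ``P = L / L.sum()`` with row weights ``r`` and column weights
``c`` (the CA margins), and ``R~``, ``Q~`` for the weighted standardised
tables, the analysis reduces to the SVD of the crossed matrix

    X = R~' P Q~      (metrics x traits),

whose entries are exactly the fourth-corner correlations between each
metric and each trait.  The RLQ eigenvalues are the squared singular
values of X, so the total co-inertia equals the squared Frobenius norm
of X — the identity ``sum(lambda) == sum(X**2)`` ties this module to the
fourth-corner module and is asserted in the test suite.

Axis signs from an SVD are arbitrary; each axis is oriented so that the
variable (metric or trait) with the largest absolute loading on it loads
positive, which makes outputs reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .tables import StudyTables

__all__ = [
    "RLQResult",
    "correspondence_weights",
    "weighted_standardize",
    "weighted_corr",
    "rlq",
    "inertia_contributions",
]

#: singular values below this (relative to the largest) count as zero
_RANK_TOL = 1e-12


@dataclass
class RLQResult:
    """Eigen structure and scores of an RLQ analysis.

    ``eigenvalues`` are the squared singular values of the crossed matrix;
    ``percent`` their shares of the total co-inertia.  Loadings are the
    singular vectors (metrics on the left, traits on the right); plot and
    species scores are the standardised tables projected on them.
    ``metric_axis_corr`` / ``trait_axis_corr`` hold weighted Pearson
    correlations of each raw variable with the axis scores.
    """

    eigenvalues: np.ndarray
    percent: np.ndarray
    total_inertia: float
    crossed: pd.DataFrame  # metrics x traits
    metric_loadings: pd.DataFrame
    trait_loadings: pd.DataFrame
    plot_scores: pd.DataFrame
    species_scores: pd.DataFrame
    metric_axis_corr: pd.DataFrame
    trait_axis_corr: pd.DataFrame
    row_weights: pd.Series
    col_weights: pd.Series

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def axis_share(self, axis: int = 1) -> float:
        """Percent of co-inertia carried by ``axis`` (1-based)."""
        return float(self.percent[axis - 1])

    def cumulative_share(self, n_axes: int = 2) -> float:
        return float(self.percent[:n_axes].sum())


def correspondence_weights(L: pd.DataFrame):
    """CA margins of L: relative table P and its row / column weights."""
    X = L.to_numpy(dtype=float)
    total = X.sum()
    if total <= 0:
        raise DegenerateInputError("L has zero grand total")
    if (X < 0).any():
        raise DegenerateInputError("L must be nonnegative")
    P = pd.DataFrame(X / total, index=L.index, columns=L.columns)
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise DegenerateInputError("L has an all-zero row or column")
    return P, r, c


def weighted_standardize(table: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Center and norm each column to weighted mean 0 and variance 1.

    The variance is the plain weighted second moment about the weighted
    mean (weights sum to 1; no small-sample correction), matching the
    "centred normed" convention of CA-weighted PCA.
    """
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any():
        raise DegenerateInputError("weights must be positive")
    if not np.isclose(w.sum(), 1.0):
        raise DegenerateInputError("weights must sum to 1")
    X = table.to_numpy(dtype=float)
    mean = w @ X
    Xc = X - mean
    var = w @ Xc**2
    bad = np.asarray(var <= 0).nonzero()[0]
    if bad.size:
        raise DegenerateInputError(
            f"constant column(s) cannot be normed: {[table.columns[i] for i in bad]}"
        )
    return pd.DataFrame(Xc / np.sqrt(var), index=table.index, columns=table.columns)


def weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation (weights sum to 1)."""
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def _orient_axes(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip axis signs so the largest-|loading| variable loads positive.

    U and V share the flip (the crossed matrix U S V' is unchanged).
    """
    loadings = np.vstack([U, V])
    for a in range(U.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            U[:, a] *= -1
            V[:, a] *= -1
    return U, V


def rlq(
    tables: StudyTables,
    *,
    R_std: pd.DataFrame | None = None,
    P: pd.DataFrame | None = None,
) -> RLQResult:
    """Run the RLQ analysis on aligned study tables.

    ``R_std`` and ``P`` allow a caller (the partial-RLQ module) to inject
    an already-conditioned standardised R table or relative abundance
    table; by default both derive from the tables themselves.
    """
    tables.validate()
    P_default, r, c = correspondence_weights(tables.L)
    if P is None:
        P = P_default
    Rt = R_std if R_std is not None else weighted_standardize(tables.R, r)
    Qt = weighted_standardize(tables.Q, c)

    X = Rt.to_numpy().T @ P.to_numpy() @ Qt.to_numpy()  # metrics x traits
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > (s[0] * _RANK_TOL if s.size and s[0] > 0 else _RANK_TOL)
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    U, V = _orient_axes(U, V)

    eig = s**2
    total = float((X**2).sum())
    percent = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    axes = [f"axis{i + 1}" for i in range(len(eig))]

    metric_loadings = pd.DataFrame(U, index=tables.R.columns, columns=axes)
    trait_loadings = pd.DataFrame(V, index=tables.Q.columns, columns=axes)
    plot_scores = pd.DataFrame(Rt.to_numpy() @ U, index=tables.R.index, columns=axes)
    species_scores = pd.DataFrame(Qt.to_numpy() @ V, index=tables.Q.index, columns=axes)

    rw, cw = r.to_numpy(), c.to_numpy()
    mcorr = pd.DataFrame(
        [
            [weighted_corr(tables.R[m].to_numpy(dtype=float), plot_scores[a].to_numpy(), rw) for a in axes]
            for m in tables.R.columns
        ],
        index=tables.R.columns,
        columns=axes,
    )
    tcorr = pd.DataFrame(
        [
            [weighted_corr(tables.Q[t].to_numpy(dtype=float), species_scores[a].to_numpy(), cw) for a in axes]
            for t in tables.Q.columns
        ],
        index=tables.Q.columns,
        columns=axes,
    )
    return RLQResult(
        eigenvalues=eig,
        percent=percent,
        total_inertia=total,
        crossed=pd.DataFrame(X, index=tables.R.columns, columns=tables.Q.columns),
        metric_loadings=metric_loadings,
        trait_loadings=trait_loadings,
        plot_scores=plot_scores,
        species_scores=species_scores,
        metric_axis_corr=mcorr,
        trait_axis_corr=tcorr,
        row_weights=r,
        col_weights=c,
    )


def inertia_contributions(result: RLQResult, n_axes: int = 2):
    """Per-variable percentage contributions to the leading axes.

    Within one axis the squared loadings of the metrics (resp. traits)
    sum to 1, so contributions per axis sum to 100%.  The returned
    ``metric_total``/``trait_total`` sum each variable's contributions
    over the first ``n_axes`` axes (so the column totals ~= 100 * n_axes).
    """
    if not 1 <= n_axes <= result.n_axes:
        raise DegenerateInputError(f"n_axes must be in [1, {result.n_axes}]")
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    m = 100.0 * result.metric_loadings[axes] ** 2
    t = 100.0 * result.trait_loadings[axes] ** 2
    return {
        "metric_per_axis": m,
        "trait_per_axis": t,
        "metric_total": m.sum(axis=1),
        "trait_total": t.sum(axis=1),
    }
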