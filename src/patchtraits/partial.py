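"""Partial RLQ: RLQ conditioned on a categorical plot covariate.

The covariate (terrain-age class or cobble-cover class) partitions the
plots into groups.  Conditioning removes between-group structure from
the environment side before the co-inertia analysis: each landscape
metric is centred *within every class* (using the CA row weights
restricted to the class) and then re-normed to weighted variance 1, so
only within-class variation in spatial configuration can couple with
the traits.  Comparing the share of co-inertia carried by the first
partial-RLQ axis with the basic RLQ tells whether the covariate
structures the trait–metric relationship: a much higher partial share
would mean the covariate was masking it, a similar or lower share that
the covariate is irrelevant.

An alternative scheme that additionally conditions the species profiles
of L within the classes is available via ``condition_l=True``; see
docs/methods.md for the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .rlq import RLQResult, correspondence_weights, rlq
from .tables import StudyTables

__all__ = ["PartialRLQResult", "within_class_center", "partial_rlq"]


@dataclass
class PartialRLQResult(RLQResult):
    covariate: str = ""
    class_sizes: dict[str, int] | None = None


def within_class_center(
    table: pd.DataFrame, partition: pd.Series, weights: pd.Series
) -> pd.DataFrame:
    """Center each column to weighted mean 0 within every class.

    ``partition`` assigns every row of ``table`` to one class; the class
    mean uses ``weights`` renormalised within the class.  With a single
    class this reduces to global weighted centering, and a column that is
    constant within every class becomes identically zero.
    """
    missing = table.index.difference(partition.index)
    if len(missing):
        raise DegenerateInputError(f"rows without a class: {list(missing)}")
    part = partition.loc[table.index]
    w = weights.loc[table.index].to_numpy(dtype=float)
    X = table.to_numpy(dtype=float).copy()
    for cls in part.unique():
        sel = (part == cls).to_numpy()
        wsum = w[sel].sum()
        if wsum <= 0:
            raise DegenerateInputError(f"class {cls!r} has zero total weight")
        mean = w[sel] @ X[sel] / wsum
        X[sel] -= mean
    return pd.DataFrame(X, index=table.index, columns=table.columns)


def _renorm(table: pd.DataFrame, weights: pd.Series, ref_var: np.ndarray) -> pd.DataFrame:
    """Scale columns to weighted variance 1.

    A column whose residual variance is numerically zero relative to its
    pre-conditioning variance (``ref_var``) is set to exactly zero — it
    carries no information after conditioning, and renorming the rounding
    residue of the class means would amplify noise to full amplitude.
    """
    w = weights.to_numpy(dtype=float)
    X = table.to_numpy(dtype=float)
    var = w @ X**2
    live = var > ref_var * 1e-24
    X = np.where(live, X, 0.0)
    scale = np.where(live, np.sqrt(np.where(live, var, 1.0)), 1.0)
    return pd.DataFrame(X / scale, index=table.index, columns=table.columns)


def partial_rlq(
    tables: StudyTables,
    covariate: str,
    *,
    condition_l: bool = False,
) -> PartialRLQResult:
    """RLQ with the named covariate ('terrain_age' or 'cobble') partialled out.

    ``condition_l=True`` additionally replaces the CA deviations of L by
    within-class deviations (class-conditional expected profiles instead
    of the global margin), conditioning the link table as well.
    """
    tables.validate()
    classes = tables.class_labels(covariate)
    P, r, c = correspondence_weights(tables.L)

    w = r.to_numpy(dtype=float)
    Rm = tables.R.to_numpy(dtype=float)
    ref_var = w @ (Rm - w @ Rm) ** 2
    R_cond = _renorm(within_class_center(tables.R, classes, r), r, ref_var)

    P_use = None
    if condition_l:
        # replace the implicit global expectation r c' by the class-conditional
        # expectation r c_g' so that between-class compositional differences
        # cannot contribute to the cross matrix
        Pm = P.to_numpy()
        rv = r.to_numpy()
        adj = Pm.astype(float).copy()
        for cls in classes.unique():
            sel = (classes == cls).to_numpy()
            cg = Pm[sel].sum(axis=0) / rv[sel].sum()
            adj[sel] = Pm[sel] - np.outer(rv[sel], cg)
        # the basic analysis uses X = R~' (P - r c') Q~ implicitly because R~
        # is centred; here the centering must be explicit
        P_use = pd.DataFrame(adj, index=P.index, columns=P.columns)

    base = rlq(tables, R_std=R_cond, P=P_use)
    sizes = classes.value_counts().to_dict()
    return PartialRLQResult(
        eigenvalues=base.eigenvalues,
        percent=base.percent,
        total_inertia=base.total_inertia,
        crossed=base.crossed,
        metric_loadings=base.metric_loadings,
        trait_loadings=base.trait_loadings,
        plot_scores=base.plot_scores,
        species_scores=base.species_scores,
        metric_axis_corr=base.metric_axis_corr,
        trait_axis_corr=base.trait_axis_corr,
        row_weights=base.row_weights,
        col_weights=base.col_weights,
        covariate=covariate,
        class_sizes={str(k): int(v) for k, v in sizes.items()},
    )
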