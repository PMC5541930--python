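"""Fourth-corner statistics and permutation tests.

The fourth-corner matrix X crosses the traits (Q) with the landscape
metrics (R) through the abundances (L): with CA weights and
weighted-standardised tables,

    X[trait j, metric k] = sum_i sum_s P[i, s] * R~[i, k] * Q~[s, j],

i.e., the weighted Pearson correlation between metric k and trait j
over the abundance-inflated table.  ``sum(X**2)`` equals the RLQ total
co-inertia.

Because a trait–metric correlation can be produced either by the
environment structuring the species distribution or by the traits
structuring it, the null hypothesis is tested twice:

* **model 2** permutes the plots (rows of L), breaking the L–R link
  while preserving L–Q;
* **model 4** permutes the species (columns of L), breaking L–Q while
  preserving L–R.

The overall null is rejected only when both are: each cell's combined
p-value is the maximum of the two models' p-values (the sequential
max-p rule), and significance is reported under both the
alpha = sqrt(0.05) and the alpha = 0.05 conventions.  p-values use the
(b + 1) / (B + 1) estimator and never return 0.

Permutation note: permuting the rows of L (with the CA weights riding
along) is algebraically identical to permuting the rows of R while the
weights stay attached to L's rows; the latter is cheaper because P and
Q~ need no recomputation, and is what the hot loop does.  The test
suite checks the equivalence against a literal permute-L
implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rlq import RLQResult, correspondence_weights, weighted_standardize
from .tables import StudyTables

__all__ = [
    "FourthCornerResult",
    "GlobalTestResult",
    "PermutationTestResult",
    "fourth_corner_matrix",
    "permutation_test",
    "combined_test",
    "axes_association_test",
    "ALPHA_SQRT05",
]

ALPHA_SQRT05 = math.sqrt(0.05)
_EPS = 1e-12


@dataclass
class GlobalTestResult:
    """Global (multivariate) permutation test of the total co-inertia."""

    statistic: float  # sum of RLQ eigenvalues == sum(X**2)
    p: float
    model: int
    n_permutations: int
    seed: int | None


@dataclass
class PermutationTestResult:
    """Per-cell and global p-values for one permutation model."""

    model: int
    stat: pd.DataFrame  # traits x metrics
    p_cells: pd.DataFrame
    global_test: GlobalTestResult
    n_permutations: int
    seed: int | None


@dataclass
class FourthCornerResult:
    """Trait x metric fourth-corner correlations with combined inference."""

    stat: pd.DataFrame  # traits x metrics
    p_model2: pd.DataFrame
    p_model4: pd.DataFrame
    p_combined: pd.DataFrame
    significant_sqrt05: pd.DataFrame
    significant_05: pd.DataFrame
    global_model2: GlobalTestResult
    global_model4: GlobalTestResult
    n_permutations: int
    seed: int | None
    fdr: bool = False

    def n_significant(self, convention: str = "sqrt05") -> int:
        flags = self.significant_sqrt05 if convention == "sqrt05" else self.significant_05
        return int(flags.to_numpy().sum())

    def summary_table(self) -> pd.DataFrame:
        """Long-format table mirroring the per-pair report layout."""
        rows = []
        for trait in self.stat.index:
            for metric in self.stat.columns:
                rows.append(
                    {
                        "trait": trait,
                        "metric": metric,
                        "statistic": self.stat.loc[trait, metric],
                        "p_model2": self.p_model2.loc[trait, metric],
                        "p_model4": self.p_model4.loc[trait, metric],
                        "p_combined": self.p_combined.loc[trait, metric],
                        "sig_sqrt05": bool(self.significant_sqrt05.loc[trait, metric]),
                        "sig_05": bool(self.significant_05.loc[trait, metric]),
                    }
                )
        return pd.DataFrame(rows)


def _std(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted standardisation without label bookkeeping (hot path)."""
    m = w @ X
    Xc = X - m
    v = w @ Xc**2
    return Xc / np.sqrt(v)


def _prepare(tables: StudyTables):
    P, r, c = correspondence_weights(tables.L)
    rv, cv = r.to_numpy(), c.to_numpy()
    Rt = weighted_standardize(tables.R, r).to_numpy()
    Qt = weighted_standardize(tables.Q, c).to_numpy()
    Pm = P.to_numpy()
    Z = Rt.T @ Pm @ Qt  # metrics x traits
    return Pm, rv, cv, Rt, Qt, Z


def fourth_corner_matrix(tables: StudyTables) -> pd.DataFrame:
    """Observed trait x metric fourth-corner correlation matrix."""
    tables.validate()
    _, _, _, _, _, Z = _prepare(tables)
    return pd.DataFrame(Z.T, index=tables.Q.columns, columns=tables.R.columns)


def permutation_test(
    tables: StudyTables,
    model: int,
    n_perm: int = 49999,
    seed: int | None = None,
    permutations: list[np.ndarray] | None = None,
) -> PermutationTestResult:
    """Permutation test of the fourth-corner cells and the global co-inertia.

    ``model`` is 2 (permute plots; tests the L–R link) or 4 (permute
    species; tests the L–Q link).  ``permutations`` overrides the random
    draw with an explicit list of row orderings (used by the tests).
    Two-sided per cell on |X|; the global statistic is sum(X**2).
    """
    if model not in (2, 4):
        raise ValidationError("permutation model must be 2 or 4")
    if permutations is None and n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    tables.validate()
    Pm, rv, cv, Rt, Qt, Z = _prepare(tables)
    obs = np.abs(Z)
    obs_global = float((Z**2).sum())

    rng = np.random.default_rng(seed)
    Rraw = tables.R.to_numpy(dtype=float)
    Qraw = tables.Q.to_numpy(dtype=float)
    if model == 2:
        fixed = Pm @ Qt  # plots x traits
        n = Rraw.shape[0]
    else:
        fixed = Pm.T @ Rt  # species x metrics
        n = Qraw.shape[0]

    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_perm)]
    B = len(permutations)

    count_cells = np.zeros_like(Z, dtype=int)
    count_global = 0
    for perm in permutations:
        if model == 2:
            Zp = _std(Rraw[perm], rv).T @ fixed  # metrics x traits
        else:
            Zp = (fixed.T @ _std(Qraw[perm], cv))  # metrics x traits
        count_cells += np.abs(Zp) >= obs - _EPS
        count_global += (Zp**2).sum() >= obs_global - _EPS

    p_cells = (count_cells + 1) / (B + 1)
    p_global = (count_global + 1) / (B + 1)
    stat = pd.DataFrame(Z.T, index=tables.Q.columns, columns=tables.R.columns)
    pdf = pd.DataFrame(p_cells.T, index=tables.Q.columns, columns=tables.R.columns)
    g = GlobalTestResult(obs_global, float(p_global), model, B, seed)
    return PermutationTestResult(model, stat, pdf, g, B, seed)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjustment of a flat p-value array."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def combined_test(
    tables: StudyTables,
    n_perm: int = 49999,
    seed: int | None = None,
    alphas: tuple[float, float] = (ALPHA_SQRT05, 0.05),
    fdr: bool = False,
) -> FourthCornerResult:
    """Run both permutation models and combine them with the max-p rule.

    A cell is flagged significant at an alpha iff
    ``max(p_model2, p_model4) < alpha``; the sign of the association is
    the sign of the statistic.  With ``fdr=True`` the combined p-values
    are Benjamini–Hochberg adjusted across all cells before flagging
    (off by default; the raw combined p against both alpha conventions is
    the reference behaviour).
    """
    rng = np.random.default_rng(seed)
    seed2, seed4 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    t2 = permutation_test(tables, 2, n_perm, seed2)
    t4 = permutation_test(tables, 4, n_perm, seed4)
    p_comb = pd.DataFrame(
        np.maximum(t2.p_cells.to_numpy(), t4.p_cells.to_numpy()),
        index=t2.p_cells.index,
        columns=t2.p_cells.columns,
    )
    p_flag = p_comb
    if fdr:
        adj = _bh_adjust(p_comb.to_numpy().ravel()).reshape(p_comb.shape)
        p_flag = pd.DataFrame(adj, index=p_comb.index, columns=p_comb.columns)
    a_loose, a_strict = max(alphas), min(alphas)
    return FourthCornerResult(
        stat=t2.stat,
        p_model2=t2.p_cells,
        p_model4=t4.p_cells,
        p_combined=p_comb,
        significant_sqrt05=p_flag < a_loose,
        significant_05=p_flag < a_strict,
        global_model2=t2.global_test,
        global_model4=t4.global_test,
        n_permutations=t2.n_permutations,
        seed=seed,
        fdr=fdr,
    )


def _batch_weighted_corr(Xp: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted correlation of each row of Xp (B x n) with y (n,); w sums to 1.

    Uses sum w (x - mx)(y - my) = sum x * w (y - my), which drops the mx
    cross term because the weighted deviations of y sum to zero.
    """
    my = w @ y
    yc = (y - my) * w
    vy = w @ (y - my) ** 2
    mx = Xp @ w
    cov = Xp @ yc
    vx = (Xp**2 @ w) - mx**2
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / np.sqrt(vx * vy)


def axes_association_test(
    tables: StudyTables,
    rlq_result: RLQResult,
    n_perm: int = 49999,
    seed: int | None = None,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Association of each variable with the leading RLQ axes.

    The statistic per (variable, axis) is the weighted Pearson
    correlation of the raw variable with the observed axis scores — the
    quantitative–quantitative form of the squared-association (D2)
    statistic whose square is reported alongside.  Landscape metrics use
    the plot scores and CA row weights, with significance from model-2
    (plot) permutations; traits use the species scores and CA column
    weights with model-4 (species) permutations.  Axis scores stay fixed
    under permutation.  Two-sided p-values with the +1 correction.
    """
    if not 1 <= n_axes <= rlq_result.n_axes:
        raise ValidationError(f"n_axes must be in [1, {rlq_result.n_axes}]")
    tables.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for kind, table, scores, weights in (
        ("metric", tables.R, rlq_result.plot_scores, rlq_result.row_weights),
        ("trait", tables.Q, rlq_result.species_scores, rlq_result.col_weights),
    ):
        n = table.shape[0]
        w = weights.to_numpy(dtype=float)
        perm_matrix = np.array([rng.permutation(n) for _ in range(n_perm)])
        for var in table.columns:
            x = table[var].to_numpy(dtype=float)
            Xp = x[perm_matrix]
            row: dict[str, object] = {"variable": var, "kind": kind}
            for a in range(1, n_axes + 1):
                y = scores[f"axis{a}"].to_numpy()
                mx, my = w @ x, w @ y
                obs_num = w @ ((x - mx) * (y - my))
                obs_den = math.sqrt((w @ (x - mx) ** 2) * (w @ (y - my) ** 2))
                obs = obs_num / obs_den
                null = _batch_weighted_corr(Xp, y, w)
                count = int(np.sum(np.abs(null) >= abs(obs) - _EPS))
                row[f"corr_axis{a}"] = obs
                row[f"d2_axis{a}"] = obs**2
                row[f"p_axis{a}"] = (count + 1) / (n_perm + 1)
            rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
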