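"""Floristic clustering of releves and ANOVA of metrics across groups.

The 46 vegetation releves are grouped by agglomerative clustering of
Bray–Curtis dissimilarities with Ward's criterion, and one-way ANOVA
then asks whether the landscape metrics differ among the resulting
clusters (or among the terrain-age / cobble-cover classes, where the
null is expected to hold).

Two Ward variants exist in the literature.  ``"D"`` applies the
Lance–Williams Ward update directly to the (unsquared) dissimilarities,
``"D2"`` to their squares.  ``"D"`` is the default here.  Internally
Ward.D is computed as Ward.D2 on the square roots of the input
dissimilarities with the merge heights squared afterwards, which is the
same recurrence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ClusterResult",
    "AnovaResult",
    "bray_curtis",
    "ward_cluster",
    "cluster_releves",
    "anova_oneway",
]


@dataclass
class ClusterResult:
    """A cut agglomerative tree: scipy linkage matrix + plot assignment."""

    linkage: np.ndarray
    assignment: pd.Series  # plot_id -> "CL1".."CLk"
    k: int
    variant: str
    characteristic_species: dict[str, str] | None = None


@dataclass
class AnovaResult:
    response: str
    grouping: str
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: pd.DataFrame  # index: group; columns: n, mean, ci_low, ci_high


def bray_curtis(L: pd.DataFrame) -> pd.DataFrame:
    """Plot x plot Bray–Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    X = L.to_numpy(dtype=float)
    if (X < 0).any():
        raise DegenerateInputError("abundances must be nonnegative")
    if (X.sum(axis=1) == 0).any():
        bad = list(L.index[X.sum(axis=1) == 0])
        raise DegenerateInputError(f"Bray–Curtis undefined for all-zero plots: {bad}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=L.index, columns=L.index)


def ward_cluster(D: pd.DataFrame, k: int, variant: str = "D") -> ClusterResult:
    """Agglomerative Ward clustering of a dissimilarity matrix, cut at k.

    Cluster labels are ``CL1..CLk`` in order of first appearance; use
    :func:`cluster_releves` for the abundance-based canonical labeling.
    """
    Dm = D.to_numpy(dtype=float)
    if Dm.shape[0] != Dm.shape[1] or not np.allclose(Dm, Dm.T, atol=1e-10):
        raise ValidationError("D must be a symmetric square dissimilarity matrix")
    n = Dm.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    condensed = squareform(Dm, checks=False)
    if variant == "D":
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2  # heights back on the Ward.D scale
    elif variant == "D2":
        Z = hierarchy.linkage(condensed, method="ward")
    else:
        raise ValidationError("variant must be 'D' or 'D2'")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # stable relabeling by order of first appearance
    seen: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(f"CL{seen[r]}")
    assignment = pd.Series(labels, index=D.index, name="cluster")
    return ClusterResult(linkage=Z, assignment=assignment, k=k, variant=variant)


def cluster_releves(L: pd.DataFrame, k: int = 3, variant: str = "D") -> ClusterResult:
    """Bray–Curtis + Ward clustering of an abundance table with canonical labels.

    Each cluster's *characteristic species* is the species whose
    within-cluster mean abundance is most inflated relative to its overall
    mean; clusters are then labeled CL1..CLk by descending within-cluster
    mean abundance of their characteristic species, making labels stable
    across plot input order.
    """
    res = ward_cluster(bray_curtis(L), k, variant)
    overall = L.mean(axis=0).replace(0, np.nan)
    info = []
    for lab in sorted(res.assignment.unique()):
        sub = L.loc[res.assignment == lab]
        ratio = sub.mean(axis=0) / overall
        champ = ratio.idxmax()
        info.append((lab, champ, float(sub[champ].mean())))
    info.sort(key=lambda t: -t[2])
    remap = {old: f"CL{i + 1}" for i, (old, _, _) in enumerate(info)}
    assignment = res.assignment.map(remap).rename("cluster")
    chars = {remap[old]: str(champ) for old, champ, _ in info}
    return ClusterResult(
        linkage=res.linkage, assignment=assignment, k=k, variant=variant,
        characteristic_species=chars,
    )


def anova_oneway(values, groups, response: str = "value", grouping: str = "group") -> AnovaResult:
    """Classical one-way ANOVA with per-group means and t-based 95% CIs.

    Zero pooled within-group variance with unequal means yields F = inf
    (flagged by p = 0); identical constant groups yield F = NaN.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    if len(v) != len(g):
        raise ValidationError("values and groups must have equal length")
    levels = g.unique()
    if len(levels) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    samples = [v[g == lev].to_numpy() for lev in levels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("every group needs >= 1 observation")
    n, kk = len(v), len(levels)
    grand = v.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = kk - 1, n - kk
    if df_w <= 0:
        raise ValidationError("ANOVA needs more observations than groups")
    if ss_within == 0:
        F = np.inf if ss_between > 0 else np.nan
        p = 0.0 if ss_between > 0 else np.nan
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    rows = []
    for lev, s in zip(levels, samples):
        m = s.mean()
        if len(s) > 1 and s.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, len(s) - 1) * s.std(ddof=1) / np.sqrt(len(s))
        else:
            half = 0.0 if len(s) > 0 else np.nan
        rows.append({"group": lev, "n": len(s), "mean": m, "ci_low": m - half, "ci_high": m + half})
    gm = pd.DataFrame(rows).set_index("group")
    return AnovaResult(response, grouping, float(F), float(p), df_b, df_w, gm)
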