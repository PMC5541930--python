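"""The R / L / Q table triplet and its alignment.

The analysis state is three tables sharing labels:

* **R** — plots x landscape metrics (the "environment" of the ordination,
  here the spatial configuration of the vegetation mosaic),
* **L** — plots x species abundances (cm^2 of cover per 1 m^2 plot),
* **Q** — species x functional traits,

plus the categorical plot covariates (terrain-age class ta1-ta3 and
cobble-cover class ts1-ts3).  Plots are the shared rows of R and L;
species are the columns of L and the rows of Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError

__all__ = ["StudyTables", "load_study_tables"]

logger = logging.getLogger(__name__)


@dataclass
class StudyTables:
    """Aligned R (plots x metrics), L (plots x species), Q (species x traits).

    Use :meth:`from_frames` (or :func:`load_study_tables`) to build one from
    unaligned inputs; the constructor assumes labels already agree.
    """

    R: pd.DataFrame
    L: pd.DataFrame
    Q: pd.DataFrame
    covariates: pd.DataFrame | None = None
    dropped_species: list[str] = field(default_factory=list)

    @property
    def plots(self) -> pd.Index:
        return self.L.index

    @property
    def species(self) -> pd.Index:
        return self.L.columns

    def validate(self) -> "StudyTables":
        if not self.R.index.equals(self.L.index):
            raise AlignmentError("R and L plot labels differ")
        if not self.Q.index.equals(self.L.columns):
            raise AlignmentError("Q species labels differ from L columns")
        if (self.L.to_numpy() < 0).any():
            raise DegenerateInputError("L contains negative abundances")
        if (self.L.sum(axis=1) == 0).any():
            bad = list(self.L.index[self.L.sum(axis=1) == 0])
            raise DegenerateInputError(f"all-zero plots in L: {bad}")
        if (self.L.sum(axis=0) == 0).any():
            bad = list(self.L.columns[self.L.sum(axis=0) == 0])
            raise DegenerateInputError(f"all-zero species in L: {bad}")
        if self.covariates is not None and not self.covariates.index.equals(self.L.index):
            raise AlignmentError("covariate plot labels differ from L rows")
        return self

    @classmethod
    def from_frames(
        cls,
        R: pd.DataFrame,
        L: pd.DataFrame,
        Q: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
    ) -> "StudyTables":
        """Align on labels (order-insensitive) and drop all-zero species.

        Raises :class:`AlignmentError` naming any plot of L missing from R
        (or the covariates), or any species of L missing from Q.  Species
        present in Q but absent from L are dropped silently; species whose
        L column sums to zero are dropped with a logged warning (mirroring
        the omission of species with negligible cover from the analysis).
        """
        missing_plots = L.index.difference(R.index)
        if len(missing_plots):
            raise AlignmentError(f"plots in L missing from R: {list(missing_plots)}")
        extra_plots = R.index.difference(L.index)
        if len(extra_plots):
            raise AlignmentError(f"plots in R missing from L: {list(extra_plots)}")
        missing_species = L.columns.difference(Q.index)
        if len(missing_species):
            raise AlignmentError(f"species in L missing from Q: {list(missing_species)}")

        L = L.copy()
        zero = L.columns[L.sum(axis=0) == 0]
        dropped = [str(s) for s in zero]
        if dropped:
            logger.warning("dropping all-zero species from L: %s", dropped)
            L = L.drop(columns=zero)
        R = R.loc[L.index]
        Q = Q.loc[L.columns]
        if covariates is not None:
            missing_cov = L.index.difference(covariates.index)
            if len(missing_cov):
                raise AlignmentError(f"plots missing covariates: {list(missing_cov)}")
            covariates = covariates.loc[L.index]
        return cls(R=R, L=L, Q=Q, covariates=covariates, dropped_species=dropped).validate()

    def class_labels(self, covariate: str) -> pd.Series:
        """Per-plot class labels for ``covariate`` in {terrain_age, cobble}."""
        if self.covariates is None:
            raise AlignmentError("no covariates attached to these tables")
        column = {"terrain_age": "terrain_age_class", "cobble": "cobble_class"}.get(covariate)
        if column is None or column not in self.covariates.columns:
            raise AlignmentError(f"unknown covariate {covariate!r}")
        labels = self.covariates[column]
        if labels.isna().any():
            bad = list(labels.index[labels.isna()])
            raise AlignmentError(f"missing {covariate} class for plots: {bad}")
        return labels


def load_study_tables(
    r_path: str | Path,
    l_path: str | Path,
    q_path: str | Path,
    covariate_path: str | Path | None = None,
) -> StudyTables:
    """Load the R, L, Q (and covariate) CSVs and align them.

    Each CSV's first column holds the row labels (plots for R and L,
    species for Q).  The covariate CSV has columns
    ``plot_id,terrain_age_class,cobble_class``.
    """
    R = pd.read_csv(r_path, index_col=0)
    L = pd.read_csv(l_path, index_col=0)
    Q = pd.read_csv(q_path, index_col=0)
    cov = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, index_col=0)
    for name, df in (("R", R), ("Q", Q)):
        nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if nonnum:
            raise DegenerateInputError(f"{name} has non-numeric columns: {nonnum}")
    return StudyTables.from_frames(R, L, Q, cov)
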