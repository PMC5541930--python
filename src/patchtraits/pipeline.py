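"""Config-driven end-to-end runner.

One call (or ``patchtraits all`` from the shell) takes a study — species
rasters, ready-made R/L/Q tables, or a simulation block — through the
whole analysis: landscape metrics, releve clustering + ANOVA, basic and
partial RLQ, and the fourth-corner permutation tests, writing stable
CSV outputs plus a JSON run manifest (config hash, seed, versions, wall
time) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import anova_oneway, cluster_releves
from .errors import ValidationError
from .fourthcorner import axes_association_test, combined_test
from .grids import SpeciesGrid, read_grid
from .metrics import METRIC_NAMES, label_patches, plot_metrics_table, species_metrics
from .partial import partial_rlq
from .rlq import inertia_contributions, rlq
from .simulate import SimulationConfig, generate_study
from .tables import StudyTables, load_study_tables

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; exactly one input mode must be set."""

    output_dir: str = "patchtraits_out"
    grids: list[str] | None = None  # long-CSV grid files
    tables: dict | None = None  # {r, l, q, covariates} paths
    simulate: dict | None = None  # SimulationConfig fields
    ward_variant: str = "D"
    k_clusters: int = 3
    n_permutations: int = 49999
    seed: int = 0
    alphas: tuple[float, float] = (np.sqrt(0.05), 0.05)
    covariates: list[str] = field(default_factory=lambda: ["terrain_age", "cobble"])
    fdr: bool = False
    grid_shape: tuple[int, int] = (100, 100)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.alphas = tuple(cfg.alphas)  # yaml gives a list
        return cfg

    def validate(self) -> "RunConfig":
        if self.simulate is not None:
            if self.grids is not None:
                raise ValidationError("give either a simulate block or input files, not both")
            return self
        if self.grids is not None:
            if not self.tables or "q" not in self.tables:
                raise ValidationError("grids input additionally needs tables: {q: <trait csv>}")
            if set(self.tables) & {"r", "l"}:
                raise ValidationError("grids input derives R and L; do not also give r/l paths")
            return self
        if self.tables is None:
            raise ValidationError("one of grids/tables/simulate is required")
        missing = {"r", "l", "q"} - set(self.tables)
        if missing:
            raise ValidationError(f"tables input missing paths: {sorted(missing)}")
        return self


def _species_label(code: int, labels: dict[int, str] | None) -> str:
    return labels[code] if labels else f"sp{code}"


def _load_inputs(config: RunConfig):
    """Returns (grids or None, aligned StudyTables)."""
    if config.simulate is not None:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulate})
        study = generate_study(sim)
        return study.grids, study.tables
    if config.grids is not None:
        grids = [
            read_grid(p, "long_csv", shape=tuple(config.grid_shape)) for p in config.grids
        ]
        labels = None
        if "species_labels" in config.tables:
            lab = pd.read_csv(config.tables["species_labels"])
            labels = dict(zip(lab["code"].astype(int), lab["label"].astype(str)))
        R = plot_metrics_table(grids)
        codes = sorted({c for g in grids for c in g.species_present()})
        L = pd.DataFrame(
            [[int((g.values == c).sum()) for c in codes] for g in grids],
            index=pd.Index([g.plot_id for g in grids], name="plot_id"),
            columns=[_species_label(c, labels) for c in codes],
        )
        Q = pd.read_csv(config.tables["q"], index_col=0)
        cov = None
        if "covariates" in config.tables:
            cov = pd.read_csv(config.tables["covariates"], index_col=0)
        elif any(g.terrain_age_class for g in grids):
            cov = pd.DataFrame(
                {
                    "terrain_age_class": [g.terrain_age_class for g in grids],
                    "cobble_class": [g.cobble_class for g in grids],
                },
                index=L.index,
            )
        return grids, StudyTables.from_frames(R, L, Q, cov)
    t = config.tables
    tables = load_study_tables(t["r"], t["l"], t["q"], t.get("covariates"))
    return None, tables


def _stage(name: str, manifest: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        raise ValidationError(f"stage {name!r} failed: {exc}") from exc
    manifest["stages"][name] = {
        "status": "ok",
        "seconds": round(time.perf_counter() - t0, 3),
    }
    return out


def _write_rlq(res, outdir: Path, suffix: str = "") -> None:
    tag = f"_{suffix}" if suffix else ""
    eig = pd.DataFrame(
        {
            "axis": np.arange(1, res.n_axes + 1),
            "eigenvalue": res.eigenvalues,
            "percent": res.percent,
        }
    )
    eig.to_csv(outdir / f"rlq_eigen{tag}.csv", index=False)
    frames = []
    for kind, df in (
        ("plot", res.plot_scores),
        ("species", res.species_scores),
        ("metric", res.metric_loadings),
        ("trait", res.trait_loadings),
    ):
        sub = df.iloc[:, : min(2, df.shape[1])].copy()
        sub.columns = [f"axis{i + 1}" for i in range(sub.shape[1])]
        sub.insert(0, "label", sub.index)
        sub.insert(0, "entity", kind)
        frames.append(sub.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(outdir / f"rlq_scores{tag}.csv", index=False)
    contrib = inertia_contributions(res, n_axes=min(2, res.n_axes))
    corr = pd.concat(
        [
            res.metric_axis_corr.assign(kind="metric", contribution=contrib["metric_total"]),
            res.trait_axis_corr.assign(kind="trait", contribution=contrib["trait_total"]),
        ]
    )
    corr.index.name = "variable"
    corr.to_csv(outdir / f"rlq_correlations{tag}.csv")


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": {},
    }
    t_start = time.perf_counter()

    grids, tables = _stage("load", manifest, _load_inputs, config)
    if tables.dropped_species:
        logger.warning("species dropped for zero cover: %s", tables.dropped_species)

    if grids is not None:
        patches = [p for g in grids for p in label_patches(g)]
        pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in patches],
                "species": [p.species_code for p in patches],
                "area_cm2": [p.area for p in patches],
                "perimeter_cm": [p.perimeter for p in patches],
                "shape_index": [p.shape_index for p in patches],
            }
        ).to_csv(outdir / "patches.csv", index=False)
        pm = plot_metrics_table(grids)
        pm.to_csv(outdir / "plot_metrics.csv")
        species_metrics(patches, n_plots=len(grids)).to_csv(outdir / "species_metrics.csv")
    else:
        tables.R[list(tables.R.columns)].to_csv(outdir / "plot_metrics.csv")

    clusters = _stage(
        "cluster", manifest, cluster_releves, tables.L, config.k_clusters, config.ward_variant
    )
    clusters.assignment.rename_axis("plot_id").to_csv(outdir / "clusters.csv")

    anova_rows = []
    groupings = {"cluster": clusters.assignment}
    if tables.covariates is not None:
        for cov in config.covariates:
            groupings[cov] = tables.class_labels(cov)
    for gname, glabels in groupings.items():
        for metric in tables.R.columns:
            res = anova_oneway(
                tables.R[metric], glabels.loc[tables.R.index], response=metric, grouping=gname
            )
            row = {"response": metric, "grouping": gname, "F": res.F, "p": res.p}
            for grp, stats_row in res.group_means.iterrows():
                row[f"mean_{grp}"] = stats_row["mean"]
                row[f"ci_low_{grp}"] = stats_row["ci_low"]
                row[f"ci_high_{grp}"] = stats_row["ci_high"]
            anova_rows.append(row)
    pd.DataFrame(anova_rows).to_csv(outdir / "anova.csv", index=False)

    basic = _stage("rlq", manifest, rlq, tables)
    _write_rlq(basic, outdir)
    if tables.covariates is not None:
        for cov in config.covariates:
            part = _stage(f"partial_rlq_{cov}", manifest, partial_rlq, tables, cov)
            _write_rlq(part, outdir, suffix=cov)

    fc = _stage(
        "fourthcorner",
        manifest,
        combined_test,
        tables,
        n_perm=config.n_permutations,
        seed=config.seed,
        alphas=tuple(config.alphas),
        fdr=config.fdr,
    )
    fc.summary_table().to_csv(outdir / "fourthcorner.csv", index=False)
    axes = _stage(
        "axes_association",
        manifest,
        axes_association_test,
        tables,
        basic,
        n_perm=config.n_permutations,
        seed=config.seed + 1,
    )
    axes.to_csv(outdir / "axes_association.csv")

    manifest["wall_seconds"] = round(time.perf_counter() - t_start, 3)
    manifest["global_p_LR"] = fc.global_model2.p
    manifest["global_p_LQ"] = fc.global_model4.p
    manifest["total_coinertia"] = basic.total_inertia
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
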