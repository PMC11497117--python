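"""Tabular/geometric I/O, pipeline configuration and the end-to-end runner.

All tables are comma-separated UTF-8 CSV with a header and '.' decimal;
coordinates are μm and densities cells/mm^2 throughout.  File writes are
atomic (write to a temp file in the target directory, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import neighborhoods, phenotyping, sumap, survival, synthetic_data

_pkg_version = "0.1.0"

REQUIRED_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um")


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_csv(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_cell_table(path):
    """Read and validate a cell-table CSV.

    Requires cell_id, sample_id, x_um, y_um and at least one marker column.
    Returns ``(cells, report)`` where ``report`` lists missing values,
    duplicate ids and non-finite coordinates.  A missing required column
    raises; duplicate cell ids raise (they break every downstream join).
    """
    cells = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    markers = [
        c
        for c in cells.columns
        if c not in REQUIRED_COLUMNS
        and c not in ("region", "true_phenotype", "phenotype")
        and not c.startswith("level_")
        and pd.api.types.is_numeric_dtype(cells[c])
    ]
    if not markers:
        raise ValueError(f"no marker intensity columns found in {path}")
    report = {"n_cells": len(cells), "markers": markers, "issues": []}
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id values: {dup.unique()[:5].tolist()}")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        report["issues"].append(
            {"kind": "non_finite_coordinates",
             "cells": cells.loc[bad, "cell_id"].tolist()}
        )
    for m in markers:
        n_missing = int(cells[m].isna().sum())
        if n_missing:
            report["issues"].append(
                {"kind": "missing_values", "column": m, "n": n_missing}
            )
    return cells, report


def read_geo_series_matrix(path) -> tuple:
    """Minimal reader for a GEO series-matrix text file.

    Returns ``(expression, metadata)``: a genes/probes x samples float
    DataFrame and a characteristics DataFrame (one row per sample).  Only
    the plain-text, uncompressed format is supported.
    """
    meta_rows = {}
    table_lines = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                vals = [v.strip('"') for v in vals]
                meta_rows.setdefault(key.lstrip("!"), []).append(vals)
    from io import StringIO

    expr = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    expr = expr.set_index(expr.columns[0])
    expr.columns = [c.strip('"') for c in expr.columns]
    expr.index = [str(i).strip('"') for i in expr.index]
    meta = {}
    for key, rows in meta_rows.items():
        for i, vals in enumerate(rows):
            name = key if i == 0 else f"{key}.{i}"
            meta[name] = vals
    metadata = pd.DataFrame(meta)
    return expr.astype(float), metadata


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full run."""

    out_dir: str = "run"
    seed: int = 0
    # cohort simulation (used when no cell table is supplied)
    n_deceased: int = 5
    n_alive: int = 5
    # phenotyping
    quantile_thresholds: tuple = (0.5, 0.75, 0.9)
    use_canonical_rule: bool = True
    # census
    bin_edges_um: tuple = neighborhoods.DEFAULT_EDGES_UM
    edge_policy: str = "flag"
    # embedding / histogram / clustering
    n_neighbors: int = 30
    min_dist: float = 0.1
    grid_bins: int = 100
    log_ratio_threshold: float = 0.01
    k_min: int = 2
    k_max: int = 10
    restarts: int = 10
    ratio_floor: float = 1.0
    # survival
    horizon_years: float = 5.0

    def validate(self):
        if self.k_max < self.k_min:
            raise ValueError("k_max < k_min")
        if self.edge_policy not in ("keep", "flag", "exclude"):
            raise ValueError(f"bad edge_policy {self.edge_policy!r}")
        if self.log_ratio_threshold <= 0:
            raise ValueError("log_ratio_threshold must be > 0")
        return self

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("quantile_thresholds", "bin_edges_um"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload).validate()


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    cells: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Execute phenotype -> census -> niche discovery -> survival.

    If no cell table is given, a synthetic cohort is simulated first.
    Writes profiles, embedding, cluster report and survival results under
    ``config.out_dir`` together with a manifest of seeds/parameters, and
    returns the result dictionary.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # label which stage failed
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    if cells is None:
        cells, meta, _ = synthetic_data.simulate_cohort(
            config.n_deceased, config.n_alive, seed=config.seed
        )

    def _phenotype():
        rule = (
            synthetic_data.canonical_rule()
            if config.use_canonical_rule
            else phenotyping.QuantizationRule.from_quantiles(
                cells, quantiles=config.quantile_thresholds
            )
        )
        return phenotyping.phenotype_cells(cells, rule), rule

    phenotyped, rule = stage("phenotype")(_phenotype)

    bins = neighborhoods.DistanceBins(tuple(config.bin_edges_um))
    profiles = stage("census")(
        lambda: neighborhoods.profiles_for_cohort(
            phenotyped, bins, config.edge_policy
        )
    )
    prof_cols = neighborhoods.profile_columns(bins)
    write_csv(profiles, os.path.join(config.out_dir, "profiles.csv"))

    group_of = dict(zip(meta["sample_id"], meta["group"]))
    groups = profiles["sample_id"].map(group_of).to_numpy()
    X = profiles[prof_cols].to_numpy(float)

    emb = stage("embed")(
        lambda: sumap.embed_profiles(
            X,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            seed=config.seed,
        )
    )
    hist = sumap.group_histograms(emb.coords, groups, config.grid_bins)
    fld = sumap.log_ratio_field(hist, threshold=config.log_ratio_threshold)
    dec_idx, alv_idx = sumap.prevalence_cells(fld, emb.coords, groups)

    clusters = {}
    for gname, idx in (("deceased", dec_idx), ("alive", alv_idx)):
        cs = stage(f"kmeans_{gname}")(
            lambda idx=idx, gname=gname: sumap.adaptive_kmeans(
                emb.coords[idx],
                k_range=range(config.k_min, config.k_max + 1),
                seed=config.seed,
                restarts=config.restarts,
                group=gname,
            )
        )
        cs.cell_index = idx
        sumap.characterize(cs, X[idx], int((groups == gname).sum()))
        clusters[gname] = cs

    ratios = {
        name: survival.cohort_ratios(phenotyped, name, pseudocount=1.0)
        for name in ("nos2s", "cox2")
    }
    surv_results = {}
    for name, r in ratios.items():
        try:
            res = survival.ratio_survival(
                r, meta, horizon_years=config.horizon_years
            )
            surv_results[name] = {
                "hr": res.hr, "ci": [res.ci_low, res.ci_high],
                "chi_square": res.chi_square, "p": res.p_value,
            }
        except ValueError as exc:
            surv_results[name] = {"error": str(exc)}

    embedding_df = pd.DataFrame(
        {
            "cell_id": profiles["cell_id"],
            "sample_id": profiles["sample_id"],
            "group": groups,
            "umap_x": emb.coords[:, 0],
            "umap_y": emb.coords[:, 1],
        }
    )
    write_csv(embedding_df, os.path.join(config.out_dir, "embedding.csv"))

    report = {
        "clusters": {
            g: {
                "k": cs.k,
                "davies_bouldin": cs.davies_bouldin,
                "db_per_k": cs.db_per_k,
                "names": cs.names,
                "sizes": np.bincount(cs.labels, minlength=cs.k).tolist(),
                "prevalence": cs.prevalence.tolist(),
                "mean_profiles": cs.mean_profiles.tolist(),
                "sem_profiles": cs.sem_profiles.tolist(),
            }
            for g, cs in clusters.items()
        },
        "survival": surv_results,
    }
    write_json(report, os.path.join(config.out_dir, "report.json"))

    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "rule_thresholds": {m: list(t) for m, t in rule.thresholds.items()},
        "n_cells": len(cells),
        "cells_digest": _digest(cells),
        "sample_seeds": meta["seed"].tolist() if "seed" in meta else None,
    }
    write_json(manifest, os.path.join(config.out_dir, "manifest.json"))

    return {
        "cells": phenotyped,
        "meta": meta,
        "profiles": profiles,
        "embedding": emb,
        "field": fld,
        "clusters": clusters,
        "survival": surv_results,
        "manifest": manifest,
    }
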