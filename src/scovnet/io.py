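"""Reading and writing cohorts, specs, networks and comparison reports.

File layout: a cohort is a values CSV (first column ``subject_id``, one
column per atlas region) plus a covariates CSV (``subject_id, age, sex,
tiv``). Generating specs round-trip through YAML; comparison results are
written as tidy CSV tables with a run-metadata YAML recording every seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .atlas import load_atlas
from .network import DensityGrid
from .synthetic import GroundTruthSpec, MorphometryCohort

__all__ = [
    "read_cohort",
    "write_cohort",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_report",
]

_TOPOLOGIES = {
    "watts_strogatz": synthetic.WattsStrogatz,
    "erdos_renyi": synthetic.ErdosRenyi,
    "lattice": synthetic.RingLattice,
    "hub_spoke": synthetic.HubSpoke,
    "modular_bridge": synthetic.ModularBridge,
    "custom": synthetic.CustomAdjacency,
}


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row + 2}, "
                f"column {col!r}"
            )


def read_cohort(
    values_path: str | Path,
    covariates_path: str | Path,
    atlas: pd.DataFrame | None = None,
    group_label: str = "group",
) -> MorphometryCohort:
    """Load and validate a cohort, canonicalizing region order to the atlas.

    Region columns may appear in any order; subjects are aligned between the
    two files by ``subject_id``. Sex must already be encoded 0/1 — any other
    coding is refused rather than guessed.
    """
    vals = _read_table(values_path)
    cov = _read_table(covariates_path)
    if "subject_id" not in vals.columns or "subject_id" not in cov.columns:
        raise ValueError("both files need a 'subject_id' column")
    vals = vals.set_index("subject_id")
    cov = cov.set_index("subject_id")

    if atlas is None and vals.shape[1] == 90:
        atlas = load_atlas()
    if atlas is not None:
        known = list(atlas["abbreviation"])
        unknown = [c for c in vals.columns if c not in known]
        if unknown:
            raise ValueError(f"{values_path}: unknown region columns {unknown}")
        missing = [c for c in known if c not in vals.columns]
        if missing:
            raise ValueError(f"{values_path}: missing region columns {missing}")
        vals = vals[known]

    missing_subj = [s for s in vals.index if s not in cov.index]
    if missing_subj:
        raise ValueError(
            f"{covariates_path}: no covariates for subjects {missing_subj}"
        )
    cov = cov.loc[vals.index]

    _check_numeric(vals, values_path)
    need = ["age", "sex", "tiv"]
    miss = [c for c in need if c not in cov.columns]
    if miss:
        raise ValueError(f"{covariates_path}: missing covariate columns {miss}")
    cov = cov[need]
    _check_numeric(cov, covariates_path)
    sex = cov["sex"].to_numpy(dtype=float)
    if not np.isin(sex, [0.0, 1.0]).all():
        raise ValueError(
            f"{covariates_path}: sex must be encoded 0/1 "
            f"(found values {sorted(set(sex))}); re-encode explicitly"
        )
    return MorphometryCohort(
        group_label=group_label,
        values=vals.to_numpy(dtype=float),
        covariates=cov.astype(float),
        region_names=list(vals.columns),
    )


def write_cohort(cohort: MorphometryCohort, out_dir: str | Path, prefix: str = "cohort"):
    """Write values and covariates CSVs; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vals = pd.DataFrame(
        cohort.values, columns=cohort.region_names, index=cohort.covariates.index
    )
    vals.index.name = "subject_id"
    cov = cohort.covariates.copy()
    cov.index.name = "subject_id"
    vpath = out / f"{prefix}_values.csv"
    cpath = out / f"{prefix}_covariates.csv"
    vals.to_csv(vpath)
    cov.to_csv(cpath)
    return vpath, cpath


# ---------------------------------------------------------------------------
# Spec YAML
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: GroundTruthSpec, path: str | Path) -> None:
    topo = spec.topology
    kind = next(k for k, cls in _TOPOLOGIES.items() if isinstance(topo, cls))
    doc = dataclasses.asdict(spec)
    doc["covariate_effects"] = list(spec.covariate_effects)
    doc["topology"] = {"kind": kind, **dataclasses.asdict(topo)}
    if kind == "custom":
        doc["topology"]["adjacency"] = [
            list(row) for row in np.asarray(topo.adjacency)
        ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def spec_from_yaml(path: str | Path) -> GroundTruthSpec:
    doc = yaml.safe_load(Path(path).read_text())
    topo_doc = dict(doc.pop("topology"))
    kind = topo_doc.pop("kind")
    cls = _TOPOLOGIES[kind]
    if kind == "custom":
        topo = synthetic.CustomAdjacency.from_array(np.asarray(topo_doc["adjacency"]))
    else:
        topo = cls(**topo_doc)
    doc["covariate_effects"] = tuple(doc["covariate_effects"])
    return GroundTruthSpec(topology=topo, **doc)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _grid_to_str(grid: DensityGrid) -> str:
    return f"{grid.start}:{grid.step}:{grid.stop}"


def write_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write comparison results as tidy CSVs plus a run-metadata YAML.

    ``results`` may hold: 'global' (GlobalComparison), 'nodal'
    (PermutationResult, table), 'resilience' ((PermutationResult, meta)
    per strategy), and 'config' (PermutationConfig). Written tables
    re-parse to the in-memory values exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cfg = results.get("config")
    meta: dict = {"tables": []}
    if cfg is not None:
        meta["config"] = {
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
            "densities": _grid_to_str(cfg.densities),
            "n_nulls": cfg.n_nulls,
            "edge_rank": cfg.edge_rank,
            "n_orders": cfg.n_orders,
            "attack_recompute": cfg.attack_recompute,
            "seed": cfg.seed,
        }

    gc = results.get("global")
    if gc is not None:
        rows = []
        for m, res in gc.per_density.items():
            for k, d in enumerate(res.points):
                rows.append(
                    dict(
                        metric=m,
                        density=float(d),
                        value_a=float(gc.curves_a[m][k]),
                        value_b=float(gc.curves_b[m][k]),
                        observed_diff=float(res.observed_diff[k]),
                        null_mean=float(res.null_mean[k]),
                        null_lo=float(res.null_lo[k]),
                        null_hi=float(res.null_hi[k]),
                        critical_value=float(res.critical_value[k]),
                        p_value=float(res.p_value[k]),
                        significant=bool(res.significant[k]),
                    )
                )
        path = out / "global_metrics_by_density.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        auc_rows = [
            dict(
                metric=m,
                auc_a=r.auc_a,
                auc_b=r.auc_b,
                diff=r.diff,
                critical_value=r.critical_value,
                p_value=r.p_value,
                significant=r.significant,
            )
            for m, r in gc.auc.items()
        ]
        path = out / "auc.csv"
        pd.DataFrame(auc_rows).to_csv(path, index=False)
        written.append(path)

    nodal = results.get("nodal")
    if nodal is not None:
        _, table = nodal
        path = out / "nodal_betweenness.csv"
        table.to_csv(path, index=False)
        written.append(path)

    resil = results.get("resilience")
    if resil is not None:
        rows = []
        for strategy, (res, rmeta) in resil.items():
            meta.setdefault("resilience", {})[strategy] = {
                "reference_density": float(rmeta["reference_density"])
            }
            for k in range(len(res.points)):
                rows.append(
                    dict(
                        strategy=strategy,
                        n_removed=int(res.points[k]),
                        rel_gcc_a=float(rmeta["curve_a"][k]),
                        rel_gcc_b=float(rmeta["curve_b"][k]),
                        observed_diff=float(res.observed_diff[k]),
                        null_lo=float(res.null_lo[k]),
                        null_hi=float(res.null_hi[k]),
                        p_value=float(res.p_value[k]),
                        significant=bool(res.significant[k]),
                    )
                )
        path = out / "resilience.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)

    meta["tables"] = [p.name for p in written]
    meta_path = out / "run_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(meta_path)
    return written
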