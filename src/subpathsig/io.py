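"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are TSV with the gene id in the first column; survival
tables are TSV indexed by ``sample_id`` with ``time`` and ``event`` columns;
gene sets travel as GMT (set id, parent/description, tab-separated genes);
pathway graphs as two-column edge lists (TSV or SIF); drug and response
tables as TSV.  A YAML manifest ties a simulated or assembled study together
(cohort names, file paths, platform tags, training/test split).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import Cohort, DataError, FeatureSet, LEVELS, PATHWAY, SUBPATHWAY
from .pathways import PathwayGraph
from .simulate import SyntheticCohortBundle


# --- expression / survival -------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate gene ids")
    return df


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    return df


# --- gene sets (GMT) -------------------------------------------------------

def write_gmt(features: list[FeatureSet], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            desc = f.parent or f.level
            fh.write("\t".join([f.id, desc, *sorted(f.genes)]) + "\n")


def read_gmt(path) -> list[FeatureSet]:
    out: list[FeatureSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: GMT lines need id, description, >=1 gene")
            fid, desc, *genes = parts
            if desc in LEVELS:
                level, parent = desc, ""
            else:
                level = SUBPATHWAY if "_" in fid.split(":")[-1] else PATHWAY
                parent = desc
            out.append(FeatureSet(id=fid, level=level, genes=frozenset(genes), parent=parent))
    return out


# --- pathway graphs --------------------------------------------------------

def read_edge_list(path, pathway_id: str | None = None) -> PathwayGraph:
    """Two-column TSV edge list, or SIF (node, interaction, node...)."""
    path = Path(path)
    pid = pathway_id or path.stem
    edges: list = []
    nodes: list = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if path.suffix == ".sif":
                if len(parts) < 3:
                    raise DataError(f"{path}:{ln}: SIF needs source, interaction, target")
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                if len(parts) == 1:
                    nodes.append(parts[0])  # isolated node
                else:
                    edges.append((parts[0], parts[1]))
    return PathwayGraph(pid, edges, nodes=nodes)


def write_edge_list(graph: PathwayGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.graph.edges):
            fh.write(f"{u}\t{v}\n")
        for node in sorted(n for n in graph.graph.nodes if graph.graph.degree(n) == 0):
            fh.write(f"{node}\n")


# --- bundle round trip ------------------------------------------------------

def write_bundle(bundle: SyntheticCohortBundle, out_dir) -> Path:
    """Write a synthetic study to disk; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "n_training": bundle.config.n_training,
        "feature_sets": "feature_sets.gmt",
        "drug_table": "drug_table.tsv",
        "response_table": "response_table.tsv",
        "pathway_edges": {},
        "cohorts": [],
    }
    for cohort in bundle.cohorts:
        e = f"{cohort.name}_expression.tsv"
        s = f"{cohort.name}_survival.tsv"
        write_expression(cohort.expression, out / e)
        write_survival(cohort.survival, out / s)
        manifest["cohorts"].append(
            {"name": cohort.name, "platform": cohort.platform, "expression": e, "survival": s}
        )
    write_gmt(bundle.feature_sets, out / "feature_sets.gmt")
    for g in bundle.pathway_graphs:
        fname = f"{g.id.replace(':', '_')}.edges.tsv"
        write_edge_list(g, out / fname)
        manifest["pathway_edges"][g.id] = fname
    bundle.drug_table.to_csv(out / "drug_table.tsv", sep="\t")
    bundle.response_table.to_csv(out / "response_table.tsv", sep="\t")
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_manifest(manifest_path) -> dict:
    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    base = mpath.parent
    cohorts = []
    for c in manifest["cohorts"]:
        expr_path = base / c["expression"]
        surv_path = base / c["survival"]
        if not expr_path.exists():
            raise DataError(f"missing cohort file: {expr_path}")
        if not surv_path.exists():
            raise DataError(f"missing cohort file: {surv_path}")
        cohorts.append(
            Cohort(
                name=c["name"],
                expression=read_expression(expr_path),
                survival=read_survival(surv_path),
                platform=c.get("platform", "microarray"),
            )
        )
    features = read_gmt(base / manifest["feature_sets"])
    out = {
        "cohorts": cohorts,
        "feature_sets": features,
        "n_training": int(manifest["n_training"]),
    }
    if manifest.get("drug_table"):
        out["drug_table"] = pd.read_csv(base / manifest["drug_table"], sep="\t", index_col=0)
    if manifest.get("response_table"):
        out["response_table"] = pd.read_csv(
            base / manifest["response_table"], sep="\t", index_col=0
        )
    return out
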