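"""TSV dialects for corpora, matrices and result tables.

All numeric output is TSV with 6 significant digits, ``.`` decimal
separator and LF endings; every writer round-trips through its reader.

Corpus dialects:

* ``long_tsv`` — one row per (assay, gene) measurement with columns
  ``assay_id project_id species tissue disease is_tumour gene log2fc``;
  missing measurements are simply absent rows.
* ``atlas_wide`` — the bulk-download layout of Expression Atlas
  differential-expression tables: one file per project with a ``Gene Name``
  column and one ``<assay_id>.log2foldchange`` column per contrast, empty
  cells meaning missing; project metadata comes from a sidecar TSV with
  columns ``project_id species tissue disease is_tumour``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chemocoex._util import fmt6
from chemocoex.clustering import ClusterAssignment
from chemocoex.filtering import ExpressionMatrix
from chemocoex.relatedness import RelatednessSummary
from chemocoex.simulate import AssayRecord, Corpus

LONG_COLUMNS = [
    "assay_id",
    "project_id",
    "species",
    "tissue",
    "disease",
    "is_tumour",
    "gene",
    "log2fc",
]


class ParseError(ValueError):
    pass


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the long TSV dialect (one row per measurement)."""
    lines = ["\t".join(LONG_COLUMNS)]
    for a in corpus.assays:
        base = f"{a.assay_id}\t{a.project_id}\t{a.species}\t{a.tissue}\t{a.disease}\t{int(a.is_tumour)}"
        for g in sorted(a.measurements):
            lines.append(f"{base}\t{g}\t{a.measurements[g]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus(path: str | Path, dialect: str = "long_tsv", metadata: str | Path | None = None) -> Corpus:
    """Read a corpus file; ``dialect`` is ``long_tsv`` or ``atlas_wide``."""
    if dialect == "long_tsv":
        return _read_long(Path(path))
    if dialect == "atlas_wide":
        if metadata is None:
            raise ParseError("atlas_wide dialect requires a project metadata sidecar TSV")
        return _read_atlas_wide(Path(path), Path(metadata))
    raise ParseError(f"unknown corpus dialect {dialect!r}")


def _read_long(path: Path) -> Corpus:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LONG_COLUMNS:
            raise ParseError(f"{path}:1: bad corpus header {header}")
        assays: dict[str, dict] = {}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(LONG_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(LONG_COLUMNS)} fields, got {len(f)}")
            assay_id, project_id, species, tissue, disease, is_tum, gene, val = f
            rec = assays.setdefault(
                assay_id,
                {
                    "project_id": project_id,
                    "species": species,
                    "tissue": tissue,
                    "disease": disease,
                    "is_tumour": is_tum not in ("0", "false", "False", ""),
                    "measurements": {},
                },
            )
            if gene in rec["measurements"]:
                raise ParseError(f"{path}:{lineno}: duplicate measurement for ({assay_id}, {gene})")
            try:
                rec["measurements"][gene] = float(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad log2fc value {val!r}") from exc
    if not assays:
        raise ParseError(f"corpus file {path} contains no measurements")
    records = tuple(
        AssayRecord(assay_id=aid, **{k: v for k, v in rec.items()}) for aid, rec in assays.items()
    )
    return Corpus(assays=records)


def _read_atlas_wide(path: Path, metadata: Path) -> Corpus:
    meta = pd.read_csv(metadata, sep="\t", dtype=str)
    required = {"project_id", "species", "tissue", "disease", "is_tumour"}
    if not required.issubset(meta.columns):
        raise ParseError(f"metadata sidecar missing columns {sorted(required - set(meta.columns))}")
    table = pd.read_csv(path, sep="\t", dtype={"Gene Name": str})
    if "Gene Name" not in table.columns:
        raise ParseError(f"{path}: atlas_wide file lacks a 'Gene Name' column")
    if table["Gene Name"].duplicated().any():
        dup = table.loc[table["Gene Name"].duplicated(), "Gene Name"].iloc[0]
        raise ParseError(f"{path}: duplicate gene row {dup!r}")
    fc_cols = [c for c in table.columns if c.endswith(".log2foldchange")]
    if not fc_cols:
        raise ParseError(f"{path}: no '<assay_id>.log2foldchange' columns found")
    project_id = path.stem
    row = meta[meta["project_id"] == project_id]
    if row.empty:
        raise ParseError(f"project {project_id!r} absent from metadata sidecar")
    info = row.iloc[0]
    records = []
    for col in fc_cols:
        assay_id = col[: -len(".log2foldchange")]
        vals = pd.to_numeric(table[col], errors="coerce")
        measurements = {
            str(g): float(v) for g, v in zip(table["Gene Name"], vals) if pd.notna(v)
        }
        records.append(
            AssayRecord(
                assay_id=f"{project_id}.{assay_id}",
                project_id=project_id,
                species=str(info["species"]),
                tissue=str(info["tissue"]),
                disease=str(info["disease"]),
                is_tumour=str(info["is_tumour"]).lower() in ("1", "true", "yes"),
                measurements=measurements,
            )
        )
    return Corpus(assays=tuple(records))


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Wide matrix TSV: first column ``gene``, missing cells empty."""
    v = matrix.values
    lines = ["gene\t" + "\t".join(str(c) for c in v.columns)]
    for g in v.index:
        cells = ["" if np.isnan(x) else fmt6(x) for x in v.loc[g].to_numpy()]
        lines.append(str(g) + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path: str | Path, assay_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    v = pd.read_csv(path, sep="\t", index_col="gene")
    if assay_meta is None:
        assay_meta = pd.DataFrame(index=v.columns)
    return ExpressionMatrix(values=v, assay_meta=assay_meta.loc[v.columns])


def write_correlation(corr: pd.DataFrame, path: str | Path) -> None:
    """Square correlation TSV with gene header row/column, 6 significant digits."""
    lines = ["gene\t" + "\t".join(str(g) for g in corr.columns)]
    for g in corr.index:
        lines.append(str(g) + "\t" + "\t".join(fmt6(x) for x in corr.loc[g].to_numpy()))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_correlation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_clusters(assignment: ClusterAssignment, path: str | Path) -> None:
    lines = ["gene\tcluster\tis_medoid"]
    medoids = set(assignment.medoids)
    for item, lab in zip(assignment.items, assignment.labels):
        lines.append(f"{item}\t{int(lab)}\t{int(item in medoids)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_silhouette_table(table: pd.DataFrame, path: str | Path) -> None:
    lines = ["k\tmean_silhouette"]
    for _, row in table.iterrows():
        lines.append(f"{int(row['k'])}\t{fmt6(row['mean_silhouette'])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_relatedness(summaries: list[RelatednessSummary], path: str | Path) -> None:
    lines = ["family\tn_ligand_pairs\tn_ligand_receptor_pairs\tmean_ligand_ligand\tmean_ligand_receptor\tdifference"]
    for s in summaries:
        lines.append(
            f"{s.family}\t{len(s.ligand_ligand)}\t{len(s.ligand_receptor)}\t"
            f"{fmt6(s.mean_ligand_ligand)}\t{fmt6(s.mean_ligand_receptor)}\t{fmt6(s.difference)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
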