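"""Readers and writers for the flat tab-delimited formats the pipeline uses.

The dialect is deliberately rigid: tab-separated, UTF-8, no quoting, matching
TCGA-style flat exports. Readers validate and reject rather than coerce.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    TargetEdgeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Edge labels used in SIF-like output: "cerna" lncRNA-mRNA pair edges,
# "coexp" correlation edges, "targets" miRNA->gene edges.
INTERACTION_LABELS = ("cerna", "coexp", "targets")


def read_expression_matrix(path, role: str, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found (malformed header?)")
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene id(s) {dups}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        values[col] = converted
    return ExpressionMatrix(values, role=role, unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_table(path) -> ClinicalTable:
    """Read the per-sample clinical TSV.

    Required columns: sample_id, patient_id, condition, pair_id, tnm_stage,
    survival_time, event. Empty cells mean missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str,
                                            "condition": str, "pair_id": str,
                                            "tnm_stage": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing clinical columns {missing}")
    df["survival_time"] = pd.to_numeric(df["survival_time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    return ClinicalTable(df[list(CLINICAL_COLUMNS)])


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_target_edges(path) -> TargetEdgeTable:
    """Read a two-column (mirna_id, target_id) TSV; duplicates are dropped."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty target edge file", path)
        return TargetEdgeTable(pd.DataFrame(columns=["mirna_id", "target_id"]))
    if df.shape[1] != 2:
        raise ValidationError(
            f"{path}: expected 2 columns (mirna_id, target_id), got {df.shape[1]}"
        )
    df.columns = ["mirna_id", "target_id"]
    if df.isna().any().any():
        raise ValidationError(f"{path}: empty id cell in target edge table")
    table = TargetEdgeTable.from_edges(df)
    if table.n_duplicates_dropped:
        logger.info(
            "%s: dropped %d duplicate target edges", path, table.n_duplicates_dropped
        )
    if len(table) == 0:
        logger.warning("%s: target edge table is empty", path)
    return table


def write_target_edges(table: TargetEdgeTable, path) -> None:
    table.data.sort_values(["mirna_id", "target_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(network: nx.Graph, path) -> None:
    """Write a SIF-like (source, interaction, target) TSV.

    Edges need an ``interaction`` attribute; rows are emitted in lexicographic
    order with each undirected edge's endpoints sorted, so rewriting the same
    network is byte-identical.
    """
    rows = []
    for u, v, attrs in network.edges(data=True):
        interaction = attrs.get("interaction", "edge")
        if interaction == "targets":  # directed miRNA->gene, keep orientation
            rows.append((str(u), interaction, str(v)))
        else:
            a, b = sorted((str(u), str(v)))
            rows.append((a, interaction, b))
    rows.sort()
    df = pd.DataFrame(rows, columns=["source", "interaction", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["source", "interaction", "target"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member ids."""
    sets: dict = {}
    descriptions: dict = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r has duplicate members; deduplicated", path, lineno, name
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            desc = collection.descriptions.get(name, "")
            fh.write(f"{name}\t{desc}\t{members}\n")
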