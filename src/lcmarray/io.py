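"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tab-separated expression matrices and sample metadata, GMT gene-set
collections, FASTA promoter sets, a minimal probability-matrix motif format,
JSON result bundles and newick dendrograms.  Readers validate and reject
malformed input rather than silently coercing it; every writer produces a
file its paired reader accepts.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
MOTIF_ROW_TOL = 1e-6


class FormatError(ValidationError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix / sample annotation TSV


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene x sample TSV: header of sample ids, first column gene ids."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id(s): {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample id(s): {dup[:5]}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise FormatError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        df[col] = converted
    return ExpressionMatrix(df.astype(float))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    # repr-roundtrip float format so read(write(m)) == m exactly
    df = matrix.data.copy()
    df.index.name = "gene"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(str(s) for s in matrix.sample_ids) + "\n")
        values = matrix.values
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in values[i])
            fh.write(f"{gene}\t{row}\n")


def read_annotation_tsv(path) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return SampleAnnotation(df)


def write_annotation_tsv(annotation: SampleAnnotation, path) -> None:
    df = annotation.table.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict:
    """Read a GMT file into {term id: (description, set of gene ids)}."""
    path = Path(path)
    collection: dict = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene "
                    f"(got {len(fields)} fields)"
                )
            term, description, *genes = fields
            if term in collection:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            collection[term] = (description, set(genes))
    if n_lines == 0:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return collection


def write_gmt(collection: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in collection:
            entry = collection[term]
            if isinstance(entry, tuple):
                description, genes = entry
            else:
                description, genes = "", entry
            fh.write("\t".join([str(term), str(description), *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# FASTA promoters


def read_fasta(path) -> dict:
    """Read promoter sequences into {record id: uppercase sequence}.

    Sequences are validated against the alphabet A/C/G/T/N.
    """
    path = Path(path)
    promoters: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(seq) if b in bad)
            raise FormatError(
                f"{path}: record {record.id!r} has illegal character "
                f"{seq[pos]!r} at position {pos}"
            )
        if record.id in promoters:
            raise FormatError(f"{path}: duplicate record id {record.id!r}")
        promoters[record.id] = seq
    return promoters


def write_fasta(promoters: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(gene), description="") for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Motif matrices (minimal MEME-like text: "MOTIF <id>" then rows "A C G T")


def read_motifs(path) -> list:
    """Read motifs into a list of dicts {id, matrix (L x 4 probabilities)}.

    Rows are probabilities over A, C, G, T; rows not summing to 1 within
    tolerance are renormalized with a warning, zero rows are an error.
    """
    from .motifs import MotifMatrix  # local import to avoid cycle

    path = Path(path)
    motifs = []
    current_id = None
    rows: list = []

    def flush():
        nonlocal rows, current_id
        if current_id is None:
            return
        if not rows:
            raise FormatError(f"{path}: motif {current_id!r} has no matrix rows")
        matrix = np.array(rows, dtype=float)
        motifs.append(MotifMatrix(id=current_id, matrix=matrix))
        rows = []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("MOTIF"):
                flush()
                parts = line.split(maxsplit=1)
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: MOTIF line missing id")
                current_id = parts[1].strip()
                continue
            if current_id is None:
                raise FormatError(f"{path}:{lineno}: matrix row before any MOTIF header")
            values = line.split()
            if len(values) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 probabilities (A C G T), got {len(values)}"
                )
            try:
                row = [float(v) for v in values]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric probability") from exc
            total = sum(row)
            if total <= 0:
                raise FormatError(f"{path}:{lineno}: motif row sums to {total}")
            if abs(total - 1.0) > MOTIF_ROW_TOL:
                logger.warning(
                    "%s:%d: motif row sums to %.6g, renormalizing", path, lineno, total
                )
                row = [v / total for v in row]
            if any(v < 0 for v in row):
                raise FormatError(f"{path}:{lineno}: negative probability")
            rows.append(row)
    flush()
    return motifs


def write_motifs(motifs: Sequence, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# motif probability matrices: columns A C G T\n")
        for motif in motifs:
            fh.write(f"MOTIF {motif.id}\n")
            for row in motif.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# JSON and newick


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Convert a scipy linkage matrix to a newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(linkage_matrix, rd=False)

    def build(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        if parent_height is None:
            return f"({left},{right});"
        return f"({left},{right}):{length:.10g}"

    return build(tree, None)


def write_newick(linkage_matrix: np.ndarray, labels: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(linkage_to_newick(linkage_matrix, labels) + "\n")
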