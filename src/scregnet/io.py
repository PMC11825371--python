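"""Readers and writers for every on-disk format the pipeline touches.

Formats: Matrix-Market (.mtx) with sidecar row/column id files, TSV matrices
with header, BED3/BED4, edge-list TSV, gene/cell annotation TSV, GWAS TSV,
FASTA (via Biopython) and JASPAR-style PWM text (via Bio.motifs).

All readers return the containers in :mod:`scregnet.types`; coordinates are
0-based half-open internally. ``read_bed``/``read_gene_annotation`` accept a
``one_based=True`` flag for 1-based inclusive dialects and convert at this
boundary.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AccessibilityMatrix,
    CellAnnotation,
    EdgeTable,
    ExpressionMatrix,
    GeneAnnotation,
    GWASSummary,
    LabeledMatrix,
    MotifLibrary,
    RegionSet,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_bed",
    "write_bed",
    "read_edge_table",
    "write_edge_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_cell_annotation",
    "write_cell_annotation",
    "read_gwas",
    "write_gwas",
    "read_fasta",
    "write_fasta",
    "read_motifs",
    "write_motifs",
]


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def read_matrix(path, format: str | None = None, kind: type[LabeledMatrix] = ExpressionMatrix):
    """Read a labeled matrix from ``.mtx`` (+ sidecar id files) or TSV.

    TSV layout: header row of sample ids, first column of row ids. Matrix-
    Market inputs keep sparse storage when density < 0.3, else densify.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        rows_path, cols_path = _sidecars(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar id file {p} for {path}")
        values = scipy.io.mmread(path)
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        if values.shape[0] != len(row_ids):
            raise ValueError(
                f"{path}: {values.shape[0]} matrix rows but {len(row_ids)} ids in {rows_path}"
            )
        if values.shape[1] != len(col_ids):
            raise ValueError(
                f"{path}: {values.shape[1]} matrix columns but {len(col_ids)} ids in {cols_path}"
            )
        density = values.nnz / max(1, values.shape[0] * values.shape[1])
        if density >= LabeledMatrix.SPARSE_DENSITY:
            values = np.asarray(values.todense())
        return kind(values, row_ids, col_ids)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return kind(df.to_numpy(dtype=float), df.index.astype(str), df.columns.astype(str))
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(matrix: LabeledMatrix, path, format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        rows_path, cols_path = _sidecars(path)
        values = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.to_dense())
        scipy.io.mmwrite(path, values)
        rows_path.write_text("\n".join(matrix.row_ids) + "\n")
        cols_path.write_text("\n".join(matrix.col_ids) + "\n")
    elif format == "tsv":
        pd.DataFrame(matrix.to_dense(), index=matrix.row_ids, columns=matrix.col_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return path


def read_bed(path, one_based: bool = False) -> RegionSet:
    """Read BED3/BED4; re_id synthesized as chrom:start-end when absent."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if one_based:
                start -= 1  # 1-based inclusive -> 0-based half-open
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            re_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            rows.append((re_id, chrom, start, end))
    return RegionSet(pd.DataFrame(rows, columns=["re_id", "chrom", "start", "end"]))


def write_bed(regions: RegionSet, path) -> Path:
    path = Path(path)
    regions.table[["chrom", "start", "end", "re_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


def write_edge_table(edges: EdgeTable, path) -> Path:
    """Edge-list TSV with header source/target/score/context, sorted rows."""
    path = Path(path)
    out = edges.table.sort_values(["source", "target", "context"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_edge_table(path) -> EdgeTable:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "context": str})
    df["context"] = df["context"].fillna("")
    return EdgeTable(df)


def read_gene_annotation(path, one_based: bool = False) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    if one_based:
        df = df.assign(tss=df["tss"] - 1)
    return GeneAnnotation(df)


def write_gene_annotation(genes: GeneAnnotation, path) -> Path:
    path = Path(path)
    genes.table.to_csv(path, sep="\t", index=False)
    return path


def read_cell_annotation(path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_cell_annotation(cells: CellAnnotation, path) -> Path:
    path = Path(path)
    cells.table.to_csv(path, sep="\t", index=False)
    return path


def read_gwas(path) -> GWASSummary:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return GWASSummary(df)


def write_gwas(gwas: GWASSummary, path) -> Path:
    path = Path(path)
    gwas.table.to_csv(path, sep="\t", index=False)
    return path


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_motifs(pwm_path, pairs_path=None) -> MotifLibrary:
    """Read JASPAR-format PWMs plus an optional tf_id/motif_id pairing TSV."""
    with open(pwm_path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    pwms = {}
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        colsum = counts.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError(f"motif {m.matrix_id or m.name}: zero column in matrix")
        pwms[m.matrix_id or m.name] = counts / colsum
    pairs = []
    if pairs_path is not None:
        df = pd.read_csv(pairs_path, sep="\t", dtype=str)
        pairs = list(df[["tf_id", "motif_id"]].itertuples(index=False, name=None))
    return MotifLibrary(pwms, pairs)


def write_motifs(library: MotifLibrary, pwm_path, pairs_path=None) -> Path:
    pwm_path = Path(pwm_path)
    with open(pwm_path, "w") as fh:
        for mid, pwm in library.pwms.items():
            fh.write(f">{mid}\t{mid}\n")
            for base, row in zip("ACGT", pwm):
                vals = " ".join(format(v, ".17g") for v in row)
                fh.write(f"{base} [ {vals} ]\n")
    if pairs_path is not None:
        pd.DataFrame(library.tf_motif_pairs, columns=["tf_id", "motif_id"]).to_csv(
            pairs_path, sep="\t", index=False
        )
    return pwm_path
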