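"""Core domain containers shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED-native). Any 1-based
input dialect is converted at the I/O boundary, never inside the library.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneAnnotation",
    "RegionSet",
    "LabeledMatrix",
    "ExpressionMatrix",
    "AccessibilityMatrix",
    "CellAnnotation",
    "MotifLibrary",
    "GWASSummary",
    "EdgeTable",
]

BASES = "ACGT"


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class GeneAnnotation:
    """Gene/TSS table: gene_id, chrom, tss (0-based bp), strand in {+,-}."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns {sorted(missing)}")
        _check_unique(self.table["gene_id"], "gene_id")
        if (self.table["tss"] < 0).any():
            raise ValueError("negative TSS coordinate")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {self.table.loc[bad, 'strand'].unique()}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_spans(cls, gene_id, chrom, start, end, strand) -> "GeneAnnotation":
        """Build from gene spans; TSS = start for '+' genes, end-1 for '-'."""
        start = np.asarray(start, dtype=int)
        end = np.asarray(end, dtype=int)
        strand = np.asarray(strand)
        tss = np.where(strand == "+", start, end - 1)
        return cls(pd.DataFrame({"gene_id": gene_id, "chrom": chrom, "tss": tss, "strand": strand}))

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RegionSet:
    """Regulatory-element intervals, 0-based half-open, unique re_id."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"re_id", "chrom", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"region set missing columns {sorted(missing)}")
        _check_unique(self.table["re_id"], "re_id")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            raise ValueError(
                f"start >= end for regions {self.table.loc[bad, 're_id'].tolist()[:5]}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def re_ids(self) -> list[str]:
        return self.table["re_id"].tolist()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.table["start"] + self.table["end"]) // 2).to_numpy()

    def sorted_index(self) -> np.ndarray:
        """Row order sorted by (chrom, start); the table itself keeps input order."""
        return np.lexsort((self.table["start"].to_numpy(), self.table["chrom"].to_numpy()))

    def __len__(self) -> int:
        return len(self.table)


class LabeledMatrix:
    """Dense or sparse 2-D matrix with row/column string ids.

    Values are nonnegative reals with no NaN. Sparse storage (CSR) is kept
    when density < ``SPARSE_DENSITY``; all math contracts are dense.
    """

    SPARSE_DENSITY = 0.3

    def __init__(self, values, row_ids, col_ids):
        self.row_ids = list(map(str, row_ids))
        self.col_ids = list(map(str, col_ids))
        _check_unique(self.row_ids, "row id")
        _check_unique(self.col_ids, "column id")
        if sp.issparse(values):
            values = values.tocsr()
            data = values.data
        else:
            values = np.asarray(values, dtype=float)
            if values.ndim != 2:
                raise ValueError("matrix must be 2-D")
            data = values
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match id counts "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        if np.isnan(data).any():
            raise ValueError("matrix contains NaN")
        self.values = values
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}

    @property
    def shape(self):
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def row(self, row_id: str) -> np.ndarray:
        i = self._row_index[row_id]
        v = self.values[i]
        return np.asarray(v.todense()).ravel() if sp.issparse(v) else np.asarray(v).ravel()

    def subset_rows(self, ids) -> "LabeledMatrix":
        idx = [self._row_index[i] for i in ids]
        return type(self)(self.to_dense()[idx], list(ids), self.col_ids)

    def subset_cols(self, ids) -> "LabeledMatrix":
        pos = {c: i for i, c in enumerate(self.col_ids)}
        idx = [pos[i] for i in ids]
        return type(self)(self.to_dense()[:, idx], self.row_ids, list(ids))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabeledMatrix)
            and self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.allclose(self.to_dense(), other.to_dense(), atol=1e-12, rtol=0)
        )


class ExpressionMatrix(LabeledMatrix):
    """Genes x samples expression (counts or normalized), rows = gene_id."""


class AccessibilityMatrix(LabeledMatrix):
    """REs x samples chromatin accessibility, rows = re_id."""


@dataclass
class CellAnnotation:
    """cell_id -> cell_type mapping; every declared type has >= 1 cell."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"cell_id", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cell annotation missing columns {sorted(missing)}")
        _check_unique(self.table["cell_id"], "cell_id")
        self.table = self.table.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def cells_of_type(self, cell_type: str) -> list[str]:
        sub = self.table[self.table["cell_type"] == cell_type]
        if sub.empty:
            raise ValueError(f"cell type {cell_type!r} has no cells")
        return sub["cell_id"].tolist()


@dataclass
class MotifLibrary:
    """PWMs (4 x L probability matrices, rows A,C,G,T) plus TF<->motif pairs."""

    pwms: dict[str, np.ndarray]
    tf_motif_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for mid, pwm in self.pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            if pwm.shape[0] != 4:
                raise ValueError(f"PWM {mid} must have 4 rows (A,C,G,T)")
            if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError(f"PWM {mid} columns do not sum to 1")
            self.pwms[mid] = pwm
        for tf, mid in self.tf_motif_pairs:
            if mid not in self.pwms:
                raise ValueError(f"pair ({tf}, {mid}) references unknown motif")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.pwms)

    def motifs_of_tf(self, tf_id: str) -> list[str]:
        return [m for t, m in self.tf_motif_pairs if t == tf_id]

    @property
    def tf_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tf, _ in self.tf_motif_pairs:
            seen.setdefault(tf)
        return list(seen)


@dataclass
class GWASSummary:
    """GWAS summary statistics: snp_id, chrom, pos (0-based bp), pvalue."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"snp_id", "chrom", "pos", "pvalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table missing columns {sorted(missing)}")
        if (self.table["pos"] < 0).any():
            raise ValueError("negative SNP position")
        p = self.table["pvalue"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must be in (0, 1]")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EdgeTable:
    """Directed scored edges with an optional context (cell type / cell id)."""

    table: pd.DataFrame

    COLUMNS = ["source", "target", "score", "context"]

    def __post_init__(self):
        if self.table.empty and not set(self.COLUMNS) <= set(self.table.columns):
            self.table = pd.DataFrame(columns=self.COLUMNS)
        missing = {"source", "target", "score"} - set(self.table.columns)
        if missing:
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        if "context" not in self.table.columns:
            self.table = self.table.assign(context="")
        self.table = self.table[self.COLUMNS].reset_index(drop=True)
        key = self.table[["source", "target", "context"]]
        if key.duplicated().any():
            raise ValueError("duplicate (source, target, context) edges")

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, source_ids, target_ids, context: str = "") -> "EdgeTable":
        matrix = np.asarray(matrix)
        src, tgt = np.meshgrid(np.arange(len(source_ids)), np.arange(len(target_ids)), indexing="ij")
        return cls(
            pd.DataFrame(
                {
                    "source": np.asarray(source_ids)[src.ravel()],
                    "target": np.asarray(target_ids)[tgt.ravel()],
                    "score": matrix.ravel(),
                    "context": context,
                }
            )
        )

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeTable):
            return NotImplemented
        a = self.table.sort_values(["source", "target", "context"]).reset_index(drop=True)
        b = other.table.sort_values(["source", "target", "context"]).reset_index(drop=True)
        if not (a[["source", "target", "context"]].equals(b[["source", "target", "context"]])):
            return False
        return bool(np.allclose(a["score"], b["score"], atol=1e-12, rtol=0))
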