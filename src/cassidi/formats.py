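"""Readers and writers for count matrices, marker tables, CSS matrices and
ranked grid results.

Count matrices use the 10x triplet layout (``matrix.mtx`` / ``features.tsv`` /
``barcodes.tsv``, each optionally gzipped), genes x cells, integer counts.
Marker tables follow the Seurat export dialect: TSV with columns ``gene``,
``cluster``, ``avg_logFC`` (natural log), ``pct.1``, ``pct.2``, ``p_val``,
``p_val_adj``.  The schema check is strict because the downstream similarity
weights consume exactly these fields; a log2 column (``avg_log2FC``) is
rejected rather than silently mis-scaled.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = [
    "CountMatrix",
    "MarkerRecord",
    "MarkerTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_marker_table",
    "write_marker_table",
    "write_css_matrix",
    "read_css_matrix",
    "write_ranked_table",
    "read_ranked_table",
    "format_cluster_label",
]

#: default retention thresholds for marker records
P_ADJ_THRESHOLD = 0.05


@dataclass
class CountMatrix:
    """A genes x cells raw count matrix with row/column identifiers."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix  # genes x cells, non-negative integers
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"format error: matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("format error: duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("format error: duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("format error: negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class MarkerRecord:
    """One positive-marker candidate for one cluster.

    ``avg_log_fc`` is the natural-log fold change of the cluster's mean
    (de-logged normalized) expression over the background; ``pct_in`` and
    ``pct_bg`` are the expressing-cell fractions inside the cluster and in
    the background population.
    """

    gene: str
    cluster: str
    avg_log_fc: float
    pct_in: float
    pct_bg: float
    p_val: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_in <= 1.0 and 0.0 <= self.pct_bg <= 1.0):
            raise ValueError(
                f"value error: pct values must lie in [0, 1] "
                f"(gene {self.gene}: pct_in={self.pct_in}, pct_bg={self.pct_bg})"
            )
        if not (0.0 <= self.p_adj <= 1.0):
            raise ValueError(f"value error: p_adj outside [0, 1] for gene {self.gene}")


@dataclass
class MarkerTable:
    """Per-cluster marker records for one clustering run.

    ``cluster_labels`` lists every cluster of the clustering, including those
    left with no retained marker.  When ``retained_only`` is set, every record
    satisfies p_adj <= 0.05 and avg_log_fc > 0.
    """

    run_id: str
    records: list[MarkerRecord]
    cluster_labels: list[str] = field(default_factory=list)
    retained_only: bool = False

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(r.cluster for r in self.records))
        if not self.cluster_labels:
            self.cluster_labels = sorted(seen)
        else:
            missing = set(seen) - set(self.cluster_labels)
            if missing:
                raise ValueError(f"value error: records reference unknown clusters {sorted(missing)}")
        if self.retained_only:
            for r in self.records:
                if r.p_adj > P_ADJ_THRESHOLD or r.avg_log_fc <= 0:
                    raise ValueError(
                        f"value error: retained_only table contains non-retained record "
                        f"({r.gene}, cluster {r.cluster})"
                    )

    def by_cluster(self) -> dict[str, list[MarkerRecord]]:
        out: dict[str, list[MarkerRecord]] = {c: [] for c in self.cluster_labels}
        for r in self.records:
            out[r.cluster].append(r)
        return out

    def gene_sets(self) -> dict[str, set[str]]:
        return {c: {r.gene for r in recs} for c, recs in self.by_cluster().items()}

    def filtered(self, p_threshold: float = P_ADJ_THRESHOLD, positive_only: bool = True) -> "MarkerTable":
        keep = [
            r
            for r in self.records
            if r.p_adj <= p_threshold and (not positive_only or r.avg_log_fc > 0)
        ]
        return MarkerTable(
            run_id=self.run_id,
            records=keep,
            cluster_labels=list(self.cluster_labels),
            retained_only=positive_only and p_threshold <= P_ADJ_THRESHOLD,
        )


# ---------------------------------------------------------------------------
# 10x triplet I/O


def _open_member(directory: Path, stem: str) -> IO[bytes]:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return gzip.open(p, "rb") if name.endswith(".gz") else open(p, "rb")
    raise FormatError(f"format error: missing member {stem}[.gz] in {directory}")


def _read_tsv_column(handle: IO[bytes], column: int = 0) -> list[str]:
    out = []
    for line in handle:
        text = line.decode().rstrip("\n")
        if not text:
            continue
        out.append(text.split("\t")[column])
    return out


def _dedupe(ids: Sequence[str], what: str) -> list[str]:
    counts: dict[str, int] = {}
    out = []
    n_dup = 0
    for x in ids:
        if x in counts:
            counts[x] += 1
            out.append(f"{x}.{counts[x]}")
            n_dup += 1
        else:
            counts[x] = 0
            out.append(x)
    if n_dup:
        warnings.warn(f"{n_dup} duplicate {what} ids deduplicated by suffixing", stacklevel=3)
    return out


def read_count_matrix(path: str | Path, dataset_id: str | None = None) -> CountMatrix:
    """Read a 10x triplet directory (``matrix.mtx``, ``features.tsv``,
    ``barcodes.tsv``, optionally gzipped) into a :class:`CountMatrix`."""
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"format error: {directory} is not a directory")
    with _open_member(directory, "matrix.mtx") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("format error: matrix.mtx contains non-integer values")
    counts = sp.csr_matrix(
        (np.asarray(np.round(mat.data), dtype=np.int64), (mat.row, mat.col)), shape=mat.shape
    )
    with _open_member(directory, "features.tsv") as fh:
        genes = _read_tsv_column(fh)
    with _open_member(directory, "barcodes.tsv") as fh:
        cells = _read_tsv_column(fh)
    genes = _dedupe(genes, "gene")
    cells = _dedupe(cells, "cell")
    return CountMatrix(
        gene_ids=genes,
        cell_ids=cells,
        counts=counts,
        dataset_id=dataset_id if dataset_id is not None else directory.name,
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a :class:`CountMatrix` as an uncompressed 10x triplet directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer")
    (directory / "features.tsv").write_text("".join(g + "\n" for g in matrix.gene_ids))
    (directory / "barcodes.tsv").write_text("".join(c + "\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# marker tables

_REQUIRED_MARKER_COLUMNS = ("gene", "cluster", "avg_logFC", "pct.1", "pct.2", "p_val_adj")


def read_marker_table(
    path: str | Path,
    p_threshold: float = P_ADJ_THRESHOLD,
    positive_only: bool = True,
    run_id: str | None = None,
) -> MarkerTable:
    """Read a Seurat-dialect marker TSV, applying the retention filter.

    Rows with ``p_val_adj`` above ``p_threshold`` — and, when
    ``positive_only``, rows with non-positive ``avg_logFC`` — are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "avg_log2FC" in df.columns and "avg_logFC" not in df.columns:
        raise FormatError(
            "format error: column avg_log2FC found; this reader expects the "
            "natural-log dialect column avg_logFC"
        )
    missing = [c for c in _REQUIRED_MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"format error: marker table missing required columns {missing}")
    for col in ("pct.1", "pct.2"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"value error: column {col} has values outside [0, 1]")
    cluster_labels = sorted(df["cluster"].astype(str).unique())
    keep = df["p_val_adj"] <= p_threshold
    if positive_only:
        keep &= df["avg_logFC"] > 0
    df = df[keep]
    records = [
        MarkerRecord(
            gene=str(r["gene"]),
            cluster=str(r["cluster"]),
            avg_log_fc=float(r["avg_logFC"]),
            pct_in=float(r["pct.1"]),
            pct_bg=float(r["pct.2"]),
            p_val=float(r.get("p_val", np.nan)),
            p_adj=float(r["p_val_adj"]),
        )
        for _, r in df.iterrows()
    ]
    return MarkerTable(
        run_id=run_id if run_id is not None else path.stem,
        records=records,
        cluster_labels=cluster_labels,
        retained_only=positive_only and p_threshold <= P_ADJ_THRESHOLD,
    )


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in table.records],
            "cluster": [format_cluster_label(r.cluster, table.cluster_labels) for r in table.records],
            "avg_logFC": [r.avg_log_fc for r in table.records],
            "pct.1": [r.pct_in for r in table.records],
            "pct.2": [r.pct_bg for r in table.records],
            "p_val": [r.p_val for r in table.records],
            "p_val_adj": [r.p_adj for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# CSS matrices and ranked tables


def format_cluster_label(label: str, all_labels: Iterable[str]) -> str:
    """Zero-pad purely numeric labels to a common width for stable ordering."""
    labels = list(all_labels)
    if all(l.isdigit() for l in labels):
        width = max(len(l) for l in labels)
        return str(label).zfill(width)
    return str(label)


def write_css_matrix(matrix, path: str | Path) -> None:
    """Write a CSS matrix as CSV with row/column cluster labels."""
    rows = [format_cluster_label(l, matrix.row_labels) for l in matrix.row_labels]
    cols = [format_cluster_label(l, matrix.col_labels) for l in matrix.col_labels]
    df = pd.DataFrame(matrix.values, index=rows, columns=cols)
    df.to_csv(path, float_format="%.15g", index_label="cluster")


def read_css_matrix(path: str | Path):
    from .similarity import CSSMatrix

    df = pd.read_csv(path, dtype={"cluster": str}).set_index("cluster")
    return CSSMatrix(
        row_labels=[str(x) for x in df.index],
        col_labels=[str(x) for x in df.columns],
        values=df.to_numpy(dtype=float),
    )


_RANKED_COLUMNS = ["rank", "res", "npcs", "di", "m_clusters", "n_clusters"]


def write_ranked_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked parameter table (columns rank, res, npcs, di,
    m_clusters, n_clusters) as CSV."""
    missing = [c for c in _RANKED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"value error: ranked table missing columns {missing}")
    table[_RANKED_COLUMNS].to_csv(path, index=False, float_format="%.15g")


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
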