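"""Preprocessing, graph clustering and positive-marker detection.

One dataset at a time: library-size normalization to 10,000 counts/cell,
log1p, highly-variable-gene selection, capped z-scaling, PCA, shared
nearest-neighbor graph, and modularity-based (Leiden) community detection at
a given resolution.  The two datasets of a comparison are always clustered
separately — never merged, never batch-corrected — which is what makes the
post-hoc similarity matching meaningful.

Marker detection is a two-sided Wilcoxon rank-sum test per gene (cluster vs
all other cells of the same dataset) on log-normalized expression, with
Benjamini-Hochberg adjustment across the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .formats import CountMatrix, MarkerRecord, MarkerTable

__all__ = [
    "ParameterPair",
    "ClusteringRun",
    "preprocess_and_cluster",
    "find_markers",
    "markers_for_clustering",
    "run_grid_cell",
    "derive_cell_seed",
]

NORMALIZATION_TARGET = 1e4
N_TOP_GENES = 2000
SCALE_CAP = 10.0
N_NEIGHBORS = 20
MIN_CELLS = 50
DEFAULT_MIN_PCT = 0.1
DEFAULT_MIN_LOGFC = 0.25


@dataclass(frozen=True)
class ParameterPair:
    """A (clustering resolution, number of principal components) pair."""

    res: float
    n_pcs: int

    def __post_init__(self) -> None:
        if not self.res > 0:
            raise ParameterError(f"parameter error: res must be > 0, got {self.res}")
        if self.n_pcs < 2:
            raise ParameterError(f"parameter error: n_pcs must be >= 2, got {self.n_pcs}")


@dataclass
class ClusteringRun:
    """Labels and retained markers for one dataset at one parameter pair."""

    dataset_id: str
    params: ParameterPair
    cell_ids: list[str]
    labels: np.ndarray  # per-cell cluster label, string dtype
    markers: MarkerTable
    seed: int


def _normalize_log1p(counts: sp.csr_matrix) -> sp.csr_matrix:
    """Library-size normalize cells to a fixed total and apply log1p.

    Input and output are genes x cells.
    """
    totals = np.asarray(counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    scale = sp.diags(NORMALIZATION_TARGET / totals)
    out = (counts @ scale).tocsr()
    out.data = np.log1p(out.data)
    return out


def preprocess_and_cluster(
    counts: CountMatrix,
    params: ParameterPair,
    seed: int,
    *,
    n_top_genes: int = N_TOP_GENES,
    n_neighbors: int = N_NEIGHBORS,
) -> tuple[np.ndarray, list[str]]:
    """Cluster one count matrix; returns (labels, retained cell ids).

    All-zero cells are dropped with a warning.  Deterministic for a fixed
    (counts, params, seed).
    """
    import scanpy as sc
    import anndata as ad

    nonzero = np.asarray(counts.counts.sum(axis=0)).ravel() > 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero cells", stacklevel=2)
    cell_ids = [c for c, keep in zip(counts.cell_ids, nonzero) if keep]
    X = counts.counts[:, nonzero].T.tocsr().astype(np.float32)  # cells x genes

    n_cells, n_genes = X.shape
    if n_cells < MIN_CELLS:
        raise ParameterError(
            f"parameter error: need at least {MIN_CELLS} cells, got {n_cells}"
        )
    if params.n_pcs >= min(n_genes, n_cells):
        raise ParameterError(
            f"parameter error: n_pcs={params.n_pcs} must be < min(#genes, #cells)="
            f"{min(n_genes, n_cells)}"
        )

    adata = ad.AnnData(X=X)
    adata.obs_names = cell_ids
    adata.var_names = counts.gene_ids
    sc.pp.normalize_total(adata, target_sum=NORMALIZATION_TARGET)
    sc.pp.log1p(adata)
    n_hvg = min(n_top_genes, n_genes)
    if n_hvg < n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
        adata = adata[:, adata.var["highly_variable"]].copy()
    if params.n_pcs >= adata.n_vars:
        raise ParameterError(
            f"parameter error: n_pcs={params.n_pcs} >= {adata.n_vars} variable genes"
        )
    with warnings.catch_warnings():
        # zero-centering densifies the matrix; expected at these sizes
        warnings.filterwarnings("ignore", message=".*densifies.*", category=UserWarning)
        sc.pp.scale(adata, max_value=SCALE_CAP)
    sc.tl.pca(adata, n_comps=params.n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(
        adata,
        n_neighbors=min(n_neighbors, n_cells - 1),
        n_pcs=params.n_pcs,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=params.res,
            random_state=seed,
            flavor="leidenalg",
            key_added="cluster",
        )
    labels = adata.obs["cluster"].astype(str).to_numpy()
    return labels, cell_ids


def _rank_sum_pvalues(expr: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per gene (columns of ``expr``).

    Tie-corrected normal approximation, no continuity correction.
    """
    n1 = int(in_cluster.sum())
    n2 = expr.shape[0] - n1
    N = n1 + n2
    pvals = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        col = expr[:, j]
        ranks = scipy.stats.rankdata(col)
        r1 = ranks[in_cluster].sum()
        _, tie_counts = np.unique(col, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
        if var <= 0:
            pvals[j] = 1.0
            continue
        z = (r1 - n1 * (N + 1) / 2.0) / np.sqrt(var)
        pvals[j] = 2.0 * scipy.stats.norm.sf(abs(z))
    return pvals


def find_markers(
    counts: CountMatrix,
    labels: np.ndarray,
    cluster: str,
    min_pct: float = DEFAULT_MIN_PCT,
    min_logfc: float = DEFAULT_MIN_LOGFC,
) -> list[MarkerRecord]:
    """Candidate markers of ``cluster`` against all other cells.

    Only genes with max(pct_in, pct_bg) >= min_pct and avg_log_fc >= min_logfc
    are tested; BH adjustment runs over the tested genes only.  Returned
    records are sorted by adjusted p, then by decreasing fold change.
    """
    labels = np.asarray(labels, dtype=str)
    if len(labels) != counts.n_cells:
        raise ValueError("value error: labels length does not match cell count")
    in_cluster = labels == str(cluster)
    if not in_cluster.any():
        raise KeyError(f"key error: cluster {cluster!r} not present in labels")
    if in_cluster.sum() < 3:
        raise ParameterError("parameter error: cluster has fewer than 3 cells")
    if in_cluster.all():
        raise ParameterError("parameter error: background population is empty")

    norm = _normalize_log1p(counts.counts)  # genes x cells
    raw = counts.counts
    pct_in = np.clip(np.asarray((raw[:, in_cluster] > 0).mean(axis=1)).ravel(), 0.0, 1.0)
    pct_bg = np.clip(np.asarray((raw[:, ~in_cluster] > 0).mean(axis=1)).ravel(), 0.0, 1.0)

    # mean de-logged normalized expression, pseudocount 1, natural log ratio
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)
    mean_in = np.asarray(expm1[:, in_cluster].mean(axis=1)).ravel()
    mean_bg = np.asarray(expm1[:, ~in_cluster].mean(axis=1)).ravel()
    avg_log_fc = np.log((mean_in + 1.0) / (mean_bg + 1.0))

    tested = (np.maximum(pct_in, pct_bg) >= min_pct) & (avg_log_fc >= min_logfc)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return []
    expr = norm[idx, :].T.toarray()  # cells x tested genes, log-normalized
    pvals = _rank_sum_pvalues(expr, in_cluster)
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    records = [
        MarkerRecord(
            gene=counts.gene_ids[g],
            cluster=str(cluster),
            avg_log_fc=float(avg_log_fc[g]),
            pct_in=float(pct_in[g]),
            pct_bg=float(pct_bg[g]),
            p_val=float(pvals[k]),
            p_adj=float(p_adj[k]),
        )
        for k, g in enumerate(idx)
    ]
    records.sort(key=lambda r: (r.p_adj, -r.avg_log_fc, r.gene))
    return records


def markers_for_clustering(
    counts: CountMatrix,
    labels: np.ndarray,
    cell_ids: list[str],
    run_id: str,
    min_pct: float = DEFAULT_MIN_PCT,
    min_logfc: float = DEFAULT_MIN_LOGFC,
) -> MarkerTable:
    """Retained (positive, p_adj <= 0.05) markers for every cluster."""
    keep = [i for i, c in enumerate(counts.cell_ids) if c in set(cell_ids)]
    sub = counts
    if len(keep) != counts.n_cells:
        sub = CountMatrix(
            gene_ids=list(counts.gene_ids),
            cell_ids=[counts.cell_ids[i] for i in keep],
            counts=counts.counts[:, keep],
            dataset_id=counts.dataset_id,
        )
    clusters = sorted(set(np.asarray(labels, dtype=str)))
    records: list[MarkerRecord] = []
    for c in clusters:
        if (np.asarray(labels, dtype=str) == c).sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; no markers tested", stacklevel=2)
            continue
        records.extend(find_markers(sub, labels, c, min_pct=min_pct, min_logfc=min_logfc))
    table = MarkerTable(run_id=run_id, records=records, cluster_labels=clusters)
    return table.filtered()


def derive_cell_seed(base_seed: int, params: ParameterPair, which: int = 0) -> int:
    """Deterministic per-grid-cell seed from (base seed, res, n_pcs)."""
    ss = np.random.SeedSequence(
        entropy=int(base_seed),
        spawn_key=(int(round(params.res * 1_000_000)), int(params.n_pcs), int(which)),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_grid_cell(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    params: ParameterPair,
    seed: int,
    *,
    min_pct: float = DEFAULT_MIN_PCT,
    min_logfc: float = DEFAULT_MIN_LOGFC,
) -> tuple[ClusteringRun, ClusteringRun]:
    """Cluster the two datasets separately at one parameter pair.

    The output for dataset A depends only on (counts_a, params, seed) — the
    content of dataset B cannot influence it.
    """
    runs = []
    cell_seed = derive_cell_seed(seed, params)
    for counts in (counts_a, counts_b):
        labels, cell_ids = preprocess_and_cluster(counts, params, cell_seed)
        run_id = f"{counts.dataset_id}:res={params.res:g},npcs={params.n_pcs}"
        markers = markers_for_clustering(
            counts, labels, cell_ids, run_id, min_pct=min_pct, min_logfc=min_logfc
        )
        runs.append(
            ClusteringRun(
                dataset_id=counts.dataset_id,
                params=params,
                cell_ids=cell_ids,
                labels=labels,
                markers=markers,
                seed=cell_seed,
            )
        )
    return runs[0], runs[1]
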