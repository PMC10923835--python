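"""Cluster similarity scores (CSS) between two independently clustered
datasets.

The basic score is the Jaccard index of two clusters' marker gene sets,

    CSS_basic = C12 / (C12 + U1 + U2),

with C12 shared markers and U1/U2 markers unique to either cluster.  The
enhanced score weights every marker gene by how strongly, widely and
exclusively it marks its cluster:

    w = avgLogFC * pct_in^2 / pct_bg          (expression weight)
    u = 1 - sqrt(L_i / L_n)                   (uniqueness)

where L_i is the number of clusters — across BOTH datasets — for which the
gene is a retained marker and L_n = m + n is the total cluster count.  Then

    CSS_enh = [ sum_shared (w_a + w_b) * u ]
              / [ sum_shared (w_a + w_b) * u + sum_uniq_a w * u + sum_uniq_b w * u ].

Both scores live in [0, 1]; 1 means identical marker profiles, 0 maximally
dissimilar.  0/0 situations (no markers at all, or zero uniqueness
everywhere) score 0, the conservative "most dissimilar" reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError
from .formats import MarkerRecord, MarkerTable

__all__ = [
    "DEFAULT_PCT_FLOOR",
    "UniquenessContext",
    "CSSMatrix",
    "uniqueness_score",
    "marker_weight",
    "css_basic",
    "css_enhanced",
    "build_uniqueness_context",
    "build_css_matrix",
]

logger = logging.getLogger(__name__)

#: floor for the pct_bg division; matches the 3-decimal granularity of
#: exported marker tables, where pct.2 can be rounded to exactly 0.
DEFAULT_PCT_FLOOR = 0.001


def uniqueness_score(l_i: int, l_n: int) -> float:
    """Uniqueness u = 1 - sqrt(L_i / L_n) of a marker gene.

    Strictly decreasing in L_i: a gene marking a single cluster out of many is
    nearly unique (u -> 1), one marking every cluster carries no information
    (u = 0).
    """
    if l_i < 1 or l_i > l_n:
        raise ValueError(f"value error: require 1 <= L_i <= L_n, got L_i={l_i}, L_n={l_n}")
    return 1.0 - math.sqrt(l_i / l_n)


def marker_weight(
    avg_log_fc: float,
    pct_in: float,
    pct_bg: float,
    pct_floor: float = DEFAULT_PCT_FLOOR,
) -> float:
    """Expression weight w = avgLogFC * pct_in^2 / max(pct_bg, pct_floor)."""
    if avg_log_fc <= 0:
        raise ValueError(
            f"value error: marker weight requires avg_log_fc > 0, got {avg_log_fc} "
            "(non-positive markers must be filtered upstream)"
        )
    if not (0.0 <= pct_in <= 1.0 and 0.0 <= pct_bg <= 1.0):
        raise ValueError("value error: pct values must lie in [0, 1]")
    return avg_log_fc * pct_in**2 / max(pct_bg, pct_floor)


def css_basic(markers_a: Iterable[str], markers_b: Iterable[str]) -> float:
    """Jaccard similarity of two marker gene sets; 0/0 scores 0."""
    a, b = set(markers_a), set(markers_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass(frozen=True)
class UniquenessContext:
    """Per-gene cluster counts over the m + n clusters of one comparison."""

    cluster_count_per_gene: Mapping[str, int]
    total_clusters: int

    def __post_init__(self) -> None:
        if self.total_clusters < 2:
            raise ValueError(f"value error: L_n must be >= 2, got {self.total_clusters}")
        for g, l in self.cluster_count_per_gene.items():
            if not (1 <= l <= self.total_clusters):
                raise ValueError(f"value error: L_i={l} out of range for gene {g}")

    def uniqueness(self, gene: str) -> float:
        if gene not in self.cluster_count_per_gene:
            raise ConsistencyError(f"consistency error: gene {gene!r} absent from uniqueness context")
        return uniqueness_score(self.cluster_count_per_gene[gene], self.total_clusters)


def build_uniqueness_context(markers_a: MarkerTable, markers_b: MarkerTable) -> UniquenessContext:
    """L_i / L_n over the combined cluster sets of the two tables.

    A gene's L_i counts the clusters (on either side) for which it is a
    retained marker; L_n is the total number of clusters, m + n.
    """
    counts: dict[str, int] = {}
    for table in (markers_a, markers_b):
        for genes in table.gene_sets().values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
    l_n = len(markers_a.cluster_labels) + len(markers_b.cluster_labels)
    return UniquenessContext(cluster_count_per_gene=counts, total_clusters=l_n)


def css_enhanced(
    markers_a: Sequence[MarkerRecord],
    markers_b: Sequence[MarkerRecord],
    ctx: UniquenessContext,
    pct_floor: float = DEFAULT_PCT_FLOOR,
) -> float:
    """Weighted, uniqueness-aware similarity of two clusters' marker lists.

    Symmetric in (a, b); always in [0, 1]; 0 when the denominator vanishes.
    """
    wa = {r.gene: marker_weight(r.avg_log_fc, r.pct_in, r.pct_bg, pct_floor) for r in markers_a}
    wb = {r.gene: marker_weight(r.avg_log_fc, r.pct_in, r.pct_bg, pct_floor) for r in markers_b}
    shared = wa.keys() & wb.keys()
    numerator = sum((wa[g] + wb[g]) * ctx.uniqueness(g) for g in shared)
    denom = numerator
    denom += sum(wa[g] * ctx.uniqueness(g) for g in wa.keys() - shared)
    denom += sum(wb[g] * ctx.uniqueness(g) for g in wb.keys() - shared)
    if denom == 0.0:
        return 0.0
    return numerator / denom


@dataclass
class CSSMatrix:
    """m x n matrix of enhanced similarity scores between two cluster sets."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    params: object | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("value error: CSS matrix shape does not match labels")
        if self.values.size == 0:
            raise ValueError("value error: CSS matrix must be at least 1x1")

    @property
    def m(self) -> int:
        return len(self.row_labels)

    @property
    def n(self) -> int:
        return len(self.col_labels)


def build_css_matrix(
    markers_a: MarkerTable,
    markers_b: MarkerTable,
    params: object | None = None,
    pct_floor: float = DEFAULT_PCT_FLOOR,
) -> CSSMatrix:
    """Assemble the m x n CSS_enh matrix for one pair of clusterings.

    The uniqueness context is built once over the combined m + n clusters of
    this comparison.  Clusters with no retained marker contribute a zero
    row/column (logged).
    """
    if not (markers_a.retained_only and markers_b.retained_only):
        raise ValueError("value error: both marker tables must be retained_only")
    if not markers_a.cluster_labels or not markers_b.cluster_labels:
        raise ValueError("value error: empty cluster set")
    ctx = build_uniqueness_context(markers_a, markers_b)
    by_a = markers_a.by_cluster()
    by_b = markers_b.by_cluster()
    rows = sorted(markers_a.cluster_labels)
    cols = sorted(markers_b.cluster_labels)
    for side, by in (("A", by_a), ("B", by_b)):
        for c, recs in by.items():
            if not recs:
                logger.warning("cluster %s (dataset %s) has no retained markers; zero row/column", c, side)
    values = np.zeros((len(rows), len(cols)))
    for i, ca in enumerate(rows):
        for j, cb in enumerate(cols):
            values[i, j] = css_enhanced(by_a[ca], by_b[cb], ctx, pct_floor)
    return CSSMatrix(row_labels=rows, col_labels=cols, values=values, params=params)
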