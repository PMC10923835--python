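"""The Nebula plot: a per-gene, four-violin comparison of two clusters.

For every displayed gene there are four violins — the two focal clusters in
the middle and their respective background populations (all other cells of
the same dataset) on the outside.  A diamond marks the average expression
(the same averaging convention as marker detection: natural log of the mean
de-logged normalized expression, plus one), and a top bar shows the fraction
of cluster cells expressing the gene.

Genes are laid out in three blocks: cluster-A-specific markers on the left
in decreasing order of the A diamond, shared markers in the middle ordered
center-out by the mean of the two diamonds (highest mean at the center,
falling off on either side), and cluster-B-specific markers on the right in
increasing order of the B diamond.  "Top" genes within each block are those
with the largest marker weight w = avgLogFC * pct_in^2 / pct_bg (mean of the
two weights for shared genes) — the only ranking-compatible scalar the
similarity framework defines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .formats import CountMatrix, MarkerRecord
from .clustering import _normalize_log1p
from .similarity import DEFAULT_PCT_FLOOR, marker_weight

__all__ = [
    "NebulaGeneEntry",
    "NebulaSpec",
    "select_nebula_genes",
    "center_out_order",
    "prepare_nebula_data",
    "render_nebula",
]

Group = Literal["specific_a", "shared", "specific_b"]


@dataclass
class NebulaGeneEntry:
    gene: str
    group: Group
    dist_a: np.ndarray
    dist_b: np.ndarray
    bg_a: np.ndarray
    bg_b: np.ndarray
    diamond_a: float
    diamond_b: float
    frac_a: float
    frac_b: float


@dataclass
class NebulaSpec:
    entries: list[NebulaGeneEntry]
    cluster_a: str
    cluster_b: str
    color_a: str = "#1f77b4"
    color_b: str = "#ff7f0e"
    color_shared: str = "#7f7f7f"

    @property
    def counts(self) -> tuple[int, int, int]:
        groups = [e.group for e in self.entries]
        return (
            groups.count("specific_a"),
            groups.count("shared"),
            groups.count("specific_b"),
        )


def select_nebula_genes(
    markers_a: Sequence[MarkerRecord],
    markers_b: Sequence[MarkerRecord],
    k_specific: int = 15,
    k_shared: int = 10,
    pct_floor: float = DEFAULT_PCT_FLOOR,
) -> dict[str, list[str]]:
    """Partition the two clusters' markers into specific/shared top genes.

    Specific genes are ranked by their marker weight, shared genes by the
    mean of the two weights.  When a block has fewer candidates than
    requested, all available genes are returned with a warning.
    """
    wa = {r.gene: marker_weight(r.avg_log_fc, r.pct_in, r.pct_bg, pct_floor) for r in markers_a}
    wb = {r.gene: marker_weight(r.avg_log_fc, r.pct_in, r.pct_bg, pct_floor) for r in markers_b}
    shared = wa.keys() & wb.keys()
    only_a = sorted(wa.keys() - shared, key=lambda g: (-wa[g], g))
    only_b = sorted(wb.keys() - shared, key=lambda g: (-wb[g], g))
    both = sorted(shared, key=lambda g: (-(wa[g] + wb[g]) / 2.0, g))
    for name, cands, k in (("specific_a", only_a, k_specific), ("shared", both, k_shared), ("specific_b", only_b, k_specific)):
        if len(cands) < k:
            warnings.warn(f"only {len(cands)} candidate genes for block {name} (requested {k})", stacklevel=2)
    return {
        "specific_a": only_a[:k_specific],
        "shared": both[:k_shared],
        "specific_b": only_b[:k_specific],
    }


def center_out_order(values: Sequence[float]) -> list[int]:
    """Indices arranging ``values`` with the maximum at the center and the
    rest falling off on either side (right first for even-length splits)."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    layout: list[int] = []
    for pos, idx in enumerate(order):
        if pos == 0:
            layout.append(idx)
        elif pos % 2 == 1:
            layout.append(idx)  # place to the right
        else:
            layout.insert(0, idx)  # then to the left
    return layout


def prepare_nebula_data(
    counts: CountMatrix,
    labels: np.ndarray,
    cluster_a: str,
    cluster_b: str,
    partition: dict[str, list[str]],
) -> NebulaSpec:
    """Assemble the per-gene expression samples and ordering for a plot.

    Backgrounds mirror marker detection: all cells of the dataset outside the
    focal cluster.  Expression values are log1p library-size-normalized.
    """
    labels = np.asarray(labels, dtype=str)
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    for block in partition.values():
        for g in block:
            if g not in gene_index:
                raise KeyError(f"key error: gene {g!r} absent from count matrix")
    in_a = labels == str(cluster_a)
    in_b = labels == str(cluster_b)
    if not in_a.any() or not in_b.any():
        raise KeyError("key error: focal cluster has no cells")
    norm = _normalize_log1p(counts.counts)
    raw = counts.counts

    def entry(gene: str, group: Group) -> NebulaGeneEntry:
        gi = gene_index[gene]
        row = np.asarray(norm[gi].todense()).ravel()
        rawrow = np.asarray(raw[gi].todense()).ravel()
        # diamond: same averaging as marker detection (log of de-logged mean + 1)
        d_a = float(np.log(np.expm1(row[in_a]).mean() + 1.0))
        d_b = float(np.log(np.expm1(row[in_b]).mean() + 1.0))
        return NebulaGeneEntry(
            gene=gene,
            group=group,
            dist_a=row[in_a],
            dist_b=row[in_b],
            bg_a=row[~in_a],
            bg_b=row[~in_b],
            diamond_a=d_a,
            diamond_b=d_b,
            frac_a=float((rawrow[in_a] > 0).mean()),
            frac_b=float((rawrow[in_b] > 0).mean()),
        )

    left = [entry(g, "specific_a") for g in partition.get("specific_a", [])]
    mid = [entry(g, "shared") for g in partition.get("shared", [])]
    right = [entry(g, "specific_b") for g in partition.get("specific_b", [])]

    left.sort(key=lambda e: -e.diamond_a)
    right.sort(key=lambda e: e.diamond_b)
    mid = [mid[i] for i in center_out_order([(e.diamond_a + e.diamond_b) / 2.0 for e in mid])]
    return NebulaSpec(entries=left + mid + right, cluster_a=str(cluster_a), cluster_b=str(cluster_b))


def _safe_violin(ax, data: np.ndarray, pos: float, color: str, width: float = 0.8) -> None:
    """Violin that degrades to a flat tick for zero-variance samples (a KDE
    cannot be formed there)."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        return
    if np.ptp(data) == 0:
        ax.plot([pos - width / 4, pos + width / 4], [data[0], data[0]], color=color, lw=1.0)
        return
    parts = ax.violinplot([data], positions=[pos], widths=[width], showextrema=False)
    for body in parts["bodies"]:
        body.set_facecolor(color)
        body.set_alpha(0.6)
        body.set_edgecolor("none")


def render_nebula(spec: NebulaSpec, path, format: str = "svg") -> None:
    """Render a NebulaSpec to a static image (deterministic for a fixed spec)."""
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "nebula"
    from matplotlib.figure import Figure

    n = len(spec.entries)
    if n == 0:
        raise ValueError("value error: empty nebula spec")
    fig = Figure(figsize=(max(6.0, 0.6 * n), 5.0))
    gs = fig.add_gridspec(2, 1, height_ratios=[1, 4], hspace=0.05)
    ax_bar = fig.add_subplot(gs[0])
    ax = fig.add_subplot(gs[1], sharex=ax_bar)

    group_color = {
        "specific_a": spec.color_a,
        "shared": spec.color_shared,
        "specific_b": spec.color_b,
    }
    bg_color = "#c7c7c7"
    step = 4.0
    for i, e in enumerate(spec.entries):
        x0 = i * step
        _safe_violin(ax, e.bg_a, x0 + 0.0, bg_color)
        _safe_violin(ax, e.dist_a, x0 + 1.0, spec.color_a)
        _safe_violin(ax, e.dist_b, x0 + 2.0, spec.color_b)
        _safe_violin(ax, e.bg_b, x0 + 3.0, bg_color)
        ax.plot([x0 + 1.0], [e.diamond_a], marker="D", color="black", ms=4)
        ax.plot([x0 + 2.0], [e.diamond_b], marker="D", color="black", ms=4)
        ax_bar.bar([x0 + 1.0], [e.frac_a], width=0.8, color=spec.color_a)
        ax_bar.bar([x0 + 2.0], [e.frac_b], width=0.8, color=spec.color_b)

    centers = [i * step + 1.5 for i in range(n)]
    ax.set_xticks(centers)
    ax.set_xticklabels(
        [e.gene for e in spec.entries], rotation=90, fontsize=7,
    )
    for tick, e in zip(ax.get_xticklabels(), spec.entries):
        tick.set_color(group_color[e.group])
    ax_bar.set_ylim(0, 1.05)
    ax_bar.set_ylabel("fraction\nexpressing", fontsize=8)
    ax_bar.tick_params(labelbottom=False)
    ax.set_ylabel("log-normalized expression")
    ax.set_title(f"{spec.cluster_a} vs {spec.cluster_b}")
    fig.savefig(path, format=format, metadata={"Date": None} if format == "svg" else None)
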