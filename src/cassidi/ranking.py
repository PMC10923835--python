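"""Distinction indices, parameter grids, and the grid sweep that ranks
(resolution, nPCs) pairs from best to worst.

The distinction index (DI) of a row (or column) of a CSS matrix is the
maximum entry minus the mean of the remaining entries; it is large when one
partner cluster stands out cleanly from the rest.  The matrix-level DI
averages the m row and n column DIs and scores the whole clustering
condition: high values mean crisp one-to-one cluster correspondences plus
well-isolated unique clusters, low values mean smeared or redundant
(over-clustered) matches.

Two normalizations of the matrix-level DI are exposed: the default divides
the summed row and column DIs by m + n (a true mean over the m + n indices);
the alternative divides by m * n.  They disagree whenever m + n != m * n and
can rank conditions differently, so both are selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusteringRun, ParameterPair, run_grid_cell
from .errors import ConsistencyError, ParameterError
from .formats import CountMatrix
from .similarity import CSSMatrix, build_css_matrix

__all__ = [
    "DIDecomposition",
    "ParameterGrid",
    "SweepResult",
    "row_col_distinction",
    "matrix_distinction_index",
    "build_parameter_grid",
    "sweep_and_rank",
    "rank_rows",
    "cross_tabulate_labelings",
]

Normalization = Literal["m_plus_n", "mn"]


@dataclass
class DIDecomposition:
    """Row-wise and column-wise distinction indices of a CSS matrix."""

    row_dis: np.ndarray
    col_dis: np.ndarray
    matrix_di: float | None = None
    normalization: Normalization | None = None


def _axis_distinction(values: np.ndarray) -> np.ndarray:
    """max - mean(rest) per row of ``values``.

    A row of length 1 has no "remaining elements"; its DI is defined as the
    single value itself (mean of the empty rest taken as 0).
    """
    n = values.shape[1]
    if n == 1:
        return values[:, 0].astype(float).copy()
    mx = values.max(axis=1)
    rest_mean = (values.sum(axis=1) - mx) / (n - 1)
    return mx - rest_mean


def row_col_distinction(matrix: CSSMatrix) -> DIDecomposition:
    """Per-row and per-column distinction indices (no matrix-level DI yet)."""
    v = np.asarray(matrix.values, dtype=float)
    if v.size == 0:
        raise ValueError("value error: empty CSS matrix")
    return DIDecomposition(row_dis=_axis_distinction(v), col_dis=_axis_distinction(v.T))


def matrix_distinction_index(
    decomp: DIDecomposition, normalization: Normalization = "m_plus_n"
) -> float:
    """Matrix-level DI: summed row + column DIs over m + n (default) or m * n."""
    total = float(decomp.row_dis.sum() + decomp.col_dis.sum())
    m, n = len(decomp.row_dis), len(decomp.col_dis)
    if normalization == "m_plus_n":
        di = total / (m + n)
    elif normalization == "mn":
        di = total / (m * n)
    else:
        raise ValueError(f"value error: unknown normalization {normalization!r}")
    decomp.matrix_di = di
    decomp.normalization = normalization
    return di


def _axis_values(start: float, stop: float, step: float, integer: bool) -> list:
    if step <= 0:
        raise ParameterError(f"parameter error: step must be positive, got {step}")
    if start > stop:
        raise ParameterError(f"parameter error: start {start} > stop {stop}")
    values = []
    k = 0
    # integer index arithmetic avoids accumulating float error; the 1e-9
    # tolerance keeps the inclusive endpoint (e.g. 2.0 for 0.4:2.0:0.2)
    while True:
        v = start + k * step
        if v > stop + 1e-9:
            break
        values.append(int(round(v)) if integer else round(v, 12))
        k += 1
    return values


@dataclass
class ParameterGrid:
    """The (res, nPCs) search space, with optional extra axes."""

    res_values: list[float]
    npc_values: list[int]
    extra_axes: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vals in [("res", self.res_values), ("npcs", self.npc_values)] + list(
            self.extra_axes.items()
        ):
            if len(set(vals)) != len(vals) or sorted(vals) != list(vals):
                raise ParameterError(f"parameter error: axis {name} must be unique and ascending")

    @property
    def size(self) -> int:
        s = len(self.res_values) * len(self.npc_values)
        for vals in self.extra_axes.values():
            s *= len(vals)
        return s

    def pairs(self) -> list[ParameterPair]:
        return [ParameterPair(res=r, n_pcs=p) for r, p in product(self.res_values, self.npc_values)]

    def cells(self) -> list[tuple]:
        axes = [self.res_values, self.npc_values] + list(self.extra_axes.values())
        return list(product(*axes))


def _parse_spec(spec) -> tuple[float, float, float]:
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ParameterError(f"parameter error: axis spec {spec!r} is not start:stop:step")
        return tuple(float(x) for x in parts)  # type: ignore[return-value]
    start, stop, step = spec
    return float(start), float(stop), float(step)


def build_parameter_grid(res_spec, npc_spec, extra_axes: Mapping[str, Sequence] | None = None) -> ParameterGrid:
    """Build the search grid from inclusive ``start:stop:step`` axis specs.

    The default published search space, res 0.4:2.0:0.2 by nPCs 10:75:5,
    yields 9 x 14 = 126 parameter pairs.
    """
    r0, r1, rs = _parse_spec(res_spec)
    p0, p1, ps = _parse_spec(npc_spec)
    return ParameterGrid(
        res_values=_axis_values(r0, r1, rs, integer=False),
        npc_values=_axis_values(p0, p1, ps, integer=True),
        extra_axes={k: sorted(v) for k, v in (extra_axes or {}).items()},
    )


@dataclass
class SweepResult:
    """Ranked table plus per-cell CSS matrices and clustering runs."""

    ranked: pd.DataFrame
    css_matrices: dict[ParameterPair, CSSMatrix]
    runs: dict[ParameterPair, tuple[ClusteringRun, ClusteringRun]]
    failures: dict[ParameterPair, str]


def sweep_and_rank(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    grid: ParameterGrid,
    seed: int,
    normalization: Normalization = "m_plus_n",
) -> SweepResult:
    """Run every grid cell and rank parameter pairs by descending matrix DI.

    Each cell clusters the two datasets separately with a seed derived from
    (seed, res, nPCs), builds the CSS matrix, and reduces it to a matrix DI.
    Ties are broken by fewer total clusters (anti-over-clustering), then
    lower res, then lower nPCs.  A failing cell is recorded and skipped; the
    sweep does not abort.
    """
    rows = []
    css_matrices: dict[ParameterPair, CSSMatrix] = {}
    runs: dict[ParameterPair, tuple[ClusteringRun, ClusteringRun]] = {}
    failures: dict[ParameterPair, str] = {}
    for params in grid.pairs():
        try:
            run_a, run_b = run_grid_cell(counts_a, counts_b, params, seed)
            css = build_css_matrix(run_a.markers, run_b.markers, params=params)
            di = matrix_distinction_index(row_col_distinction(css), normalization)
        except Exception as exc:  # cell failures are reported, not fatal
            failures[params] = f"{type(exc).__name__}: {exc}"
            rows.append(
                dict(res=params.res, npcs=params.n_pcs, di=np.nan, m_clusters=0, n_clusters=0, status="failed")
            )
            continue
        css_matrices[params] = css
        runs[params] = (run_a, run_b)
        rows.append(
            dict(res=params.res, npcs=params.n_pcs, di=di, m_clusters=css.m, n_clusters=css.n, status="ok")
        )
    df = rank_rows(pd.DataFrame(rows))
    return SweepResult(ranked=df, css_matrices=css_matrices, runs=runs, failures=failures)


def rank_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Sort sweep rows by descending DI and assign contiguous ranks.

    Ties break toward fewer total clusters, then lower res, then lower nPCs;
    failed cells sink to the bottom.
    """
    ok = df["status"] == "ok"
    df = df.copy()
    df["_total"] = df["m_clusters"] + df["n_clusters"]
    df = pd.concat(
        [
            df[ok].sort_values(["di", "_total", "res", "npcs"], ascending=[False, True, True, True]),
            df[~ok].sort_values(["res", "npcs"]),
        ]
    ).drop(columns="_total")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def cross_tabulate_labelings(
    labels_x: Mapping[str, str] | pd.Series,
    labels_y: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Contingency table of two labelings over the same cells.

    Inputs map cell id -> cluster label (dict or Series indexed by cell id).
    Rows are x-clusters, columns y-clusters; row sums equal x-cluster sizes.
    """
    sx = pd.Series(labels_x, dtype=str)
    sy = pd.Series(labels_y, dtype=str)
    if set(sx.index) != set(sy.index):
        raise ConsistencyError("consistency error: the two labelings cover different cells")
    sy = sy.reindex(sx.index)
    table = pd.crosstab(sx, sy)
    table.index.name = "x"
    table.columns.name = "y"
    return table.sort_index(axis=0).sort_index(axis=1)
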