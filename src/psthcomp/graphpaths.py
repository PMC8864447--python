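"""Graph-theoretic component tracking through the intensity-time PSTH grid.

The intensity x time matrix of mean firing rates is turned into a
weighted directed graph: one vertex per (intensity z, time bin t), with
every vertex receiving edges from its grid neighbours at z±1, t±1
(including diagonals).  All edges into a vertex carry the same weight

    w(z, t) = unit max firing rate / vertex mean firing rate,

so high-rate vertices are cheap to enter; zero-rate vertices are floored
at a small rate ``epsilon`` to keep weights finite.  A pseudo start
vertex feeds every lowest-intensity vertex and every highest-intensity
vertex feeds a pseudo goal, so Dijkstra's shortest path from start to
goal traces a contiguous high-rate ridge — a response component —
across all intensities.  Re-weighting all edges into the used vertices
with an arbitrarily large weight and re-running Dijkstra yields the
second and third vertex-disjoint component paths.

Path features: the median time bin of the path, the per-intensity
(median time, mean rate) profile, and the non-stationarity — how far
the component's time shifts across intensities (max - min of the
per-intensity path times, in ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .psth import PSTHMatrix

#: Rate floor (Hz) substituted for zero-rate vertices in the edge weight.
EPSILON_HZ = 1e-3


def _lower_median(values) -> int:
    v = sorted(values)
    return v[(len(v) - 1) // 2]


@dataclass
class ComponentPath:
    """One vertex-disjoint shortest path through the PSTH grid."""

    vertices: list[tuple[int, int]]  # (z, t), start/goal stripped
    total_weight: float
    rank: int
    median_time_bin: int = 0
    per_row: list[tuple[int, int, float]] = field(default_factory=list)  # (z, t, Hz)
    nonstationarity_ms: float = 0.0

    @property
    def row_times(self) -> dict[int, int]:
        return {z: t for z, t, _ in self.per_row}

    @property
    def row_rates(self) -> dict[int, float]:
        return {z: r for z, _, r in self.per_row}


def build_graph(psth: PSTHMatrix, epsilon: float = EPSILON_HZ) -> nx.DiGraph:
    """Build the weighted directed grid graph for one unit's PSTH matrix."""
    if psth.n_intensities < 2 or psth.n_bins < 2:
        raise ValueError("graph analysis needs at least a 2x2 PSTH matrix")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    z_n, b_n = psth.rates.shape
    r_max = float(psth.rates.max())
    g = nx.DiGraph(r_max=r_max, epsilon=epsilon,
                   n_intensities=z_n, n_bins=b_n)
    w = r_max / np.maximum(psth.rates, epsilon) if r_max > 0 else \
        np.ones_like(psth.rates)
    for z in range(1, z_n + 1):
        for t in range(1, b_n + 1):
            g.add_node((z, t), rate=float(psth.rates[z - 1, t - 1]),
                       weight=float(w[z - 1, t - 1]))
    for z in range(1, z_n + 1):
        for t in range(1, b_n + 1):
            wt = g.nodes[(z, t)]["weight"]
            for dz in (-1, 0, 1):
                for dt in (-1, 0, 1):
                    if dz == 0 and dt == 0:
                        continue
                    src = (z + dz, t + dt)
                    if 1 <= src[0] <= z_n and 1 <= src[1] <= b_n:
                        g.add_edge(src, (z, t), weight=wt)
    for t in range(1, b_n + 1):
        g.add_edge("start", (1, t), weight=g.nodes[(1, t)]["weight"])
        g.add_edge((z_n, t), "goal", weight=0.0)
    return g


def k_disjoint_shortest_paths(g: nx.DiGraph, k: int = 3) -> list[ComponentPath]:
    """Up to ``k`` vertex-disjoint shortest start->goal paths.

    Path 1 is Dijkstra's shortest path; before each subsequent run every
    edge into an already-used vertex is re-weighted to W_big (10 x number
    of vertices x the largest finite vertex weight), so later paths avoid
    earlier vertices whenever any disjoint route exists.  A candidate
    whose total weight reaches W_big necessarily re-visits a used vertex,
    meaning the grid is exhausted: it is discarded and the search stops,
    so fewer than ``k`` paths may be returned.  An all-zero unit
    (max rate 0) has no components and returns no paths.
    """
    if g.graph.get("r_max", 0.0) <= 0.0:
        return []
    n_vertices = g.number_of_nodes() - 2
    max_w = max(d["weight"] for _, d in g.nodes(data=True) if isinstance(_, tuple))
    w_big = 10.0 * n_vertices * max_w
    h = g.copy()
    paths: list[ComponentPath] = []
    for rank in range(1, k + 1):
        try:
            total, nodes = nx.single_source_dijkstra(h, "start", "goal",
                                                     weight="weight")
        except nx.NetworkXNoPath:
            break
        if total >= w_big:
            break
        grid_nodes = [v for v in nodes if isinstance(v, tuple)]
        paths.append(ComponentPath(vertices=grid_nodes, total_weight=float(total),
                                   rank=rank))
        for v in grid_nodes:
            for u in list(h.predecessors(v)):
                h[u][v]["weight"] = w_big
    return paths


def path_features(path: ComponentPath, psth: PSTHMatrix) -> ComponentPath:
    """Fill in median time, per-intensity profile and non-stationarity."""
    if not path.vertices:
        raise ValueError("empty path")
    times = [t for _, t in path.vertices]
    path.median_time_bin = _lower_median(times)
    rows: dict[int, list[int]] = {}
    for z, t in path.vertices:
        rows.setdefault(z, []).append(t)
    per_row = []
    for z in sorted(rows):
        t_med = _lower_median(rows[z])
        rate = float(np.mean([psth.rates[z - 1, t - 1] for t in rows[z]]))
        per_row.append((z, t_med, rate))
    path.per_row = per_row
    row_times = [t for _, t, _ in per_row]
    path.nonstationarity_ms = float(max(row_times) - min(row_times))
    return path


def component_paths(psth: PSTHMatrix, k: int = 3,
                    epsilon: float = EPSILON_HZ) -> list[ComponentPath]:
    """Convenience: build the graph, extract paths, compute features."""
    if float(psth.rates.max()) <= 0.0:
        return []
    g = build_graph(psth, epsilon=epsilon)
    return [path_features(p, psth) for p in k_disjoint_shortest_paths(g, k=k)]


def path_rate_correlation(a: ComponentPath, b: ComponentPath):
    """Pearson correlation of two paths' per-intensity mean firing rates.

    Returns ``(r, p, computable)``; two-tailed p.  Paths sharing fewer
    than 3 intensity rows (or with constant rates) are not computable.
    """
    ra, rb = a.row_rates, b.row_rates
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 3:
        return float("nan"), float("nan"), False
    x = np.array([ra[z] for z in shared])
    y = np.array([rb[z] for z in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True
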