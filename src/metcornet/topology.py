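"""Thresholded correlation networks and threshold selection.

A network is built by keeping every metabolite as a node and adding an edge
for each pair whose Spearman r reaches the threshold; by default only
positive correlations become edges (metabolomic correlation networks show
few negative correlations and those are deliberately excluded; a flag
switches to |r| thresholding).

Six graph metrics are computed per threshold over a 0..1 grid in 0.01
steps, for the real data and for randomized datasets in which every
metabolite's values are independently permuted across samples — this
destroys inter-metabolite correlation while preserving each metabolite's
marginal distribution, giving a topology null band.  The working threshold
is selected at the small-to-large transition of the component count: the
smallest grid point at which the randomized nulls are fully fragmented
(chance correlations no longer form edges), falling back to the largest
forward jump of the real component curve when no null band is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from .containers import ProfileMatrix
from .correlation import rho_matrix, spearman_square

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "graph_metrics",
    "GraphMetrics",
    "randomize_profiles",
    "sweep_thresholds",
    "select_threshold",
    "TopologySweep",
]

METRIC_NAMES = (
    "graph_density", "clustering_coefficient", "average_degree",
    "average_path_length", "n_components", "n_edges",
)

DEFAULT_THRESHOLD = 0.5
GRID_STEP = 0.01


def build_network(
    correlations: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    only_positive: bool = True,
) -> nx.Graph:
    """Graph over all metabolites with edges where r passes the threshold.

    ``correlations`` is a long pair table with columns u, v, r.  With
    ``only_positive`` (default) an edge requires ``r >= threshold`` and
    ``r > 0``; otherwise ``|r| >= threshold``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    nodes = sorted(set(correlations["u"]) | set(correlations["v"]))
    g.add_nodes_from(nodes)
    for u, v, r in correlations[["u", "v", "r"]].itertuples(index=False):
        if np.isnan(r) or u == v:
            continue
        keep = (r >= threshold and r > 0) if only_positive else abs(r) >= threshold
        if keep:
            g.add_edge(u, v, r=float(r))
    return g


@dataclass
class GraphMetrics:
    graph_density: float
    clustering_coefficient: float
    average_degree: float
    average_path_length: float
    n_components: int
    n_edges: int

    def as_tuple(self) -> tuple:
        return (self.graph_density, self.clustering_coefficient,
                self.average_degree, self.average_path_length,
                self.n_components, self.n_edges)


def _metrics_from_adjacency(A: np.ndarray) -> GraphMetrics:
    """Six metrics from a boolean adjacency matrix (zero diagonal).

    Distances come from breadth-first expansion by boolean matrix products
    — cheap at the network sizes of metabolite panels (tens to a few
    hundred nodes) and free of per-call sparse-structure overhead.
    """
    A = A.astype(bool)
    N = A.shape[0]
    deg = A.sum(axis=1).astype(float)
    E = int(deg.sum() // 2)
    density = np.nan if N < 2 else 2.0 * E / (N * (N - 1))
    avg_degree = np.nan if N == 0 else 2.0 * E / N

    # global transitivity: 3 * triangles / connected triples
    Af = A.astype(np.uint8)
    triangles = int(np.trace(Af @ Af @ Af)) / 6.0
    triples = float(np.sum(deg * (deg - 1) / 2.0))
    transitivity = 0.0 if triples == 0 else 3.0 * triangles / triples

    if N == 0:
        return GraphMetrics(density, transitivity, avg_degree, np.nan, 0, E)
    if E == 0:
        return GraphMetrics(density, transitivity, avg_degree, np.nan, N, E)

    # BFS by matrix product: D[i, j] = first power at which j is reached
    reach = A | np.eye(N, dtype=bool)
    D = np.where(A, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    dist = 1
    while True:
        new = (reach.astype(np.uint8) @ Af).astype(bool) | reach
        newly = new & ~reach
        if not newly.any():
            break
        dist += 1
        D[newly] = dist
        reach = new
    # component representative = lowest-index reachable node
    ncomp = int(np.unique(reach.argmax(axis=1)).size)
    finite = np.isfinite(D) & ~np.eye(N, dtype=bool)
    apl = float(D[finite].mean()) if finite.any() else np.nan
    return GraphMetrics(density, transitivity, avg_degree, apl, ncomp, E)


def graph_metrics(graph: nx.Graph) -> GraphMetrics:
    """Graph density, global transitivity, average degree, average shortest
    path length over connected ordered pairs, component count and edge count.

    Density is undefined (NaN) for graphs with fewer than 2 nodes; average
    path length is over connected pairs only, so disconnected graphs are
    well-defined, and is NaN for edgeless graphs.
    """
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    np.fill_diagonal(A, 0.0)
    return _metrics_from_adjacency(A.astype(bool))


def average_local_clustering(graph: nx.Graph) -> float:
    """Average local clustering coefficient (alternative to transitivity)."""
    return nx.average_clustering(graph)


def randomize_profiles(matrix: ProfileMatrix, n_random: int = 100, seed: int = 0):
    """Yield matrices with each metabolite's values permuted across samples.

    Each randomized matrix permutes every row independently, destroying
    inter-metabolite correlation while preserving each metabolite's marginal
    distribution.  Default 100 randomizations.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    X = matrix.values.to_numpy(dtype=float)
    for _ in range(n_random):
        perm = rng.permuted(X, axis=1)
        out = matrix.copy()
        out.values.iloc[:, :] = perm
        yield out


@dataclass
class TopologySweep:
    """Metrics over the threshold grid for real data and randomized nulls."""

    thresholds: np.ndarray
    real: pd.DataFrame                       # one row per threshold
    null: dict = field(default_factory=dict)  # metric -> (n_null, n_thr) array

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: real value and null mean/q05/q95 per metric."""
        out = self.real.copy()
        for name in METRIC_NAMES:
            if name not in self.null or self.null[name].size == 0:
                continue
            vals = self.null[name]
            # high thresholds give edgeless nulls -> all-NaN path lengths
            import warnings
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[f"{name}_null_mean"] = np.nanmean(vals, axis=0)
                out[f"{name}_null_q05"] = np.nanquantile(vals, 0.05, axis=0)
                out[f"{name}_null_q95"] = np.nanquantile(vals, 0.95, axis=0)
        return out


def _sweep_one(R: np.ndarray, thresholds: np.ndarray, only_positive: bool):
    """Metric curves for one correlation matrix over the grid.

    Thresholded edge sets are nested, so thresholds keeping the same number
    of edges keep the same graph; metrics are computed once per distinct
    edge count.
    """
    R = np.asarray(R, dtype=float).copy()
    np.fill_diagonal(R, 0.0)
    iu = np.triu_indices(R.shape[0], 1)
    vals = R[iu] if only_positive else np.abs(R[iu])
    vals_sorted = np.sort(vals[~np.isnan(vals)])
    rows = []
    cache: dict[int, tuple] = {}
    for t in thresholds:
        lo = max(t, np.nextafter(0.0, 1.0)) if only_positive else t
        n_edges = len(vals_sorted) - np.searchsorted(vals_sorted, lo, "left")
        if n_edges not in cache:
            if only_positive:
                A = (R >= t) & (R > 0)
            else:
                A = np.abs(R) >= t
            cache[n_edges] = _metrics_from_adjacency(A).as_tuple()
        rows.append(cache[n_edges])
    return np.asarray(rows, dtype=float)


def sweep_thresholds(
    correlations: pd.DataFrame,
    null_matrices=(),
    grid_step: float = GRID_STEP,
    only_positive: bool = True,
) -> TopologySweep:
    """Compute the six metrics at each grid threshold, real and null.

    ``correlations`` is the real long pair table; ``null_matrices`` is an
    iterable of randomized :class:`ProfileMatrix` objects whose Spearman
    correlations supply the null band.
    """
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    ids = sorted(set(correlations["u"]) | set(correlations["v"]))
    R = rho_matrix(correlations, ids).to_numpy()
    R = np.nan_to_num(R, nan=0.0)  # untestable pairs contribute no edges
    real = _sweep_one(R, thresholds, only_positive)
    real_df = pd.DataFrame(real, columns=METRIC_NAMES)
    real_df.insert(0, "threshold", thresholds)

    null_curves = []
    for nm in null_matrices:
        Rn = np.nan_to_num(spearman_square(nm), nan=0.0)
        null_curves.append(_sweep_one(Rn, thresholds, only_positive))
    null = {}
    if null_curves:
        stack = np.stack(null_curves)  # (n_null, n_thr, n_metric)
        for k, name in enumerate(METRIC_NAMES):
            null[name] = stack[:, :, k]
    return TopologySweep(thresholds=thresholds, real=real_df, null=null)


def select_threshold(
    sweep: TopologySweep,
    override: float | None = None,
    null_fragmentation: float = 0.99,
) -> float:
    """Threshold at the small-to-large transition of the component count.

    With a randomized-data null band available (the 100-randomization
    default), returns the smallest grid threshold at which the null
    networks are essentially fully fragmented: mean null component count
    >= ``null_fragmentation`` times the node count.  At that point chance
    correlations no longer form edges, so the surviving structure is the
    real one — the transition the component curve shows when the network
    stops being held together by spurious edges.

    Without a null band, falls back to the grid threshold t maximizing the
    forward difference ``n_components(t + step) - n_components(t)`` (ties
    toward the smaller threshold).  A flat curve falls back to the default
    0.5 with a warning.  ``override`` short-circuits the rule.
    """
    if override is not None:
        if not (0.0 <= override <= 1.0):
            raise ValueError("override threshold must be in [0, 1]")
        return float(override)
    null_comp = sweep.null.get("n_components")
    if null_comp is not None and null_comp.size:
        mean_comp = np.nanmean(null_comp, axis=0)
        n_nodes = float(np.nanmax(null_comp))
        frag = mean_comp >= null_fragmentation * n_nodes
        if frag.any():
            return float(sweep.thresholds[int(np.argmax(frag))])
        logger.warning("null networks never fragment; falling back to the "
                       "component-jump rule")
    comp = sweep.real["n_components"].to_numpy(dtype=float)
    diffs = np.diff(comp)
    if diffs.size == 0 or np.nanmax(diffs) <= 0:
        logger.warning("flat component curve; using default threshold %.2f",
                       DEFAULT_THRESHOLD)
        return DEFAULT_THRESHOLD
    return float(sweep.thresholds[int(np.argmax(diffs))])
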