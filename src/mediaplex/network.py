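"""Two-layer multiplex networks with a selective mass-media targeting rule.

A multiplex network here is a pair of undirected simple graphs — an
*information* (virtual-contact) layer and an *epidemic* (physical-contact)
layer — defined on one shared population of individuals.  Each individual
occupies one node position in each layer; the interlayer coupling controls
the rank correlation ``rs`` between an individual's degrees in the two
layers (matched, anti-matched, or random).

The mass-media broadcaster is a global node that can reach only the top-η
fraction of individuals ranked by information-layer degree; :func:`media_mask`
materialises that targeting rule.  :func:`fragment_after_media_removal`
measures how the epidemic layer fragments when all edges incident to the
targeted individuals are removed, which bounds how far an epidemic can
travel once those individuals are effectively immune.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

RsMode = Literal["positive", "negative", "none"]

__all__ = [
    "LayerGraph",
    "MultiplexNetwork",
    "MediaMask",
    "generate_layer",
    "couple_layers",
    "degree_ranking",
    "media_mask",
    "interlayer_rank_correlation",
    "fragment_after_media_removal",
    "read_edge_list",
    "write_edge_list",
    "read_bundle",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LayerGraph:
    """An undirected simple graph on contiguous node IDs ``0..n_nodes-1``.

    ``edges`` is a canonical ``(m, 2)`` integer array: each row ``(u, v)``
    with ``u < v``, rows lexicographically sorted, no duplicates.
    """

    n_nodes: int
    edges: np.ndarray

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "LayerGraph":
        """Build a layer from an edge iterable, canonicalising and validating."""
        arr = np.asarray(sorted({(min(u, v), max(u, v)) for u, v in edges}), dtype=np.int64)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=np.int64)
        g = cls(int(n_nodes), arr)
        g.validate()
        return g

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("layer must have at least one node")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint outside 0..n_nodes-1")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop in edge set")
            canon = np.sort(self.edges, axis=1)
            if np.unique(canon, axis=0).shape[0] != self.edges.shape[0]:
                raise ValueError("duplicate edge in edge set")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degree(self) -> np.ndarray:
        """Per-node degree vector (nonnegative integers)."""
        deg = np.bincount(self.edges.ravel(), minlength=self.n_nodes)
        return deg.astype(np.int64)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR form."""
        if not self.edges.size:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        u, v = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(u))
        a = sp.coo_matrix(
            (data, (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()

    def to_networkx(self) -> nx.Graph:
        g = nx.empty_graph(self.n_nodes)
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass
class MultiplexNetwork:
    """Two layers on one shared individual-ID space.

    Both ``info_layer`` and ``epi_layer`` are indexed by *individual* IDs:
    :func:`couple_layers` relabels the raw epidemic layer so that individual
    ``i`` is the same node index in both layers.  ``coupling[i]`` records the
    node position individual ``i`` held in the raw (pre-relabelling)
    epidemic layer.
    """

    info_layer: LayerGraph
    epi_layer: LayerGraph
    coupling: np.ndarray
    rs_mode: RsMode = "none"

    def __post_init__(self) -> None:
        if self.info_layer.n_nodes != self.epi_layer.n_nodes:
            raise ValueError("layers must share one node count")
        n = self.info_layer.n_nodes
        c = np.asarray(self.coupling, dtype=np.int64)
        if c.shape != (n,) or not np.array_equal(np.sort(c), np.arange(n)):
            raise ValueError("coupling must be a bijection on 0..n-1")
        self.coupling = c

    @property
    def n_nodes(self) -> int:
        return self.info_layer.n_nodes


@dataclass
class MediaMask:
    """Which individuals the selective mass-media broadcast can reach.

    ``ranking`` is the 1-based information-layer degree rank (1 = highest
    degree, ties broken by ascending node ID); ``targeted[i]`` is True iff
    the broadcast reaches individual ``i``; ``m`` is the per-step probability
    that a targeted unaware individual becomes aware.
    """

    ranking: np.ndarray
    targeted: np.ndarray
    m: float
    eta: float

    @property
    def m_i(self) -> np.ndarray:
        """Per-node media awareness probability (``m`` if targeted else 0)."""
        return np.where(self.targeted, self.m, 0.0)

    @property
    def n_targeted(self) -> int:
        return int(self.targeted.sum())


# ---------------------------------------------------------------------------
# generation and coupling
# ---------------------------------------------------------------------------

def generate_layer(n: int, exponent: float, mean_degree: float, seed: int) -> LayerGraph:
    """Generate a scale-free layer with an exact edge budget.

    A degree sequence is drawn by flooring continuous power-law (Pareto)
    samples whose minimum is calibrated so the expected floored mean matches
    ``mean_degree``; the sequence is realised with a configuration model,
    self-loops and multi-edges are discarded, and edges are then randomly
    removed or added (uniformly) until the graph has exactly
    ``round(n * mean_degree / 2)`` edges.

    The realised degree distribution has a power-law tail with the requested
    exponent; the exact edge count pins the realised mean degree.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if exponent <= 2:
        raise ValueError("degree exponent must exceed 2")
    if not (2 <= mean_degree < n - 1):
        raise ValueError("mean_degree must lie in [2, n-1)")

    rng = np.random.default_rng(seed)
    m_target = round(n * mean_degree / 2)

    # E[floor(Pareto(xmin, a))] ~= xmin*(a-1)/(a-2) - 1/2
    xmin = (mean_degree + 0.5) * (exponent - 2.0) / (exponent - 1.0)
    u = rng.random(n)
    deg = np.floor(xmin * (1.0 - u) ** (-1.0 / (exponent - 1.0))).astype(np.int64)
    deg = np.clip(deg, 1, n - 1)
    if deg.sum() % 2:
        i = int(rng.integers(n))
        deg[i] += 1 if deg[i] < n - 1 else -1

    g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    edge_set = {(min(u_, v_), max(u_, v_)) for u_, v_ in g.edges()}

    if len(edge_set) > m_target:
        edge_list = sorted(edge_set)
        drop = rng.choice(len(edge_list), size=len(edge_list) - m_target, replace=False)
        for i in drop:
            edge_set.discard(edge_list[i])
    while len(edge_set) < m_target:
        u_, v_ = int(rng.integers(n)), int(rng.integers(n))
        if u_ != v_:
            edge_set.add((min(u_, v_), max(u_, v_)))

    return LayerGraph.from_edges(n, edge_set)


def degree_ranking(layer: LayerGraph) -> np.ndarray:
    """1-based degree ranks, descending degree, ties by ascending node ID."""
    n = layer.n_nodes
    order = np.lexsort((np.arange(n), -layer.degree))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def couple_layers(
    info: LayerGraph,
    epi: LayerGraph,
    rs_mode: RsMode = "none",
    seed: int | None = None,
) -> MultiplexNetwork:
    """Identify the nodes of the two layers into one population.

    ``positive``: the individual with the k-th largest information-layer
    degree is the node with the k-th largest epidemic-layer degree;
    ``negative``: the k-th smallest; ``none``: a uniformly random (seeded)
    identification.  Degree ties are broken deterministically by ascending
    node ID.  Individual IDs coincide with information-layer node IDs.
    """
    if info.n_nodes != epi.n_nodes:
        raise ValueError("layers differ in node count")
    n = info.n_nodes
    ids = np.arange(n)
    info_order = np.lexsort((ids, -info.degree))  # info nodes, degree desc
    if rs_mode == "positive":
        epi_order = np.lexsort((ids, -epi.degree))
    elif rs_mode == "negative":
        epi_order = np.lexsort((ids, epi.degree))
    elif rs_mode == "none":
        epi_order = np.random.default_rng(seed).permutation(n)
    else:
        raise ValueError(f"unknown rs_mode: {rs_mode!r}")

    coupling = np.empty(n, dtype=np.int64)  # individual -> raw epi node
    coupling[info_order] = epi_order
    inv = np.empty(n, dtype=np.int64)  # raw epi node -> individual
    inv[coupling] = np.arange(n)

    epi_relab = LayerGraph.from_edges(n, (tuple(row) for row in inv[epi.edges]))
    return MultiplexNetwork(info, epi_relab, coupling, rs_mode)


# ---------------------------------------------------------------------------
# media targeting and fragmentation
# ---------------------------------------------------------------------------

def _n_targeted(eta: float, n: int) -> int:
    # round() guards against float fuzz in eta*n (e.g. 0.35*1000 -> 350.00000000000006)
    return int(math.ceil(round(eta * n, 9)))


def media_mask(
    net: MultiplexNetwork, eta: float, m: float, strict: bool = False
) -> MediaMask:
    """Targeting rule of the selective broadcaster.

    Individual ``i`` is targeted iff its information-layer degree rank
    ``R_i`` satisfies ``R_i <= ceil(eta * N)``, so ``eta=0`` targets nobody
    and ``eta=1`` targets everybody.  With ``strict=True`` the literal
    strict-inequality variant ``eta > R_i / N`` is used instead (under which
    ``eta=1`` excludes the lowest-ranked node).
    """
    if not (0 <= eta <= 1):
        raise ValueError("eta must be in [0, 1]")
    if not (0 <= m <= 1):
        raise ValueError("m must be in [0, 1]")
    n = net.n_nodes
    ranks = degree_ranking(net.info_layer)
    if strict:
        targeted = eta > ranks / n
    else:
        targeted = ranks <= _n_targeted(eta, n)
    return MediaMask(ranking=ranks, targeted=targeted, m=float(m), eta=float(eta))


def interlayer_rank_correlation(net: MultiplexNetwork) -> float:
    """Spearman rank correlation of paired per-individual layer degrees."""
    d_info = net.info_layer.degree
    d_epi = net.epi_layer.degree
    if np.all(d_info == d_info[0]) or np.all(d_epi == d_epi[0]):
        raise ValueError("rank correlation undefined: constant degree vector")
    rho = spearmanr(d_info, d_epi).statistic
    return float(rho)


def fragment_after_media_removal(net: MultiplexNetwork, eta: float) -> int:
    """Components of the epidemic layer after unplugging targeted individuals.

    Every epidemic-layer edge incident to an individual whose
    information-layer degree rank is within the top-η set (same rule as
    :func:`media_mask`) is deleted; returns the number of connected
    components of what remains, counting isolated nodes.
    """
    if not (0 <= eta <= 1):
        raise ValueError("eta must be in [0, 1]")
    n = net.n_nodes
    ranks = degree_ranking(net.info_layer)
    targeted = ranks <= _n_targeted(eta, n)
    edges = net.epi_layer.edges
    if edges.size:
        keep = ~(targeted[edges[:, 0]] | targeted[edges[:, 1]])
        edges = edges[keep]
    if not edges.size:
        return n
    adj = LayerGraph(n, edges).adjacency()
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, n_nodes: int | None = None) -> LayerGraph:
    """Read a two-column whitespace-delimited 0-based undirected edge list.

    Blank lines and lines starting with ``#`` are skipped.  Self-loops and
    duplicate edges are rejected with an error naming the offending line.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    max_id = -1
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node ID") from exc
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node ID")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop ({u}, {v})")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate edge ({u}, {v})")
            seen.add(key)
            edges.append(key)
            max_id = max(max_id, u, v)
    n = n_nodes if n_nodes is not None else max_id + 1
    return LayerGraph.from_edges(max(n, 1), edges)


def write_edge_list(graph: LayerGraph, path: str | Path) -> None:
    """Write the canonical edge list (lower ID first, sorted)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")


def write_bundle(net: MultiplexNetwork, directory: str | Path) -> None:
    """Write a multiplex bundle: info.edges, epi.edges, coupling.tsv.

    Both edge lists are on the shared individual-ID space; coupling.tsv maps
    each individual to its node position in the raw information and epidemic
    layers (the former is the identity by construction).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edge_list(net.info_layer, directory / "info.edges")
    write_edge_list(net.epi_layer, directory / "epi.edges")
    with (directory / "coupling.tsv").open("w") as fh:
        fh.write("# individual\tinfo_node\tepi_node\n")
        for i, c in enumerate(net.coupling):
            fh.write(f"{i}\t{i}\t{c}\n")


def read_bundle(directory: str | Path, rs_mode: RsMode = "none") -> MultiplexNetwork:
    """Read a multiplex bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    info = read_edge_list(directory / "info.edges")
    epi = read_edge_list(directory / "epi.edges")
    n = max(info.n_nodes, epi.n_nodes)
    info = LayerGraph.from_edges(n, map(tuple, info.edges))
    epi = LayerGraph.from_edges(n, map(tuple, epi.edges))
    coupling = np.arange(n, dtype=np.int64)
    coupling_path = directory / "coupling.tsv"
    if coupling_path.exists():
        rows = np.loadtxt(coupling_path, dtype=np.int64, comments="#", ndmin=2)
        if rows.size:
            coupling[rows[:, 0]] = rows[:, 2]
    return MultiplexNetwork(info, epi, coupling, rs_mode)
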