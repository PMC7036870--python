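"""Area adjacency structures for spatial smoothing.

The spatial models in this package place an intrinsic conditional
autoregressive (ICAR) prior on area-level effects, which only requires a
neighbourhood graph: which areas share a boundary with which.  This module
provides :class:`AreaGraph`, a validated symmetric adjacency structure,
plus constructors for regular lattices (synthetic stand-ins for real
district maps) and a plain-text adjacency-list format.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AreaGraph",
    "build_lattice",
    "read_adjacency",
    "write_adjacency",
    "connected_components",
]


class AreaGraph:
    """Symmetric area adjacency graph.

    Parameters
    ----------
    area_ids : sequence of hashable
        Ordered area identifiers.  The order fixes the index used by all
        array-valued views.
    adjacency : mapping area -> iterable of areas
        Neighbour sets.  Must be symmetric, contain no self-loops and
        reference only known areas.

    Notes
    -----
    Isolated areas (no neighbours) are allowed but trigger a warning: the
    ICAR conditional is undefined for them, so their structured spatial
    effect is pinned at zero downstream and all between-area information
    flows through the unstructured effect.
    """

    def __init__(self, area_ids: Sequence, adjacency: Mapping):
        self.area_ids = list(area_ids)
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        self.index = {a: i for i, a in enumerate(self.area_ids)}
        adj = {}
        for a in self.area_ids:
            nbrs = set(adjacency.get(a, ()))
            if a in nbrs:
                raise ValueError(f"self-loop on area {a!r}")
            for b in nbrs:
                if b not in self.index:
                    raise ValueError(f"area {a!r} lists unknown neighbor {b!r}")
            adj[a] = frozenset(nbrs)
        for a, nbrs in adj.items():
            for b in nbrs:
                if a not in adj[b]:
                    raise ValueError(f"asymmetric adjacency: {a!r} -> {b!r}")
        self.adjacency = adj
        isolated = [a for a in self.area_ids if not adj[a]]
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated area(s) (no neighbors): "
                f"{isolated[:5]}{'...' if len(isolated) > 5 else ''}; their "
                "structured spatial effect will be fixed at 0",
                stacklevel=2,
            )

    # -- basic views -------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def neighbors(self, area) -> frozenset:
        return self.adjacency[area]

    def num_neighbors(self, area) -> int:
        return len(self.adjacency[area])

    @property
    def m(self) -> np.ndarray:
        """Neighbour counts m_k in area order."""
        return np.array([len(self.adjacency[a]) for a in self.area_ids])

    @property
    def n_edges(self) -> int:
        return int(self.m.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for a, nbrs in self.adjacency.items():
            g.add_edges_from((a, b) for b in nbrs)
        return g

    def components(self) -> list[set]:
        """Connected components as sets of area ids (isolated areas are
        singleton components)."""
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    # -- array form used by the sampler ------------------------------

    def to_arrays(self):
        """CSR-style arrays in area order.

        Returns
        -------
        nbr_ptr : int64 array, shape (K+1,)
        nbr_idx : int64 array
            ``nbr_idx[nbr_ptr[k]:nbr_ptr[k+1]]`` are the neighbour indices
            of area ``k``.
        m : int64 array, shape (K,)
        comp : int64 array, shape (K,)
            Connected-component label per area.
        edges : int64 array, shape (n_edges, 2)
            Each undirected edge once, as (i, j) with i < j.
        """
        K = self.n_areas
        m = self.m.astype(np.int64)
        nbr_ptr = np.zeros(K + 1, dtype=np.int64)
        nbr_ptr[1:] = np.cumsum(m)
        nbr_idx = np.empty(nbr_ptr[-1], dtype=np.int64)
        edges = []
        for a in self.area_ids:
            i = self.index[a]
            js = sorted(self.index[b] for b in self.adjacency[a])
            nbr_idx[nbr_ptr[i] : nbr_ptr[i + 1]] = js
            edges.extend((i, j) for j in js if i < j)
        comp = np.empty(K, dtype=np.int64)
        for c, members in enumerate(self.components()):
            for a in members:
                comp[self.index[a]] = c
        edge_arr = (
            np.array(edges, dtype=np.int64)
            if edges
            else np.empty((0, 2), dtype=np.int64)
        )
        return nbr_ptr, nbr_idx, m, comp, edge_arr

    def __eq__(self, other):
        return (
            isinstance(other, AreaGraph)
            and self.area_ids == other.area_ids
            and self.adjacency == other.adjacency
        )

    def __repr__(self):
        return f"AreaGraph({self.n_areas} areas, {self.n_edges} edges)"


def build_lattice(rows: int, cols: int) -> AreaGraph:
    """Rook-adjacency ``rows x cols`` grid graph.

    Areas are labelled ``"r{i}c{j}"`` in row-major order; two cells are
    neighbours iff they share an edge (rook moves), matching the
    share-a-common-boundary convention used for district maps.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs positive dimensions and >= 2 cells")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    adj: dict[str, set] = {a: set() for a in ids}
    for i in range(rows):
        for j in range(cols):
            a = f"r{i}c{j}"
            if i + 1 < rows:
                adj[a].add(f"r{i + 1}c{j}")
                adj[f"r{i + 1}c{j}"].add(a)
            if j + 1 < cols:
                adj[a].add(f"r{i}c{j + 1}")
                adj[f"r{i}c{j + 1}"].add(a)
    return AreaGraph(ids, adj)


def connected_components(graph: AreaGraph) -> list[set]:
    """Partition of the areas into connected components."""
    return graph.components()


def read_adjacency(path) -> AreaGraph:
    """Read an adjacency-list text file.

    Format: one line per area, ``area_id: id1 id2 ...`` with
    whitespace-separated neighbour ids; ``#`` starts a comment.  One-sided
    entries are symmetrised with a warning; a neighbour id with no area
    line of its own is an error, as is a duplicated area line.
    """
    entries: dict[str, set] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'area: nbrs...'")
            aid, rest = line.split(":", 1)
            aid = aid.strip()
            if aid in entries:
                raise ValueError(f"{path}:{lineno}: duplicate area line {aid!r}")
            order.append(aid)
            entries[aid] = set(rest.split())
    for aid, nbrs in entries.items():
        for b in nbrs:
            if b not in entries:
                raise ValueError(f"area {aid!r} references unknown area {b!r}")
    sym = {a: set(n) for a, n in entries.items()}
    one_sided = []
    for a, nbrs in entries.items():
        for b in nbrs:
            if a not in entries[b]:
                one_sided.append((b, a))
                sym[b].add(a)
    if one_sided:
        warnings.warn(
            f"symmetrized {len(one_sided)} one-sided adjacency entr"
            f"{'y' if len(one_sided) == 1 else 'ies'}, e.g. {one_sided[0]}",
            stacklevel=2,
        )
    return AreaGraph(order, sym)


def write_adjacency(graph: AreaGraph, path) -> None:
    """Write ``graph`` in the adjacency-list dialect of :func:`read_adjacency`."""
    with open(path, "w") as fh:
        for a in graph.area_ids:
            nbrs = " ".join(str(b) for b in sorted(graph.adjacency[a], key=str))
            fh.write(f"{a}: {nbrs}\n" if nbrs else f"{a}:\n")
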