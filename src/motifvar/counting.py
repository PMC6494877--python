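"""Exact motif (non-induced) and graphlet (induced) counting for k <= 5.

Counts are per unordered vertex subset: the number of embeddings divided by
the motif's automorphism count, so a triangle on {a, b, c} counts once.
Connected k-subsets are enumerated exactly once with the ESU expansion
scheme; each subset's induced edge mask is classified through a precomputed
mask table, giving induced counts per isomorphism class in one pass.
Non-induced counts follow by the linear conversion

    N_sub(H) = sum_{G >= H, |G| = |H|} (# spanning copies of H in G) * N_ind(G),

e.g. squares = induced squares + 1 * diamonds + 3 * K4s.  Dedicated fast
paths exist for edges, wedges (sum d(d-1)/2) and triangles (sparse-matrix
trace), which the general enumeration must and does agree with.

Orbit-resolved degree statistics attribute every vertex of every induced
4-vertex graphlet occurrence to its automorphism orbit (vertex type) and
report mean degrees — the empirical counterpart of the typical-variation
prediction for vertex types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log

import numpy as np

from .hvmodel import SampledGraph, read_edge_list  # re-exported reader
from .motifs import (
    Motif,
    automorphism_count,
    automorphism_orbits,
    enumerate_connected_motifs,
)

__all__ = [
    "CountTable",
    "OrbitDegreeStats",
    "count_motif",
    "count_all_k",
    "count_wedges",
    "count_triangles",
    "orbit_degree_stats",
    "conversion_matrix",
    "read_edge_list",
]


@lru_cache(maxsize=None)
def _pair_order(k: int) -> tuple:
    return tuple(itertools.combinations(range(k), 2))


@lru_cache(maxsize=None)
def _mask_class_table(k: int) -> dict:
    """mask over the C(k,2) pair slots -> index into the connected catalog."""
    catalog = enumerate_connected_motifs(k)
    index = {m.canonical_id: i for i, m in enumerate(catalog)}
    pairs = _pair_order(k)
    table = {}
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if len(edges) < k - 1:
            continue
        mot = Motif(k, edges)
        if mot.is_connected():
            table[mask] = index[mot.canonical_id]
    return table


@lru_cache(maxsize=None)
def _mask_orbit_table(k: int = 4) -> dict:
    """mask -> (class index, orbit id per local vertex position).

    Orbit ids are global across the catalog: (class index, orbit index).
    """
    catalog = enumerate_connected_motifs(k)
    orbit_parts = [automorphism_orbits(m) for m in catalog]
    pairs = _pair_order(k)
    table = {}
    for mask, ci in _mask_class_table(k).items():
        edges = {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
        rep = catalog[ci]
        # find one isomorphism local -> rep and read off orbit membership
        for perm in itertools.permutations(range(k)):
            if all(
                (tuple(sorted((perm[a], perm[b]))) in rep.edges) == ((a, b) in edges)
                for a, b in pairs
            ):
                orbits = tuple(
                    (ci, orbit_parts[ci].orbit_of(perm[v])) for v in range(k)
                )
                table[mask] = (ci, orbits)
                break
    return table


@lru_cache(maxsize=None)
def conversion_matrix(k: int) -> np.ndarray:
    """M[i, j] = number of spanning copies of catalog motif i inside motif j.

    Upper-triangular in edge count; non_induced = M @ induced and the matrix
    is unimodular (diagonal of ones), so induced counts are recoverable.
    """
    catalog = enumerate_connected_motifs(k)
    ncls = len(catalog)
    M = np.zeros((ncls, ncls), dtype=np.int64)
    for i, h in enumerate(catalog):
        aut_h = automorphism_count(h)
        for j, g in enumerate(catalog):
            copies = 0
            for perm in itertools.permutations(range(k)):
                if all((min(perm[a], perm[b]), max(perm[a], perm[b])) in g.edges
                       for a, b in h.edges):
                    copies += 1
            M[i, j] = copies // aut_h
    return M


@dataclass
class CountTable:
    """Induced and non-induced counts over the connected k-vertex catalog."""

    n: int
    m: int
    k: int
    motifs: tuple  # catalog order
    induced: dict  # canonical_id -> int
    non_induced: dict

    def induced_vector(self) -> np.ndarray:
        return np.array([self.induced[mo.canonical_id] for mo in self.motifs])

    def non_induced_vector(self) -> np.ndarray:
        return np.array([self.non_induced[mo.canonical_id] for mo in self.motifs])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "canonical_id": [mo.canonical_id for mo in self.motifs],
                "edges": [mo.to_edgelist_str() for mo in self.motifs],
                "induced": self.induced_vector(),
                "non_induced": self.non_induced_vector(),
            }
        )


def _esu_subsets(adj: list, n: int, k: int):
    """Yield every connected k-subset exactly once (ESU expansion)."""
    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        yield from _esu_extend([v], ext, v, adj, k)


def _esu_extend(sub, ext, v_root, adj, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = set(ext)
    while ext:
        w = ext.pop()
        # extension set: exclusive neighbors of w greater than the root
        new_ext = ext | {
            u for u in adj[w] if u > v_root and u not in sub and not any(
                u in adj[s] for s in sub
            )
        }
        yield from _esu_extend(sub + [w], new_ext, v_root, adj, k)


def count_all_k(graph: SampledGraph, k: int, induced: bool = True) -> CountTable:
    """Complete count table over the connected catalog for k in {3, 4, 5}."""
    if k not in (3, 4, 5):
        raise ValueError("k must be 3, 4 or 5")
    catalog = enumerate_connected_motifs(k)
    table = _mask_class_table(k)
    pairs = _pair_order(k)
    adj = graph.adjacency_sets()
    counts = np.zeros(len(catalog), dtype=np.int64)
    for sub in _esu_subsets(adj, graph.n, k):
        s = sorted(sub)
        mask = 0
        for idx, (a, b) in enumerate(pairs):
            if s[b] in adj[s[a]]:
                mask |= 1 << idx
        counts[table[mask]] += 1
    M = conversion_matrix(k)
    non_ind = M @ counts
    return CountTable(
        n=graph.n,
        m=graph.m,
        k=k,
        motifs=catalog,
        induced={mo.canonical_id: int(c) for mo, c in zip(catalog, counts)},
        non_induced={mo.canonical_id: int(c) for mo, c in zip(catalog, non_ind)},
    )


# -- fast paths -------------------------------------------------------------

_WEDGE_ID = Motif(3, [(0, 1), (1, 2)]).canonical_id
_TRIANGLE_ID = Motif(3, [(0, 1), (0, 2), (1, 2)]).canonical_id
_EDGE_ID = Motif(2, [(0, 1)]).canonical_id


def count_wedges(graph: SampledGraph) -> int:
    """Non-induced paths on 3 vertices: sum_v d(v)(d(v)-1)/2."""
    d = graph.degrees().astype(np.int64)
    return int((d * (d - 1) // 2).sum())


def count_triangles(graph: SampledGraph) -> int:
    """Triangles via the sparse adjacency: tr(A^3)/6 as (A@A o A)/6."""
    if graph.m == 0:
        return 0
    A = graph.to_sparse().astype(np.int64)
    return int((A @ A).multiply(A).sum() // 6)


def count_motif(graph: SampledGraph, motif: Motif, induced: bool = False) -> int:
    """Count occurrences of one motif (per unordered vertex subset).

    Non-induced edge/wedge/triangle counts use closed-form fast paths; other
    cases go through the full k-subset enumeration.
    """
    if motif.k > 5:
        raise ValueError("counting limited to motifs on <= 5 vertices")
    if motif.k > graph.n:
        raise ValueError("motif larger than graph")
    if not induced:
        cid = motif.canonical_id
        if cid == _EDGE_ID:
            return graph.m
        if cid == _WEDGE_ID:
            return count_wedges(graph)
        if cid == _TRIANGLE_ID:
            return count_triangles(graph)
    if motif.k == 2:
        return graph.m  # induced = non-induced for the single edge
    tab = count_all_k(graph, motif.k, induced=induced)
    d = tab.induced if induced else tab.non_induced
    return d[motif.canonical_id]


# -- orbit-resolved degree statistics ---------------------------------------


@dataclass
class OrbitRecord:
    graphlet: Motif
    graphlet_index: int
    orbit_index: int
    orbit_vertices: tuple  # representative's vertices in this orbit
    occurrences: int
    mean_degree: float
    mean_log_degree: float  # mean of log(deg)/log(n)


@dataclass
class OrbitDegreeStats:
    """Per-orbit occurrence counts and degree statistics (4-vertex graphlets)."""

    n: int
    m: int
    records: tuple

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "graphlet": [r.graphlet.to_edgelist_str() for r in self.records],
                "orbit": [r.orbit_index for r in self.records],
                "orbit_vertices": [r.orbit_vertices for r in self.records],
                "occurrences": [r.occurrences for r in self.records],
                "mean_degree": [r.mean_degree for r in self.records],
                "mean_log_n_degree": [r.mean_log_degree for r in self.records],
            }
        )


def orbit_degree_stats(graph: SampledGraph) -> OrbitDegreeStats:
    """Mean (log-)degree of every 4-vertex graphlet orbit, one ESU pass.

    Degrees are whole-graph degrees of the vertices sitting in each orbit
    position, aggregated over all induced occurrences.
    """
    if graph.n < 4:
        return OrbitDegreeStats(n=graph.n, m=graph.m, records=())
    k = 4
    catalog = enumerate_connected_motifs(k)
    orbit_parts = [automorphism_orbits(m) for m in catalog]
    otab = _mask_orbit_table(k)
    pairs = _pair_order(k)
    adj = graph.adjacency_sets()
    deg = graph.degrees()
    logn = log(graph.n)
    acc: dict = {}
    for sub in _esu_subsets(adj, graph.n, k):
        s = sorted(sub)
        mask = 0
        for idx, (a, b) in enumerate(pairs):
            if s[b] in adj[s[a]]:
                mask |= 1 << idx
        _, orbits = otab[mask]
        for pos in range(k):
            key = orbits[pos]
            d = deg[s[pos]]
            cnt, dsum, lsum = acc.get(key, (0, 0.0, 0.0))
            acc[key] = (cnt + 1, dsum + d, lsum + log(d) / logn)
    records = []
    for (ci, oi), (cnt, dsum, lsum) in sorted(acc.items()):
        records.append(
            OrbitRecord(
                graphlet=catalog[ci],
                graphlet_index=ci,
                orbit_index=oi,
                orbit_vertices=orbit_parts[ci].orbits[oi],
                occurrences=cnt,
                mean_degree=dsum / cnt,
                mean_log_degree=lsum / cnt,
            )
        )
    return OrbitDegreeStats(n=graph.n, m=graph.m, records=tuple(records))
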