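"""Small simple graphs (motifs/graphlets): canonical forms, enumeration, orbits.

A motif is a small labeled simple undirected graph on vertices ``0..k-1``.
Isomorphism classes are identified through an exact canonical form: the
lexicographically minimal adjacency bit-string over all vertex relabelings,
computed with a branch-and-bound search pruned by Weisfeiler-Leman color
refinement.  This is exact and fast for the sizes that occur here (k <= 10;
merged two-copy graphs reach 2k-1 = 9 vertices).

Automorphism orbits partition the vertices into the motif's "vertex types":
the granularity at which typical degrees are predicted and measured.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from functools import lru_cache

Edge = tuple[int, int]

MAX_VERTICES = 10


def _normalize_edges(k: int, edges) -> frozenset:
    out = set()
    for e in edges:
        a, b = e
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-loop at vertex {a}")
        if not (0 <= a < k and 0 <= b < k):
            raise ValueError(f"edge {e!r} out of range for k={k}")
        pair = (a, b) if a < b else (b, a)
        if pair in out:
            raise ValueError(f"duplicate edge {pair}")
        out.add(pair)
    return frozenset(out)


@dataclass(frozen=True)
class Motif:
    """A simple undirected graph on ``k`` labeled vertices ``0..k-1``.

    ``edges`` is a frozenset of sorted pairs.  Two motifs are isomorphic
    iff their :attr:`canonical_id` tokens are equal.
    """

    k: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (1 <= self.k <= MAX_VERTICES):
            raise ValueError(f"vertex count {self.k} outside 1..{MAX_VERTICES}")
        object.__setattr__(self, "edges", _normalize_edges(self.k, self.edges))

    # -- basic structure ---------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[set]:
        adj = [set() for _ in range(self.k)]
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degrees(self) -> list[int]:
        deg = [0] * self.k
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def non_edges(self) -> list[Edge]:
        return [
            (a, b)
            for a, b in itertools.combinations(range(self.k), 2)
            if (a, b) not in self.edges
        ]

    def is_connected(self) -> bool:
        if self.k == 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == self.k

    def relabel(self, perm) -> "Motif":
        """Apply the permutation ``perm`` (``perm[v]`` = new label of v)."""
        return Motif(self.k, [(perm[a], perm[b]) for a, b in self.edges])

    # -- identity ----------------------------------------------------------

    @property
    def canonical_id(self) -> str:
        return _canonical_token(self.k, self.edges)

    def canonical_relabel(self) -> "Motif":
        """The canonically labeled representative of this isomorphism class."""
        _, perm = _canonical_bits_perm(self.k, self.edges)
        inv = [0] * self.k
        for pos, v in enumerate(perm):
            inv[v] = pos
        return self.relabel(inv)

    # -- serialization -----------------------------------------------------

    def to_edgelist_str(self) -> str:
        return ",".join(f"{a}-{b}" for a, b in sorted(self.edges))

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "edges": [list(e) for e in sorted(self.edges)]})

    @classmethod
    def from_json(cls, text: str) -> "Motif":
        obj = json.loads(text)
        return cls(obj["k"], [tuple(e) for e in obj["edges"]])

    def __repr__(self):
        return f"Motif(k={self.k}, edges='{self.to_edgelist_str()}')"


@dataclass(frozen=True)
class OrbitPartition:
    """Partition of a motif's vertices into automorphism orbits."""

    motif: Motif
    orbits: tuple  # tuple of sorted tuples, sorted by first element

    @property
    def n_orbits(self) -> int:
        return len(self.orbits)

    def orbit_of(self, v: int) -> int:
        for i, orb in enumerate(self.orbits):
            if v in orb:
                return i
        raise ValueError(f"vertex {v} not in partition")


# ---------------------------------------------------------------------------
# canonical labeling


def _wl_colors(k: int, adj: list[set]) -> list[int]:
    """Stable 1-WL colors as isomorphism-invariant integer ranks."""
    colors = [len(adj[v]) for v in range(k)]
    for _ in range(k):
        sigs = [(colors[v], tuple(sorted(colors[u] for u in adj[v]))) for v in range(k)]
        order = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [order[s] for s in sigs]
        if new == colors:
            break
        colors = new
    return colors


def _canonical_search(k: int, edges: frozenset):
    """Minimal adjacency bit-string (column-major) and a witnessing ordering.

    Positions are constrained to an invariant color sequence (WL colors in
    ascending order), which preserves canonicity while pruning the search.
    """
    adj = [set() for _ in range(k)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    colors = _wl_colors(k, adj)
    colseq = sorted(colors)
    by_color: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        by_color.setdefault(c, []).append(v)

    best: list = [None]  # best chunk list
    best_order: list = [None]

    def rec(p, order, chunks, tight):
        if p == k:
            if best[0] is None or chunks < best[0]:
                best[0] = list(chunks)
                best_order[0] = list(order)
            return
        cands = []
        for v in by_color[colseq[p]]:
            if v in order:
                continue
            ch = 0
            for j, u in enumerate(order):
                ch = (ch << 1) | (1 if u in adj[v] else 0)
            cands.append((ch, v))
        cands.sort()
        for ch, v in cands:
            nt = tight
            if best[0] is not None and nt:
                if ch > best[0][p]:
                    continue  # prefix already worse; siblings are >= too
                nt = ch == best[0][p]
            order.append(v)
            chunks.append(ch)
            rec(p + 1, order, chunks, nt)
            order.pop()
            chunks.pop()

    rec(0, [], [], True)
    return tuple(best[0]), best_order[0]


@lru_cache(maxsize=200_000)
def _canonical_bits_perm(k: int, edges: frozenset):
    return _canonical_search(k, edges)


def _canonical_token(k: int, edges: frozenset) -> str:
    bits, _ = _canonical_bits_perm(k, edges)
    word = 0
    for i, ch in enumerate(bits):
        word = (word << i) | ch
    return f"g{k}-{word:x}"


def canonical_form(motif: Motif) -> str:
    """Opaque token equal for two motifs iff they are isomorphic."""
    return motif.canonical_id


# ---------------------------------------------------------------------------
# automorphisms and orbits


def automorphisms(motif: Motif) -> list[tuple]:
    """All adjacency-preserving permutations, as tuples ``perm[v] -> image``."""
    k = motif.k
    adj = motif.adjacency()
    colors = _wl_colors(k, adj)
    autos = []

    def rec(p, mapping):
        if p == k:
            autos.append(tuple(mapping))
            return
        for w in range(k):
            if w in mapping[:p] or colors[w] != colors[p]:
                continue
            ok = True
            for q in range(p):
                if (q in adj[p]) != (mapping[q] in adj[w]):
                    ok = False
                    break
            if ok:
                mapping[p] = w
                rec(p + 1, mapping)
        mapping[p] = -1

    rec(0, [-1] * k)
    return autos


def automorphism_count(motif: Motif) -> int:
    return len(automorphisms(motif))


def automorphism_orbits(motif: Motif) -> OrbitPartition:
    """Orbits of the automorphism group — the motif's vertex types."""
    parent = list(range(motif.k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sigma in automorphisms(motif):
        for v, w in enumerate(sigma):
            ra, rb = find(v), find(w)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for v in range(motif.k):
        groups.setdefault(find(v), []).append(v)
    orbits = tuple(tuple(sorted(g)) for g in sorted(groups.values()))
    return OrbitPartition(motif, orbits)


# ---------------------------------------------------------------------------
# enumeration


@lru_cache(maxsize=None)
def enumerate_connected_motifs(k: int) -> tuple:
    """One canonical representative per connected isomorphism class on k vertices.

    Deterministic order: by edge count, then canonical token.  There are
    2, 6, 21 classes for k = 3, 4, 5.
    """
    if not (2 <= k <= 5):
        raise ValueError("enumeration supported for 2 <= k <= 5")
    pairs = list(itertools.combinations(range(k), 2))
    seen: dict[str, Motif] = {}
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if len(edges) < k - 1:
            continue
        mot = Motif(k, edges)
        if not mot.is_connected():
            continue
        cid = mot.canonical_id
        if cid not in seen:
            seen[cid] = mot.canonical_relabel()
    return tuple(sorted(seen.values(), key=lambda m: (m.m, m.canonical_id)))


# ---------------------------------------------------------------------------
# named motifs and parsing

_NAMED_MOTIFS: dict[str, str] = {
    "edge": "0-1",
    "wedge": "0-1,1-2",
    "path3": "0-1,1-2",
    "triangle": "0-1,0-2,1-2",
    "path4": "0-1,1-2,2-3",
    "claw": "0-1,0-2,0-3",
    "star4": "0-1,0-2,0-3",
    "paw": "0-1,0-2,1-2,0-3",
    "square": "0-1,1-2,2-3,0-3",
    "cycle4": "0-1,1-2,2-3,0-3",
    "diamond": "0-1,0-2,1-2,0-3,1-3",
    "k4": "0-1,0-2,0-3,1-2,1-3,2-3",
    "path5": "0-1,1-2,2-3,3-4",
    "star5": "0-1,0-2,0-3,0-4",
    "cycle5": "0-1,1-2,2-3,3-4,0-4",
    "bull": "0-1,0-2,1-2,0-3,1-4",
    "bowtie": "0-1,0-2,1-2,0-3,0-4,3-4",
    "bow-tie": "0-1,0-2,1-2,0-3,0-4,3-4",
    "butterfly": "0-1,0-2,1-2,0-3,0-4,3-4",
    "house": "0-1,1-2,2-3,0-3,0-4,1-4",
    "k23": "0-2,0-3,0-4,1-2,1-3,1-4",
    "wheel5": "0-1,0-2,0-3,0-4,1-2,2-3,3-4,1-4",
    "k5": "0-1,0-2,0-3,0-4,1-2,1-3,1-4,2-3,2-4,3-4",
}

_EDGE_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


def motif_names() -> tuple:
    return tuple(sorted(_NAMED_MOTIFS))


def parse_motif_spec(spec: str) -> Motif:
    """Build a motif from a registered name or an edge-list string ``a-b,c-d``."""
    key = spec.strip().lower()
    if key in _NAMED_MOTIFS:
        spec = _NAMED_MOTIFS[key]
    edges = []
    for part in spec.split(","):
        m = _EDGE_RE.match(part)
        if m is None:
            raise ValueError(
                f"unknown motif name or malformed edge list: {spec!r} "
                f"(known names: {', '.join(motif_names())})"
            )
        edges.append((int(m.group(1)), int(m.group(2))))
    if not edges:
        raise ValueError("empty motif specification")
    k = max(max(e) for e in edges) + 1
    return Motif(k, edges)
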