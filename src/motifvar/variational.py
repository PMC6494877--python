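"""The variational principle for dominant motif structure.

Write the hidden variable of motif vertex ``i`` as ``h_i ~ n^{alpha_i}``.
The exponent of the contribution of such an assignment to the expected
number of copies of a motif ``H`` on ``k`` vertices is

    f(alpha) = (1 - tau) * sum_i alpha_i
               + sum_{(i,j) in E_H, alpha_i + alpha_j < 1} (alpha_i + alpha_j - 1),

and the motif count scales as ``n^{k + max f}``.  The maximum over the free
box ``alpha in [0, 1]^k`` is attained at assignments with values in
{0, 1/2, 1}; under the typical-sample cutoff ``alpha_i <= 1/(tau-1)`` it is
attained at values in {0, (tau-2)/(tau-1), 1/2, 1/(tau-1)}.  The free optimum
is equivalently a partition problem: with S1 = {alpha=0}, S2 = {alpha=1},
S3 = {alpha=1/2},

    B_f(H) = max over partitions of |S1| - |S2| - (2 E_{S1} + E_{S1,S3})/(tau-1),

and  k + max f = (3-tau) k / 2 + (tau-1) B_f / 2.

The graphlet (induced-subgraph) variant additionally requires
``alpha_i + alpha_j <= 1`` for every non-edge, so that the absent edges can
actually be absent.

All arithmetic is exact rational; floats appear only in the simulation
modules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .motifs import Motif
from .piecewise import (
    F,
    LinearExponent,
    PiecewiseExponent,
    RationalExponent,
    upper_envelope,
)

FREE_VALUES = (F(0), F(1, 2), F(1))


def check_tau(tau) -> Fraction:
    tau = F(tau)
    if not (F(2) < tau < F(3)):
        raise ValueError(f"tau={tau} outside the open interval (2, 3)")
    return tau


def typical_values(tau) -> tuple:
    """The four candidate optimizer values under the hub cutoff 1/(tau-1)."""
    tau = check_tau(tau)
    return (F(0), (tau - 2) / (tau - 1), F(1, 2), 1 / (tau - 1))


def typical_cap(tau) -> Fraction:
    """The hub cutoff 1/(tau-1): the scale of the largest typical degree."""
    return 1 / (check_tau(tau) - 1)


# role names for the candidate degree scales
_ROLE_NAMES = {
    "0": "constant",
    "1/2": "n^(1/2)",
    "1": "n",
    "cap": "n^(1/(tau-1))",
    "conj": "n^((tau-2)/(tau-1))",
}


@dataclass(frozen=True)
class AlphaAssignment:
    """A vector of per-vertex degree-scale exponents ``h_i ~ n^{alpha_i}``."""

    motif: Motif
    alpha: tuple
    mode: str = "free"

    def __post_init__(self):
        if len(self.alpha) != self.motif.k:
            raise ValueError("alpha length must equal vertex count")
        object.__setattr__(self, "alpha", tuple(F(a) for a in self.alpha))


def objective_value(motif: Motif, alpha, tau, mode: str = "free") -> Fraction:
    """Exact contribution exponent (minus k) of a degree-scale assignment.

    Each edge contributes ``min(alpha_i + alpha_j - 1, 0)``; each vertex costs
    ``(1 - tau) alpha_i``.  Bounds: free mode 0 <= alpha <= 1; typical mode
    0 <= alpha <= 1/(tau-1).
    """
    tau = check_tau(tau)
    if isinstance(alpha, AlphaAssignment):
        mode = alpha.mode
        alpha = alpha.alpha
    alpha = [F(a) for a in alpha]
    if len(alpha) != motif.k:
        raise ValueError("alpha length must equal vertex count")
    cap = F(1) if mode == "free" else 1 / (tau - 1)
    for a in alpha:
        if not (0 <= a <= cap):
            raise ValueError(f"alpha={a} outside [0, {cap}] for mode {mode!r}")
    val = (1 - tau) * sum(alpha)
    for i, j in motif.edges:
        s = alpha[i] + alpha[j]
        if s < 1:
            val += s - 1
    return val


@dataclass
class VariationalResult:
    """Solution of the variational problem at a fixed rational tau."""

    motif: Motif
    mode: str
    variant: str
    tau: Fraction
    feasible: bool
    optimal_value: Fraction | None
    bf_value: Fraction | None
    count_exponent: Fraction | None
    optimizers: tuple
    degenerate: bool
    face_dimension: int
    log_flag: bool
    vertex_roles: tuple

    def to_dict(self) -> dict:
        return {
            "motif": self.motif.to_edgelist_str(),
            "canonical_id": self.motif.canonical_id,
            "mode": self.mode,
            "variant": self.variant,
            "tau": str(self.tau),
            "feasible": self.feasible,
            "optimal_value": str(self.optimal_value),
            "bf_value": None if self.bf_value is None else str(self.bf_value),
            "count_exponent": str(self.count_exponent),
            "count_exponent_float": float(self.count_exponent)
            if self.count_exponent is not None
            else None,
            "optimizers": [[str(a) for a in opt] for opt in self.optimizers],
            "degenerate": self.degenerate,
            "face_dimension": self.face_dimension,
            "log_flag": self.log_flag,
            "vertex_roles": list(self.vertex_roles),
        }


def _rank_fraction_matrix(rows) -> int:
    """Rank of a small matrix of Fractions by Gaussian elimination."""
    mat = [list(r) for r in rows]
    rank = 0
    ncols = len(mat[0]) if mat else 0
    for col in range(ncols):
        piv = next((r for r in range(rank, len(mat)) if mat[r][col] != 0), None)
        if piv is None:
            continue
        mat[rank], mat[piv] = mat[piv], mat[rank]
        prow = mat[rank]
        for r in range(len(mat)):
            if r != rank and mat[r][col] != 0:
                fac = mat[r][col] / prow[col]
                mat[r] = [x - fac * y for x, y in zip(mat[r], prow)]
        rank += 1
    return rank


def _role_of(value: Fraction, tau: Fraction, mode: str) -> str:
    if value == 0:
        return _ROLE_NAMES["0"]
    if value == F(1, 2):
        return _ROLE_NAMES["1/2"]
    if mode == "free":
        if value == 1:
            return _ROLE_NAMES["1"]
    else:
        if value == 1 / (tau - 1):
            return _ROLE_NAMES["cap"]
        if value == (tau - 2) / (tau - 1):
            return _ROLE_NAMES["conj"]
    return f"n^({value})"


def optimize(
    motif: Motif, tau, mode: str = "free", variant: str = "motif"
) -> VariationalResult:
    """Exhaustive exact solution over the mode's candidate assignment set.

    Evaluates all 3^k (free) or 4^k (typical) candidate assignments, returns
    the maximum, every maximizing assignment, the degeneracy flag (>= 2
    maximizers, which by concavity of the objective implies a whole optimal
    face and a logarithmic correction to the count scaling), the affine
    dimension of that face, and per-vertex roles.  The graphlet variant keeps
    only assignments with ``alpha_i + alpha_j <= 1`` on every non-edge.
    """
    tau = check_tau(tau)
    if mode not in ("free", "typical"):
        raise ValueError(f"unknown mode {mode!r}")
    if variant not in ("motif", "graphlet"):
        raise ValueError(f"unknown variant {variant!r}")
    k = motif.k
    if k > 9:
        raise ValueError("optimize supports up to 9 vertices")
    values = FREE_VALUES if mode == "free" else typical_values(tau)
    non_edges = motif.non_edges() if variant == "graphlet" else ()

    best = None
    argmax: list[tuple] = []
    for alpha in itertools.product(values, repeat=k):
        if non_edges and any(alpha[i] + alpha[j] > 1 for i, j in non_edges):
            continue
        val = (1 - tau) * sum(alpha)
        for i, j in motif.edges:
            s = alpha[i] + alpha[j]
            if s < 1:
                val += s - 1
        if best is None or val > best:
            best = val
            argmax = [alpha]
        elif val == best:
            argmax.append(alpha)

    if best is None:
        return VariationalResult(
            motif, mode, variant, tau, False, None, None, None, (), False, 0, False, ()
        )

    count_exponent = k + best
    bf = None
    if mode == "free":
        # back-solved from the partition identity; equals the brute-force
        # partition maximum for the plain motif variant (asserted in tests).
        bf = (2 * count_exponent - (3 - tau) * k) / (tau - 1)
    degenerate = len(argmax) >= 2
    face_dim = 0
    if degenerate:
        v0 = argmax[0]
        rows = [[a - b for a, b in zip(v, v0)] for v in argmax[1:]]
        face_dim = _rank_fraction_matrix(rows)
    roles = []
    for i in range(k):
        vals_i = {opt[i] for opt in argmax}
        if len(vals_i) == 1:
            val = next(iter(vals_i))
            roles.append((str(val), _role_of(val, tau, mode)))
        else:
            roles.append(("varies", "pair-constrained"))
    return VariationalResult(
        motif=motif,
        mode=mode,
        variant=variant,
        tau=tau,
        feasible=True,
        optimal_value=best,
        bf_value=bf,
        count_exponent=count_exponent,
        optimizers=tuple(sorted(argmax)),
        degenerate=degenerate,
        face_dimension=face_dim,
        log_flag=degenerate,
        vertex_roles=tuple(roles),
    )


# ---------------------------------------------------------------------------
# the partition form of the free problem


def bf_value(motif: Motif, partition, tau) -> Fraction:
    """Partition functional ``|S1| - |S2| - (2 E_S1 + E_S1S3)/(tau-1)``.

    ``partition`` maps each vertex to 1, 2 or 3 (sequence or dict); S1 holds
    constant-degree vertices, S2 hubs (degree ~ n), S3 the sqrt(n) bulk.
    """
    tau = check_tau(tau)
    if isinstance(partition, dict):
        partition = [partition[v] for v in range(motif.k)]
    partition = list(partition)
    if len(partition) != motif.k or any(p not in (1, 2, 3) for p in partition):
        raise ValueError("partition must assign every vertex to S1, S2 or S3")
    s1 = sum(1 for p in partition if p == 1)
    s2 = sum(1 for p in partition if p == 2)
    e_s1 = sum(1 for i, j in motif.edges if partition[i] == 1 and partition[j] == 1)
    e_s1s3 = sum(
        1 for i, j in motif.edges if {partition[i], partition[j]} == {1, 3}
    )
    return s1 - s2 - F(2 * e_s1 + e_s1s3, 1) / (tau - 1)


def bf_max(motif: Motif, tau) -> Fraction:
    """Brute-force maximum of the partition functional over all 3^k partitions."""
    tau = check_tau(tau)
    return max(
        bf_value(motif, part, tau)
        for part in itertools.product((1, 2, 3), repeat=motif.k)
    )


# ---------------------------------------------------------------------------
# exponent functions of tau


def _free_candidate_lines(k: int, edges, non_edge_constraints=None):
    """Count-exponent lines of all free candidates, with multiplicities.

    Works in half-integer units so everything is vectorized integer
    arithmetic: candidate alpha in {0, 1/2, 1} is encoded as a in {0, 1, 2};
    the count exponent of a candidate is k + (S+D)/2 - (S/2) tau with
    S = sum a_i and D = sum_edges min(a_i + a_j - 2, 0).

    Returns dict mapping (S, D) -> (multiplicity, lexicographically smallest
    candidate in half-units as a tuple).
    """
    grids = np.stack(
        np.meshgrid(*([np.arange(3, dtype=np.int8)] * k), indexing="ij"), axis=-1
    ).reshape(-1, k)
    keep = np.ones(len(grids), dtype=bool)
    if non_edge_constraints:
        for i, j in non_edge_constraints:
            keep &= grids[:, i] + grids[:, j] <= 2
    grids = grids[keep]
    S = grids.sum(axis=1, dtype=np.int64)
    D = np.zeros(len(grids), dtype=np.int64)
    for i, j in edges:
        D += np.minimum(grids[:, i].astype(np.int64) + grids[:, j] - 2, 0)
    out: dict = {}
    # grids from meshgrid with indexing="ij" are in lexicographic order
    for idx in range(len(grids)):
        key = (int(S[idx]), int(D[idx]))
        if key in out:
            mult, first = out[key]
            out[key] = (mult + 1, first)
        else:
            out[key] = (1, tuple(int(x) for x in grids[idx]))
    return out


def _halves_to_alpha(halves) -> tuple:
    return tuple(F(h, 2) for h in halves)


@lru_cache(maxsize=4096)
def _exponent_function_cached(k, edges, mode, variant):
    motif = Motif(k, edges)
    non_edges = tuple(motif.non_edges()) if variant == "graphlet" else ()
    if mode == "free":
        lines = _free_candidate_lines(k, tuple(motif.edges), non_edges)
        fns, payloads = [], []
        for (S, D), (mult, first) in lines.items():
            fns.append(LinearExponent(F(2 * k + S + D, 2), F(-S, 2)))
            payloads.append(
                {
                    "multiplicity": mult,
                    "assignment": _halves_to_alpha(first),
                    "degenerate": mult >= 2,
                }
            )
        return upper_envelope(fns, payloads)

    # typical mode: symbolic candidate values over (tau - 1); every edge
    # saturation regime is tau-independent on (2, 3), so each labeled
    # candidate is one rational function on the whole interval.
    #   labels: 0 -> 0, 1 -> (tau-2)/(tau-1), 2 -> 1/2, 3 -> 1/(tau-1)
    vertex_cost = {  # (1 - tau) * value, numerator coefficients over (tau-1)
        0: (F(0), F(0), F(0)),
        1: (F(-2), F(3), F(-1)),  # -(tau-2)(tau-1)
        2: (F(-1, 2), F(1), F(-1, 2)),  # -(tau-1)^2 / 2
        3: (F(1), F(-1), F(0)),  # -(tau-1)
    }
    edge_term = {  # min(v_i + v_j - 1, 0) * (tau-1), by unordered label pair
        (0, 0): (F(1), F(-1), F(0)),  # -1 -> -(tau-1)
        (0, 1): (F(-1), F(0), F(0)),  # -1/(tau-1)
        (0, 2): (F(1, 2), F(-1, 2), F(0)),  # -(tau-1)/2
        (0, 3): (F(2), F(-1), F(0)),  # (2-tau)/(tau-1)
        (1, 1): (F(-3), F(1), F(0)),  # (tau-3)/(tau-1)
        (1, 2): (F(-3, 2), F(1, 2), F(0)),  # (tau-3)/(2(tau-1))
        (1, 3): (F(0), F(0), F(0)),
        (2, 2): (F(0), F(0), F(0)),
        (2, 3): (F(0), F(0), F(0)),
        (3, 3): (F(0), F(0), F(0)),
    }
    label_values = {0: "0", 1: "(tau-2)/(tau-1)", 2: "1/2", 3: "1/(tau-1)"}
    # graphlet non-edge feasibility by label pair: values sum <= 1 on (2,3)?
    #   3+3: 2/(tau-1) > 1 always; 2+3: >= 1 with equality only at tau=3 -> ok;
    #   all other pairs sum <= 1.  Only the (3,3) pair is infeasible.
    fns: dict = {}
    for labels in itertools.product(range(4), repeat=k):
        if variant == "graphlet" and any(
            labels[i] == 3 and labels[j] == 3 for i, j in non_edges
        ):
            continue
        c0, c1, c2 = F(k) * -1, F(k), F(0)  # k as k(tau-1)/(tau-1): (-k, k, 0)
        for v in labels:
            a, b, c = vertex_cost[v]
            c0, c1, c2 = c0 + a, c1 + b, c2 + c
        for i, j in motif.edges:
            pair = tuple(sorted((labels[i], labels[j])))
            a, b, c = edge_term[pair]
            c0, c1, c2 = c0 + a, c1 + b, c2 + c
        fn = RationalExponent(c0, c1, c2)
        entry = fns.setdefault(fn, [0, labels])
        entry[0] += 1
    functions, payloads = [], []
    for fn, (mult, labels) in fns.items():
        functions.append(fn)
        payloads.append(
            {
                "multiplicity": mult,
                "assignment": tuple(label_values[l] for l in labels),
                "degenerate": mult >= 2,
            }
        )
    return upper_envelope(functions, payloads)


def exponent_function(
    motif: Motif, mode: str = "free", variant: str = "motif"
) -> PiecewiseExponent:
    """Exact count-scaling exponent as a piecewise function of tau on (2, 3).

    Free mode yields an upper envelope of lines with rational breakpoints;
    typical mode an envelope of quadratics over ``(tau - 1)``.  Each piece's
    meta records the witnessing candidate(s) and a per-piece degeneracy flag.
    """
    if mode not in ("free", "typical"):
        raise ValueError(f"unknown mode {mode!r}")
    if variant not in ("motif", "graphlet"):
        raise ValueError(f"unknown variant {variant!r}")
    if motif.k > 9:
        raise ValueError("exponent_function supports up to 9 vertices")
    env = _exponent_function_cached(motif.k, motif.edges, mode, variant)
    for m in env.meta:
        w = m["witness"]
        m["degenerate"] = any(p["degenerate"] for p in w)
    return env


# ---------------------------------------------------------------------------
# independent grid oracle


def grid_oracle(
    motif: Motif,
    tau,
    mode: str = "free",
    variant: str = "motif",
    step=F(1, 12),
    return_argmax: bool = False,
):
    """Maximum of the objective over a dense rational grid (independent check).

    The grid holds all multiples of ``step`` inside the mode's box; in typical
    mode it always also contains the cutoff ``1/(tau-1)`` (the box bound) and
    its complement ``(tau-2)/(tau-1)`` (the kink of the edge-saturation terms
    toward a cutoff-level hub), so the grid can express every kink of the
    piecewise-linear objective.  Used to verify that the finite candidate sets
    of :func:`optimize` really contain the optimum.
    """
    tau = check_tau(tau)
    step = F(step)
    if step.numerator != 1 or step.denominator > 24:
        raise ValueError("step must be 1/m with m <= 24")
    if motif.k > 5:
        raise ValueError("grid oracle limited to 5 vertices")
    cap = F(1) if mode == "free" else 1 / (tau - 1)
    vals = {F(j) * step for j in range(int(1 / step) + 2) if F(j) * step <= cap}
    vals.add(cap)
    if mode == "typical":
        vals.add((tau - 2) / (tau - 1))
    values = sorted(vals)
    den = 1
    for v in values:
        den = den * v.denominator // math.gcd(den, v.denominator)
    ints = np.array([int(v * den) for v in values], dtype=np.int64)
    k = motif.k
    if len(values) ** k > 40_000_000:
        raise ValueError("grid too large")
    grids = np.stack(
        np.meshgrid(*([ints] * k), indexing="ij"), axis=-1
    ).reshape(-1, k)
    p, q = tau.numerator, tau.denominator
    score = (q - p) * grids.sum(axis=1)
    for i, j in motif.edges:
        score = score + q * np.minimum(grids[:, i] + grids[:, j] - den, 0)
    if variant == "graphlet":
        keep = np.ones(len(grids), dtype=bool)
        for i, j in motif.non_edges():
            keep &= grids[:, i] + grids[:, j] <= den
        score = np.where(keep, score, np.iinfo(np.int64).min)
        if not keep.any():
            raise ValueError("no feasible grid point")
    best = int(score.max())
    value = F(best, q * den)
    if not return_argmax:
        return value
    idx = np.nonzero(score == best)[0]
    args = [tuple(F(int(x), den) for x in grids[i]) for i in idx]
    return value, args
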