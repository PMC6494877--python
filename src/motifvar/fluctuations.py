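"""Motif-count fluctuations: merge classes, variance scaling, self-averaging.

The variance of a motif count N(H) decomposes over the isomorphism classes
H_1, ..., H_l of graphs obtained by merging two labeled copies of H on
r >= 1 vertices:

    Var(N(H)) = C_1 E[N(H_1)] + ... + C_l E[N(H_l)] + E[N(H)]^2 O(1/n),

where C_i counts the ordered merge configurations (pair of r-subsets plus a
bijection) producing class i; the C_i sum to
sum_{s=0}^{k-1} binom(k,s)^2 (k-s)!.  Each merged class' expectation scales
with the free count exponent of the merged graph, so the variance exponent is
an exact upper envelope of piecewise-linear functions of tau, the correction
term contributing the line 2*count_exponent - 1.

N(H) is self-averaging when Var(N(H)) / E[N(H)]^2 -> 0; the exact ratio
exponent decides this on open rational subintervals of (2, 3).  Motifs split
into Type I (B_f = 0, self-averaging), Type II (B_f = 0, not self-averaging)
and Type III (B_f > 0: hub-dominated, never self-averaging).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

from .motifs import Motif
from .piecewise import F, LinearExponent, PiecewiseExponent, upper_envelope
from .variational import (
    _free_candidate_lines,
    check_tau,
    exponent_function,
    optimize,
)


@dataclass(frozen=True)
class MergeClass:
    """An isomorphism class of two-copy merges of a motif."""

    merged: Motif
    constant: int  # number of ordered configurations yielding this class
    overlaps: frozenset  # overlap sizes r realizing the class


def merge_constant_total(k: int) -> int:
    """sum_{s=0}^{k-1} binom(k, s)^2 (k-s)! — the required sum of the C_i."""
    return sum(math.comb(k, s) ** 2 * math.factorial(k - s) for s in range(k))


@lru_cache(maxsize=256)
def _enumerate_merges_cached(k: int, edges: frozenset) -> tuple:
    motif = Motif(k, edges)
    groups: dict[str, dict] = {}
    verts = range(k)
    for r in range(1, k + 1):
        for sub_a in itertools.combinations(verts, r):
            for sub_b in itertools.combinations(verts, r):
                for image in itertools.permutations(sub_b):
                    # copy 1 keeps labels 0..k-1; copy-2 vertex image[i]
                    # lands on sub_a[i]; remaining copy-2 vertices append.
                    mapping = {}
                    for i in range(r):
                        mapping[image[i]] = sub_a[i]
                    nxt = k
                    for v in verts:
                        if v not in mapping:
                            mapping[v] = nxt
                            nxt += 1
                    union = set(motif.edges)
                    for a, b in motif.edges:
                        union.add(tuple(sorted((mapping[a], mapping[b]))))
                    merged = Motif(2 * k - r, union)
                    cid = merged.canonical_id
                    g = groups.setdefault(
                        cid, {"merged": merged, "constant": 0, "overlaps": set()}
                    )
                    g["constant"] += 1
                    g["overlaps"].add(r)
    classes = tuple(
        sorted(
            (
                MergeClass(
                    g["merged"].canonical_relabel(),
                    g["constant"],
                    frozenset(g["overlaps"]),
                )
                for g in groups.values()
            ),
            key=lambda c: (c.merged.k, c.merged.m, c.merged.canonical_id),
        )
    )
    total = sum(c.constant for c in classes)
    expected = merge_constant_total(k)
    if total != expected:
        raise AssertionError(
            f"merge constants sum to {total}, expected {expected}"
        )
    return classes


def enumerate_merges(motif: Motif) -> tuple:
    """All merge classes of two copies of the motif, with exact constants C_i.

    Configurations are ordered: every pair of r-subsets of the two copies and
    every bijection between them counts once (this is the convention under
    which the triangle yields bow-tie 9, diamond 18, triangle 6 and the C_i
    totals hold).  The full aligned overlap reproduces H itself, so the
    identity class is always present.
    """
    if motif.k > 5:
        raise ValueError("merge enumeration limited to motifs on <= 5 vertices")
    if not motif.is_connected():
        raise ValueError("merge calculus requires a connected motif")
    return _enumerate_merges_cached(motif.k, motif.edges)


# ---------------------------------------------------------------------------
# variance / ratio exponents


@lru_cache(maxsize=4096)
def _free_lines_of(k: int, edges: frozenset):
    """(line, multiplicity) list for the free count exponent of one graph."""
    out = []
    for (S, D), (mult, _first) in _free_candidate_lines(k, tuple(edges)).items():
        out.append((LinearExponent(F(2 * k + S + D, 2), F(-S, 2)), mult))
    return tuple(out)


def variance_exponent_function(motif: Motif) -> PiecewiseExponent:
    """Exact variance-scaling exponent of N(H) as a function of tau.

    Upper envelope over (a) every merged class' free count-exponent lines and
    (b) the correction line ``2 * count_exponent - 1`` (the subtracted
    diagonal terms, maximal at overlap r = 1).  Each piece's meta lists the
    dominating merge classes and whether a degenerate (log-carrying) class
    decides the piece.
    """
    fns, payloads = [], []
    for mc in enumerate_merges(motif):
        for line, mult in _free_lines_of(mc.merged.k, mc.merged.edges):
            fns.append(line)
            payloads.append(
                {
                    "kind": "merge",
                    "class": mc.merged.canonical_id,
                    "constant": mc.constant,
                    "multiplicity": mult,
                    "degenerate": mult >= 2,
                }
            )
    for line, mult in _free_lines_of(motif.k, motif.edges):
        fns.append(line * 2 - 1)
        payloads.append(
            {"kind": "correction", "multiplicity": mult, "degenerate": False}
        )
    env = upper_envelope(fns, payloads)
    for m in env.meta:
        m["log_tie"] = any(p["degenerate"] for p in m["witness"])
    return env


def ratio_exponent_function(motif: Motif) -> PiecewiseExponent:
    """Exponent of Var(N(H)) / E[N(H)]^2 (negative = vanishing fluctuations)."""
    return variance_exponent_function(motif) - exponent_function(motif).scale(2)


@dataclass
class FluctuationReport:
    """Complete fluctuation summary of one motif."""

    motif: Motif
    merge_catalog: tuple
    count_exponent: PiecewiseExponent
    variance_exponent: PiecewiseExponent
    ratio_exponent: PiecewiseExponent
    sa_intervals: tuple
    type_map: tuple  # ((lo, hi, "I"|"II"|"III"), ...)
    tie_warnings: tuple


def self_averaging_intervals(motif: Motif):
    """Open tau-intervals in (2, 3) where Var/E^2 -> 0 (ratio exponent < 0).

    Intervals where the ratio exponent is exactly 0 are excluded: a bounded,
    non-vanishing relative variance fails the self-averaging definition.
    """
    return tuple(ratio_exponent_function(motif).negative_intervals())


def tie_warnings(motif: Motif) -> tuple:
    """Intervals where the scaling comparison is decided only up to log factors.

    Flags (a) envelope pieces of the variance exponent won by a degenerate
    (log-carrying) merged class and (b) intervals where the ratio exponent is
    identically zero, where the polynomial order alone cannot separate
    variance from squared mean.
    """
    out = []
    var_env = variance_exponent_function(motif)
    for i, m in enumerate(var_env.meta):
        if m.get("log_tie"):
            out.append(
                (
                    var_env.breakpoints[i],
                    var_env.breakpoints[i + 1],
                    "variance piece dominated by a log-degenerate merge class",
                )
            )
    for lo, hi in ratio_exponent_function(motif).zero_intervals():
        out.append((lo, hi, "ratio exponent identically zero"))
    return tuple(out)


def _bf_positive_intervals(motif: Motif):
    """Open intervals where B_f(H) > 0, i.e. where the free envelope exceeds
    the all-sqrt(n) line (3-tau) k / 2."""
    env = exponent_function(motif)
    allhalf = PiecewiseExponent.constant_like(
        LinearExponent(F(3 * motif.k, 2), F(-motif.k, 2))
    )
    diff = env - allhalf
    return tuple(diff._sign_intervals(lambda v: v > 0))


def _in_intervals(tau, intervals) -> bool:
    return any(lo < tau < hi for lo, hi in intervals)


def classify_type(motif: Motif, tau) -> str:
    """Type III if B_f > 0 at tau; else Type I on a self-averaging interval,
    Type II otherwise.  Interval endpoints classify non-self-averaging, with
    a boundary warning."""
    tau = check_tau(tau)
    res = optimize(motif, tau, mode="free")
    if res.bf_value > 0:
        return "III"
    sa = self_averaging_intervals(motif)
    if _in_intervals(tau, sa):
        return "I"
    if any(tau == lo or tau == hi for lo, hi in sa):
        warnings.warn(
            f"tau={tau} is a self-averaging boundary point; classified "
            "non-self-averaging by convention",
            stacklevel=2,
        )
    return "II"


def type_map(motif: Motif) -> tuple:
    """Partition of (2, 3) into maximal intervals with a constant type."""
    cuts = {F(2), F(3)}
    sa = self_averaging_intervals(motif)
    bf_pos = _bf_positive_intervals(motif)
    for lo, hi in list(sa) + list(bf_pos):
        cuts.update([lo, hi])
    cuts = sorted(c for c in cuts if F(2) <= c <= F(3))
    out = []
    for lo, hi in zip(cuts, cuts[1:]):
        mid = (lo + hi) / 2
        if _in_intervals(mid, bf_pos):
            t = "III"
        elif _in_intervals(mid, sa):
            t = "I"
        else:
            t = "II"
        if out and out[-1][2] == t:
            out[-1] = (out[-1][0], hi, t)
        else:
            out.append((lo, hi, t))
    return tuple(out)


def fluctuation_report(motif: Motif) -> FluctuationReport:
    return FluctuationReport(
        motif=motif,
        merge_catalog=enumerate_merges(motif),
        count_exponent=exponent_function(motif),
        variance_exponent=variance_exponent_function(motif),
        ratio_exponent=ratio_exponent_function(motif),
        sa_intervals=self_averaging_intervals(motif),
        type_map=type_map(motif),
        tie_warnings=tie_warnings(motif),
    )
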