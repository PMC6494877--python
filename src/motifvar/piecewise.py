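"""Exact piecewise exponents in the power-law exponent tau on (2, 3).

Count-scaling, variance and ratio exponents are functions of tau built from
finitely many candidate assignments.  Each free-mode candidate yields an
exponent linear in tau; each typical-mode candidate yields a ratio of a
quadratic and (tau - 1).  Upper envelopes over candidates are computed by
exact rational arithmetic: pairwise crossing points partition (2, 3) into
intervals on which a single candidate wins, decided at rational midpoints.

Candidate crossing points may be quadratic surds; these are kept exact
(:class:`QuadSurd`) and all winner decisions are made at rational probe
points, so the whole construction stays in exact arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

F = Fraction

TAU_LO = F(2)
TAU_HI = F(3)


def _float_eval(seg, x: float) -> float:
    if isinstance(seg, LinearExponent):
        return float(seg.a) + float(seg.b) * x
    return (float(seg.c0) + float(seg.c1) * x + float(seg.c2) * x * x) / (x - 1.0)


@dataclass(frozen=True)
class LinearExponent:
    """Exact linear function ``a + b*tau`` of the power-law exponent."""

    a: Fraction
    b: Fraction

    def __call__(self, tau) -> Fraction:
        return self.a + self.b * tau

    def __add__(self, other):
        if isinstance(other, LinearExponent):
            return LinearExponent(self.a + other.a, self.b + other.b)
        return LinearExponent(self.a + F(other), self.b)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, LinearExponent):
            return LinearExponent(self.a - other.a, self.b - other.b)
        return LinearExponent(self.a - F(other), self.b)

    def __mul__(self, c):
        c = F(c)
        return LinearExponent(self.a * c, self.b * c)

    __rmul__ = __mul__

    def __str__(self):
        if self.b == 0:
            return f"{self.a}"
        return f"{self.a} + {self.b}*tau" if self.a != 0 else f"{self.b}*tau"


@dataclass(frozen=True)
class RationalExponent:
    """Exact function ``(c0 + c1*tau + c2*tau^2) / (tau - 1)`` on (2, 3).

    Houses the typical-variation exponents; linear functions embed via
    multiplication of numerator and denominator by ``(tau - 1)``.
    """

    c0: Fraction
    c1: Fraction
    c2: Fraction

    @classmethod
    def from_linear(cls, lin: LinearExponent) -> "RationalExponent":
        # (a + b t)(t - 1) = -a + (a - b) t + b t^2
        return cls(-lin.a, lin.a - lin.b, lin.b)

    def __call__(self, tau):
        tau = F(tau) if not hasattr(tau, "free_symbols") else tau
        return (self.c0 + self.c1 * tau + self.c2 * tau * tau) / (tau - 1)

    def __add__(self, other):
        if isinstance(other, RationalExponent):
            return RationalExponent(
                self.c0 + other.c0, self.c1 + other.c1, self.c2 + other.c2
            )
        return self + RationalExponent.from_linear(LinearExponent(F(other), F(0)))

    __radd__ = __add__

    def as_linear(self):
        """Exact linear form if ``(tau - 1)`` divides the numerator, else None."""
        if self.c0 + self.c1 + self.c2 != 0:
            return None
        return LinearExponent(-self.c0, self.c2)

    def __str__(self):
        lin = self.as_linear()
        if lin is not None:
            return str(lin)
        return f"({self.c0} + {self.c1}*tau + {self.c2}*tau^2)/(tau - 1)"


def _square_free_split(n: int) -> tuple[int, int]:
    """n = f^2 * g with g square-free (n >= 1, small integers)."""
    f, g, d = 1, 1, 2
    while d * d <= n:
        while n % (d * d) == 0:
            f *= d
            n //= d * d
        if n % d == 0:
            g *= d
            n //= d
        d += 1
    return f, g * n


class QuadSurd:
    """Exact real number ``p + s*sqrt(d)`` with rational p, s != 0, integer
    square-free d >= 2.  Supports exact comparison against rationals, which is
    all the envelope construction needs for irrational crossing points."""

    __slots__ = ("p", "s", "d")

    def __init__(self, p: Fraction, s: Fraction, d: int):
        self.p, self.s, self.d = F(p), F(s), int(d)

    @classmethod
    def make(cls, p: Fraction, s: Fraction, d: Fraction):
        """Normalize p + s*sqrt(d) for rational d >= 0; returns Fraction if exact."""
        if s == 0 or d == 0:
            return F(p)
        num, den = d.numerator, d.denominator
        f, g = _square_free_split(num * den)  # sqrt(num/den) = sqrt(num*den)/den
        s2 = s * F(f, den)
        if g == 1:
            return p + s2
        return cls(p, s2, g)

    def __float__(self):
        return float(self.p) + float(self.s) * math.sqrt(self.d)

    def _cmp_fraction(self, r: Fraction) -> int:
        """Sign of (self - r), exact."""
        t = (r - self.p) / self.s  # self > r  <=>  sqrt(d) > t (s>0) / < t (s<0)
        if self.s > 0:
            if t < 0:
                return 1
            return 1 if t * t < self.d else -1  # t*t == d impossible (d square-free)
        if t < 0:
            return -1
        return -1 if t * t < self.d else 1

    def __lt__(self, other):
        if isinstance(other, (Fraction, int)):
            return self._cmp_fraction(F(other)) < 0
        if isinstance(other, QuadSurd):
            if self == other:
                return False
            return float(self) < float(other)
        return NotImplemented

    def __gt__(self, other):
        if isinstance(other, (Fraction, int)):
            return self._cmp_fraction(F(other)) > 0
        if isinstance(other, QuadSurd):
            if self == other:
                return False
            return float(self) > float(other)
        return NotImplemented

    def __le__(self, other):
        return self == other or self < other

    def __ge__(self, other):
        return self == other or self > other

    def __eq__(self, other):
        if isinstance(other, QuadSurd):
            return (self.p, self.s, self.d) == (other.p, other.s, other.d)
        return False  # a surd never equals a rational

    def __hash__(self):
        return hash((self.p, self.s, self.d))

    def __repr__(self):
        return f"({self.p} + {self.s}*sqrt({self.d}))"


def rational_between(x, y) -> Fraction:
    """A rational strictly between x < y (each Fraction or QuadSurd), exact."""
    if isinstance(x, Fraction) and isinstance(y, Fraction):
        return (x + y) / 2
    mid = (float(x) + float(y)) / 2
    for nd in (10**4, 10**8, 10**12, 10**16):
        r = F(mid).limit_denominator(nd)
        if x < r < y:
            return r
    raise ArithmeticError(f"no rational found between {x} and {y}")


def _quad_roots(c2: Fraction, c1: Fraction, c0: Fraction):
    """Real roots of c2 x^2 + c1 x + c0 = 0, exact; [] if none or identically 0."""
    if c2 == 0:
        if c1 == 0:
            return []
        return [-c0 / c1]
    disc = c1 * c1 - 4 * c2 * c0
    if disc < 0:
        return []
    return [
        QuadSurd.make(-c1 / (2 * c2), F(-1) / (2 * c2), disc),
        QuadSurd.make(-c1 / (2 * c2), F(1) / (2 * c2), disc),
    ]


def _difference_roots(f, g):
    """Crossing points of two exponent functions (exact)."""
    if isinstance(f, LinearExponent) and isinstance(g, LinearExponent):
        return _quad_roots(F(0), f.b - g.b, f.a - g.a)
    rf = f if isinstance(f, RationalExponent) else RationalExponent.from_linear(f)
    rg = g if isinstance(g, RationalExponent) else RationalExponent.from_linear(g)
    return _quad_roots(rf.c2 - rg.c2, rf.c1 - rg.c1, rf.c0 - rg.c0)


class PiecewiseExponent:
    """Continuous piecewise exponent on the open interval (2, 3).

    ``breakpoints`` includes both domain endpoints; ``segments[i]`` is valid on
    the open interval (breakpoints[i], breakpoints[i+1]) and, by continuity, at
    the shared breakpoints.  ``meta[i]`` carries arbitrary per-piece payload
    (witnessing assignments, degeneracy flags, dominant merge classes).
    """

    def __init__(self, breakpoints, segments, meta=None):
        if len(breakpoints) != len(segments) + 1:
            raise ValueError("need one more breakpoint than segments")
        if len(segments) == 0:
            raise ValueError("need at least one segment")
        self.breakpoints = list(breakpoints)
        self.segments = list(segments)
        self.meta = list(meta) if meta is not None else [{} for _ in segments]
        for i in range(len(segments) - 1):
            x = self.breakpoints[i + 1]
            if isinstance(x, Fraction):
                if self.segments[i](x) != self.segments[i + 1](x):
                    raise ValueError(f"discontinuity at breakpoint {x}")
            else:  # surd breakpoint: numeric sanity check only
                fx = float(x)
                va = _float_eval(self.segments[i], fx)
                vb = _float_eval(self.segments[i + 1], fx)
                if abs(va - vb) > 1e-9:
                    raise ValueError(f"discontinuity at breakpoint {x}")

    @classmethod
    def constant_like(cls, seg, meta=None):
        return cls([TAU_LO, TAU_HI], [seg], [meta or {}])

    def __call__(self, tau):
        tau = F(tau)
        if not (TAU_LO < tau < TAU_HI):
            raise ValueError(f"tau={tau} outside the open interval (2, 3)")
        for i in range(len(self.segments)):
            if tau <= self.breakpoints[i + 1]:
                return self.segments[i](tau)
        return self.segments[-1](tau)

    def segment_at(self, tau):
        """(segment, meta) governing the given tau (right piece at breakpoints)."""
        tau = F(tau)
        for i in range(len(self.segments)):
            if tau < self.breakpoints[i + 1]:
                return self.segments[i], self.meta[i]
        return self.segments[-1], self.meta[-1]

    @property
    def interior_breakpoints(self):
        return self.breakpoints[1:-1]

    def is_linear(self) -> bool:
        return all(isinstance(s, LinearExponent) for s in self.segments)

    def linear_segments(self):
        out = []
        for s in self.segments:
            if isinstance(s, LinearExponent):
                out.append(s)
            else:
                lin = s.as_linear()
                if lin is None:
                    raise ValueError("segment is not linear in tau")
                out.append(lin)
        return out

    # -- arithmetic on piecewise-linear functions -------------------------

    def combine(self, other: "PiecewiseExponent", op):
        """Pointwise combination of two piecewise-linear functions."""
        a, b = self.linear_segments(), other.linear_segments()
        cuts = sorted(set(self.breakpoints) | set(other.breakpoints))
        segs, meta = [], []
        for i in range(len(cuts) - 1):
            mid = (cuts[i] + cuts[i + 1]) / 2
            sa = a[self._index_at(self, mid)]
            sb = b[self._index_at(other, mid)]
            segs.append(op(sa, sb))
            meta.append({})
        return PiecewiseExponent(cuts, segs, meta)._merged()

    @staticmethod
    def _index_at(pw, tau):
        for i in range(len(pw.segments)):
            if tau < pw.breakpoints[i + 1]:
                return i
        return len(pw.segments) - 1

    def __sub__(self, other):
        if isinstance(other, PiecewiseExponent):
            return self.combine(other, lambda x, y: x - y)
        return self.combine(
            PiecewiseExponent.constant_like(LinearExponent(F(other), F(0))),
            lambda x, y: x - y,
        )

    def scale(self, c):
        c = F(c)
        return PiecewiseExponent(
            self.breakpoints, [s * c for s in self.linear_segments()], self.meta
        )

    def shift(self, c):
        c = F(c)
        return PiecewiseExponent(
            self.breakpoints, [s + c for s in self.linear_segments()], self.meta
        )

    def _merged(self):
        """Merge adjacent segments that are the same function."""
        bps = [self.breakpoints[0]]
        segs, meta = [], []
        for i, s in enumerate(self.segments):
            if segs and segs[-1] == s:
                bps[-1] = self.breakpoints[i + 1]
                continue
            segs.append(s)
            meta.append(self.meta[i])
            bps.append(self.breakpoints[i + 1])
        return PiecewiseExponent(bps, segs, meta)

    # -- sign analysis (piecewise-linear only) ----------------------------

    def negative_intervals(self):
        """Maximal open subintervals of (2, 3) where the value is < 0 (exact)."""
        return self._sign_intervals(lambda v: v < 0)

    def zero_intervals(self):
        """Open subintervals where the function is identically 0."""
        out = []
        for i, s in enumerate(self.linear_segments()):
            if s.a == 0 and s.b == 0:
                out.append((self.breakpoints[i], self.breakpoints[i + 1]))
        return _merge_intervals(out)

    def _sign_intervals(self, pred):
        pieces = []
        for i, s in enumerate(self.linear_segments()):
            lo, hi = self.breakpoints[i], self.breakpoints[i + 1]
            if s.b == 0:
                if pred(s.a):
                    pieces.append((lo, hi))
                continue
            root = -s.a / s.b
            mid_lo = (lo + min(max(root, lo), hi)) / 2
            mid_hi = (min(max(root, lo), hi) + hi) / 2
            for a, b, probe in (
                (lo, min(max(root, lo), hi), mid_lo),
                (min(max(root, lo), hi), hi, mid_hi),
            ):
                if a < b and pred(s(probe)):
                    pieces.append((a, b))
        return _merge_intervals(pieces)

    def __eq__(self, other):
        if not isinstance(other, PiecewiseExponent):
            return NotImplemented
        return (
            self.breakpoints == other.breakpoints and self.segments == other.segments
        )

    def __str__(self):
        parts = []
        for i, s in enumerate(self.segments):
            parts.append(
                f"{s} on ({self.breakpoints[i]}, {self.breakpoints[i + 1]})"
            )
        return "; ".join(parts)

    def pretty(self) -> str:
        return str(self)


def _merge_intervals(intervals):
    """Merge adjacent open intervals sharing an endpoint; assumes sorted input."""
    intervals = sorted(intervals)
    out = []
    for lo, hi in intervals:
        if out and out[-1][1] == lo:
            out[-1] = (out[-1][0], hi)
        else:
            out.append((lo, hi))
    return [tuple(iv) for iv in out]


def upper_envelope(functions, payloads=None, lo=TAU_LO, hi=TAU_HI) -> PiecewiseExponent:
    """Exact upper envelope of exponent functions over the open (lo, hi).

    ``payloads`` maps each function (by index) to arbitrary metadata; each
    envelope piece records the winning function's payload under ``"witness"``
    and the functions tying the winner at interior breakpoints are implicit
    (distinct functions agree only at isolated points).
    """
    fns = list(functions)
    if not fns:
        raise ValueError("empty function list")
    if payloads is None:
        payloads = [None] * len(fns)
    # dedupe identical functions, merging payloads
    uniq: dict = {}
    for fn, pl in zip(fns, payloads):
        key = fn
        if key in uniq:
            uniq[key].append(pl)
        else:
            uniq[key] = [pl]
    fns = list(uniq.keys())
    pls = list(uniq.values())

    lo, hi = F(lo), F(hi)
    cuts = {lo, hi}
    for i in range(len(fns)):
        for j in range(i + 1, len(fns)):
            for r in _difference_roots(fns[i], fns[j]):
                if lo < r < hi:
                    cuts.add(r)
    cuts = sorted(cuts)

    segs, meta, bps = [], [], [cuts[0]]
    for i in range(len(cuts) - 1):
        mid = rational_between(cuts[i], cuts[i + 1])
        vals = [fn(mid) for fn in fns]
        best = max(range(len(fns)), key=lambda j: vals[j])
        if segs and segs[-1] == fns[best]:
            bps[-1] = cuts[i + 1]
            continue
        segs.append(fns[best])
        meta.append({"witness": pls[best]})
        bps.append(cuts[i + 1])
    return PiecewiseExponent(bps, segs, meta)
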