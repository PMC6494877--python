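"""Simulation experiments connecting the exact theory to sampled graphs.

Three harnesses:

* scaling_experiment — motif counts over a grid of network sizes; the slope
  of log(median count) against log(n) estimates the typical count exponent
  (medians, not means: when the dominant structure contains hubs, the mean
  is driven by vanishingly rare samples and converges far too slowly for
  simulation sizes).
* fluctuation_experiment — the distribution of counts across samples at one
  size: normalized counts, the empirical relative variance Var/mean^2, and a
  histogram of the normalized density.
* classification_report — machine-readable table of the exact theory for
  every catalog motif: exponent pieces, degeneracy, merge-class counts,
  self-averaging intervals and the Type I/II/III map.

Every experiment is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .counting import count_motif
from .fluctuations import (
    enumerate_merges,
    self_averaging_intervals,
    type_map,
    variance_exponent_function,
)
from .hvmodel import sample_graph, sample_hidden_variables
from .motifs import Motif, enumerate_connected_motifs
from .piecewise import RationalExponent
from .variational import exponent_function, optimize

F = Fraction

# guard against accidentally huge pair scans (sum of n^2 * samples)
_DESK_BUDGET = 5e11


def _check_budget(n_grid, samples):
    cost = sum(float(n) ** 2 * samples for n in n_grid)
    if cost > _DESK_BUDGET:
        raise ValueError(
            f"requested simulation cost {cost:.2e} pair-draws exceeds the "
            f"desk-scale budget {_DESK_BUDGET:.0e}"
        )


def _sample_counts(motif, tau, n, samples, seed, induced=False):
    counts = np.empty(samples, dtype=np.int64)
    for s in range(samples):
        hv = sample_hidden_variables(n, tau, seed=_derive_seed(seed, n, s))
        g = sample_graph(hv)
        counts[s] = count_motif(g, motif, induced=induced)
    return counts


def _derive_seed(seed, n, s):
    # stable sub-seed below 2^31 for each (n, sample) pair
    return (1_000_003 * (seed % 977) + 31 * n + s) % (2**31 - 1)


@dataclass
class ScalingEstimate:
    motif: Motif
    tau: float
    n_grid: tuple
    samples: int
    median_counts: tuple
    mean_counts: tuple
    slope: float  # log-log slope of the median counts
    slope_stderr: float
    mean_slope: float
    typical_exponent: float
    free_exponent: float


def scaling_experiment(
    motif: Motif, tau, n_grid, samples: int, seed: int = 0, induced: bool = False
) -> ScalingEstimate:
    """Median-count scaling across network sizes vs the exact exponents.

    Grid points whose median count is zero are dropped with a warning (the
    log-log fit needs positive medians); at least 3 points must remain.
    """
    n_grid = tuple(sorted(int(n) for n in n_grid))
    if len(n_grid) < 3:
        raise ValueError("need at least 3 grid points")
    _check_budget(n_grid, samples)
    tau_f = F(tau)
    medians, means = [], []
    for n in n_grid:
        counts = _sample_counts(motif, tau_f, n, samples, seed, induced)
        medians.append(float(np.median(counts)))
        means.append(float(np.mean(counts)))
    keep = [i for i, mval in enumerate(medians) if mval > 0]
    if len(keep) < len(n_grid):
        warnings.warn(
            f"dropped {len(n_grid) - len(keep)} grid point(s) with zero median count",
            stacklevel=2,
        )
    if len(keep) < 3:
        raise ValueError("fewer than 3 usable grid points")
    x = np.log([n_grid[i] for i in keep])
    y = np.log([medians[i] for i in keep])
    coef, cov = np.polyfit(x, y, 1, cov=True)
    mean_coef = np.polyfit(x, np.log([max(means[i], 1e-300) for i in keep]), 1)
    typ = optimize(motif, tau_f, mode="typical").count_exponent
    free = optimize(motif, tau_f, mode="free").count_exponent
    return ScalingEstimate(
        motif=motif,
        tau=float(tau_f),
        n_grid=n_grid,
        samples=samples,
        median_counts=tuple(medians),
        mean_counts=tuple(means),
        slope=float(coef[0]),
        slope_stderr=float(np.sqrt(max(cov[0, 0], 0.0))),
        mean_slope=float(mean_coef[0]),
        typical_exponent=float(typ),
        free_exponent=float(free),
    )


@dataclass
class FluctuationSample:
    motif: Motif
    tau: float
    n: int
    samples: int
    counts: np.ndarray = field(repr=False)
    normalized: np.ndarray = field(repr=False)  # counts / sample mean
    var_over_mean2: float
    mean: float
    median: float
    skewness: float
    histogram: tuple  # (densities, bin edges) of the normalized counts


def fluctuation_experiment(
    motif: Motif, tau, n: int, samples: int, seed: int = 0, bins: int = 30
) -> FluctuationSample:
    """Distribution of motif counts across model samples at one size."""
    _check_budget([n], samples)
    tau_f = F(tau)
    counts = _sample_counts(motif, tau_f, int(n), samples, seed)
    mean = float(np.mean(counts))
    norm = counts / mean if mean > 0 else counts.astype(float)
    var = float(np.var(counts))
    sd = float(np.std(counts))
    skew = float(np.mean((counts - mean) ** 3) / sd**3) if sd > 0 else 0.0
    dens, edges = np.histogram(norm, bins=bins, density=True)
    return FluctuationSample(
        motif=motif,
        tau=float(tau_f),
        n=int(n),
        samples=samples,
        counts=counts,
        normalized=norm,
        var_over_mean2=var / mean**2 if mean > 0 else float("nan"),
        mean=mean,
        median=float(np.median(counts)),
        skewness=skew,
        histogram=(dens, edges),
    )


def fluctuation_trend(motif: Motif, tau, n_grid, samples: int, seed: int = 0):
    """Empirical Var/mean^2 across sizes: the finite-n self-averaging probe."""
    return tuple(
        fluctuation_experiment(motif, tau, n, samples, seed) for n in sorted(n_grid)
    )


def _fmt_intervals(ivs) -> str:
    if not ivs:
        return "-"
    return ", ".join(f"({lo}, {hi})" for lo, hi in ivs)


def _bf_pieces(free_env, k) -> str:
    """B_f as a function of tau, back-solved piecewise from the count envelope:
    B_f = (2 c(tau) - (3-tau) k) / (tau - 1)."""
    parts = []
    for i, seg in enumerate(free_env.linear_segments()):
        bf = RationalExponent(2 * seg.a - 3 * k, 2 * seg.b + k, F(0))
        lin = bf.as_linear()
        parts.append(
            f"{lin if lin is not None else bf} on "
            f"({free_env.breakpoints[i]}, {free_env.breakpoints[i + 1]})"
        )
    return "; ".join(parts)


def classification_report(max_k: int = 5, include_typical: bool = True):
    """The exact classification of every connected motif on 3..max_k vertices.

    Returns a pandas DataFrame with one row per motif: free (and typical)
    count-exponent pieces, per-piece degeneracy, merge-catalog size,
    variance-exponent pieces, self-averaging intervals and the type map.
    """
    import pandas as pd

    if max_k not in (3, 4, 5):
        raise ValueError("max_k must be 3, 4 or 5")
    rows = []
    for k in range(3, max_k + 1):
        for motif in enumerate_connected_motifs(k):
            free_env = exponent_function(motif, mode="free")
            var_env = variance_exponent_function(motif)
            sa = self_averaging_intervals(motif)
            tmap = type_map(motif)
            row = {
                "k": k,
                "edges": motif.to_edgelist_str(),
                "canonical_id": motif.canonical_id,
                "m": motif.m,
                "free_exponent": str(free_env),
                "bf_pieces": _bf_pieces(free_env, k),
                "free_degenerate": any(m.get("degenerate") for m in free_env.meta),
                "merge_classes": len(enumerate_merges(motif)),
                "variance_exponent": str(var_env),
                "sa_intervals": _fmt_intervals(sa),
                "types": "; ".join(f"({lo},{hi}):{t}" for lo, hi, t in tmap),
            }
            if include_typical:
                row["typical_exponent"] = str(exponent_function(motif, mode="typical"))
            rows.append(row)
    return pd.DataFrame(rows)
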