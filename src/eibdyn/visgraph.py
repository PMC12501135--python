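"""Natural visibility graph (NVG) temporal features of a concentration curve.

A time series maps to a graph whose nodes are time points; two points are
connected when the straight line between them passes strictly above every
intermediate sample.  Directing every edge forward in time gives a directed
graph whose mean out-degree tracks the local temporal gradient of the curve
(lower out-degree = more time-dependent change) and whose Kullback–Leibler
divergence between out- and in-degree distributions indexes temporal
irreversibility: a stationary, time-reversible series has matching degree
distributions and KLD near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "VisibilityGraph",
    "VisibilityFeatures",
    "nvg_adjacency",
    "degree_features",
    "degree_kld",
    "visibility_features",
]


@dataclass(frozen=True)
class VisibilityGraph:
    """Directed natural visibility graph of a uniformly sampled series.

    Edges are (a, b) index pairs with a < b, directed forward in time.
    """

    n: int
    edges: frozenset
    out_degree: np.ndarray
    in_degree: np.ndarray


@dataclass(frozen=True)
class VisibilityFeatures:
    mean_out_degree: float
    kld: float
    n_frames: int


def nvg_adjacency(series) -> VisibilityGraph:
    """Build the directed natural visibility graph of a series.

    Indices a < b are connected iff every intermediate sample lies strictly
    below the chord from (a, y_a) to (b, y_b):

        y_c < y_b + (y_a − y_b) · (b − c) / (b − a)   for all a < c < b.

    Strict inequality: collinear points block visibility.  Uniform unit frame
    spacing is assumed (the spacing constant cancels in the criterion).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("series must be 1-D with at least 2 points")
    if not np.all(np.isfinite(y)):
        bad = np.nonzero(~np.isfinite(y))[0].tolist()
        raise ValueError(f"series contains non-finite values at frames {bad}")

    n = y.size
    edges = set()
    out_deg = np.zeros(n, dtype=int)
    in_deg = np.zeros(n, dtype=int)
    for a in range(n - 1):
        # b visible from a iff slope(a→b) strictly exceeds the running max
        # slope to all intermediate points
        max_slope = -np.inf
        for b in range(a + 1, n):
            slope = (y[b] - y[a]) / (b - a)
            if b == a + 1 or slope > max_slope:
                edges.add((a, b))
                out_deg[a] += 1
                in_deg[b] += 1
            max_slope = max(max_slope, slope)
    return VisibilityGraph(n=n, edges=frozenset(edges),
                           out_degree=out_deg, in_degree=in_deg)


def degree_features(graph: VisibilityGraph) -> float:
    """Mean out-degree over all nodes (= |edges| / n)."""
    return float(graph.out_degree.mean())


def degree_kld(graph: VisibilityGraph) -> float:
    """KL divergence between out- and in-degree distributions.

    Both empirical distributions (over degree values k = 0..n−1) are restricted
    to their common support and renormalized before computing
    Σ P̃_out(k) · ln(P̃_out(k) / P̃_in(k)); this guarantees a non-negative,
    finite divergence (Gibbs' inequality) without ad-hoc zero-bin smoothing.
    """
    n = graph.n
    p_out = np.bincount(graph.out_degree, minlength=n).astype(float) / n
    p_in = np.bincount(graph.in_degree, minlength=n).astype(float) / n
    common = (p_out > 0) & (p_in > 0)
    if not common.any():
        warnings.warn("degree distributions share no support; returning +inf")
        return float("inf")
    q_out = p_out[common] / p_out[common].sum()
    q_in = p_in[common] / p_in[common].sum()
    return float(np.sum(q_out * np.log(q_out / q_in)))


def visibility_features(series) -> VisibilityFeatures:
    """Convenience wrapper: NVG then both temporal features."""
    g = nvg_adjacency(series)
    return VisibilityFeatures(mean_out_degree=degree_features(g),
                              kld=degree_kld(g), n_frames=g.n)
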