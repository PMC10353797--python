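"""Intrinsic Gaussian Markov random field structure over a region graph.

The structured spatial effect g follows an intrinsic CAR prior: given its
neighbours, the effect of region k is Gaussian with mean the neighbour
average and variance delta / |N(k)|.  Jointly this is the improper GMRF
with precision Q/delta, where Q has the neighbour counts on the diagonal
and -1 for each adjacent pair; Q annihilates the constant vector, which is
why the sampler recentres g every iteration.
"""

from __future__ import annotations

import numpy as np

from .graphs import RegionGraph


def gmrf_structure(graph: RegionGraph) -> np.ndarray:
    """Unit-variance ICAR structure matrix Q (neighbour counts / -adjacency)."""
    n = graph.n_regions
    q = np.zeros((n, n))
    idx = {r: i for i, r in enumerate(graph.region_ids)}
    for r, nbrs in graph.neighbors.items():
        q[idx[r], idx[r]] = len(nbrs)
        for s in nbrs:
            q[idx[r], idx[s]] = -1.0
    return q


def gmrf_precision(
    graph: RegionGraph, delta: float, isolated: str = "error"
) -> np.ndarray:
    """Prior precision Q/delta of the structured spatial effect.

    ``isolated`` picks the policy for regions with no neighbours:
    ``"error"`` refuses the graph, ``"zero"`` leaves the corresponding
    row/column zero (that region's structured effect is pinned to 0 by the
    sampler instead of smoothed).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    isolates = graph.isolated_regions()
    if isolates and isolated == "error":
        raise ValueError(
            f"regions with no neighbours: {isolates}; pass isolated='zero' "
            "to drop their structured effect"
        )
    return gmrf_structure(graph) / delta


def gmrf_conditional(graph: RegionGraph, values, region, delta: float):
    """Conditional (mean, variance) of one region's effect given the rest.

    Implements the neighbour-average form: mean is the average of the
    adjacent regions' current values, variance is delta / |N(k)|.
    """
    values = np.asarray(values, dtype=float)
    nbrs = graph.neighbors[region]
    if not nbrs:
        raise ValueError(f"region {region!r} has no neighbours")
    idx = {r: i for i, r in enumerate(graph.region_ids)}
    nb_vals = [values[idx[s]] for s in nbrs]
    return float(np.mean(nb_vals)), delta / len(nbrs)


def sample_icar(graph: RegionGraph, delta: float, rng: np.random.Generator):
    """One draw of the centred ICAR effect vector with variance scale delta.

    Samples on the span of Q's non-null eigenvectors (variance delta per
    unit eigenvalue), which yields a sum-to-zero vector for a connected
    graph; used to generate spatial ground truth for simulations.
    """
    q = gmrf_structure(graph)
    w, v = np.linalg.eigh(q)
    keep = w > 1e-10
    z = rng.standard_normal(keep.sum())
    g = v[:, keep] @ (z * np.sqrt(delta / w[keep]))
    return g - g.mean()
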