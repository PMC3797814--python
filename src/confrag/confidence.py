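"""Recurrence, consistency, the confidence score, centroids and prediction.

A filtered (stable) cluster at target position i is summarized by two
quantities:

- *recurrence* r — the number of fragments (vertices) in the filtered
  cluster, a proxy for the motif's abundance in a non-redundant structure
  database;
- *consistency* c — the fraction of pairwise RMSDs (edges) not greater than
  the critical 1.5 Å threshold, a proxy for structural homogeneity.

The per-position *confidence* combines the two:

    k = c * log10(r)

At r = 10 the logarithm equals 1 and the confidence is determined entirely
by the structural consistency; smaller clusters are severely penalized,
clusters above 10 fragments are up-weighted.  A confidence of 0.8 or higher
flags a reliable prediction; 1.0 marks the transitional zone and 1.5 a
credible prediction.

The *centroid* (representative fragment) of a stable cluster is the vertex
with minimum average RMSD to its adjacent vertices, among vertices connected
to a significant number of cluster elements.  Its (phi, psi) pair at the
target position is reported directly as the prediction for that position.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .cluster import (
    PairCache,
    build_cluster,
    pairwise_rmsd_cache,
    shrink_cluster,
)
from .config import (
    MIN_DEGREE_FRACTION,
    RMSD_THRESHOLD,
    TIE_TOLERANCE,
    PredictorConfig,
)
from .core import ClusterGraph, Fragment, PositionAssignment


def consistency(g: ClusterGraph, threshold: float = RMSD_THRESHOLD) -> float:
    """Fraction of edges with weight <= threshold (in [0, 1]).

    Edges of weight exactly equal to the threshold count as similar ("not
    greater than").  Undefined for an edgeless graph.
    """
    if g.n_edges == 0:
        raise ValueError("consistency is undefined for an edgeless cluster")
    similar = sum(1 for _, _, w in g.edges() if w <= threshold)
    return similar / g.n_edges


def recurrence(g: ClusterGraph) -> int:
    """Number of fragments (vertices) in the filtered cluster."""
    return g.n_vertices


def recurrence_weight(r: int) -> float:
    """Logarithmic weighting factor log10(r) applied to the consistency."""
    if r < 1:
        raise ValueError("recurrence weight requires r >= 1")
    return math.log10(r)


def confidence(c: float, r: int) -> float:
    """Confidence score k = c * log10(r); 0 for an unassignable position.

    Requires 0 <= c <= 1.  r = 0 denotes an unassignable position and maps
    to confidence 0; r = 1 also yields 0 since log10(1) = 0.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"consistency {c} outside [0, 1]")
    if r < 0:
        raise ValueError("recurrence must be non-negative")
    if r == 0:
        return 0.0
    return c * recurrence_weight(r)


def centroid(
    g: ClusterGraph,
    min_degree_fraction: float = MIN_DEGREE_FRACTION,
    tol: float = TIE_TOLERANCE,
) -> Optional[Fragment]:
    """Representative fragment of a stable filtered cluster.

    Among vertices with degree >= ceil(min_degree_fraction * (|V| - 1))
    (and at least 1 — isolated vertices are never representative), returns
    the one minimizing the average incident weight w(v)/deg(v).  Ties break
    toward the smaller total incident weight w(v), then the smaller id.
    Returns None when no vertex is eligible.
    """
    n = g.n_vertices
    if n == 0:
        return None
    min_degree = max(1, math.ceil(min_degree_fraction * (n - 1)))
    best_id: Optional[str] = None
    best_avg = math.inf
    for vid in g.vertex_ids():
        deg = g.degree(vid)
        if deg < min_degree:
            continue
        avg = g.incident_weight(vid) / deg
        if best_id is None or avg < best_avg - tol:
            best_id, best_avg = vid, avg
        elif abs(avg - best_avg) <= tol:
            w_new, w_best = g.incident_weight(vid), g.incident_weight(best_id)
            if w_new < w_best - tol or (
                abs(w_new - w_best) <= tol and vid < best_id
            ):
                best_id, best_avg = vid, avg
    return g.fragment(best_id) if best_id is not None else None


def predict_position(
    library: Sequence[Fragment],
    position: int,
    config: PredictorConfig = PredictorConfig(),
    cache: Optional[PairCache] = None,
) -> PositionAssignment:
    """Full per-position pipeline: cluster, filter, score, predict.

    Diverging and empty clusters yield an assignment with no centroid and
    confidence 0 — the position belongs to a low-precision region.  A stable
    cluster without an eligible centroid keeps its confidence score but
    produces no torsion prediction and is never flagged reliable.
    """
    g = build_cluster(library, position, config.min_overlap, cache)
    result = shrink_cluster(g, config.threshold)
    if result.status != "stable":
        return PositionAssignment(
            position=position,
            status=result.status,
            recurrence=len(result.surviving),
        )
    filtered = result.graph
    assert filtered is not None
    r = recurrence(filtered)
    c = consistency(filtered, config.threshold)
    k = confidence(c, r) if r >= 1 else 0.0
    rep = centroid(filtered, config.min_degree_fraction)
    phi = psi = None
    if rep is not None:
        phi, psi = rep.torsion_at(position)
    return PositionAssignment(
        position=position,
        status="stable",
        centroid=rep,
        recurrence=r,
        consistency=c,
        confidence=k,
        phi=phi,
        psi=psi,
        reliable=rep is not None and k >= config.reliable_cutoff,
    )


def predict_target(
    library: Sequence[Fragment],
    target_length: int,
    config: PredictorConfig = PredictorConfig(),
) -> list[PositionAssignment]:
    """One PositionAssignment per residue 1..target_length.

    Pairwise RMSDs are computed once for the whole library and shared by all
    per-position clusters.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    cache = pairwise_rmsd_cache(library, config.min_overlap)
    return [
        predict_position(library, pos, config, cache)
        for pos in range(1, target_length + 1)
    ]
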