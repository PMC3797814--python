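"""Per-position cluster graphs and the greedy outlier-rejection filter.

For every position i of the target sequence, all fragments covering i form a
cluster, modeled as a graph whose edge weights are pairwise Cα-RMSDs.  A
cluster is *stable* when the average RMSD over all its edges,

    avg = W / |E|,

is below the critical 1.5 Å threshold.  The greedy filter (ShrinkCluster)
repeatedly probes every vertex v with the average that would result from its
exclusion,

    avg_-v = (W - w(v)) / (|E| - deg(v)),

and deletes the vertex producing the largest drop, until the cluster becomes
stable, cannot shrink further (*diverging* — no removal lowers the average),
or has no edges at all (*empty*).  Thanks to the cached sums in ClusterGraph,
probing costs O(|V|) and a removal O(deg(v)) per iteration.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .config import MIN_OVERLAP, RMSD_THRESHOLD, TIE_TOLERANCE
from .core import ClusterGraph, FilterResult, Fragment
from .geometry import fragment_rmsd

PairCache = dict[frozenset, Optional[float]]


def pairwise_rmsd_cache(
    library: Sequence[Fragment], min_overlap: int = MIN_OVERLAP
) -> PairCache:
    """Precompute fragment-pair RMSDs for a whole library.

    Fragment pairs recur across the per-position clusters of neighbouring
    target positions; computing each overlapping pair once dominates the cost
    of whole-target prediction.
    """
    cache: PairCache = {}
    frags = list(library)
    for i, f1 in enumerate(frags):
        for f2 in frags[i + 1 :]:
            if f1.overlap(f2) >= min_overlap:
                cache[frozenset((f1.id, f2.id))] = fragment_rmsd(
                    f1, f2, min_overlap
                )
    return cache


def build_cluster(
    library: Sequence[Fragment],
    position: int,
    min_overlap: int = MIN_OVERLAP,
    cache: Optional[PairCache] = None,
) -> ClusterGraph:
    """Cluster graph of all fragments covering `position`.

    Edges connect exactly the pairs whose query intervals overlap by at
    least `min_overlap` residues, weighted by their pairwise Cα-RMSD.
    An optional precomputed pair cache avoids recomputing superpositions.
    """
    g = ClusterGraph(position)
    covering = [f for f in library if f.covers(position)]
    for f in covering:
        g.add_vertex(f)
    for i, f1 in enumerate(covering):
        for f2 in covering[i + 1 :]:
            if f1.overlap(f2) < min_overlap:
                continue
            if cache is not None:
                w = cache.get(frozenset((f1.id, f2.id)))
                if w is None:
                    w = fragment_rmsd(f1, f2, min_overlap)
                    cache[frozenset((f1.id, f2.id))] = w
            else:
                w = fragment_rmsd(f1, f2, min_overlap)
            if w is not None:
                g.add_edge(f1.id, f2.id, w)
    return g


def average_rmsd(g: ClusterGraph) -> Optional[float]:
    """Average edge weight W / |E|; None for an edgeless graph."""
    if g.n_edges == 0:
        return None
    return g.total_weight / g.n_edges


def probe_removal(g: ClusterGraph, vid: str) -> Optional[float]:
    """Average RMSD that would result from excluding vertex `vid`.

    Computed from the cached sums as (W - w(v)) / (|E| - deg(v)) without
    modifying the graph; None when the removal would leave no edges.
    """
    if vid not in g:
        raise KeyError(f"vertex {vid!r} not in graph")
    remaining_edges = g.n_edges - g.degree(vid)
    if remaining_edges == 0:
        return None
    return (g.total_weight - g.incident_weight(vid)) / remaining_edges


def _select_rejection(
    g: ClusterGraph, current_avg: float, tol: float
) -> Optional[str]:
    """Vertex whose removal yields the minimal resulting average RMSD.

    Only removals that leave at least one edge and *strictly* decrease the
    current average qualify.  Ties (within `tol`) are broken toward the
    larger incident weight w(v), then the lexicographically smallest id,
    making runs reproducible.  Returns None when no removal helps.
    """
    best_id: Optional[str] = None
    best_avg = math.inf
    for vid in g.vertex_ids():
        avg = probe_removal(g, vid)
        if avg is None or avg >= current_avg - tol:
            continue
        if best_id is None or avg < best_avg - tol:
            best_id, best_avg = vid, avg
        elif abs(avg - best_avg) <= tol:
            w_new, w_best = g.incident_weight(vid), g.incident_weight(best_id)
            if w_new > w_best + tol or (
                abs(w_new - w_best) <= tol and vid < best_id
            ):
                best_id, best_avg = vid, avg
    return best_id


def shrink_cluster(
    g: ClusterGraph,
    threshold: float = RMSD_THRESHOLD,
    tol: float = TIE_TOLERANCE,
) -> FilterResult:
    """Greedy outlier rejection until stability, divergence or exhaustion.

    The input graph is not modified; the returned FilterResult carries the
    filtered graph, the surviving fragments and the ordered removal trace
    (fragment id, average RMSD after its removal).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    work = g.copy()
    removed: list[tuple[str, float]] = []
    if work.n_edges == 0:
        # all overlaps < 6 residues (or < 2 fragments): stability is
        # defined over edges, so the cluster can never be stable
        return FilterResult(
            status="empty",
            surviving=work.fragments(),
            removed=removed,
            final_avg_rmsd=None,
            graph=work,
        )
    while True:
        avg = work.total_weight / work.n_edges
        if avg < threshold:
            return FilterResult(
                status="stable",
                surviving=work.fragments(),
                removed=removed,
                final_avg_rmsd=avg,
                graph=work,
            )
        victim = _select_rejection(work, avg, tol)
        if victim is None:
            return FilterResult(
                status="diverging",
                surviving=work.fragments(),
                removed=removed,
                final_avg_rmsd=avg,
                graph=work,
            )
        work.remove_vertex(victim)
        # the victim's probe was defined, so at least one edge remains
        removed.append((victim, work.total_weight / work.n_edges))
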