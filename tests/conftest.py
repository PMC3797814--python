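"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the package's cached
graph machinery: they rebuild candidate subgraphs from scratch at every
step (plain dicts and sets), so agreement with the incremental
implementation is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from confrag import ClusterGraph, Fragment

TOL = 1e-12


def dummy_fragment(
    fid: str, start: int = 1, end: int = 6, source: str = "dummy"
) -> Fragment:
    """Minimal valid fragment for graph-level tests (geometry unused)."""
    n = end - start + 1
    return Fragment(
        id=fid,
        source_id=source,
        query_start=start,
        query_end=end,
        torsions=np.zeros((n, 2)),
        ca_trace=np.zeros((n, 3)),
    )


def graph_from_weights(
    weights: dict[tuple[str, str], float], n_vertices: int | None = None,
    position: int = 1,
) -> ClusterGraph:
    """ClusterGraph over dummy fragments with prescribed edge weights."""
    ids = sorted({v for e in weights for v in e})
    if n_vertices is not None:
        ids = sorted(set(ids) | {f"v{i:02d}" for i in range(n_vertices)})
    frags = [dummy_fragment(i) for i in ids]
    return ClusterGraph.from_edges(
        position, frags, {tuple(e): w for e, w in weights.items()}
    )


def random_graph(
    rng: np.random.Generator,
    n_min: int = 3,
    n_max: int = 8,
    edge_prob: float = 0.7,
    w_lo: float = 0.5,
    w_hi: float = 5.0,
) -> ClusterGraph:
    """Random graph with generic (tie-free, continuous) weights."""
    n = int(rng.integers(n_min, n_max + 1))
    ids = [f"v{i:02d}" for i in range(n)]
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                weights[(ids[i], ids[j])] = float(rng.uniform(w_lo, w_hi))
    return graph_from_weights(weights, n_vertices=n)


def graph_as_dicts(
    g: ClusterGraph,
) -> tuple[list[str], dict[frozenset, float]]:
    vertices = g.vertex_ids()
    edges = {frozenset((u, v)): w for u, v, w in g.edges()}
    return vertices, edges


def oracle_shrink(
    vertices: list[str],
    edges: dict[frozenset, float],
    threshold: float,
    tol: float = TOL,
) -> tuple[str, set[str], list[tuple[str, float]]]:
    """Brute-force greedy filter: rebuilds every candidate subgraph from
    scratch at each iteration.  Same tie rules as the implementation:
    minimal resulting average, then larger incident weight, then smaller id.
    """

    def sub(vs: set[str]) -> dict[frozenset, float]:
        return {e: w for e, w in edges.items() if e <= vs}

    verts = set(vertices)
    removed: list[tuple[str, float]] = []
    current = sub(verts)
    if not current:
        return "empty", verts, removed
    while True:
        avg = sum(current.values()) / len(current)
        if avg < threshold:
            return "stable", verts, removed
        best = None  # (avg_after, incident_weight, vid)
        for v in sorted(verts):
            rest = sub(verts - {v})
            if not rest:
                continue
            avg_after = sum(rest.values()) / len(rest)
            if avg_after >= avg - tol:
                continue
            wv = sum(w for e, w in current.items() if v in e)
            if (
                best is None
                or avg_after < best[0] - tol
                or (
                    abs(avg_after - best[0]) <= tol
                    and (
                        wv > best[1] + tol
                        or (abs(wv - best[1]) <= tol and v < best[2])
                    )
                )
            ):
                best = (avg_after, wv, v)
        if best is None:
            return "diverging", verts, removed
        verts.discard(best[2])
        current = sub(verts)
        removed.append((best[2], sum(current.values()) / len(current)))


def oracle_centroid(
    g: ClusterGraph, min_degree_fraction: float, tol: float = TOL
) -> str | None:
    """Exhaustive scan for the eligible vertex with minimal average
    incident weight, recomputing everything from the edge list."""
    _, edges = graph_as_dicts(g)
    n = g.n_vertices
    min_degree = max(1, math.ceil(min_degree_fraction * (n - 1)))
    best = None  # (avg, total, vid)
    for v in g.vertex_ids():
        incident = [w for e, w in edges.items() if v in e]
        if len(incident) < min_degree:
            continue
        avg = sum(incident) / len(incident)
        total = sum(incident)
        if (
            best is None
            or avg < best[0] - tol
            or (
                abs(avg - best[0]) <= tol
                and (
                    total < best[1] - tol
                    or (abs(total - best[1]) <= tol and v < best[2])
                )
            )
        ):
            best = (avg, total, v)
    return best[2] if best else None


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
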