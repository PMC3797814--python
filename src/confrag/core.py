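"""Domain model: fragments, per-position cluster graphs, filter results.

A *fragment* is a short (6–21 residue) segment excised from a known protein
structure and matched by remote-homology detection to a window of the target
sequence.  All residue indexing on the target is 1-based and inclusive.
Torsion angles are degrees in (-180, 180]; -180 is normalized to +180 on
construction.  Coordinates are Å.

A *cluster graph* holds every fragment covering one target position, with
edges weighted by pairwise Cα-RMSD.  It caches the total edge weight W, the
per-vertex incident weight w(v) and the per-vertex degree, and updates them
incrementally on vertex removal in O(deg(v)) — this is what makes the greedy
outlier-rejection filter run in linear time per removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .config import MAX_FRAGMENT_LENGTH, MIN_FRAGMENT_LENGTH, MIN_OVERLAP


def normalize_angle(deg: float) -> float:
    """Map an angle in degrees into (-180, 180]; -180 becomes +180."""
    a = math.fmod(float(deg), 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


@dataclass
class Fragment:
    """One detected variable-length structural motif.

    Parameters
    ----------
    id:
        Opaque unique identifier within a library.
    source_id:
        Structure + chain identifier of the template the fragment was
        excised from.
    query_start, query_end:
        1-based inclusive residue interval on the target sequence.
    torsions:
        Array of shape (L, 2) with per-residue (phi, psi) in degrees.
    ca_trace:
        Array of shape (L, 3) with per-residue Cα coordinates in Å.
    label:
        Optional ground-truth tag used only by synthetic-data tests
        ("true" / "outlier"); never serialized, never read by the pipeline.
    """

    id: str
    source_id: str
    query_start: int
    query_end: int
    torsions: np.ndarray
    ca_trace: np.ndarray
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.torsions = np.asarray(self.torsions, dtype=float).reshape(-1, 2)
        self.ca_trace = np.asarray(self.ca_trace, dtype=float).reshape(-1, 3)
        norm = np.vectorize(normalize_angle)
        if self.torsions.size:
            self.torsions = norm(self.torsions)

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1

    def covers(self, position: int) -> bool:
        return self.query_start <= position <= self.query_end

    def offset(self, position: int) -> int:
        """0-based offset of a covered target position inside the fragment."""
        if not self.covers(position):
            raise ValueError(
                f"fragment {self.id} [{self.query_start},{self.query_end}] "
                f"does not cover position {position}"
            )
        return position - self.query_start

    def torsion_at(self, position: int) -> tuple[float, float]:
        phi, psi = self.torsions[self.offset(position)]
        return float(phi), float(psi)

    def overlap(self, other: "Fragment") -> int:
        """Number of target residues shared by the two query intervals."""
        lo = max(self.query_start, other.query_start)
        hi = min(self.query_end, other.query_end)
        return max(0, hi - lo + 1)


def validate_fragment(f: Fragment) -> list[str]:
    """Return a list of invariant violations (empty list = valid).

    Checks interval/array length agreement, the 6–21 residue length range,
    angle range and finite coordinates.
    """
    violations: list[str] = []
    n = f.query_end - f.query_start + 1
    if n < 1:
        violations.append(
            f"query interval [{f.query_start},{f.query_end}] is empty"
        )
    if len(f.torsions) != n:
        violations.append(
            f"torsions length {len(f.torsions)} != interval length {n}"
        )
    if len(f.ca_trace) != n:
        violations.append(
            f"ca_trace length {len(f.ca_trace)} != interval length {n}"
        )
    if len(f.torsions) != len(f.ca_trace):
        violations.append(
            f"torsions length {len(f.torsions)} != ca_trace length "
            f"{len(f.ca_trace)}"
        )
    if n < MIN_FRAGMENT_LENGTH:
        violations.append(f"length {n} < {MIN_FRAGMENT_LENGTH}")
    if n > MAX_FRAGMENT_LENGTH:
        violations.append(f"length {n} > {MAX_FRAGMENT_LENGTH}")
    if f.torsions.size and not np.all(
        (f.torsions > -180.0) & (f.torsions <= 180.0)
    ):
        violations.append("torsion angles outside (-180, 180]")
    if f.ca_trace.size and not np.all(np.isfinite(f.ca_trace)):
        violations.append("ca_trace contains non-finite coordinates")
    return violations


class ClusterGraph:
    """Weighted undirected graph of fragments covering one target position.

    Vertices are fragments (keyed by fragment id, insertion-ordered); an
    edge carries the pairwise Cα-RMSD of the two fragments.  The total edge
    weight W, per-vertex incident weights w(v) and degrees are cached and
    maintained incrementally under vertex removal.
    """

    def __init__(self, position: int) -> None:
        self.position = position
        self._fragments: dict[str, Fragment] = {}
        self._adj: dict[str, dict[str, float]] = {}
        self._incident: dict[str, float] = {}
        self._total_weight: float = 0.0
        self._n_edges: int = 0

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        position: int,
        fragments: Sequence[Fragment],
        edges: dict[tuple[str, str], float],
    ) -> "ClusterGraph":
        """Build a graph directly from fragments and precomputed weights.

        No overlap rule is enforced here; callers supplying weights are
        responsible for edge eligibility (`build_cluster` applies the
        >= 6-residue overlap rule).
        """
        g = cls(position)
        for f in fragments:
            g.add_vertex(f)
        for (u, v), w in edges.items():
            g.add_edge(u, v, w)
        return g

    def add_vertex(self, f: Fragment) -> None:
        if f.id in self._fragments:
            raise ValueError(f"duplicate fragment id {f.id!r}")
        self._fragments[f.id] = f
        self._adj[f.id] = {}
        self._incident[f.id] = 0.0

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError("self-edges are not allowed")
        if weight < 0:
            raise ValueError("edge weights must be non-negative")
        if u not in self._adj or v not in self._adj:
            raise KeyError(f"unknown vertex in edge ({u!r}, {v!r})")
        if v in self._adj[u]:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        w = float(weight)
        self._adj[u][v] = w
        self._adj[v][u] = w
        self._incident[u] += w
        self._incident[v] += w
        self._total_weight += w
        self._n_edges += 1

    # -- queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self._fragments)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    @property
    def total_weight(self) -> float:
        """Cached sum W of all edge weights (Å)."""
        return self._total_weight

    def vertex_ids(self) -> list[str]:
        return list(self._fragments)

    def fragments(self) -> list[Fragment]:
        return list(self._fragments.values())

    def fragment(self, vid: str) -> Fragment:
        return self._fragments[vid]

    def __contains__(self, vid: str) -> bool:
        return vid in self._fragments

    def incident_weight(self, vid: str) -> float:
        """Cached sum w(v) of weights of edges incident to vertex `vid`."""
        return self._incident[vid]

    def degree(self, vid: str) -> int:
        return len(self._adj[vid])

    def neighbors(self, vid: str) -> list[str]:
        return list(self._adj[vid])

    def edge_weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, {})

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once, in insertion order of u."""
        seen: set[frozenset[str]] = set()
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    yield u, v, w

    # -- mutation ------------------------------------------------------

    def remove_vertex(self, vid: str) -> None:
        """Remove a vertex and its edges, updating caches in O(deg(v))."""
        if vid not in self._fragments:
            raise KeyError(f"vertex {vid!r} not in graph")
        for nbr, w in self._adj[vid].items():
            del self._adj[nbr][vid]
            self._incident[nbr] -= w
            self._total_weight -= w
            self._n_edges -= 1
        del self._adj[vid]
        del self._incident[vid]
        del self._fragments[vid]

    def copy(self) -> "ClusterGraph":
        g = ClusterGraph(self.position)
        g._fragments = dict(self._fragments)
        g._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        g._incident = dict(self._incident)
        g._total_weight = self._total_weight
        g._n_edges = self._n_edges
        return g

    # -- integrity -----------------------------------------------------

    def recompute_caches(self) -> tuple[float, dict[str, float]]:
        """Recompute W and w(v) from scratch (for integrity checks)."""
        total = 0.0
        incident = {vid: 0.0 for vid in self._fragments}
        for u, v, w in self.edges():
            total += w
            incident[u] += w
            incident[v] += w
        return total, incident

    def check_integrity(self, tol: float = 1e-9) -> None:
        """Raise AssertionError if any cached sum drifted beyond `tol` Å."""
        total, incident = self.recompute_caches()
        if abs(total - self._total_weight) > tol:
            raise AssertionError(
                f"total_weight cache {self._total_weight} != recomputed "
                f"{total}"
            )
        for vid, w in incident.items():
            if abs(w - self._incident[vid]) > tol:
                raise AssertionError(
                    f"incident_weight cache for {vid!r}: "
                    f"{self._incident[vid]} != recomputed {w}"
                )


@dataclass
class FilterResult:
    """Outcome of the greedy cluster-shrinking filter.

    status is one of:

    - ``"stable"``: average pairwise RMSD dropped below the threshold;
    - ``"diverging"``: no single removal strictly lowered the average —
      a heterogeneous aggregate of false positives;
    - ``"empty"``: the cluster had no edges to begin with (all pairwise
      overlaps < 6 residues, or fewer than two fragments).

    `removed` records every deletion in order as (fragment id, average RMSD
    of the remaining graph after the removal).
    """

    status: str
    surviving: list[Fragment]
    removed: list[tuple[str, float]]
    final_avg_rmsd: Optional[float]
    graph: Optional[ClusterGraph] = None


@dataclass
class PositionAssignment:
    """Per-position prediction: centroid fragment, confidence, (phi, psi).

    `centroid` is None when the position's cluster diverged, was empty, or
    contained no centroid-eligible vertex; the position then belongs to a
    low-precision region and phi/psi are None.
    """

    position: int
    status: str
    centroid: Optional[Fragment] = None
    recurrence: int = 0
    consistency: Optional[float] = None
    confidence: float = 0.0
    phi: Optional[float] = None
    psi: Optional[float] = None
    reliable: bool = False
    #: id of the centroid when only the serialized form is available
    centroid_id: Optional[str] = None

    @property
    def centroid_ref(self) -> Optional[str]:
        """Centroid fragment id, whether held in memory or read from disk."""
        if self.centroid is not None:
            return self.centroid.id
        return self.centroid_id


@dataclass
class EvaluationReport:
    """Aggregate scores of a prediction against a native reference."""

    mae_phi: Optional[float]
    mae_psi: Optional[float]
    n_residues: int
    per_cutoff: "object"  # pandas.DataFrame: cutoff, n, mae_phi, mae_psi
    precision_by_position: np.ndarray
    coverage: float
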