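"""Rigid-body superposition, pairwise fragment Cα-RMSD, backbone dihedrals.

The pairwise RMSD between two fragments is computed over the residues in the
intersection of their query intervals, pairing residues by target-sequence
index, after an optimal proper-rotation (Kabsch) superposition of the two
sub-traces.  Pairs overlapping by fewer than 6 residues yield no value: the
RMSD of so short a match is not a meaningful divergence measure and such
pairs are not connected by an edge in the cluster graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from .config import MIN_OVERLAP
from .core import Fragment, normalize_angle


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid superposition mapping point set A onto B.

    ``rotation`` is a proper 3x3 rotation matrix (det = +1), ``translation``
    a 3-vector in Å; the transform is x -> rotation @ x + translation.
    ``rmsd`` is the root-mean-square deviation of the transformed A from B.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal proper-rotation superposition of A onto B.

    Both inputs are (n, 3) arrays with n >= 3.  Reflections are never
    returned, even for degenerate (e.g. planar) point sets.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise ValueError("inputs must be (n, 3) coordinate arrays")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"point counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    ac = a - cen_a
    bc = b - cen_b
    u, _, vt = np.linalg.svd(ac.T @ bc)
    # reflection correction: flip the smallest singular direction so the
    # returned transform is always a proper rotation
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    matrix = vt.T @ d @ u.T
    translation = cen_b - matrix @ cen_a
    residual = ac @ matrix.T - bc
    rmsd = math.sqrt(float((residual * residual).sum()) / a.shape[0])
    return Superposition(rotation=matrix, translation=translation, rmsd=rmsd)


def fragment_rmsd(
    f1: Fragment, f2: Fragment, min_overlap: int = MIN_OVERLAP
) -> Optional[float]:
    """Kabsch-minimal Cα-RMSD over the query-interval intersection.

    Residues are paired by target-sequence index.  Returns None when the two
    intervals overlap by fewer than `min_overlap` residues (no edge).
    """
    lo = max(f1.query_start, f2.query_start)
    hi = min(f1.query_end, f2.query_end)
    n = hi - lo + 1
    if n < min_overlap:
        return None
    a = f1.ca_trace[lo - f1.query_start : lo - f1.query_start + n]
    b = f2.ca_trace[lo - f2.query_start : lo - f2.query_start + n]
    return kabsch(a, b).rmsd


def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: 0° for the cis (eclipsed) arrangement, sign by the
    right-hand rule looking along p2 -> p3.  Raises ValueError when three
    consecutive points are collinear (undefined angle).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0:
        raise ValueError("coincident central points: dihedral undefined")
    denom = np.linalg.norm(n1) * np.linalg.norm(n2)
    if denom < 1e-12:
        raise ValueError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    return normalize_angle(math.degrees(math.atan2(y, x)))
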