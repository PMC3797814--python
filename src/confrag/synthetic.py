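"""Seeded generator of synthetic targets and fragment libraries.

Real dynamic fragment libraries show an alternating pattern: easily
detectable conserved elements (helices, strands matching known motifs)
connected by highly variable coil linkers with no usable hits.  The
generator emulates exactly that: a native backbone built from canonical
region torsions, per-region sets of "true" fragments excised from the
(jittered) native structure, and planted outliers excised from decoy
backbones obtained by permuting the native torsion sequence — which lands
outlier RMSDs in a realistic 3–10 Å band rather than the unbounded values a
random walk would give.

Backbones are built with ideal peptide geometry (N, CA, C atoms, omega
fixed at 180°) from (phi, psi) lists via sequential internal-coordinate
placement, so recomputing dihedrals from the generated coordinates
round-trips to the generating torsions.  The pipeline itself only ever sees
Cα traces and torsion lists.

Every generated fragment carries a hidden ``label`` ("true"/"outlier") for
test assertions only; the label never influences the pipeline and is never
serialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Fragment, normalize_angle

# ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

#: canonical region torsions (phi, psi) in degrees
HELIX_TORSIONS = (-57.0, -47.0)
STRAND_TORSIONS = (-120.0, 120.0)

REGION_KINDS = ("helix", "strand", "coil")
CONSERVED_KINDS = ("helix", "strand")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic target scenario.

    regions is an ordered list of (kind, length) with kind in
    {"helix", "strand", "coil"}; lengths must sum to target_length.
    recurrence_profile gives, per region, the number of true fragments for
    conserved regions and the number of (outlier-only) hits for coil
    linkers.  trace_noise_sd is the Gaussian jitter (Å, per coordinate)
    applied to the Cα trace of true fragments; torsion_noise_sd the matching
    angular jitter in degrees.  Both are scaled per fragment by a quality
    factor ~ U(0.5, 1.5) so coordinate and torsion fidelity covary, as they
    do for real template hits of varying quality.  outlier_rate is the
    fraction of fragments in conserved regions drawn from decoys.
    """

    target_length: int
    regions: tuple[tuple[str, int], ...]
    recurrence_profile: tuple[int, ...]
    trace_noise_sd: float = 0.5
    outlier_rate: float = 0.2
    torsion_noise_sd: float = 5.0
    fragment_length_range: tuple[int, int] = (6, 21)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(length for _, length in self.regions) != self.target_length:
            raise ValueError("region lengths must sum to target_length")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if len(self.recurrence_profile) != len(self.regions):
            raise ValueError("recurrence_profile must match regions")
        for kind, length in self.regions:
            if kind not in REGION_KINDS:
                raise ValueError(f"unknown region kind {kind!r}")
            if length < 1:
                raise ValueError("region lengths must be positive")
        lo, hi = self.fragment_length_range
        if not 6 <= lo <= hi <= 21:
            raise ValueError("fragment_length_range must lie within [6, 21]")

    @classmethod
    def default(cls, seed: int = 0) -> "ScenarioSpec":
        """The reference scenario: a 40-residue target with one helix and
        one strand separated by coil linkers; 25 true fragments per
        conserved region, 5 decoy-only hits per linker (variable linkers
        yield few, unreliable remote-homology hits)."""
        return cls(
            target_length=40,
            regions=(
                ("coil", 6),
                ("helix", 12),
                ("coil", 7),
                ("strand", 10),
                ("coil", 5),
            ),
            recurrence_profile=(5, 25, 5, 25, 5),
            seed=seed,
        )

    def region_bounds(self) -> list[tuple[str, int, int]]:
        """(kind, start, end) per region, 1-based inclusive."""
        out = []
        start = 1
        for kind, length in self.regions:
            out.append((kind, start, start + length - 1))
            start += length
        return out


@dataclass
class NativeStructure:
    """Generated native reference: torsions and ideal-geometry backbone."""

    torsions: np.ndarray  # (L, 2) degrees; fully assigned, incl. termini
    n: np.ndarray  # (L, 3) backbone N
    ca: np.ndarray  # (L, 3) backbone CA
    c: np.ndarray  # (L, 3) backbone C
    region_labels: list[str] = field(default_factory=list)

    @property
    def ca_trace(self) -> np.ndarray:
        return self.ca


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Position atom D from A, B, C given |C-D|, angle(B,C,D) and the
    dihedral A-B-C-D (degrees)."""
    theta = math.radians(bond_angle)
    tau = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * math.cos(theta),
            bond_length * math.sin(theta) * math.cos(tau),
            bond_length * math.sin(theta) * math.sin(tau),
        ]
    )
    return c + bc * d_local[0] + m * d_local[1] + n * d_local[2]


def backbone_from_torsions(
    torsions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build an ideal-geometry N/CA/C backbone from (L, 2) (phi, psi).

    phi of the first residue has no geometric effect (there is no preceding
    carbonyl carbon); psi of the last residue is likewise unrealized.
    """
    tor = np.asarray(torsions, dtype=float).reshape(-1, 2)
    length = tor.shape[0]
    if length < 1:
        raise ValueError("at least one residue required")
    n_xyz = np.zeros((length, 3))
    ca_xyz = np.zeros((length, 3))
    c_xyz = np.zeros((length, 3))
    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c_xyz[0] = ca_xyz[0] + BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(length - 1):
        psi = tor[i, 1]
        phi_next = tor[i + 1, 0]
        n_xyz[i + 1] = place_atom(
            n_xyz[i], ca_xyz[i], c_xyz[i], BOND_C_N, ANGLE_CA_C_N, psi
        )
        ca_xyz[i + 1] = place_atom(
            ca_xyz[i], c_xyz[i], n_xyz[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA
        )
        c_xyz[i + 1] = place_atom(
            c_xyz[i], n_xyz[i + 1], ca_xyz[i + 1], BOND_CA_C, ANGLE_N_CA_C,
            phi_next,
        )
    return n_xyz, ca_xyz, c_xyz


def _coil_torsions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Broad coil distribution: phi ~ U(-180, -20], psi ~ U(-180, 180]."""
    phi = rng.uniform(-180.0, -20.0, n)
    psi = rng.uniform(-180.0, 180.0, n)
    return np.column_stack([phi, psi])


def generate_native(spec: ScenarioSpec) -> NativeStructure:
    """Native torsions and ideal-geometry backbone for a scenario.

    Helix and strand regions take the canonical torsion pairs exactly; coil
    residues are sampled from the broad coil distribution.  Deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng([spec.seed, 0])
    torsions = np.zeros((spec.target_length, 2))
    labels: list[str] = []
    for kind, start, end in spec.region_bounds():
        n = end - start + 1
        if kind == "helix":
            torsions[start - 1 : end] = HELIX_TORSIONS
        elif kind == "strand":
            torsions[start - 1 : end] = STRAND_TORSIONS
        else:
            torsions[start - 1 : end] = _coil_torsions(rng, n)
        labels.extend([kind] * n)
    n_xyz, ca_xyz, c_xyz = backbone_from_torsions(torsions)
    return NativeStructure(
        torsions=torsions, n=n_xyz, ca=ca_xyz, c=c_xyz, region_labels=labels
    )


def _sample_interval(
    rng: np.random.Generator,
    center: int,
    lo_bound: int,
    hi_bound: int,
    length_range: tuple[int, int],
) -> tuple[int, int]:
    """Random interval containing `center` within [lo_bound, hi_bound]."""
    max_len = min(length_range[1], hi_bound - lo_bound + 1)
    min_len = min(length_range[0], max_len)
    frag_len = int(rng.integers(min_len, max_len + 1))
    lo_start = max(lo_bound, center - frag_len + 1)
    hi_start = min(center, hi_bound - frag_len + 1)
    start = int(rng.integers(lo_start, hi_start + 1))
    return start, start + frag_len - 1


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    return np.vectorize(normalize_angle)(a)


def generate_library(
    spec: ScenarioSpec, native: Optional[NativeStructure] = None
) -> list[Fragment]:
    """Position-clustered fragment library with planted truth and outliers.

    Conserved regions receive `recurrence_profile[i]` true fragments (noisy
    excisions of the native structure confined to the region, all covering
    its center) plus decoy outliers at the configured outlier rate; coil
    regions receive only decoy outliers.  Each outlier is excised from its
    own decoy backbone, rebuilt from a seeded permutation of the native
    torsion rows.  Deterministic under the spec's seed.
    """
    if native is None:
        native = generate_native(spec)
    rng = np.random.default_rng([spec.seed, 1])
    fragments: list[Fragment] = []
    for idx, (kind, start, end) in enumerate(spec.region_bounds()):
        center = (start + end) // 2
        count = spec.recurrence_profile[idx]
        if kind in CONSERVED_KINDS:
            region_len = end - start + 1
            n_true = count if region_len >= spec.fragment_length_range[0] else 0
            n_out = round(
                n_true * spec.outlier_rate / (1.0 - spec.outlier_rate)
            )
            for j in range(n_true):
                s, e = _sample_interval(
                    rng, center, start, end, spec.fragment_length_range
                )
                quality = rng.uniform(0.5, 1.5)
                ca = native.ca[s - 1 : e] + rng.normal(
                    0.0, spec.trace_noise_sd * quality, (e - s + 1, 3)
                )
                tor = _wrap_angles(
                    native.torsions[s - 1 : e]
                    + rng.normal(
                        0.0, spec.torsion_noise_sd * quality, (e - s + 1, 2)
                    )
                )
                fragments.append(
                    Fragment(
                        id=f"r{idx}t{j:03d}",
                        source_id="synthetic-true",
                        query_start=s,
                        query_end=e,
                        torsions=tor,
                        ca_trace=ca,
                        label="true",
                    )
                )
        else:
            n_out = count
        for j in range(n_out):
            if kind in CONSERVED_KINDS:
                s, e = _sample_interval(
                    rng, center, start, end, spec.fragment_length_range
                )
            else:
                s, e = _sample_interval(
                    rng, center, 1, spec.target_length,
                    spec.fragment_length_range,
                )
            decoy_tor = rng.permutation(native.torsions, axis=0)
            _, decoy_ca, _ = backbone_from_torsions(decoy_tor)
            fragments.append(
                Fragment(
                    id=f"r{idx}o{j:03d}",
                    source_id=f"synthetic-decoy-r{idx}",
                    query_start=s,
                    query_end=e,
                    torsions=_wrap_angles(decoy_tor[s - 1 : e]),
                    ca_trace=decoy_ca[s - 1 : e].copy(),
                    label="outlier",
                )
            )
    return fragments


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[NativeStructure, list[Fragment]]:
    """Convenience: native structure plus its fragment library."""
    native = generate_native(spec)
    return native, generate_library(spec, native)
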