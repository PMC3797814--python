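"""File formats: fragment libraries, native references, assignment tables.

Fragment library dialect (TSV, one record per fragment)
-------------------------------------------------------
Comment lines start with ``#``.  The first non-comment line is the header::

    id  source_id  query_start  query_end  torsions  ca_trace

``torsions`` is a ``;``-joined list of ``phi:psi`` pairs (degrees, each in
(-180, 180]); ``ca_trace`` a ``;``-joined list of ``x:y:z`` coordinates (Å).
Intervals are 1-based inclusive on the target sequence.  Floats are printed
with 6 decimals; a trailing ``# records: N`` comment lets readers detect
truncated files.  A JSON mirror of the same schema (``.json`` extension) is
accepted interchangeably.

Native reference TSV: columns position, phi, psi, x, y, z with ``NA`` for
undefined values.  PDB coordinate files are accepted as an alternative
native source; torsions are then computed from N/CA/C records.

All writers are deterministic: fixed column order, fixed float formatting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import Fragment, PositionAssignment, validate_fragment
from .geometry import dihedral

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = (
    "id",
    "source_id",
    "query_start",
    "query_end",
    "torsions",
    "ca_trace",
)
ASSIGNMENT_COLUMNS = (
    "position",
    "status",
    "recurrence",
    "consistency",
    "confidence",
    "reliable",
    "centroid_id",
    "phi",
    "psi",
)
NA = "NA"


class LibraryParseError(ValueError):
    """Malformed library file (bad syntax, truncation, wrong columns)."""


class LibraryValidationError(ValueError):
    """A record violates fragment invariants in strict mode."""


class NativeReference(NamedTuple):
    """Per-residue native (phi, psi) and Cα trace; NaN where undefined."""

    torsions: np.ndarray  # (L, 2)
    ca_trace: np.ndarray  # (L, 3)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


# ---------------------------------------------------------------- library


def _fragment_to_row(f: Fragment) -> str:
    torsions = ";".join(
        f"{_fmt(phi)}:{_fmt(psi)}" for phi, psi in f.torsions
    )
    trace = ";".join(
        ":".join(_fmt(c) for c in xyz) for xyz in f.ca_trace
    )
    return "\t".join(
        [f.id, f.source_id, str(f.query_start), str(f.query_end), torsions,
         trace]
    )


def write_fragment_library(
    fragments: Sequence[Fragment], path: str | Path
) -> None:
    """Write a library in the TSV dialect (or JSON for .json paths)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "format": "confrag-fragment-library",
            "version": 1,
            "indexing": "1-based inclusive",
            "units": {"torsions": "degrees", "ca_trace": "angstrom"},
            "fragments": [
                {
                    "id": f.id,
                    "source_id": f.source_id,
                    "query_start": f.query_start,
                    "query_end": f.query_end,
                    "torsions": [
                        [round(float(phi), 6), round(float(psi), 6)]
                        for phi, psi in f.torsions
                    ],
                    "ca_trace": [
                        [round(float(c), 6) for c in xyz]
                        for xyz in f.ca_trace
                    ],
                }
                for f in fragments
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = [
        "# confrag fragment library v1",
        "# intervals 1-based inclusive; torsions phi:psi in degrees "
        "(-180, 180]; ca_trace x:y:z in Angstrom",
        "\t".join(LIBRARY_COLUMNS),
    ]
    lines.extend(_fragment_to_row(f) for f in fragments)
    lines.append(f"# records: {len(fragments)}")
    path.write_text("\n".join(lines) + "\n")


def _parse_pairs(text: str, width: int, what: str, lineno: int) -> np.ndarray:
    rows = []
    for token in text.split(";"):
        parts = token.split(":")
        if len(parts) != width:
            raise LibraryParseError(
                f"line {lineno}: malformed {what} token {token!r}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise LibraryParseError(
                f"line {lineno}: non-numeric {what} token {token!r}"
            ) from exc
    return np.asarray(rows)


def read_fragment_library(
    path: str | Path, mode: str = "strict"
) -> list[Fragment]:
    """Parse a library file (TSV or JSON dialect).

    strict mode raises LibraryValidationError on any fragment-invariant
    violation (naming the record); lenient mode keeps offending fragments
    and logs a warning per violation.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    path = Path(path)
    if path.suffix.lower() == ".json":
        fragments = _read_json_library(path)
    else:
        fragments = _read_tsv_library(path)
    for f in fragments:
        violations = validate_fragment(f)
        if violations:
            message = f"fragment {f.id!r}: " + "; ".join(violations)
            if mode == "strict":
                raise LibraryValidationError(message)
            logger.warning("lenient mode keeping invalid %s", message)
    return fragments


def _read_tsv_library(path: Path) -> list[Fragment]:
    fragments: list[Fragment] = []
    expected: Optional[int] = None
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# records:"):
                expected = int(line.split(":", 1)[1])
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != LIBRARY_COLUMNS:
                raise LibraryParseError(
                    f"line {lineno}: unexpected header {fields!r}"
                )
            header_seen = True
            continue
        if len(fields) != len(LIBRARY_COLUMNS):
            raise LibraryParseError(
                f"line {lineno}: expected {len(LIBRARY_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        fid, source_id, start_s, end_s, torsions_s, trace_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise LibraryParseError(
                f"line {lineno}: non-integer interval bounds"
            ) from exc
        fragments.append(
            Fragment(
                id=fid,
                source_id=source_id,
                query_start=start,
                query_end=end,
                torsions=_parse_pairs(torsions_s, 2, "torsion", lineno),
                ca_trace=_parse_pairs(trace_s, 3, "coordinate", lineno),
            )
        )
    if not header_seen:
        raise LibraryParseError("missing header line")
    if expected is not None and expected != len(fragments):
        raise LibraryParseError(
            f"truncated file: footer declares {expected} records, "
            f"found {len(fragments)}"
        )
    return fragments


def _read_json_library(path: Path) -> list[Fragment]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LibraryParseError(f"invalid JSON: {exc}") from exc
    if payload.get("format") != "confrag-fragment-library":
        raise LibraryParseError("not a confrag fragment library JSON file")
    fragments = []
    for rec in payload.get("fragments", []):
        try:
            fragments.append(
                Fragment(
                    id=rec["id"],
                    source_id=rec["source_id"],
                    query_start=int(rec["query_start"]),
                    query_end=int(rec["query_end"]),
                    torsions=np.asarray(rec["torsions"], dtype=float),
                    ca_trace=np.asarray(rec["ca_trace"], dtype=float),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LibraryParseError(f"malformed record: {exc}") from exc
    return fragments


# ------------------------------------------------------- native reference


def write_native_reference(
    torsions: np.ndarray, ca_trace: np.ndarray, path: str | Path
) -> None:
    """Write the per-residue native reference TSV (NA for undefined)."""
    torsions = np.asarray(torsions, dtype=float)
    trace = np.asarray(ca_trace, dtype=float)
    lines = [
        "# confrag native reference v1: 1-based positions, degrees, Angstrom",
        "position\tphi\tpsi\tx\ty\tz",
    ]
    for i in range(torsions.shape[0]):
        vals = [
            NA if np.isnan(v) else _fmt(v)
            for v in (*torsions[i], *trace[i])
        ]
        lines.append("\t".join([str(i + 1), *vals]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_native_tsv(path: Path) -> NativeReference:
    torsions: list[list[float]] = []
    trace: list[list[float]] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if not header_seen:
            if fields != ["position", "phi", "psi", "x", "y", "z"]:
                raise LibraryParseError(
                    f"line {lineno}: unexpected native header {fields!r}"
                )
            header_seen = True
            continue
        if len(fields) != 6:
            raise LibraryParseError(
                f"line {lineno}: expected 6 fields, got {len(fields)}"
            )
        values = [
            np.nan if v == NA else float(v) for v in fields[1:]
        ]
        torsions.append(values[:2])
        trace.append(values[2:])
    if not header_seen:
        raise LibraryParseError("missing native reference header")
    return NativeReference(np.asarray(torsions), np.asarray(trace))


def _read_native_pdb(path: Path, chain: Optional[str]) -> NativeReference:
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        if len(chain_names) != 1:
            raise ValueError(
                f"PDB file has chains {chain_names}; an explicit chain "
                "must be selected"
            )
        chain = chain_names[0]
    if chain not in chain_names:
        raise ValueError(f"chain {chain!r} not found (have {chain_names})")
    residues = list(model[chain])
    coords: list[dict[str, np.ndarray]] = []
    for res in residues:
        atoms = {}
        for name in ("N", "CA", "C"):
            atom = res.find_atom(name, "*")
            if atom is not None:
                atoms[name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
        coords.append(atoms)
    length = len(coords)
    torsions = np.full((length, 2), np.nan)
    trace = np.full((length, 3), np.nan)
    for i, atoms in enumerate(coords):
        if "CA" in atoms:
            trace[i] = atoms["CA"]
        prev_atoms = coords[i - 1] if i > 0 else {}
        next_atoms = coords[i + 1] if i < length - 1 else {}
        # a chain break (C(i-1)..N(i) distance far beyond a peptide bond)
        # invalidates the flanking dihedrals
        def _bonded(c_prev: dict, n_curr: dict) -> bool:
            if "C" not in c_prev or "N" not in n_curr:
                return False
            return np.linalg.norm(c_prev["C"] - n_curr["N"]) < 2.5

        if (
            _bonded(prev_atoms, atoms)
            and all(k in atoms for k in ("N", "CA", "C"))
        ):
            torsions[i, 0] = dihedral(
                prev_atoms["C"], atoms["N"], atoms["CA"], atoms["C"]
            )
        if (
            _bonded(atoms, next_atoms)
            and all(k in atoms for k in ("N", "CA", "C"))
            and "N" in next_atoms
        ):
            torsions[i, 1] = dihedral(
                atoms["N"], atoms["CA"], atoms["C"], next_atoms["N"]
            )
    return NativeReference(torsions, trace)


def read_native_reference(
    path: str | Path, chain: Optional[str] = None
) -> NativeReference:
    """Read a native reference from the TSV dialect or a PDB file.

    For PDB input, (phi, psi) are computed from N/CA/C ATOM records;
    residues with missing atoms or flanking a chain break get NaN angles.
    Ambiguous multi-chain files require an explicit `chain`.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return _read_native_pdb(path, chain)
    return _read_native_tsv(path)


def write_backbone_pdb(
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    path: str | Path,
    chain: str = "A",
) -> None:
    """Write a synthetic N/CA/C poly-glycine backbone as a PDB file."""
    records = []
    serial = 1
    for i in range(len(ca)):
        for name, xyz in (("N", n[i]), ("CA", ca[i]), ("C", c[i])):
            records.append(
                f"ATOM  {serial:5d}  {name:<3s}GLY {chain}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00           {name[0]}"
            )
            serial += 1
    records.append("END")
    Path(path).write_text("\n".join(records) + "\n")


# ----------------------------------------------------------- assignments


def write_assignments(
    assignments: Sequence[PositionAssignment], path: str | Path
) -> None:
    """Per-position TSV of filtering outcome, confidence and prediction."""
    lines = [
        "# confrag assignments v1",
        "\t".join(ASSIGNMENT_COLUMNS),
    ]
    for a in assignments:
        lines.append(
            "\t".join(
                [
                    str(a.position),
                    a.status,
                    str(a.recurrence),
                    NA if a.consistency is None else _fmt(a.consistency),
                    _fmt(a.confidence),
                    "1" if a.reliable else "0",
                    a.centroid_ref or NA,
                    NA if a.phi is None else _fmt(a.phi),
                    NA if a.psi is None else _fmt(a.psi),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_assignments(path: str | Path) -> list[PositionAssignment]:
    """Read an assignments TSV back (centroids as ids, not Fragment refs)."""
    out: list[PositionAssignment] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if not header_seen:
            if tuple(fields) != ASSIGNMENT_COLUMNS:
                raise LibraryParseError(
                    f"line {lineno}: unexpected assignments header"
                )
            header_seen = True
            continue
        if len(fields) != len(ASSIGNMENT_COLUMNS):
            raise LibraryParseError(
                f"line {lineno}: expected {len(ASSIGNMENT_COLUMNS)} fields"
            )
        (pos, status, rec, cons, conf, reliable, cid, phi, psi) = fields
        out.append(
            PositionAssignment(
                position=int(pos),
                status=status,
                recurrence=int(rec),
                consistency=None if cons == NA else float(cons),
                confidence=float(conf),
                reliable=reliable == "1",
                centroid_id=None if cid == NA else cid,
                phi=None if phi == NA else float(phi),
                psi=None if psi == NA else float(psi),
            )
        )
    if not header_seen:
        raise LibraryParseError("missing assignments header")
    return out
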