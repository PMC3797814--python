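"""Scoring predictions against a native reference.

Angular errors use the wraparound rule: for angles in (-180, 180] degrees,
the absolute error is |d| when |d| <= 180 and 360 - |d| otherwise, keeping
every error in [0, 180].  The mean absolute error (MAE) at a confidence
cutoff pools all residues whose confidence is at least the cutoff and whose
angles are defined on both sides.

A fragment is *compatible* with the native structure when its full-length
Cα-RMSD to the native trace (over its whole query interval) is below the
critical 1.5 Å threshold.  Local precision at a residue is the fraction of
covering fragments that are compatible; coverage is the fraction of target
residues covered by at least one compatible fragment.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RMSD_THRESHOLD
from .core import Fragment, PositionAssignment
from .geometry import kabsch

logger = logging.getLogger(__name__)


def angular_error(predicted: float, experimental: float) -> float:
    """Wraparound absolute difference of two angles, in [0, 180] degrees."""
    for name, value in (("predicted", predicted), ("experimental", experimental)):
        if not -180.0 < value <= 180.0:
            raise ValueError(f"{name} angle {value} outside (-180, 180]")
    d = abs(predicted - experimental)
    return d if d <= 180.0 else 360.0 - d


def _reference_array(reference: np.ndarray) -> np.ndarray:
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference must be an (L, 2) array of (phi, psi)")
    return ref


def evaluate_mae(
    predictions: Sequence[PositionAssignment],
    reference: np.ndarray,
    cutoff: float = 0.0,
) -> tuple[Optional[float], Optional[float], int]:
    """(MAE phi, MAE psi, n residues) at a confidence cutoff.

    `reference` is an (L, 2) array of native (phi, psi), NaN where undefined
    (chain termini, missing density); such residues are excluded from the
    denominator, as are residues without a prediction or below the cutoff.
    MAEs are None when no residue qualifies.
    """
    ref = _reference_array(reference)
    err_phi: list[float] = []
    err_psi: list[float] = []
    skipped_native = 0
    for a in predictions:
        if a.phi is None or a.psi is None or a.confidence < cutoff:
            continue
        nat_phi, nat_psi = ref[a.position - 1]
        if np.isnan(nat_phi) or np.isnan(nat_psi):
            skipped_native += 1
            continue
        err_phi.append(angular_error(a.phi, float(nat_phi)))
        err_psi.append(angular_error(a.psi, float(nat_psi)))
    if skipped_native:
        logger.info(
            "evaluate_mae: %d predicted residues skipped for undefined "
            "native angles",
            skipped_native,
        )
    n = len(err_phi)
    if n == 0:
        return None, None, 0
    return float(np.mean(err_phi)), float(np.mean(err_psi)), n


def evaluate_mae_per_protein(
    per_protein: Sequence[tuple[Sequence[PositionAssignment], np.ndarray]],
    cutoff: float = 0.0,
) -> tuple[Optional[float], Optional[float], int]:
    """Mean over per-protein MAEs (alternative to pooling all residues).

    Proteins with no qualifying residue are skipped.  Returns the number of
    proteins contributing.
    """
    phis: list[float] = []
    psis: list[float] = []
    for predictions, reference in per_protein:
        mae_phi, mae_psi, n = evaluate_mae(predictions, reference, cutoff)
        if n > 0:
            phis.append(mae_phi)  # type: ignore[arg-type]
            psis.append(mae_psi)  # type: ignore[arg-type]
    if not phis:
        return None, None, 0
    return float(np.mean(phis)), float(np.mean(psis)), len(phis)


def cutoff_curve(
    predictions: Sequence[PositionAssignment],
    reference: np.ndarray,
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """MAE at increasing confidence cutoffs (columns: cutoff, n, mae_phi,
    mae_psi; NaN MAEs where no residue qualifies)."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be ascending")
    rows = []
    for cutoff in cutoffs:
        mae_phi, mae_psi, n = evaluate_mae(predictions, reference, cutoff)
        rows.append(
            {
                "cutoff": float(cutoff),
                "n": n,
                "mae_phi": np.nan if mae_phi is None else mae_phi,
                "mae_psi": np.nan if mae_psi is None else mae_psi,
            }
        )
    return pd.DataFrame(rows, columns=["cutoff", "n", "mae_phi", "mae_psi"])


def fragment_native_rmsd(
    f: Fragment, native_trace: np.ndarray
) -> Optional[float]:
    """Cα-RMSD of a fragment to the native structure over its full interval.

    None when the native trace lacks (finite) coordinates anywhere inside
    the fragment's interval.
    """
    trace = np.asarray(native_trace, dtype=float)
    if f.query_start < 1 or f.query_end > trace.shape[0]:
        return None
    nat = trace[f.query_start - 1 : f.query_end]
    if not np.all(np.isfinite(nat)):
        return None
    return kabsch(f.ca_trace, nat).rmsd


def local_precision_coverage(
    library: Sequence[Fragment],
    native_trace: np.ndarray,
    threshold: float = RMSD_THRESHOLD,
) -> tuple[np.ndarray, float]:
    """Per-residue local precision and overall coverage of a library.

    Returns an (L,) array (NaN at residues covered by no scorable fragment)
    and the fraction of the L residues covered by >= 1 compatible fragment.
    Fragments whose native RMSD cannot be computed (missing native
    coordinates) are skipped and logged.
    """
    trace = np.asarray(native_trace, dtype=float)
    n_res = trace.shape[0]
    covering = np.zeros(n_res, dtype=int)
    compatible = np.zeros(n_res, dtype=int)
    skipped = 0
    for f in library:
        rmsd = fragment_native_rmsd(f, trace)
        if rmsd is None:
            skipped += 1
            continue
        lo = max(1, f.query_start)
        hi = min(n_res, f.query_end)
        covering[lo - 1 : hi] += 1
        if rmsd < threshold:
            compatible[lo - 1 : hi] += 1
    if skipped:
        logger.info(
            "local_precision_coverage: %d fragments skipped (native "
            "coordinates missing in their interval)",
            skipped,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(
            covering > 0, compatible / np.maximum(covering, 1), np.nan
        )
    coverage = float(np.count_nonzero(compatible > 0)) / n_res
    return precision, coverage


def optimal_centroid_baseline(
    library: Sequence[Fragment], native_trace: np.ndarray
) -> list[PositionAssignment]:
    """Best-possible centroid choice: lowest native-RMSD fragment per residue.

    At each covered position, the covering fragment with minimal full-length
    Cα-RMSD to the native structure supplies the (phi, psi) prediction.
    This defines the optimal curve against which the confidence-guided
    predictions are compared; confidences are reported as 0 so the baseline
    enters MAE comparisons at cutoff 0.
    """
    trace = np.asarray(native_trace, dtype=float)
    n_res = trace.shape[0]
    rmsds = {f.id: fragment_native_rmsd(f, trace) for f in library}
    out: list[PositionAssignment] = []
    for pos in range(1, n_res + 1):
        best: Optional[Fragment] = None
        best_rmsd = np.inf
        for f in library:
            if not f.covers(pos):
                continue
            r = rmsds[f.id]
            if r is None:
                continue
            if r < best_rmsd or (r == best_rmsd and best and f.id < best.id):
                best, best_rmsd = f, r
        if best is None:
            out.append(PositionAssignment(position=pos, status="empty"))
        else:
            phi, psi = best.torsion_at(pos)
            out.append(
                PositionAssignment(
                    position=pos,
                    status="stable",
                    centroid=best,
                    phi=phi,
                    psi=psi,
                    confidence=0.0,
                )
            )
    return out
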