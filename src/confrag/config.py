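"""Shared constants and predictor configuration.

A single critical distance threshold of 1.5 Å governs three decisions in the
pipeline: whether a pair of fragments counts as structurally similar
(consistency), whether a cluster's average pairwise RMSD is low enough to be
called stable, and whether a fragment is compatible with the native structure
(local precision).  Keeping one number for all three mirrors how the method
was designed; each call site still accepts an explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Critical Cα-RMSD threshold in Å (edge similarity, cluster stability,
#: native compatibility).
RMSD_THRESHOLD: float = 1.5

#: Minimum query-interval overlap (residues) for a pairwise RMSD to be
#: meaningful; fragment pairs overlapping by fewer residues get no edge.
MIN_OVERLAP: int = 6

#: Valid fragment length range (residues) for ingested libraries.
MIN_FRAGMENT_LENGTH: int = 6
MAX_FRAGMENT_LENGTH: int = 21

#: Centroid eligibility: a vertex must be connected to at least
#: ceil(fraction * (|V| - 1)) other cluster members.
MIN_DEGREE_FRACTION: float = 0.5

#: Named confidence thresholds.  >= 0.8 flags a reliable prediction inside a
#: local region of high precision; 1.0 marks the transitional zone; >= 1.5 a
#: credible prediction expected to be accurate.
RELIABLE_CONFIDENCE: float = 0.8
TRANSITIONAL_CONFIDENCE: float = 1.0
CREDIBLE_CONFIDENCE: float = 1.5

#: Numerical tolerance for tie detection and strict-decrease tests in the
#: greedy filter.
TIE_TOLERANCE: float = 1e-12


@dataclass(frozen=True)
class PredictorConfig:
    """Bundle of tunable parameters threaded through prediction.

    Attributes
    ----------
    threshold:
        Critical Cα-RMSD in Å (default 1.5).
    min_overlap:
        Minimum residue overlap for a cluster edge (default 6).
    min_degree_fraction:
        Centroid eligibility fraction (default 0.5).
    reliable_cutoff:
        Confidence at or above which a prediction is flagged reliable
        (default 0.8).
    """

    threshold: float = RMSD_THRESHOLD
    min_overlap: int = MIN_OVERLAP
    min_degree_fraction: float = MIN_DEGREE_FRACTION
    reliable_cutoff: float = RELIABLE_CONFIDENCE
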