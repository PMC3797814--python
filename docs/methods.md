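# Methods

## Model and assumptions

The package treats a position-specific fragment library as, per target
residue *i*, an undirected weighted graph *G(i)*: vertices are the
fragments whose query interval contains *i*, and an edge of weight
*d(u,v)* — the minimal Cα-RMSD between the two fragments — connects every
pair whose query intervals overlap by at least 6 residues.  Below that
overlap an RMSD is not a meaningful divergence measure, so the pair is
left unconnected rather than given an unreliable weight.

Pairwise RMSD convention.  Fragments differ in length and start position,
so the RMSD is computed over exactly the residues in the intersection of
the two query intervals, pairing residues by target-sequence index, after
a fresh least-squares proper-rotation (Kabsch) superposition of the two
sub-traces.  Superposing per pair (rather than scoring in one shared
frame) treats edge weights as genuinely pairwise quantities; this is the
normative convention of this implementation.  Kabsch is implemented
directly via the SVD of the 3×3 covariance matrix with the determinant
sign correction, so reflections are never returned and zero-RMSD cases
recover machine-precision zeros.  Missing Cα coordinates inside a fragment
invalidate the fragment; nothing is imputed.

Filtering.  A cluster is stable when the average edge weight
`avg = W/|E|` is strictly below the critical threshold *t* (default
1.5 Å — the single constant also used for edge similarity and native
compatibility).  While unstable, every vertex *v* is probed with the
average that its exclusion would leave, `(W − w(v)) / (|E| − deg v)`,
using cached totals; the vertex with the minimal resulting average is
removed.  Termination:

- **stable** — average below threshold (the check runs before the first
  removal, so an already-stable cluster is returned untouched);
- **diverging** — no single removal strictly lowers the current average
  (strict inequality, tolerance 1e-12); the position is left unassigned
  and marked low-precision;
- **empty** — the initial graph has no edges (fewer than two fragments,
  or all overlaps < 6).  Stability is defined over edges, so an edgeless
  cluster is never "stable".  Because an accepted removal must leave at
  least one edge (its probe would otherwise be undefined), exhaustion
  below two vertices cannot be reached mid-run; `empty` in practice
  always means "empty at the start", and a cluster that can no longer
  improve surfaces as `diverging`.

Tie-breaking (the underlying description is silent): among removals whose
resulting averages agree within 1e-12, the vertex with the larger incident
weight w(v) is removed, then the lexicographically smallest fragment id.
This makes removal traces fully reproducible; identical inputs give
identical traces.  Degree-0 vertices surviving inside a stable cluster are
kept among the survivors but are never centroid-eligible and carry no
edges, hence do not affect consistency.

Confidence.  For a stable filtered cluster, recurrence *r* = number of
surviving vertices, consistency *c* = fraction of surviving edges with
weight ≤ *t* (a weight exactly at the threshold counts as similar; the
stability test, by contrast, is strict `<`).  The confidence is

    k = c · log10(r)

This reconstruction is anchored by five reference cases it reproduces
exactly — (c, r) → k of (0.75, 100) → 1.5, (1.0, 10) → 1.0,
(0.5, 100) → 1.0, (0.8, 10) → 0.8, (0.4, 100) → 0.8 — and by the property
that at r = 10 the log factor is exactly 1, so the confidence is driven
entirely by consistency.  r = 0 (unassignable position) maps to k = 0.
Consistency and recurrence are always computed on the *filtered* cluster,
never the raw one.  Named thresholds: 0.8 (reliable), 1.0 (transitional),
1.5 (credible).

Centroid.  Among vertices with degree ≥ ceil(f · (|V| − 1)), the one
minimizing the average incident weight w(v)/deg(v); ties break toward
smaller w(v), then smaller id.  The eligibility fraction *f* defaults to
0.5: the intent is to exclude peripheral vertices that happen to sit close
to their few neighbours while being disconnected from most of the cluster,
without emptying small stable clusters.  The exact constant is a design
choice of this package (exposed as `min_degree_fraction`), not an
externally fixed value.  The centroid's (φ, ψ) at the target position is
reported directly as the prediction; a stable cluster with no eligible
centroid keeps its confidence score but yields no angles and is never
flagged reliable.

## Evaluation

Angular errors use the wraparound rule on degrees in (−180, 180]
(−180 normalizes to +180 on ingest): error = |Δ| if |Δ| ≤ 180 else
360 − |Δ|, bounding every error by 180°.  MAE at a cutoff pools residues
with confidence ≥ cutoff (ties included — "greater than a cutoff" and
"0.8 or higher" are unified as ≥) and defined angles on both sides;
residues with undefined native angles (termini, chain breaks, missing
density) are excluded from denominators and counted in the log.  Pooling
across proteins is the default; a per-protein-average variant
(`evaluate_mae_per_protein`) is provided because the two readings are both
defensible.

Native compatibility of a fragment is its full-interval Cα-RMSD to the
native trace being < 1.5 Å.  Local precision at a residue is compatible
covering fragments over all covering fragments; coverage is the fraction
of residues covered by ≥ 1 compatible fragment.  The optimal-centroid
baseline picks, per position, the covering fragment with minimal native
RMSD — the lower bound any centroid-selection rule could reach on RMSD; on
generated libraries (below) its angular MAE also bounds the method's,
because coordinate and torsion noise are correlated per fragment.

## The synthetic generator

`ScenarioSpec` describes a target as ordered (kind, length) regions —
helix, strand, coil — with a per-region recurrence profile.  The native
backbone is built from canonical torsions (helix −57/−47, strand
−120/+120; coil φ ~ U(−180, −20], ψ ~ U(−180, 180]) with ideal peptide
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/
121.7°; ω = 180°) via sequential internal-coordinate placement, so
recomputed dihedrals round-trip to the generating torsions within 1e-3°.
Terminal φ(1)/ψ(L) have no geometric realization but are still reported.

True fragments are excisions of the native structure confined to their
conserved region and required to cover its center, with Gaussian jitter on
the Cα coordinates (`trace_noise_sd`, default 0.5 Å per coordinate) and
wrapped-Gaussian jitter on the torsions (`torsion_noise_sd`, default 5°).
Both are scaled by a per-fragment quality factor ~ U(0.5, 1.5): template
hits vary in quality coherently, not independently per observable, and
this coupling is what gives the min-RMSD baseline its meaning for angular
error.  Outliers are excised from decoy backbones rebuilt from seeded
permutations of the native torsion rows — structurally plausible chains
whose local geometry is wrong, landing outlier RMSDs in a realistic
3–10 Å band instead of a random walk's unbounded drift.  Conserved
regions receive outliers at `outlier_rate` (default 0.2, as a fraction of
the region's fragments); coil linkers receive only outliers.

The reference scenario is a 40-residue target
(coil6–helix12–coil7–strand10–coil5) with recurrence 25 in the conserved
regions and 5 decoy hits per linker.  Five hits per linker reflects that
variable linkers yield few remote-homology matches; it also means linker
clusters sit below the r = 10 up-weighting knee, so even a structurally
lucky pair of decoys cannot reach the 0.8 reliable cutoff — the behaviour
the confidence score is designed to have for rare, uncertain motifs.
Every fragment carries a hidden true/outlier label used only by tests;
labels are never serialized and never read by the pipeline.

What the generator does *not* emulate: sequence profiles and HMM score
distributions, database redundancy, length-dependent hit statistics, real
loop conformational ensembles, or missing density.  Passing tests
therefore demonstrate the correctness and calibration of the filtering,
scoring and evaluation machinery under controlled conditions — not
benchmark-grade accuracy on experimental fragment libraries.

## Problem sizes and numerical choices

Tests and examples use 40-residue targets with libraries of ~75 fragments
and 100-seed batteries for rate assertions; pairwise RMSDs are computed
once per library and shared across positions, which keeps whole-target
prediction at a few hundred superpositions.  Tolerances: 1e-12 for tie
detection and strict-decrease tests in the filter; 1e-9 Å for cache
coherence checks; 1e-6 for serialization round-trips (floats are printed
with 6 decimals).  Library ingest validates the 6–21 residue length
contract; a strict/lenient switch either rejects violations (naming the
record) or keeps them with a logged warning, since externally produced
libraries may deviate.

## Known limitations

- The centroid eligibility constant (0.5) is a documented default, not an
  externally validated value; very small stable clusters can lose their
  only candidate under stricter settings.
- The greedy filter is order-deterministic but, like any greedy scheme,
  not guaranteed globally optimal in the number of deletions.
- MAE comparisons between the method and the optimal baseline are made on
  the positions the method predicts; the baseline alone covers more
  positions (including low-precision ones) and pooling over different
  position sets is not meaningful.
- PDB ingest reads single models and selects one chain; insertion codes
  and altlocs beyond the first are not handled specially.
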