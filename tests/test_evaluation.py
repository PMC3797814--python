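"""Angular MAE machinery, local precision/coverage, optimal baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from confrag import (
    Fragment,
    PositionAssignment,
    angular_error,
    cutoff_curve,
    evaluate_mae,
    evaluate_mae_per_protein,
    local_precision_coverage,
    normalize_angle,
    optimal_centroid_baseline,
)
from confrag.synthetic import ScenarioSpec, generate_scenario

angles = st.floats(-179.999, 180.0)


def excised_fragment(fid, native, start, end, jitter=None, rng=None):
    ca = native.ca_trace[start - 1 : end].copy()
    if jitter:
        ca += rng.normal(0, jitter, ca.shape)
    return Fragment(
        id=fid,
        source_id="native",
        query_start=start,
        query_end=end,
        torsions=native.torsions[start - 1 : end],
        ca_trace=ca,
    )


def assignment(pos, phi, psi, conf=1.0):
    return PositionAssignment(
        position=pos, status="stable", phi=phi, psi=psi, confidence=conf
    )


class TestAngularError:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (170.0, -170.0, 20.0),
            (180.0, 0.0, 180.0),  # antipodal bound (normalized -180)
            (45.0, 45.0, 0.0),
            (-90.0, 90.0, 180.0),
            (10.0, -20.0, 30.0),
        ],
    )
    def test_wraparound_cases(self, a, b, expected):
        assert angular_error(a, b) == pytest.approx(expected)

    @given(angles, angles)
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        e = angular_error(a, b)
        assert 0.0 <= e <= 180.0
        assert e == pytest.approx(angular_error(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            angular_error(-180.0, 0.0)
        with pytest.raises(ValueError):
            angular_error(0.0, 181.0)


class TestEvaluateMAE:
    def test_perfect_predictions(self):
        ref = np.array([[10.0, -40.0], [20.0, 60.0]])
        preds = [assignment(1, 10.0, -40.0), assignment(2, 20.0, 60.0)]
        mae_phi, mae_psi, n = evaluate_mae(preds, ref)
        assert (mae_phi, mae_psi, n) == (0.0, 0.0, 2)

    def test_cutoff_above_everything(self):
        ref = np.zeros((2, 2))
        preds = [assignment(1, 0.0, 0.0, conf=0.5)]
        assert evaluate_mae(preds, ref, cutoff=0.9) == (None, None, 0)

    def test_planted_uniform_error_recovered(self, rng):
        """Predictions offset by exactly 10 degrees (with wraparound)
        recover a 10-degree MAE."""
        ref = np.column_stack(
            [rng.uniform(-179, 180, 50), rng.uniform(-179, 180, 50)]
        )
        preds = [
            assignment(
                i + 1,
                normalize_angle(ref[i, 0] + 10.0),
                normalize_angle(ref[i, 1] - 10.0),
            )
            for i in range(50)
        ]
        mae_phi, mae_psi, n = evaluate_mae(preds, ref)
        assert n == 50
        assert mae_phi == pytest.approx(10.0, abs=1e-9)
        assert mae_psi == pytest.approx(10.0, abs=1e-9)

    def test_undefined_native_angles_excluded(self):
        ref = np.array([[np.nan, 0.0], [30.0, 30.0]])
        preds = [assignment(1, 10.0, 10.0), assignment(2, 30.0, 40.0)]
        mae_phi, mae_psi, n = evaluate_mae(preds, ref)
        assert n == 1
        assert mae_psi == pytest.approx(10.0)

    def test_per_protein_average(self):
        ref_a = np.array([[0.0, 0.0]])
        ref_b = np.array([[0.0, 0.0]])
        prot_a = [assignment(1, 10.0, 10.0)]
        prot_b = [assignment(1, 30.0, 30.0)]
        mae_phi, mae_psi, n = evaluate_mae_per_protein(
            [(prot_a, ref_a), (prot_b, ref_b)]
        )
        assert n == 2
        assert mae_phi == pytest.approx(20.0)  # (10 + 30) / 2
        pooled_phi, _, _ = evaluate_mae(
            prot_a + [assignment(1, 30.0, 30.0)], ref_a
        )
        assert pooled_phi == pytest.approx(20.0)


class TestCutoffCurve:
    def test_single_and_duplicate_cutoffs(self):
        ref = np.array([[0.0, 0.0], [0.0, 0.0]])
        preds = [
            assignment(1, 10.0, 10.0, conf=0.2),
            assignment(2, 30.0, 30.0, conf=0.9),
        ]
        curve = cutoff_curve(preds, ref, [0.0, 0.0, 0.5])
        assert list(curve.n) == [2, 2, 1]
        assert curve.mae_phi[0] == curve.mae_phi[1] == pytest.approx(20.0)
        assert curve.mae_phi[2] == pytest.approx(30.0)

    def test_counts_non_increasing_and_unsorted_rejected(self):
        ref = np.zeros((5, 2))
        preds = [
            assignment(i + 1, 0.0, 0.0, conf=i / 4) for i in range(5)
        ]
        curve = cutoff_curve(preds, ref, [0.0, 0.3, 0.6, 1.0])
        assert all(np.diff(curve.n) <= 0)
        with pytest.raises(ValueError):
            cutoff_curve(preds, ref, [0.5, 0.1])


class TestPrecisionCoverage:
    def test_native_excised_library_is_perfect(self):
        spec = ScenarioSpec.default(seed=3)
        native, _ = generate_scenario(spec)
        lib = [
            excised_fragment("a", native, 1, 12),
            excised_fragment("b", native, 20, 32),
        ]
        precision, coverage = local_precision_coverage(
            lib, native.ca_trace
        )
        covered = ~np.isnan(precision)
        assert np.all(precision[covered] == 1.0)
        assert coverage == pytest.approx(covered.sum() / 40)

    def test_decoy_library_has_zero_precision(self):
        spec = ScenarioSpec(
            target_length=20,
            regions=(("helix", 14), ("coil", 6)),
            recurrence_profile=(0, 8),
            seed=9,
        )
        native, lib = generate_scenario(spec)  # outlier-only library
        assert all(f.label == "outlier" for f in lib)
        precision, coverage = local_precision_coverage(
            lib, native.ca_trace
        )
        covered = ~np.isnan(precision)
        assert covered.any()
        assert np.nanmax(precision) <= 0.2
        assert coverage <= 0.2

    def test_counts_match_brute_force_recount(self, rng):
        from confrag.evaluation import fragment_native_rmsd

        spec = ScenarioSpec.default(seed=21)
        native, lib = generate_scenario(spec)
        precision, coverage = local_precision_coverage(
            lib, native.ca_trace
        )
        for pos in (6, 12, 22, 30, 38):
            covering = [f for f in lib if f.covers(pos)]
            good = [
                f
                for f in covering
                if fragment_native_rmsd(f, native.ca_trace) < 1.5
            ]
            if covering:
                assert precision[pos - 1] == pytest.approx(
                    len(good) / len(covering)
                )
            else:
                assert np.isnan(precision[pos - 1])

    def test_invariant_under_rigid_motion_of_native(self, rng):
        spec = ScenarioSpec.default(seed=4)
        native, lib = generate_scenario(spec)
        p1, c1 = local_precision_coverage(lib, native.ca_trace)
        rot = Rotation.random(random_state=np.random.RandomState(3))
        moved = native.ca_trace @ rot.as_matrix().T + np.array(
            [5.0, -8.0, 2.0]
        )
        p2, c2 = local_precision_coverage(lib, moved)
        np.testing.assert_allclose(p1, p2, equal_nan=True)
        assert c1 == pytest.approx(c2)

    def test_missing_native_coordinates_skip_fragment(self):
        spec = ScenarioSpec.default(seed=5)
        native, _ = generate_scenario(spec)
        lib = [excised_fragment("a", native, 1, 12)]
        trace = native.ca_trace.copy()
        trace[5] = np.nan
        precision, coverage = local_precision_coverage(lib, trace)
        assert np.all(np.isnan(precision))
        assert coverage == 0.0


class TestOptimalBaseline:
    def test_single_and_excised_fragment_selection(self, rng):
        spec = ScenarioSpec.default(seed=6)
        native, _ = generate_scenario(spec)
        exact = excised_fragment("exact", native, 8, 18)
        noisy = excised_fragment(
            "noisy", native, 8, 18, jitter=1.0, rng=rng
        )
        single = optimal_centroid_baseline([noisy], native.ca_trace)
        assert single[10].centroid.id == "noisy"
        both = optimal_centroid_baseline([exact, noisy], native.ca_trace)
        assert both[10].centroid.id == "exact"
        assert both[0].centroid is None  # uncovered position

    def test_matches_exhaustive_scan(self):
        from confrag.evaluation import fragment_native_rmsd

        spec = ScenarioSpec.default(seed=8)
        native, lib = generate_scenario(spec)
        baseline = optimal_centroid_baseline(lib, native.ca_trace)
        for pos in (12, 30):
            covering = [
                (fragment_native_rmsd(f, native.ca_trace), f.id)
                for f in lib
                if f.covers(pos)
            ]
            best_id = min(covering)[1]
            assert baseline[pos - 1].centroid.id == best_id

    def test_baseline_bounds_method_mae(self):
        """Pooled over several scenarios, the best-fitting-fragment oracle
        achieves an MAE no worse than the confidence-guided centroids at
        cutoff 0, compared on the positions the method predicts."""
        from confrag import predict_target

        errs = {"base": [], "method": []}
        for seed in range(6):
            spec = ScenarioSpec.default(seed=seed)
            native, lib = generate_scenario(spec)
            method = predict_target(lib, spec.target_length)
            base = optimal_centroid_baseline(lib, native.ca_trace)
            predicted = {a.position for a in method if a.phi is not None}
            m = [a for a in method if a.position in predicted]
            b = [a for a in base if a.position in predicted]
            for tag, preds in (("method", m), ("base", b)):
                mae_phi, mae_psi, n = evaluate_mae(
                    preds, native.torsions, 0.0
                )
                errs[tag].append((mae_phi + mae_psi) / 2 * n)
        assert sum(errs["base"]) <= sum(errs["method"]) + 1e-9
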