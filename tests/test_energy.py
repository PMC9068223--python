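import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import toy_bundle
from tmdkit.energy import (
    EnergyEvaluationError,
    EnergyReport,
    FilterThresholds,
    PACKING_EPSILON,
    PROBE_RADIUS,
    RESIDUE_RADII,
    apply_design_filters,
    classify_interface_positions,
    ddg_binding,
    energy_percentile_mask,
    helicality,
    interface_sasa,
    lipophilicity_energy,
    packing_energy,
    sasa_per_atom,
    sc_from_points,
    score_bundle,
    shape_complementarity,
    system_energy,
    tm_span_extent,
    topology_match_fraction,
)
from tmdkit.geometry import CrickParams, HelixBundle, build_symmetric_bundle

POLY_L = "L" * 24


class TestPacking:
    def test_no_contacts_beyond_cutoff(self, far_apart_dimer):
        assert packing_energy(far_apart_dimer) == 0.0

    def test_two_residue_toy_matches_hand_sum(self):
        d = 6.0
        bundle = toy_bundle([[[0, 0, 0]], [[d, 0, 0]]], ["L", "A"])
        r0 = RESIDUE_RADII["L"] + RESIDUE_RADII["A"]
        expected = PACKING_EPSILON * ((r0 / d) ** 12 - 2 * (r0 / d) ** 6)
        assert packing_energy(bundle) == pytest.approx(expected, abs=1e-12)

    def test_intra_chain_pairs_excluded(self):
        # interface packing term: a single chain has no packing energy
        chain = np.array([[[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]])
        bundle = toy_bundle(chain, ["LLL"])
        assert packing_energy(bundle) == 0.0


class TestLipophilicity:
    def test_hydrophobic_prefers_membrane(self, lipo_table):
        centered = build_symmetric_bundle(CrickParams(n_chains=1, tilt=0.0), POLY_L)
        shifted = HelixBundle(centered.coords + np.array([0, 0, 40.0]), [POLY_L], 1)
        assert lipophilicity_energy(centered, lipo_table) < lipophilicity_energy(
            shifted, lipo_table
        )

    def test_unknown_residue_rejected(self, lipo_table):
        bundle = toy_bundle(np.zeros((1, 1, 3)), ["X"])
        with pytest.raises(EnergyEvaluationError):
            lipophilicity_energy(bundle, lipo_table)


class TestDdgBinding:
    def test_separated_chains_score_zero(self, far_apart_dimer, lipo_table):
        assert ddg_binding(far_apart_dimer, lipo_table) == pytest.approx(0.0, abs=1e-9)

    def test_packed_trimer_is_favorable(self, trimer_bundle, lipo_table):
        value = ddg_binding(trimer_bundle, lipo_table)
        assert value < 0
        # per-chain terms cancel: ddg equals the cross-chain packing energy
        isolated = sum(
            packing_energy(
                HelixBundle(trimer_bundle.coords[k : k + 1], ["L" * 24], 1)
            )
            for k in range(3)
        )
        assert value == pytest.approx(
            packing_energy(trimer_bundle) - isolated, abs=1e-9
        )

    def test_monomer_rejected(self, lipo_table):
        mono = build_symmetric_bundle(CrickParams(n_chains=1), POLY_L)
        with pytest.raises(EnergyEvaluationError):
            ddg_binding(mono, lipo_table)


def _two_sphere_buried_area(r1, r2, d):
    """Closed-form buried (mutually occluded) accessible area of two
    spheres of radius r1, r2 at center distance d < r1 + r2."""
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    return 2 * np.pi * (r1 * h1 + r2 * h2)


class TestInterfaceSasa:
    def test_separated_chains_bury_nothing(self, far_apart_dimer):
        assert interface_sasa(far_apart_dimer) == pytest.approx(0.0, abs=1.0)

    def test_two_sphere_analytic_oracle(self):
        d = 5.0
        bundle = toy_bundle([[[0, 0, 0]], [[d, 0, 0]]], ["L", "W"])
        r1 = RESIDUE_RADII["L"] + PROBE_RADIUS
        r2 = RESIDUE_RADII["W"] + PROBE_RADIUS
        expected = _two_sphere_buried_area(r1, r2, d)
        # Shrake-Rupley with 960 points: ~1% discretization error
        assert interface_sasa(bundle) == pytest.approx(expected, rel=0.02)

    def test_burial_decreases_with_separation(self, dimer_bundle):
        coords = dimer_bundle.coords.copy()
        outward = coords[1].mean(axis=0) * np.array([1.0, 1.0, 0.0])
        outward /= np.linalg.norm(outward)
        coords[1] += 4.0 * outward
        looser = HelixBundle(coords, dimer_bundle.sequences, 2)
        assert interface_sasa(looser) < interface_sasa(dimer_bundle)

    def test_never_negative(self, dimer_bundle, far_apart_dimer):
        for bundle in (dimer_bundle, far_apart_dimer):
            assert interface_sasa(bundle) > -1.0


class TestShapeComplementarity:
    def test_perfect_flat_patches_score_one(self):
        xs, ys = np.meshgrid(np.linspace(0, 3, 6), np.linspace(0, 3, 6))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(36)])
        up = np.tile([0.0, 0.0, 1.0], (36, 1))
        assert sc_from_points(pts, up, pts, -up) == pytest.approx(1.0, abs=1e-9)

    def test_packed_pose_beats_disordered_contact(self, dimer_bundle):
        from tmdkit.geometry import perturbed

        tight = shape_complementarity(dimer_bundle)
        jittered = [
            shape_complementarity(perturbed(dimer_bundle, 0.7, seed))
            for seed in range(6)
        ]
        assert np.median(jittered) < tight

    def test_value_stable_under_denser_sampling(self, dimer_bundle):
        coarse = shape_complementarity(dimer_bundle, n_points=120)
        dense = shape_complementarity(dimer_bundle, n_points=500)
        assert abs(coarse - dense) < 0.05

    def test_no_interface_is_undefined(self, far_apart_dimer):
        with pytest.raises(EnergyEvaluationError):
            shape_complementarity(far_apart_dimer)


class TestSpanAndTopology:
    def test_vertical_span_matches_rise(self):
        bundle = build_symmetric_bundle(CrickParams(n_chains=2, tilt=0.0), POLY_L)
        assert tm_span_extent(bundle) == pytest.approx(23 * 1.51, abs=1e-9)

    def test_tilted_span_follows_cosine(self):
        bundle = build_symmetric_bundle(CrickParams(n_chains=2, tilt=60.0), POLY_L)
        span = tm_span_extent(bundle)
        assert span == pytest.approx(23 * 1.51 * math.cos(math.radians(60)), abs=1.5)
        assert span < 25.0  # fails the prediction-stage span filter

    def test_in_plane_helix_has_no_extent(self):
        bundle = build_symmetric_bundle(CrickParams(n_chains=2, tilt=0.0), POLY_L)
        rot = Rotation.from_euler("x", 90, degrees=True)
        flat = HelixBundle(
            np.stack([rot.apply(c) for c in bundle.coords]), bundle.sequences, 2
        )
        assert tm_span_extent(flat) < 2.0

    def test_topology_counting_oracle(self):
        bundle = build_symmetric_bundle(CrickParams(n_chains=1, tilt=0.0), POLY_L)
        half = bundle.frame.half_thickness
        z = bundle.coords[0][:, 2]
        truth = [
            "membrane" if abs(v) <= half else ("cytosolic" if v < 0 else "external")
            for v in z
        ]
        assert topology_match_fraction(bundle, truth) == 1.0
        inverted = truth[::-1]
        expected = sum(a == b for a, b in zip(truth, inverted)) / len(truth)
        assert topology_match_fraction(bundle, inverted) == pytest.approx(expected)

    def test_helix_outside_slab_matches_nothing(self):
        bundle = build_symmetric_bundle(
            CrickParams(n_chains=1, tilt=0.0, z_offset=60.0), POLY_L
        )
        assert topology_match_fraction(bundle, ["membrane"] * 24) == 0.0

    def test_label_length_mismatch_rejected(self, dimer_bundle):
        with pytest.raises(EnergyEvaluationError):
            topology_match_fraction(dimer_bundle, ["membrane"] * 10)


class TestHelicality:
    def test_ideal_generator_output_is_zero(self, dimer_bundle):
        assert helicality(dimer_bundle) == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_detected(self, dimer_bundle):
        coords = dimer_bundle.coords.copy()
        coords[0, 12] += np.array([2.0, 0.0, 0.0])
        assert helicality(HelixBundle(coords, dimer_bundle.sequences, 2)) > 0

    def test_extended_chain_fails_filter(self):
        chain = np.zeros((1, 24, 3))
        chain[0, :, 2] = np.arange(24) * 3.8
        chain[0, ::2, 0] = 0.5  # slight zigzag so torsions are defined
        extended = toy_bundle(chain, [POLY_L])
        assert helicality(extended) > 0.1


class TestFilters:
    @staticmethod
    def _report(**kw):
        base = dict(
            total_energy=-5.0,
            packing_term=0.0,
            lipophilicity_term=0.0,
            crossing_penalty_term=0.0,
            ddg_binding=-20.0,
            interface_sasa=800.0,
            shape_complementarity=0.7,
            helicality=0.05,
            tm_span_extent=30.0,
            topology_match_fraction=0.5,
        )
        base.update(kw)
        return EnergyReport(**base)

    def test_design_stage_pass(self):
        result = apply_design_filters(self._report(), FilterThresholds.design())
        assert result.passed and not result.violations

    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("interface_sasa", 699.9, "sasa"),
            ("interface_sasa", 700.0, "sasa"),  # boundary: strict inequality
            ("shape_complementarity", 0.6, "sc"),
            ("ddg_binding", -15.0, "ddg"),
            ("helicality", 0.1, "helicality"),
        ],
    )
    def test_design_stage_boundaries_fail(self, field, value, reason):
        result = apply_design_filters(
            self._report(**{field: value}), FilterThresholds.design()
        )
        assert not result.passed
        assert result.violations == [reason]

    def test_prediction_stage_pass(self):
        report = self._report(
            interface_sasa=650.0, total_energy=-5.0, tm_span_extent=30.0,
            topology_match_fraction=0.5,
        )
        assert apply_design_filters(report, FilterThresholds.prediction()).passed

    def test_missing_field_rejected(self):
        report = self._report(interface_sasa=math.nan)
        with pytest.raises(EnergyEvaluationError):
            apply_design_filters(report, FilterThresholds.design())

    def test_energy_percentile_is_ensemble_level(self):
        energies = np.arange(100.0)
        mask = energy_percentile_mask(energies, 1.0)
        assert mask.sum() >= 1 and mask[0] and not mask[50]


class TestInterfaceClassification:
    def test_separated_chains_all_exposed(self, far_apart_dimer):
        assert set(classify_interface_positions(far_apart_dimer)) == {"exposed"}

    def test_matches_per_residue_burial_oracle(self, dimer_bundle):
        labels = classify_interface_positions(dimer_bundle)
        coords = dimer_bundle.coords.reshape(-1, 3)
        radii = np.array([RESIDUE_RADII["L"]] * 48)
        complex_sasa = sasa_per_atom(coords, radii)[:24]
        iso_sasa = sasa_per_atom(dimer_bundle.coords[0], radii[:24])
        expected = [
            "interface" if iso > 1e-9 and (iso - cplx) / iso > 0.25 else "exposed"
            for iso, cplx in zip(iso_sasa, complex_sasa)
        ]
        assert labels == expected
        assert "interface" in labels and "exposed" in labels

    def test_rigid_rotation_preserves_labels(self, dimer_bundle):
        rot = Rotation.from_euler("z", 137.0, degrees=True)
        moved = HelixBundle(
            np.stack([rot.apply(c) for c in dimer_bundle.coords]),
            dimer_bundle.sequences,
            2,
        )
        assert classify_interface_positions(moved) == classify_interface_positions(
            dimer_bundle
        )


class TestScoreBundle:
    def test_total_is_sum_of_terms(self, dimer_bundle, lipo_table):
        report = score_bundle(dimer_bundle, lipo_table)
        assert report.total_energy == pytest.approx(
            report.packing_term
            + report.lipophilicity_term
            + report.crossing_penalty_term
        )
        assert report.total_energy == pytest.approx(
            system_energy(dimer_bundle, lipo_table)
        )

    def test_deterministic(self, dimer_bundle, lipo_table):
        a = score_bundle(dimer_bundle, lipo_table)
        b = score_bundle(dimer_bundle, lipo_table)
        assert a.as_series().equals(b.as_series())
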