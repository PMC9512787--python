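"""Superposition, flexibility profiling, hinge rotations, and splicing."""

import dataclasses

import numpy as np
import pytest

from augmintools.geometry import (
    RigidTransform,
    SpliceRecipe,
    align_ensemble,
    angle_axis_of,
    extreme_pair,
    flexibility_profile,
    kabsch,
    rotation_between,
    rotation_matrix,
    splice_composite,
    transform_structure,
)
from augmintools.structio import Selection
from augmintools.synthetic import (
    BundleSpec,
    FlexSpec,
    HingeSpec,
    default_chain_map,
    make_bundle,
    make_flex_ensemble,
    make_hinge_ensemble,
    sinusoid_profile,
)

from conftest import SMALL_BUNDLE, line_structure

HINGE_BUNDLE = BundleSpec(n_chains=4, residues_per_chain=60)
HINGE_CMAP = default_chain_map(4)
REF_SEL = Selection(tuple((f"S{i + 1}", 1, 30) for i in range(4)))
MOB_SEL = Selection(tuple((f"S{i + 1}", 31, 60) for i in range(4)))


class TestKabsch:
    def test_identity_on_equal_point_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(transform.translation, 0.0, atol=1e-12)

    def test_recovers_known_rigid_motion_exactly(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        R = rotation_matrix([0, 0, 1], 30.0)
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        transform, rmsd = kabsch(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.apply(moved), pts, atol=1e-9)

    def test_beats_random_rotation_oracle_under_noise(self, rng):
        pts = rng.normal(size=(10, 3)) * 4
        moved = pts @ rotation_matrix([1, 1, 0], 40.0).T + 2.0
        moved += rng.normal(scale=0.5, size=moved.shape)
        _, rmsd = kabsch(moved, pts)
        cm, cp = moved.mean(0), pts.mean(0)
        for _ in range(2000):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            cand = (moved - cm) @ R.T + cp
            assert rmsd <= np.sqrt(np.mean(np.sum((cand - pts) ** 2, axis=1))) + 1e-12

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        bad = np.full((4, 3), np.nan)
        with pytest.raises(ValueError):
            kabsch(bad, np.zeros((4, 3)))

    def test_never_returns_reflection_for_planar_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        mirrored = pts * np.array([1, 1, -1.0]) + np.array([0, 0, 0.5])
        transform, _ = kabsch(mirrored, pts)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)


class TestRigidTransform:
    def test_compose_and_inverse(self, rng):
        a = RigidTransform(rotation_matrix([1, 2, 3], 25.0), np.array([1.0, -2.0, 0.5]))
        b = RigidTransform(rotation_matrix([0, 1, 0], 80.0), np.array([3.0, 0.0, -1.0]))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-12)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestAlignEnsemble:
    def test_identical_copies_align_with_zero_rmsd(self, small_bundle, small_chain_map):
        ensemble = [small_bundle, small_bundle, small_bundle]
        core = Selection((("S1", 1, 60),))
        _, rmsds = align_ensemble(ensemble, core, small_chain_map)
        assert rmsds == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)

    def test_hinge_ensemble_core_aligns_and_distal_half_moves(self):
        two, _ = make_hinge_ensemble(HINGE_BUNDLE, HingeSpec(split_residue=30, angle_deg=25.0))
        aligned, rmsds = align_ensemble(two, REF_SEL, HINGE_CMAP)
        assert rmsds[1] == pytest.approx(0.0, abs=1e-9)  # core is rigid
        prof = flexibility_profile(aligned, mode="extreme_pair")
        core_dev = [v for (c, r, ic), v in prof.values.items() if r <= 30]
        distal_dev = [v for (c, r, ic), v in prof.values.items() if r > 35]
        assert max(core_dev) < 1e-9
        assert min(distal_dev) > 1.0

    def test_noisy_ensemble_core_rmsd_bounded_by_amplitude(self):
        amp = np.full(SMALL_BUNDLE.residues_per_chain, 1.0)
        ensemble, _ = make_flex_ensemble(SMALL_BUNDLE, FlexSpec(n_models=25, amplitude=amp), seed=7)
        core = Selection(tuple((f"S{i + 1}", 1, 60) for i in range(4)))
        _, rmsds = align_ensemble(ensemble, core, default_chain_map(4))
        assert max(rmsds) <= 3.0  # noise amplitude 1 Å x 3

    def test_inconsistent_residue_content_is_reported(self, small_bundle, small_chain_map):
        truncated = small_bundle.with_coords(small_bundle.coords())
        truncated.models[0] = truncated.models[0][:-5]
        core = Selection((("S4", 1, 60),))
        with pytest.raises(ValueError, match="inconsistent"):
            align_ensemble([small_bundle, truncated], core, small_chain_map)


class TestFlexibilityProfile:
    def test_identical_copies_have_zero_profile(self, small_bundle):
        prof = flexibility_profile([small_bundle, small_bundle], mode="ensemble_rmsd")
        assert prof.array().max() == pytest.approx(0.0, abs=1e-12)

    def test_exact_displacement_recovered_by_extreme_pair(self):
        a = line_structure(n_res=10)
        coords = a.coords()
        coords[4] += np.array([0.0, 10.0, 0.0])
        b = a.with_coords(coords)
        prof = flexibility_profile([a, b], mode="extreme_pair")
        assert prof.values[("A", 5, "")] == pytest.approx(10.0)
        assert prof.values[("A", 1, "")] == pytest.approx(0.0)

    def test_planted_sinusoid_profile_recovered(self):
        spec = BundleSpec(n_chains=2, residues_per_chain=80)
        amp = sinusoid_profile(80, max_amp=4.0)
        ensemble, _ = make_flex_ensemble(spec, FlexSpec(n_models=25, amplitude=amp), seed=11)
        prof = flexibility_profile(ensemble, mode="ensemble_rmsd")
        recovered = np.zeros(80)
        counts = np.zeros(80)
        for (chain, res, _ic), v in prof.values.items():
            recovered[res - 1] += v
            counts[res - 1] += 1
        recovered /= counts
        assert np.corrcoef(recovered, amp)[0, 1] >= 0.9

    def test_ensemble_rmsd_invariant_to_global_rigid_motion(self, small_bundle, rng):
        coords = small_bundle.coords()
        members = [
            small_bundle.with_coords(coords + rng.normal(scale=0.8, size=coords.shape))
            for _ in range(4)
        ]
        prof = flexibility_profile(members, mode="ensemble_rmsd")
        motion = RigidTransform(rotation_matrix([1, 0, 2], 70.0), np.array([5.0, -3.0, 9.0]))
        moved = [transform_structure(s, motion) for s in members]
        prof2 = flexibility_profile(moved, mode="ensemble_rmsd")
        assert np.allclose(prof.array(), prof2.array(), atol=1e-9)

    def test_requires_two_models(self, small_bundle):
        with pytest.raises(ValueError):
            flexibility_profile([small_bundle], mode="ensemble_rmsd")


class TestExtremePair:
    def test_two_models_return_first_pair(self, small_bundle):
        assert extreme_pair([small_bundle, small_bundle]) == (0, 1)

    def test_hinge_outlier_is_in_the_pair(self):
        two, _ = make_hinge_ensemble(HINGE_BUNDLE, HingeSpec(split_residue=30, angle_deg=30.0))
        ensemble = [two[0], two[0], two[0], two[0], two[1]]
        assert 4 in extreme_pair(ensemble)

    def test_matches_brute_force_over_all_pairs(self):
        ensemble, _ = make_flex_ensemble(
            BundleSpec(n_chains=2, residues_per_chain=30), FlexSpec(n_models=10), seed=3
        )
        coords = np.stack([s.coords() for s in ensemble])
        best, best_rmsd = None, -1.0
        for i in range(10):
            for j in range(i + 1, 10):
                rmsd = np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1)))
                if rmsd > best_rmsd:
                    best, best_rmsd = (i, j), rmsd
        assert extreme_pair(ensemble) == best


class TestRotationBetween:
    def test_zero_angle_for_identical_structures(self, small_bundle, small_chain_map):
        m = rotation_between(small_bundle, small_bundle, REF_SEL, MOB_SEL, small_chain_map)
        assert m.angle_deg == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [0.0, 23.0, 90.0, 180.0])
    def test_recovers_planted_hinge_angle_exactly(self, angle):
        two, truth = make_hinge_ensemble(
            HINGE_BUNDLE, HingeSpec(split_residue=30, angle_deg=angle, axis=(1.0, 0.4, -0.2))
        )
        m = rotation_between(two[1], two[0], REF_SEL, MOB_SEL, HINGE_CMAP)
        assert m.angle_deg == pytest.approx(angle, abs=1e-6)
        if 0 < angle < 180:
            assert abs(float(np.dot(m.axis, truth.axis))) >= 0.999999
        # composing the measured rotation with the inverse planted rotation
        # gives the identity
        if 0 < angle < 180:
            planted = rotation_matrix(truth.axis, truth.angle_deg)
            resid, _ = angle_axis_of(m_rotation_matrix(m) @ planted.T)
            assert resid == pytest.approx(0.0, abs=1e-6)

    def test_angle_is_symmetric_in_argument_order(self):
        two, _ = make_hinge_ensemble(HINGE_BUNDLE, HingeSpec(split_residue=30, angle_deg=37.0))
        fwd = rotation_between(two[0], two[1], REF_SEL, MOB_SEL, HINGE_CMAP)
        rev = rotation_between(two[1], two[0], REF_SEL, MOB_SEL, HINGE_CMAP)
        assert fwd.angle_deg == pytest.approx(rev.angle_deg, abs=1e-9)

    def test_centroid_mode_measures_rotation_without_reference(self):
        domain = line_structure(n_res=12)
        R = rotation_matrix([0, 1, 0], 180.0)
        center = domain.coords().mean(axis=0)
        rotated = domain.with_coords(
            (domain.coords() - center) @ R.T + center + np.array([50.0, 0, 0])
        )
        sel = Selection((("D", 1, 12),))
        m = rotation_between(domain, rotated, None, sel, {"D": "A"}, center_mode="centroid")
        assert m.angle_deg == pytest.approx(180.0, abs=1e-6)

    def test_ref_required_unless_centroid_mode(self, small_bundle, small_chain_map):
        with pytest.raises(ValueError):
            rotation_between(small_bundle, small_bundle, None, MOB_SEL, small_chain_map)


def m_rotation_matrix(measurement):
    return rotation_matrix(measurement.axis, measurement.angle_deg)


class TestSpliceComposite:
    def test_identity_recipe_reproduces_the_model(self, small_bundle, small_chain_map):
        whole = Selection(
            tuple((f"S{i + 1}", 1, 60) for i in range(4)), atom_filter="all_atoms"
        )
        recipe = SpliceRecipe(splices=[("m", whole)])
        out = splice_composite(recipe, {"m": small_bundle}, small_chain_map)
        assert out.n_atoms() == small_bundle.n_atoms()
        assert np.allclose(
            sorted(map(tuple, out.coords().tolist())),
            sorted(map(tuple, small_bundle.coords().tolist())),
        )

    def test_complementary_segments_merge_to_range_sum(self, small_bundle, small_chain_map):
        recipe = SpliceRecipe(
            splices=[
                ("a", Selection((("S1", 1, 25), ("S2", 1, 60)))),
                ("b", Selection((("S1", 26, 60), ("S3", 1, 60)))),
            ]
        )
        out = splice_composite(
            recipe, {"a": small_bundle, "b": small_bundle}, small_chain_map
        )
        assert out.n_atoms() == 25 + 60 + 35 + 60
        keys = [a.atom_key for a in out.atoms()]
        assert len(keys) == len(set(keys))

    def test_overlapping_splices_name_the_residues(self, small_bundle, small_chain_map):
        recipe = SpliceRecipe(
            splices=[
                ("a", Selection((("S1", 1, 30),))),
                ("b", Selection((("S1", 30, 60),))),
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            splice_composite(recipe, {"a": small_bundle, "b": small_bundle}, small_chain_map)

    def test_deletions_remove_exactly_the_named_residues(self, small_bundle, small_chain_map):
        whole = Selection(tuple((f"S{i + 1}", 1, 60) for i in range(4)))
        recipe = SpliceRecipe(
            splices=[("m", whole)], deletions=[Selection((("S2", 10, 15),))]
        )
        out = splice_composite(recipe, {"m": small_bundle}, small_chain_map)
        assert out.n_atoms() == small_bundle.n_atoms() - 6
        assert not any(a.chain_id == "B" and 10 <= a.res_seq <= 15 for a in out.atoms())

    def test_deleting_unspliced_residue_warns(self, small_bundle, small_chain_map):
        recipe = SpliceRecipe(
            splices=[("m", Selection((("S1", 1, 60),)))],
            deletions=[Selection((("S2", 1, 5),))],
        )
        with pytest.warns(UserWarning, match="non-spliced"):
            splice_composite(recipe, {"m": small_bundle}, small_chain_map)

    def test_placements_transform_their_source_model(self, small_bundle, small_chain_map):
        shift = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        recipe = SpliceRecipe(
            splices=[
                ("a", Selection((("S1", 1, 60),))),
                ("b", Selection((("S2", 1, 60),))),
            ]
        )
        out = splice_composite(
            recipe,
            {"a": small_bundle, "b": small_bundle},
            small_chain_map,
            placements={"b": shift},
        )
        xs = {a.chain_id: a.pos[0] for a in out.atoms()}
        assert xs["B"] > 80.0  # chain B moved by the placement
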