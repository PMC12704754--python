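"""Matching, classification, orientation estimation, reconstruction, FSC."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spcold import reconstruct3d as r3
from spcold import simkit
from spcold.projgeom import enumerate_labeling_classes


@pytest.fixture(scope="module")
def templates(heptamer_mod):
    classes = enumerate_labeling_classes(7, 3)
    return r3.build_class_templates(
        heptamer_mod, [c.representative for c in classes],
        n_orientations=600, max_tilt_deg=35.0)


@pytest.fixture(scope="module")
def heptamer_mod():
    return simkit.build_heptamer_model(3.5)


def _heptamer_particles(rng, n, noise, orientation="uniform"):
    hep = simkit.build_heptamer_model(3.5)
    parts, rots = [], []
    for _ in range(n):
        if orientation == "uniform":
            R = simkit.sample_orientation(rng)
        else:
            R = simkit.sample_membrane_orientation(rng, 15.0)
        pts = (R @ hep.labels.T).T[:, :2] + rng.normal(0, noise, (7, 2))
        parts.append(pts)
        rots.append(R)
    return parts, rots


class TestTemplatesAndMatching:
    def test_identity_projection_equals_in_plane_model(self, heptamer_mod):
        tpl = r3.build_class_templates(heptamer_mod, [range(7)],
                                       n_orientations=1)
        # single-direction Fibonacci grid looks straight down the z axis
        assert len(tpl[0].projection_bank) == 1

    def test_tilt_collapses_extent(self, heptamer_mod):
        R = Rotation.from_euler("x", 89.9, degrees=True).as_matrix()
        proj = (R @ heptamer_mod.labels.T).T[:, :2]
        assert np.ptp(proj[:, 1]) < 0.05 * np.ptp(proj[:, 0])

    def test_bank_size(self, heptamer_mod):
        tpls = r3.build_class_templates(heptamer_mod, [range(3), range(4)],
                                        n_orientations=50)
        assert len(tpls) == 2
        assert all(len(t.projection_bank) == len(t.bank_rotations)
                   for t in tpls)

    def test_self_match_scores_one(self, templates):
        tpl = templates[1]
        assert r3.match_score(tpl.projection_bank[10], tpl, 0.7) == \
            pytest.approx(1.0, abs=1e-6)

    def test_displaced_particle_scores_zero(self, templates):
        far = templates[0].projection_bank[0] * 10.0
        assert r3.match_score(far, templates[0], 0.5) < 1e-3

    def test_point_count_mismatch_scores_zero(self, templates):
        assert r3.match_score(np.zeros((5, 2)), templates[0], 0.7) == 0.0

    def test_match_invariance_rotation_translation_reflection(self,
                                                              templates,
                                                              rng):
        pts = templates[2].projection_bank[33] + rng.normal(0, 0.2, (3, 2))
        base = r3.match_score(pts, templates[2], 1.0)
        ang = 1.1
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        for transform in (pts @ rot.T + np.array([5.0, -3.0]),
                          pts * np.array([1.0, -1.0]),
                          pts[::-1]):
            assert r3.match_score(transform, templates[2], 1.0) == \
                pytest.approx(base, abs=1e-6)


class TestClassification:
    @staticmethod
    def _class_particles(rng, cid, n, noise):
        hep = simkit.build_heptamer_model(3.5)
        classes = enumerate_labeling_classes(7, 3)
        sub = list(classes[cid].representative)
        out = []
        for _ in range(n):
            R = simkit.sample_membrane_orientation(rng, 15.0)
            out.append((R @ hep.labels[sub].T).T[:, :2]
                       + rng.normal(0, noise, (3, 2)))
        return out

    def test_accuracy_low_noise(self, templates):
        rng = np.random.default_rng(19)
        particles, truth = [], []
        for cid in range(4):
            ps = self._class_particles(rng, cid, 15, 0.35)
            particles.extend(ps)
            truth.extend([cid] * len(ps))
        results = r3.classify_particles(particles, templates, 0.7,
                                        threshold=0.8)
        correct = [r.assigned_class == t for r, t in zip(results, truth)
                   if r.assigned_class is not None]
        assert np.mean(correct) >= 0.85

    def test_score_above_threshold_at_study_noise(self, templates):
        # own-class geometric score exceeds 0.8 in >= 90% of particles
        rng = np.random.default_rng(29)
        hits, n = 0, 40
        ps = self._class_particles(rng, 1, n, 0.7)
        for pts in ps:
            if r3.match_score(pts, templates[1], 1.4) > 0.8:
                hits += 1
        assert hits / n >= 0.9

    def test_above_chance_at_study_noise(self, templates):
        rng = np.random.default_rng(37)
        particles, truth = [], []
        for cid in range(4):
            particles.extend(self._class_particles(rng, cid, 10, 0.7))
            truth.extend([cid] * 10)
        results = r3.classify_particles(particles, templates, 1.4)
        assigned = [(r.assigned_class, t) for r, t in zip(results, truth)
                    if r.assigned_class is not None]
        acc = np.mean([a == t for a, t in assigned])
        assert acc > 0.5          # 4 classes: chance level 0.25

    def test_low_scores_unassigned(self, templates):
        junk = np.array([[0.0, 0], [20.0, 0], [0, 20.0]])
        res = r3.classify_particles([junk], templates, 0.5)[0]
        assert res.assigned_class is None

    def test_tie_flagged_unassigned(self, heptamer_mod):
        # two identical templates force an exact tie
        tpls = r3.build_class_templates(heptamer_mod,
                                        [range(3), range(3)],
                                        n_orientations=20)
        pts = tpls[0].projection_bank[5]
        res = r3.classify_particles([pts], tpls, 0.7)[0]
        assert res.tie and res.assigned_class is None


class TestOrientation:
    def test_in_plane_particle_near_zero_tilt(self, heptamer_mod, rng):
        # noiseless planar case: the tilt valley (cos tilt ~ 1) collapses
        # and the in-plane orientation is identifiable
        pts = heptamer_mod.labels[:, :2]
        est = r3.estimate_orientation(pts, heptamer_mod, rng)
        assert est.tilt_deg < 3.0
        assert est.converged

    def test_known_tilt_recovered(self, heptamer_mod, rng):
        # the tilt reconstruction demo case: 3 deg about x, 56 deg about y
        Rt = Rotation.from_euler("xy", [3, 56], degrees=True).as_matrix()
        pts = (Rt @ heptamer_mod.labels.T).T[:, :2] + \
            rng.normal(0, 0.3, (7, 2))
        est = r3.estimate_orientation(pts, heptamer_mod, rng)
        assert est.tilt_deg == pytest.approx(r3.tilt_angle_deg(Rt), abs=5.0)

    def test_membrane_prior_tilt_distribution(self, heptamer_mod):
        rng = np.random.default_rng(41)
        tilts = []
        for _ in range(15):
            R = simkit.sample_membrane_orientation(rng, 10.0)
            pts = (R @ heptamer_mod.labels.T).T[:, :2] + \
                rng.normal(0, 0.3, (7, 2))
            est = r3.estimate_orientation(pts, heptamer_mod, rng,
                                          n_steps=800, n_restarts=3)
            tilts.append(est.tilt_deg)
        assert np.median(tilts) < 30.0

    def test_too_few_points_rejected(self, heptamer_mod, rng):
        with pytest.raises(ValueError):
            r3.estimate_orientation(np.zeros((2, 2)), heptamer_mod, rng)


class TestReconstruction:
    def test_noiseless_particles_exact_recovery(self, heptamer_mod):
        rng = np.random.default_rng(3)
        parts, _ = _heptamer_particles(rng, 12, noise=0.0)
        rec = r3.reconstruct_class(parts, rng, n_outer=10,
                                   marginal_passes=0,
                                   scale_calibration=None,
                                   noise_sigma_nm=0.05)
        err = _best_alignment_rmsd(rec.blob_centers_nm, heptamer_mod)
        assert err < 0.15

    def test_objective_monotone_non_increasing(self, heptamer_mod):
        rng = np.random.default_rng(4)
        parts, _ = _heptamer_particles(rng, 10, noise=0.5)
        rec = r3.reconstruct_class(parts, rng, n_outer=8)
        diffs = np.diff(rec.objective_history)
        assert np.all(diffs <= 1e-9)

    def test_blob_error_below_study_precision_bound(self, heptamer_mod):
        # blob centers within 2x the 0.7 nm noise after rigid alignment
        rng = np.random.default_rng(6)
        parts, _ = _heptamer_particles(rng, 25, noise=0.7)
        rec = r3.reconstruct_class(parts, rng, noise_sigma_nm=0.7)
        err = _best_alignment_rmsd(rec.blob_centers_nm, heptamer_mod)
        assert err < 1.4

    def test_single_orientation_flagged_degenerate(self, heptamer_mod,
                                                   rng):
        pts = heptamer_mod.labels[:, :2]
        parts = [pts + rng.normal(0, 0.1, (7, 2)) for _ in range(6)]
        rec = r3.reconstruct_class(parts, rng, n_outer=6, n_init=1,
                                   marginal_passes=0,
                                   noise_sigma_nm=0.1)
        assert rec.degenerate

    def test_too_few_particles_rejected(self, rng):
        with pytest.raises(ValueError):
            r3.reconstruct_class([np.zeros((3, 2))] * 3, rng)


class TestMerge:
    def test_classes_merge_onto_ground_truth(self, heptamer_mod):
        rng = np.random.default_rng(8)
        classes = enumerate_labeling_classes(7, 3)
        recons = []
        for c in classes[:2]:
            sub = list(c.representative)
            X = heptamer_mod.labels[sub] + rng.normal(0, 0.1, (3, 3))
            R = simkit.sample_orientation(rng)
            recons.append(r3.Reconstruction3D(
                c.class_id, (R @ (X - X.mean(0)).T).T, 0.1, [], 10))
        merged = r3.merge_class_reconstructions(recons, heptamer_mod)
        assert not any(f["flagged"] for f in merged["fits"])
        for f, c in zip(merged["fits"], classes[:2]):
            assert set(f["sites"]) in [
                {(v + r) % 7 for v in c.representative} for r in range(7)
            ] + [{(-v + r) % 7 for v in c.representative} for r in range(7)]

    def test_identity_merge(self, heptamer_mod):
        rec = r3.Reconstruction3D(0, heptamer_mod.labels.copy(), 0.1, [], 5)
        merged = r3.merge_class_reconstructions([rec, rec], heptamer_mod)
        assert np.allclose(merged["blob_centers_nm"],
                           heptamer_mod.labels, atol=1e-6)

    def test_incompatible_geometry_flagged(self, heptamer_mod):
        rec_bad = r3.Reconstruction3D(
            0, np.array([[0.0, 0, 0], [30.0, 0, 0], [0, 30.0, 0]]),
            0.1, [], 5)
        merged = r3.merge_class_reconstructions([rec_bad, rec_bad],
                                                heptamer_mod)
        assert all(f["flagged"] for f in merged["fits"])

    def test_single_recon_rejected(self, heptamer_mod):
        rec = r3.Reconstruction3D(0, heptamer_mod.labels, 0.1, [], 5)
        with pytest.raises(ValueError):
            r3.merge_class_reconstructions([rec], heptamer_mod)


class TestFSC:
    def test_self_correlation_is_one(self, heptamer_mod):
        vol = r3.volume_from_blobs(heptamer_mod.labels, 16.0, 0.4, 0.7)
        curve = r3.fsc(vol, vol, 0.4)
        filled = curve.n_voxels_per_shell > 0
        assert np.allclose(curve.correlation[filled], 1.0, atol=1e-9)

    def test_symmetric_in_arguments(self, rng):
        a = rng.random((24, 24, 24))
        b = rng.random((24, 24, 24))
        ca = r3.fsc(a, b, 0.5)
        cb = r3.fsc(b, a, 0.5)
        assert np.allclose(ca.correlation, cb.correlation, atol=1e-12)

    def test_independent_noise_decorrelates(self, rng):
        a = rng.random((32, 32, 32))
        b = rng.random((32, 32, 32))
        curve = r3.fsc(a, b, 0.5)
        assert np.abs(curve.correlation[2:]).max() < 0.2
        assert curve.resolution_nm is not None

    def test_halfbit_threshold_matches_independent_formula(self):
        # independent re-derivation of the published half-bit curve
        n = np.array([1.0, 7.0, 100.0, 5000.0])
        expected = [(0.2071 + 1.9102 / math.sqrt(v))
                    / (1.2071 + 0.9102 / math.sqrt(v)) for v in n]
        assert np.allclose(r3.half_bit_threshold(n), expected, atol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            r3.fsc(np.zeros((8, 8, 8)), np.zeros((9, 9, 9)), 0.5)

    def test_half_map_fsc_of_good_reconstruction(self, heptamer_mod):
        # split-half reconstructions of the same structure stay correlated
        rng = np.random.default_rng(9)
        X = heptamer_mod.labels
        half_a = X + rng.normal(0, 0.15, X.shape)
        half_b = X + rng.normal(0, 0.15, X.shape)
        va = r3.volume_from_blobs(half_a, 18.0, 0.45, 0.7)
        vb = r3.volume_from_blobs(half_b, 18.0, 0.45, 0.7)
        curve = r3.fsc(va, vb, 0.45)
        assert curve.correlation[1] > 0.9
        assert curve.resolution_nm is None or curve.resolution_nm < 2.0


def _best_alignment_rmsd(X, model):
    T = model.labels - model.labels.mean(0)
    best = np.inf
    for perm in itertools.permutations(range(T.shape[0])):
        r, _, _ = r3.align_point_sets_3d(X[list(perm)], T)
        best = min(best, r)
    return best
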