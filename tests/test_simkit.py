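"""Simulator: geometry, orientation sampling, blinking, rendering."""

import math

import numpy as np
import pytest
from scipy import stats

from spcold import simkit


class TestPointModels:
    def test_heptamer_geometry(self, heptamer):
        # circumradius R = d1 / (2 sin(pi/7)) and chords 2 R sin(k pi/7)
        radius = np.linalg.norm(heptamer.labels, axis=1)
        assert np.allclose(radius, 3.5 / (2 * math.sin(math.pi / 7)))
        dists = np.round(heptamer.pairwise_distances(), 6)
        expected = {round(2 * radius[0] * math.sin(k * math.pi / 7), 6)
                    for k in (1, 2, 3)}
        assert set(dists) == expected
        adjacent = np.linalg.norm(heptamer.labels[1] - heptamer.labels[0])
        assert adjacent == pytest.approx(3.5, abs=1e-9)

    def test_heptamer_three_distinct_distances(self, heptamer):
        assert len(set(np.round(heptamer.pairwise_distances(), 9))) == 3

    def test_degenerate_heptamer_collapses(self):
        m = simkit.build_heptamer_model(0.0)
        assert np.allclose(m.pairwise_distances(), 0.0)

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            simkit.build_heptamer_model(-1.0)

    def test_nanoruler_separation(self):
        m = simkit.build_nanoruler_model(30.0)
        assert m.pairwise_distances()[0] == pytest.approx(30.0)

    def test_point_model_text_roundtrip(self, tmp_path, heptamer):
        path = tmp_path / "model.txt"
        np.savetxt(path, heptamer.labels)
        loaded = simkit.load_point_model(path)
        assert np.allclose(loaded.labels, heptamer.labels)


class TestOrientations:
    def test_rotation_is_special_orthogonal(self, rng):
        for _ in range(20):
            R = simkit.sample_orientation(rng)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_same_matrix(self):
        a = simkit.sample_orientation(np.random.default_rng(3))
        b = simkit.sample_orientation(np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_tilt_cosine_uniform(self):
        # cosine of the model-plane tilt must be uniform on [-1, 1]
        rng = np.random.default_rng(0)
        n = 20000
        cosines = np.empty(n)
        for i in range(n):
            cosines[i] = simkit.sample_orientation(rng)[2, 2]
        assert abs(cosines.mean()) < 0.02
        assert stats.kstest(cosines, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_spherical_cap_counts(self):
        # rotated unit vectors: cap occupancy within 3 sigma of expectation
        rng = np.random.default_rng(1)
        n = 5000
        z = np.array([simkit.sample_orientation(rng) @ np.array([0, 0, 1.0])
                      for _ in range(n)])[:, 2]
        for cap in (0.5, 0.0, -0.5):
            p = (1 - cap) / 2            # P(z > cap)
            count = (z > cap).sum()
            sd = math.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sd

    def test_membrane_orientation_low_tilt(self, rng):
        from spcold.reconstruct3d import tilt_angle_deg
        tilts = [tilt_angle_deg(simkit.sample_membrane_orientation(rng, 10))
                 for _ in range(300)]
        assert np.median(tilts) < 15.0


class TestBlinking:
    def test_off_on_ratio_of_preset(self, preset_8k, rng):
        ons, offs = [], []
        for _ in range(300):
            tr = simkit.simulate_blinking(preset_8k, 600.0, 0.014, rng)
            ons.append(tr.on_dwells())
            offs.append(tr.off_dwells())
        ratio = np.median(np.concatenate(offs)) / np.median(
            np.concatenate(ons))
        # raw continuous dwells: long off dwells are right-censored by the
        # finite trace, biasing the off median slightly low
        assert ratio == pytest.approx(30.0, rel=0.15)

    def test_on_dwell_power_law_ks(self, preset_8k):
        rng = np.random.default_rng(2)
        ons = []
        while sum(len(o) for o in ons) < 10000:
            ons.append(simkit.simulate_blinking(
                preset_8k, 600.0, 0.014, rng).on_dwells())
        x = np.concatenate(ons)[:10000]
        alpha, xmin = preset_8k.on_exponent, preset_8k.on_xmin_s
        # drop dwells truncated by the trace end (right boundary)
        x = x[x > xmin]
        cdf = lambda t: 1.0 - (xmin / t) ** (alpha - 1.0)
        assert stats.kstest(x, cdf).pvalue > 0.01

    def test_no_bleach_means_full_survival(self, rng):
        preset = simkit.PhotoPreset("nb", 0.1, 3.0, 2.95,
                                    bleach_survival_10min=1.0,
                                    off_rate_ratios=(10.0, 1.0),
                                    off_weights=(0.5, 0.5))
        traces = [simkit.simulate_blinking(preset, 300.0, 0.014, rng)
                  for _ in range(50)]
        assert all(t.survived for t in traces)

    def test_equal_medians_give_unit_ratio(self, rng):
        preset = simkit.PhotoPreset("eq", 0.5, 0.5, 2.5, off_exponent=2.5)
        ons, offs = [], []
        for _ in range(400):
            tr = simkit.simulate_blinking(preset, 200.0, 0.014, rng)
            ons.append(tr.on_dwells())
            offs.append(tr.off_dwells())
        ratio = np.median(np.concatenate(offs)) / np.median(
            np.concatenate(ons))
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_zero_duration_rejected(self, preset_8k, rng):
        with pytest.raises(ValueError):
            simkit.simulate_blinking(preset_8k, 0.0, 0.014, rng)

    def test_frame_on_fraction_partial_frames(self):
        tr = simkit.StateTrace(np.array([[0.007, 0.021]]), 0.056)
        frac = tr.frame_on_fraction(0.014, 4)
        assert np.allclose(frac, [0.5, 0.5, 0.0, 0.0])


class TestRendering:
    @staticmethod
    def _static_scene(theta_deg, duration=10.0):
        model = simkit.build_nanoruler_model(0.0).subset([0])
        trace = simkit.StateTrace(np.array([[0.0, duration]]), duration)
        return simkit.SceneInstance(model, np.eye(3),
                                    np.array([800.0, 800.0]),
                                    np.array([float(theta_deg)]),
                                    np.array([1.0]), [trace])

    def test_photon_conservation_across_channels(self):
        # expected Ix + Iy equals the unsplit photon budget for any theta
        optics = simkit.OpticsConfig(background_rate=0.0)
        for theta in (0.0, 30.0, 45.0, 60.0, 90.0):
            pair = simkit.render_stack([self._static_scene(theta)], optics,
                                       5, (16, 16), noise=False)
            total = pair.stack_x[0].sum() + pair.stack_y[0].sum()
            assert total == pytest.approx(5000 * 0.014, rel=1e-3)

    def test_45_degrees_splits_equally(self):
        optics = simkit.OpticsConfig(background_rate=0.0)
        pair = simkit.render_stack([self._static_scene(45.0)], optics,
                                   1, (16, 16), noise=False)
        assert pair.stack_x.sum() == pytest.approx(pair.stack_y.sum(),
                                                   rel=1e-6)

    def test_0_degrees_all_in_channel_x(self):
        optics = simkit.OpticsConfig(background_rate=0.0)
        pair = simkit.render_stack([self._static_scene(0.0)], optics,
                                   1, (16, 16), noise=False)
        assert pair.stack_y.sum() == pytest.approx(0.0, abs=1e-9)
        assert pair.stack_x.sum() > 0

    def test_noisy_mean_converges_to_expectation(self, rng):
        optics = simkit.OpticsConfig(background_rate=2.0)
        scene = self._static_scene(30.0, duration=200.0)
        clean = simkit.render_stack([scene], optics, 1, (16, 16),
                                    noise=False)
        noisy = simkit.render_stack([scene], optics, 5000, (16, 16), rng)
        assert noisy.stack_x.mean(0).sum() == pytest.approx(
            clean.stack_x[0].sum(), rel=0.01)

    def test_out_of_field_emitter_warns_and_clips(self):
        optics = simkit.OpticsConfig()
        scene = self._static_scene(45.0)
        scene.position_nm = np.array([-500.0, 800.0])
        with pytest.warns(UserWarning):
            pair = simkit.render_stack([scene], optics, 1, (16, 16),
                                       noise=False)
        assert pair.stack_x.sum() == pytest.approx(
            16 * 16 * optics.background_rate)
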