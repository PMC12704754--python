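"""Projected-distance model, labeling combinatorics, max-side statistic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spcold import projgeom, simkit


class TestProjectedDistancePdf:
    def test_normalization_and_divergence(self):
        m = projgeom.projected_distance_pdf(30.0, 0.0)
        r = np.linspace(0, 30, 200001)[1:-1]
        assert np.trapezoid(m.pdf(r), r) == pytest.approx(1.0, abs=5e-3)
        # integrable divergence toward r = d
        assert m.pdf(29.99)[0] > m.pdf(15.0)[0] > m.pdf(1.0)[0]

    def test_noisy_density_normalized(self):
        m = projgeom.projected_distance_pdf(30.0, 1.0)
        r = np.linspace(-5, 45, 5001)
        assert np.trapezoid(m.pdf(r), r) == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo(self):
        # closed form vs the empirical distribution of projected segments
        rng = np.random.default_rng(3)
        seg = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        lengths = np.array([projgeom.project_segment_lengths(
            seg, simkit.sample_orientation(rng))[0] for _ in range(30000)])
        cdf = lambda r: 1 - np.sqrt(1 - (np.clip(r, 0, 30) / 30) ** 2)
        assert stats.kstest(lengths, cdf).pvalue > 0.01

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            projgeom.projected_distance_pdf(0.0)

    def test_small_d_approaches_half_gaussian(self):
        m = projgeom.projected_distance_pdf(1e-4, 1.0)
        half = 2 * stats.norm(0, 1.0).pdf([0.5, 1.0, 2.0])
        assert np.allclose(m.pdf([0.5, 1.0, 2.0]), half, rtol=1e-3)


class TestFitProjectionDistance:
    @staticmethod
    def _noisy_projections(d, sigma, n, rng):
        seg = np.array([[0.0, 0, 0], [d, 0, 0]])
        out = np.empty(n)
        for i in range(n):
            R = simkit.sample_orientation(rng)
            p = (R @ seg.T).T[:, :2] + rng.normal(0, sigma, (2, 2))
            out[i] = np.linalg.norm(p[0] - p[1])
        return out

    def test_nanoruler_recovery_53_samples(self):
        rng = np.random.default_rng(17)
        fits = [projgeom.fit_projection_distance(
            self._noisy_projections(30.0, 0.7, 53, rng)).d_nm
            for _ in range(5)]
        assert abs(np.median(fits) - 30.0) < 1.0

    def test_noiseless_degenerate_samples(self):
        fit = projgeom.fit_projection_distance(
            np.full(50, 12.0), sigma_nm=0.05)
        assert fit.d_nm == pytest.approx(12.0, abs=0.2)

    def test_large_n_consistency(self):
        rng = np.random.default_rng(23)
        samples = self._noisy_projections(20.0, 0.5, 2500, rng)
        fit = projgeom.fit_projection_distance(samples)
        # small residual bias: the model smears the distance with a
        # Gaussian while the generator perturbs the two endpoints
        assert fit.d_nm == pytest.approx(20.0, abs=0.15)
        assert fit.d_ci_nm[0] < fit.d_nm < fit.d_ci_nm[1]
        assert fit.d_ci_nm[1] - fit.d_ci_nm[0] < 0.5

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        samples = self._noisy_projections(10.0, 0.3, 200, rng)
        a = projgeom.fit_projection_distance(samples)
        b = projgeom.fit_projection_distance(samples * 3.0)
        assert b.d_nm == pytest.approx(3.0 * a.d_nm, rel=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            projgeom.fit_projection_distance(np.ones(5))


class TestLabelingClasses:
    def test_three_of_seven(self):
        classes = projgeom.enumerate_labeling_classes(7, 3)
        assert len(classes) == 4
        assert sorted(c.gap_multiset for c in classes) == [
            (1, 1, 5), (1, 2, 4), (1, 3, 3), (2, 2, 3)]
        assert sum(c.multiplicity for c in classes) == math.comb(7, 3)

    def test_full_labeling_single_class(self):
        classes = projgeom.enumerate_labeling_classes(7, 7)
        assert len(classes) == 1
        assert classes[0].multiplicity == 1

    def test_side_lengths_of_heptamer_classes(self, heptamer):
        # chord set {3.50, 6.31, 7.86} at 3.5 nm nearest-neighbour spacing
        classes = projgeom.enumerate_labeling_classes(7, 3)
        chords = np.unique(np.round(heptamer.pairwise_distances(), 2))
        for c in classes:
            assert np.all(np.isin(np.round(c.side_lengths_nm(3.5), 2),
                                  chords))

    @pytest.mark.parametrize("n,k", [(5, 2), (6, 3), (8, 3), (9, 4)])
    def test_orbit_counts_match_brute_force(self, n, k):
        # independent orbit count via explicit dihedral group action
        group = []
        for r in range(n):
            group.append(lambda i, r=r: (i + r) % n)
            group.append(lambda i, r=r: (r - i) % n)
        subsets = {frozenset(c)
                   for c in itertools.combinations(range(n), k)}
        seen, orbits = set(), 0
        for s in subsets:
            if s in seen:
                continue
            orbits += 1
            for g in group:
                seen.add(frozenset(g(i) for i in s))
        assert len(projgeom.enumerate_labeling_classes(n, k)) == orbits

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            projgeom.enumerate_labeling_classes(7, 0)
        with pytest.raises(ValueError):
            projgeom.enumerate_labeling_classes(7, 8)


class TestMaxProjectedSide:
    def test_projection_never_exceeds_true_length(self, rng):
        samples = projgeom.max_projected_side([3.5, 6.31, 7.86], 2000, rng)
        assert np.all(samples <= 7.86 + 1e-9)

    def test_equilateral_lower_bound_vs_grid_oracle(self, rng):
        # brute-force orientation grid: the max projected side of an
        # equilateral triangle never falls below (sqrt(3)/2) d
        d = 3.5
        tri = projgeom.triangle_from_sides([d, d, d])
        grid_min = np.inf
        for a in np.linspace(0, np.pi, 60):
            for b in np.linspace(0, np.pi, 60):
                ca, sa = np.cos(a), np.sin(a)
                cb, sb = np.cos(b), np.sin(b)
                R = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]]) @ \
                    np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                grid_min = min(grid_min,
                               projgeom.project_segment_lengths(tri, R).max())
        bound = math.sqrt(3.0) / 2.0 * d
        assert grid_min == pytest.approx(bound, rel=1e-3)
        samples = projgeom.max_projected_side([d, d, d], 3000, rng)
        assert samples.min() >= bound - 1e-9

    def test_in_plane_orientation_gives_true_max(self):
        sides = [3.5, 6.31, 7.86]
        tri = projgeom.triangle_from_sides(sides)
        lengths = projgeom.project_segment_lengths(tri, np.eye(3))
        assert lengths.max() == pytest.approx(max(sides), rel=1e-9)

    def test_distribution_peaks_near_largest_side(self, rng):
        classes = projgeom.enumerate_labeling_classes(7, 3)
        scalene = next(c for c in classes if c.gap_multiset == (1, 2, 4))
        samples = projgeom.max_projected_side(
            scalene.side_lengths_nm(3.5), 20000, rng)
        mode = projgeom.kde_mode(samples, bandwidth_nm=0.5)
        assert mode == pytest.approx(7.86, abs=0.5)

    def test_degenerate_triangle_warns(self, rng):
        with pytest.warns(UserWarning):
            projgeom.max_projected_side([0.0, 5.0, 5.0], 10, rng)

    def test_impossible_triangle_rejected(self, rng):
        with pytest.raises(ValueError):
            projgeom.max_projected_side([1.0, 1.0, 5.0], 10, rng)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(a=st.floats(1.0, 10.0), b=st.floats(1.0, 10.0),
           c=st.floats(1.0, 10.0), seed=st.integers(0, 2 ** 16))
    def test_projection_bound_for_arbitrary_triangles(self, a, b, c, seed):
        sides = sorted([a, b, c])
        if sides[0] + sides[1] <= sides[2] + 1e-6:
            return          # not a triangle
        rng = np.random.default_rng(seed)
        samples = projgeom.max_projected_side(sides, 50, rng)
        assert np.all(samples <= sides[2] + 1e-9)


class TestHistograms:
    def test_in_plane_triangle_three_bins(self):
        pts = projgeom.triangle_from_sides([3.0, 4.0, 5.0])[:, :2]
        counts, edges, pooled = projgeom.pairwise_distance_histogram(
            [pts], bin_nm=0.5)
        assert counts.sum() == 3
        assert sorted(np.round(pooled, 6)) == [3.0, 4.0, 5.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            projgeom.pairwise_distance_histogram([])

    def test_kde_mode_of_projected_ruler(self):
        rng = np.random.default_rng(31)
        seg = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        lengths = [projgeom.project_segment_lengths(
            seg, simkit.sample_orientation(rng))[0] for _ in range(20000)]
        noisy = np.asarray(lengths) + rng.normal(0, 0.7, 20000)
        mode = projgeom.kde_mode(noisy, bandwidth_nm=0.5)
        assert mode == pytest.approx(30.0, abs=1.0)
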