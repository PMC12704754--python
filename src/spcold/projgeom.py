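"""Projection-geometry statistics of rigid particles at random orientations.

A particle frozen at a uniform random 3D orientation is observed only as a
2D projection, so every measured pairwise distance is shortened relative to
its true 3D value.  For a segment of true length d the projected length r
has density f(r) = r / (d sqrt(d^2 - r^2)) on (0, d): a left tail with an
integrable peak at r = d.  This module provides that density (optionally
smeared by Gaussian localization noise), its maximum-likelihood inversion
to recover d from a handful of projections, the combinatorics of partial
labeling on a symmetric ring, and the per-particle maximum projected side
statistic that makes the longest true side dominate a histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gaussian_kde

from .simkit import sample_orientation

__all__ = [
    "ProjectionModel",
    "LabelClass",
    "projected_distance_pdf",
    "fit_projection_distance",
    "ProjectionFit",
    "enumerate_labeling_classes",
    "triangle_from_sides",
    "max_projected_side",
    "project_segment_lengths",
    "pairwise_distance_histogram",
    "kde_mode",
]


# --------------------------------------------------------------------------
# projected-distance density

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)


@dataclass(frozen=True)
class ProjectionModel:
    """Density of the 2D-projected distance for true separation d (nm)."""

    d_nm: float
    sigma_nm: float

    def __post_init__(self):
        if self.d_nm <= 0:
            raise ValueError("true separation must be positive")
        if self.sigma_nm < 0:
            raise ValueError("noise SD must be non-negative")

    def pdf(self, r) -> np.ndarray:
        r = np.atleast_1d(np.asarray(r, float))
        d, s = self.d_nm, self.sigma_nm
        if s == 0:
            out = np.zeros_like(r)
            ok = (r > 0) & (r < d)
            out[ok] = r[ok] / (d * np.sqrt(d * d - r[ok] ** 2))
            return out
        # substitute the projected length as r0 = d sin(u):
        # f(r) = int_0^{pi/2} sin(u) * phi_folded(r - d sin u; sigma) du,
        # with the Gaussian folded at r = 0 so distances stay non-negative
        # and the density integrates to 1 (half-Gaussian limit as d -> 0)
        u = 0.25 * math.pi * (_GL_NODES + 1.0)
        w = 0.25 * math.pi * _GL_WEIGHTS
        r0 = d * np.sin(u)
        zm = (r[:, None] - r0[None, :]) / s
        zp = (r[:, None] + r0[None, :]) / s
        norm = s * math.sqrt(2.0 * math.pi)
        phi = (np.exp(-0.5 * zm * zm) + np.exp(-0.5 * zp * zp)) / norm
        out = phi @ (w * np.sin(u))
        out[r < 0] = 0.0
        return out

    def logpdf(self, r) -> np.ndarray:
        return np.log(np.maximum(self.pdf(r), 1e-300))


def projected_distance_pdf(d_nm: float, sigma_nm: float = 0.0
                           ) -> ProjectionModel:
    """Projected-distance model for true 3D separation ``d_nm``.

    At sigma = 0 this is the closed form r / (d sqrt(d^2 - r^2)); for
    sigma > 0 it is numerically convolved with a Gaussian of SD sigma.
    """
    return ProjectionModel(d_nm, sigma_nm)


@dataclass(frozen=True)
class ProjectionFit:
    d_nm: float
    sigma_nm: float
    loglik: float
    d_ci_nm: tuple[float, float]
    converged: bool


def fit_projection_distance(samples, sigma_nm: float | None = None,
                            ci_level: float = 0.95) -> ProjectionFit:
    """Maximum-likelihood (d, sigma) fit of the projection-distance model.

    ``sigma_nm`` fixes the noise SD; if None it is fitted jointly.  The
    confidence interval for d is a profile-likelihood interval at
    ``ci_level`` (chi-square with one degree of freedom).
    """
    x = np.asarray(samples, float).reshape(-1)
    if x.size < 10:
        raise ValueError("need at least 10 projected distances")
    if np.any(x < 0):
        raise ValueError("projected distances must be non-negative")

    fit_sigma = sigma_nm is None

    def nll(params):
        d = params[0]
        s = params[1] if fit_sigma else sigma_nm
        if d <= 0 or s < 0:
            return 1e12
        return -float(np.sum(ProjectionModel(d, max(s, 1e-6)).logpdf(x)))

    d0 = float(np.quantile(x, 0.95))
    s0 = 0.05 * d0 if fit_sigma else sigma_nm
    x0 = [d0, s0] if fit_sigma else [d0]
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000})
    d_hat = float(res.x[0])
    s_hat = float(res.x[1]) if fit_sigma else float(sigma_nm)
    ll = -float(res.fun)

    # profile-likelihood CI for d
    from scipy.stats import chi2
    cut = 0.5 * chi2.ppf(ci_level, 1)

    def profile_nll(d):
        if not fit_sigma:
            return nll([d])
        r = minimize(lambda s: nll([d, s[0]]), [max(s_hat, 1e-3)],
                     method="Nelder-Mead",
                     options={"xatol": 1e-4, "fatol": 1e-7})
        return float(r.fun)

    def bound(direction):
        step = 0.02 * d_hat + 1e-3
        d = d_hat
        for _ in range(200):
            d_next = d + direction * step
            if d_next <= 0:
                return max(d_next + direction * step, 0.0)
            if profile_nll(d_next) - (-ll) > cut:
                # bisect between d and d_next
                lo, hi = (d, d_next) if direction > 0 else (d_next, d)
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    if (profile_nll(mid) - (-ll) > cut) == (direction > 0):
                        hi = mid
                    else:
                        lo = mid
                return 0.5 * (lo + hi)
            d = d_next
        return d

    ci = (bound(-1.0), bound(+1.0))
    return ProjectionFit(d_hat, s_hat, ll, ci, bool(res.success))


# --------------------------------------------------------------------------
# labeling combinatorics


@dataclass(frozen=True)
class LabelClass:
    """One equivalence class of label placements on an n-ring."""

    class_id: int
    n_subunits: int
    gap_multiset: tuple[int, ...]       # sorted circular gaps, sum = n
    side_steps: tuple[int, ...]         # sorted circular pair separations
    multiplicity: int                   # number of labelings in the orbit
    representative: tuple[int, ...]     # one member subset

    def side_lengths_nm(self, nn_distance_nm: float = 3.5) -> np.ndarray:
        """Chord lengths d_k = 2 R sin(k pi / n) for each pair step k."""
        n = self.n_subunits
        radius = nn_distance_nm / (2.0 * math.sin(math.pi / n))
        return np.array([2.0 * radius * math.sin(k * math.pi / n)
                         for k in self.side_steps])


def _canonical(subset: tuple[int, ...], n: int) -> tuple[int, ...]:
    best = None
    for refl in (False, True):
        base = tuple((-i) % n for i in subset) if refl else subset
        for r in range(n):
            cand = tuple(sorted((i + r) % n for i in base))
            if best is None or cand < best:
                best = cand
    return best


def enumerate_labeling_classes(n_subunits: int,
                               n_labels: int) -> list[LabelClass]:
    """Brute-force orbit enumeration of label subsets under the dihedral
    group of the n-gon.  Multiplicities sum to C(n_subunits, n_labels)."""
    n, k = n_subunits, n_labels
    if not (1 <= k <= n):
        raise ValueError("need 1 <= n_labels <= n_subunits")
    orbits: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for subset in combinations(range(n), k):
        orbits.setdefault(_canonical(subset, n), []).append(subset)
    classes = []
    for cid, (rep, members) in enumerate(sorted(orbits.items())):
        verts = sorted(rep)
        gaps = tuple(sorted((verts[(i + 1) % k] - verts[i]) % n
                            for i in range(k)))
        steps = tuple(sorted(min((b - a) % n, (a - b) % n)
                             for a, b in combinations(verts, 2)))
        classes.append(LabelClass(cid, n, gaps, steps, len(members), rep))
    return classes


# --------------------------------------------------------------------------
# projected sides


def triangle_from_sides(sides_nm: Sequence[float]) -> np.ndarray:
    """3D coordinates of a triangle with the given side lengths (z = 0)."""
    a, b, c = sorted(float(s) for s in sides_nm)   # a <= b <= c
    if a + b < c - 1e-12:
        raise ValueError("side lengths violate the triangle inequality")
    if a <= 1e-12:
        warnings.warn("degenerate triangle (zero side)")
    # place the longest side on x; third vertex from the law of cosines
    x = (c * c + b * b - a * a) / (2.0 * c) if c > 0 else 0.0
    y2 = max(b * b - x * x, 0.0)
    return np.array([[0.0, 0.0, 0.0],
                     [c, 0.0, 0.0],
                     [x, math.sqrt(y2), 0.0]])


def project_segment_lengths(points_3d: np.ndarray, rotation: np.ndarray
                            ) -> np.ndarray:
    """All pairwise distances of the rotated points after projection."""
    p = (rotation @ np.asarray(points_3d, float).T).T[:, :2]
    iu = np.triu_indices(p.shape[0], 1)
    diff = p[iu[0]] - p[iu[1]]
    return np.sqrt((diff ** 2).sum(1))


def max_projected_side(triangle_sides_nm: Sequence[float], n_samples: int,
                       rng: np.random.Generator,
                       sigma_nm: float = 0.0) -> np.ndarray:
    """Monte-Carlo distribution of the per-particle maximum projected side.

    Samples uniform SO(3) orientations of the triangle, projects, and
    returns the maximum of the three projected side lengths per sample
    (optionally with Gaussian localization noise of SD ``sigma_nm`` added
    to each projected vertex).
    """
    tri = triangle_from_sides(triangle_sides_nm)
    out = np.empty(n_samples)
    for i in range(n_samples):
        R = sample_orientation(rng)
        p = (R @ tri.T).T[:, :2]
        if sigma_nm > 0:
            p = p + rng.normal(0.0, sigma_nm, size=p.shape)
        d01 = np.linalg.norm(p[0] - p[1])
        d02 = np.linalg.norm(p[0] - p[2])
        d12 = np.linalg.norm(p[1] - p[2])
        out[i] = max(d01, d02, d12)
    return out


def pairwise_distance_histogram(particles, bin_nm: float = 0.5
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled pairwise-distance histogram over particles.

    ``particles`` is a sequence of (n_i, 2) position arrays (or objects
    with a ``positions_nm`` attribute).  Returns (counts, bin_edges,
    pooled_distances).
    """
    if len(particles) == 0:
        raise ValueError("no particles given")
    dists = []
    for p in particles:
        pts = np.asarray(getattr(p, "positions_nm", p), float)
        iu = np.triu_indices(pts.shape[0], 1)
        diff = pts[iu[0]] - pts[iu[1]]
        dists.append(np.sqrt((diff ** 2).sum(1)))
    pooled = np.concatenate(dists)
    edges = np.arange(0.0, pooled.max() + 2 * bin_nm, bin_nm)
    counts, edges = np.histogram(pooled, bins=edges)
    return counts, edges, pooled


def kde_mode(samples, bandwidth_nm: float = 0.5,
             grid_step_nm: float = 0.01) -> float:
    """Mode of a sample set located by a Gaussian kernel density estimate.

    The bandwidth is absolute (nm), matching the histogram bin width, so
    the mode is not pulled around by Scott-rule rescaling.
    """
    x = np.asarray(samples, float)
    kde = gaussian_kde(x, bw_method=bandwidth_nm / x.std(ddof=1))
    grid = np.arange(x.min(), x.max() + grid_step_nm, grid_step_nm)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])
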