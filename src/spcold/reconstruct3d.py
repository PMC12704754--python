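"""Class matching, orientation estimation, and 3D reconstruction from 2D
projections.

A 2D-resolved particle is a handful of fluorophore positions — one noisy
projection of a rigid 3D arrangement at an unknown orientation.  Following
the single-particle averaging idea, particles are first assigned to
labeling classes by a supervised match against model projections; the
orientation of each particle is then estimated by simulated annealing over
SO(3); and the 3D fluorophore positions of each class are reconstructed by
alternating orientation refinement with a linear least-squares update of
Gaussian-blob centers, starting from an isotropic 3D Gaussian cloud with
no symmetry imposed.  Class reconstructions are merged by rigid-body
fitting into a common accessible-volume model, and resolution is assessed
by Fourier shell correlation against the half-bit information threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .simkit import PointModel

__all__ = [
    "ClassTemplate",
    "MatchResult",
    "OrientationEstimate",
    "Reconstruction3D",
    "FSCCurve",
    "fibonacci_directions",
    "build_class_templates",
    "match_score",
    "classify_particles",
    "estimate_orientation",
    "reconstruct_class",
    "reconstruct_class_consensus",
    "merge_class_reconstructions",
    "volume_from_blobs",
    "fsc",
    "half_bit_threshold",
    "align_point_sets_3d",
]


# --------------------------------------------------------------------------
# geometry helpers


def _center(pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, float)
    return pts - pts.mean(0)


def _project(rotation: np.ndarray, pts3d: np.ndarray) -> np.ndarray:
    return (rotation @ pts3d.T).T[:, :2]


def _corresponded_rmsd2(proj: np.ndarray, target: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Mean squared distance under optimal correspondence (both centered)."""
    d2 = ((proj[:, None, :] - target[None, :, :]) ** 2).sum(-1)
    rows, cols = linear_sum_assignment(d2)
    return float(d2[rows, cols].mean()), cols


def _kabsch_2d(P: np.ndarray, Q: np.ndarray, allow_reflection: bool = True
               ) -> float:
    """Minimal RMSD of corresponded centered 2D sets over rotation
    (and reflection if allowed)."""
    H = P.T @ Q
    # closed form: best proper rotation RMSD via SVD
    U, S, Vt = np.linalg.svd(H)
    n = P.shape[0]
    normsq = (P ** 2).sum() + (Q ** 2).sum()
    d = np.sign(np.linalg.det(U @ Vt))
    rot = normsq - 2.0 * (S[0] + d * S[1])
    best = rot
    if allow_reflection:
        refl = normsq - 2.0 * (S[0] + S[1])
        best = min(rot, refl)
    return math.sqrt(max(best, 0.0) / n)


def align_point_sets_3d(P: np.ndarray, Q: np.ndarray,
                        allow_reflection: bool = True
                        ) -> tuple[float, np.ndarray, np.ndarray]:
    """Best rigid alignment of corresponded 3D sets P -> Q.

    Returns (rmsd, R, t) with R possibly improper if reflection allowed.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if not allow_reflection and np.linalg.det(R) < 0:
        Vt2 = Vt.copy()
        Vt2[-1] *= -1
        R = Vt2.T @ U.T
    t = qc - R @ pc
    resid = (R @ P.T).T + t - Q
    return float(np.sqrt((resid ** 2).sum(1).mean())), R, t


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector v onto +z."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * math.acos(c)).as_matrix()


# --------------------------------------------------------------------------
# templates and matching


@dataclass
class ClassTemplate:
    class_id: int
    model_points_3d_nm: np.ndarray          # (k, 3)
    projection_bank: list                   # list of centered (k, 2) arrays
    bank_rotations: list                    # matching 3x3 rotations


def build_class_templates(model: PointModel,
                          classes: Sequence[Sequence[int]],
                          n_orientations: int = 300,
                          max_tilt_deg: float = 90.0) -> list[ClassTemplate]:
    """Projection bank of each labeling class over an orientation grid.

    ``classes`` lists the label-site indices of each class (e.g. the
    representative subsets from the labeling-class enumeration).  Viewing
    directions cover the sphere on a Fibonacci grid; the in-plane rotation
    is handled at match time, so the bank only needs the tilt coverage.

    ``max_tilt_deg`` restricts the bank to viewing directions within that
    tilt of the model normal.  A strongly tilted large triangle projects
    onto the same 2D shape as a flatter small one, so under a full-sphere
    bank the classes are not mutually identifiable; a membrane-embedded
    sample justifies a tilt-limited bank.
    """
    if n_orientations < 1:
        raise ValueError("orientation grid must not be empty")
    dirs = fibonacci_directions(n_orientations)
    if max_tilt_deg < 90.0:
        cos_min = math.cos(math.radians(max_tilt_deg))
        keep = np.abs(dirs[:, 2]) >= cos_min
        dirs = dirs[keep]
        if dirs.shape[0] == 0:
            raise ValueError("tilt limit removed every grid orientation")
    templates = []
    for cid, subset in enumerate(classes):
        pts = model.labels[np.asarray(subset, int)]
        bank, rots = [], []
        for v in dirs:
            R = _rotation_to_z(v)
            bank.append(_center(_project(R, pts)))
            rots.append(R)
        templates.append(ClassTemplate(cid, pts, bank, rots))
    return templates


def _best_rmsd_to_template(points_2d: np.ndarray, tpl: np.ndarray,
                           allow_reflection: bool = True) -> float:
    """Min RMSD over correspondence and in-plane rotation/reflection."""
    P = _center(points_2d)
    Q = _center(tpl)
    n = P.shape[0]
    if n != Q.shape[0]:
        return math.inf
    if n <= 4:
        best = math.inf
        for perm in itertools.permutations(range(n)):
            r = _kabsch_2d(P[list(perm)], Q, allow_reflection)
            best = min(best, r)
        return best
    # ICP: several in-plane starting angles (and reflection), Hungarian
    best = math.inf
    for refl in (False, True):
        P0 = P * np.array([1.0, -1.0]) if refl else P
        for ang in np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False):
            c, s = math.cos(ang), math.sin(ang)
            Pr = P0 @ np.array([[c, -s], [s, c]]).T
            for _ in range(6):
                d2 = ((Pr[:, None] - Q[None, :]) ** 2).sum(-1)
                rows, cols = linear_sum_assignment(d2)
                r = _kabsch_2d(P0[rows], Q[cols], allow_reflection=False)
                # re-rotate P0 onto Q with the new correspondence
                H = P0[rows].T @ Q[cols]
                U, S, Vt = np.linalg.svd(H)
                Rm = Vt.T @ U.T
                if np.linalg.det(Rm) < 0:
                    Vt2 = Vt.copy()
                    Vt2[-1] *= -1
                    Rm = Vt2.T @ U.T
                Pr = P0 @ Rm.T
                best = min(best, r)
    return best


def _match_detail(pts: np.ndarray, template: ClassTemplate,
                  sigma_score_nm: float,
                  tilt_prior_sd_deg: float | None
                  ) -> tuple[float, float, int]:
    """(geometric score, posterior, best bank index) for one class."""
    best_rmsd, best_post, best_idx = math.inf, 0.0, -1
    for i, tpl in enumerate(template.projection_bank):
        if tpl.shape[0] != pts.shape[0]:
            return 0.0, 0.0, -1
        r = _best_rmsd_to_template(pts, tpl)
        lik = math.exp(-r ** 2 / (2.0 * sigma_score_nm ** 2))
        if tilt_prior_sd_deg is not None:
            tilt = tilt_angle_deg(template.bank_rotations[i])
            lik *= math.exp(-0.5 * (tilt / tilt_prior_sd_deg) ** 2)
        if lik > best_post:
            best_post, best_idx = lik, i
        best_rmsd = min(best_rmsd, r)
    score = math.exp(-best_rmsd ** 2 / (2.0 * sigma_score_nm ** 2))
    return score, best_post, best_idx


def match_score(particle, template: ClassTemplate,
                sigma_score_nm: float) -> float:
    """Supervised matching score in [0, 1].

    score = exp(-RMSD_best^2 / (2 sigma_score^2)), with the RMSD minimized
    over the template orientation bank, in-plane rotation, reflection, and
    point correspondence (Hungarian / exhaustive for small sets).
    Returns 0 for a point-count mismatch.
    """
    pts = np.asarray(getattr(particle, "positions_nm", particle), float)
    score, _, _ = _match_detail(pts, template, sigma_score_nm, None)
    return score


@dataclass
class MatchResult:
    particle_id: int
    scores: np.ndarray
    assigned_class: int | None
    best_orientation: np.ndarray | None = None
    tie: bool = False


def classify_particles(particles, templates: Sequence[ClassTemplate],
                       sigma_score_nm: float, threshold: float = 0.8,
                       tilt_prior_sd_deg: float | None = 15.0,
                       tie_tol: float = 1e-6) -> list[MatchResult]:
    """Class assignment with a 0-1 geometric acceptance score.

    Classes are ranked by the maximum-a-posteriori orientation match: the
    geometric likelihood exp(-RMSD^2 / 2 sigma^2) times a Gaussian prior
    on the out-of-plane tilt (``tilt_prior_sd_deg``; pass None for a
    uniform orientation prior).  The tilt prior resolves the geometric
    ambiguity of a large tilted triangle versus a flatter small one for
    membrane-embedded particles, where large tilts are not favored.  A
    particle is assigned to the top-ranked class only if its geometric
    score exceeds ``threshold``; exact ties stay unassigned, flagged.
    """
    results = []
    for pid, particle in enumerate(particles):
        pts = np.asarray(getattr(particle, "positions_nm", particle), float)
        detail = [_match_detail(pts, t, sigma_score_nm, tilt_prior_sd_deg)
                  for t in templates]
        scores = np.array([d[0] for d in detail])
        post = np.array([d[1] for d in detail])
        order = np.argsort(-post)
        best_post = post[order[0]]
        tie = (len(post) > 1
               and best_post - post[order[1]]
               <= tie_tol * max(best_post, 1e-12))
        assigned = None
        orientation = None
        if scores[order[0]] > threshold and not tie:
            assigned = int(order[0])
            idx = detail[assigned][2]
            if idx >= 0:
                orientation = templates[assigned].bank_rotations[idx]
        results.append(MatchResult(pid, scores, assigned, orientation, tie))
    return results


# --------------------------------------------------------------------------
# orientation estimation (simulated annealing)


@dataclass
class OrientationEstimate:
    rotation: np.ndarray
    tilt_deg: float
    in_plane_deg: float
    rmsd_nm: float
    converged: bool


def _sa_cost(R: np.ndarray, model_pts: np.ndarray,
             target_centered: np.ndarray) -> float:
    proj = _center(_project(R, model_pts))
    cost, _ = _corresponded_rmsd2(proj, target_centered)
    return cost


def _anneal_rotation(model_pts: np.ndarray, target_centered: np.ndarray,
                     rng: np.random.Generator, n_steps: int = 1500,
                     t_start_deg: float = 60.0, t_end_deg: float = 2.0,
                     R0: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """One annealing run: exponential cooling of the proposal/acceptance
    temperature; returns the best rotation and its mean-squared cost."""
    R = Rotation.random(rng=rng).as_matrix() if R0 is None else R0.copy()
    cost = _sa_cost(R, model_pts, target_centered)
    bestR, best = R, cost
    decay = (t_end_deg / t_start_deg) ** (1.0 / max(n_steps - 1, 1))
    T = t_start_deg
    scale = max(np.abs(target_centered).max(), 1e-6) ** 2
    for _ in range(n_steps):
        ang = math.radians(T) * abs(rng.standard_normal())
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        Rp = Rotation.from_rotvec(axis * ang).as_matrix() @ R
        cp = _sa_cost(Rp, model_pts, target_centered)
        # Metropolis acceptance on the squared-distance objective
        kT = scale * (T / t_start_deg) * 0.05
        if cp < cost or rng.random() < math.exp(-(cp - cost) / max(kT, 1e-12)):
            R, cost = Rp, cp
            if cost < best:
                bestR, best = R, cost
        T *= decay
    return bestR, best


def tilt_angle_deg(rotation: np.ndarray) -> float:
    """Out-of-plane tilt: angle between the rotated model normal (z) and
    the optical axis, folded into [0, 90]."""
    nz = abs(float(rotation[2, 2]))
    return math.degrees(math.acos(min(nz, 1.0)))


def estimate_orientation(particle, model: PointModel | np.ndarray,
                         rng: np.random.Generator | None = None,
                         n_steps: int = 1500, n_restarts: int = 4
                         ) -> OrientationEstimate:
    """Simulated-annealing orientation fit of a model to one 2D particle.

    Minimizes the corresponded RMSD between the projected, centered model
    and the particle positions over SO(3) (in-plane rotation is part of
    the rotation; reflection ambiguity corresponds to viewing from the
    far side and is therefore inside SO(3) already).  Multiple restarts,
    best kept.
    """
    rng = np.random.default_rng() if rng is None else rng
    pts = np.asarray(getattr(particle, "positions_nm", particle), float)
    if pts.shape[0] < 3:
        raise ValueError("orientation estimation needs at least 3 points")
    model_pts = model.labels if isinstance(model, PointModel) else \
        np.asarray(model, float)
    target = _center(pts)
    bestR, best = None, math.inf
    for _ in range(n_restarts):
        R, c = _anneal_rotation(model_pts, target, rng, n_steps)
        if c < best:
            bestR, best = R, c
    # deterministic polish around the annealed optimum
    from scipy.optimize import minimize

    def cost(rotvec):
        Rp = Rotation.from_rotvec(rotvec).as_matrix() @ bestR
        return _sa_cost(Rp, model_pts, target)

    res = minimize(cost, np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-12,
                            "maxiter": 400})
    if res.fun < best:
        bestR = Rotation.from_rotvec(res.x).as_matrix() @ bestR
        best = float(res.fun)
    tilt = tilt_angle_deg(bestR)
    inplane = math.degrees(math.atan2(bestR[1, 0], bestR[0, 0]))
    rmsd = math.sqrt(best)
    # converged when the residual is commensurate with the data scale
    conv = rmsd < 0.5 * np.sqrt((target ** 2).sum(1)).max() + 1e-9
    return OrientationEstimate(bestR, tilt, inplane, rmsd, conv)


# --------------------------------------------------------------------------
# class reconstruction


@dataclass
class Reconstruction3D:
    class_id: int
    blob_centers_nm: np.ndarray          # (k, 3)
    blob_sigma_nm: float
    per_particle_rotations: list
    n_particles: int
    objective_history: list = field(default_factory=list)
    degenerate: bool = False

    def principal_frame(self) -> np.ndarray:
        """Blob centers rotated into their principal-axes frame."""
        X = _center(self.blob_centers_nm)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        return X @ Vt.T

    def nearest_neighbor_distances(self) -> np.ndarray:
        X = self.blob_centers_nm
        d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return d.min(1)


def _orientation_posterior_samples(X: np.ndarray, Y_centered: np.ndarray,
                                   R0: np.ndarray, sigma_nm: float,
                                   rng: np.random.Generator,
                                   n_keep: int = 24, n_steps: int = 600,
                                   step_deg: float = 6.0,
                                   thin: int = 25) -> list:
    """Metropolis samples from the orientation posterior of one particle.

    Energy is the corresponded sum of squared residuals over 2 sigma^2, so
    the walk explores rotations compatible with the localization noise
    instead of locking onto the noise-fitting optimum.
    """
    n_pts = Y_centered.shape[0]
    R = R0.copy()
    c = _sa_cost(R, X, Y_centered)
    keep = []
    for s in range(n_steps):
        ang = math.radians(step_deg) * abs(rng.standard_normal())
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        Rp = Rotation.from_rotvec(axis * ang).as_matrix() @ R
        cp = _sa_cost(Rp, X, Y_centered)
        dE = n_pts * (cp - c) / (2.0 * sigma_nm ** 2)
        if dE < 0 or rng.random() < math.exp(-min(dE, 50.0)):
            R, c = Rp, cp
        if s % thin == thin - 1:
            keep.append(R.copy())
    return keep[-n_keep:] if keep else [R]


def reconstruct_class(particles, rng: np.random.Generator,
                      class_id: int = 0, n_blobs: int | None = None,
                      n_outer: int = 14, steps_per_sweep: int = 500,
                      n_init: int = 3, pilot_sweeps: int = 4,
                      t_start_deg: float = 60.0, t_end_deg: float = 1.5,
                      init_sd_nm: float | None = None,
                      marginal_passes: int = 2,
                      noise_sigma_nm: float | None = None,
                      scale_calibration: float | str | None = "uniform"
                      ) -> Reconstruction3D:
    """Class-wise 3D reconstruction by annealed alternating optimization.

    Starting from blob centers drawn from an isotropic 3D Gaussian (no
    symmetry imposed), orientations and blob centers co-evolve: every
    sweep runs a short simulated-annealing pass per particle (the
    proposal temperature cools from ``t_start_deg`` to ``t_end_deg``
    across the outer sweeps, so orientations stay mobile while the map is
    still crude), always keeping the better of old and new rotation, then
    updates the 3D blob centers by exact least squares given orientations
    and Hungarian correspondences, accepting the update only if the mean
    objective decreases — the recorded objective is therefore
    non-increasing.  ``n_init`` independent initializations run a
    ``pilot_sweeps``-long pilot each and the best continues.

    Point-estimate orientations systematically absorb localization noise
    and contract / thicken the structure, so two refinements follow the
    alternating loop: ``marginal_passes`` EM-style updates of the blob
    centers averaged over Metropolis samples of each particle's
    orientation posterior (noise scale ``noise_sigma_nm``; estimated from
    the residuals when None), and a global scale calibration against the
    unbiased projected-distance statistic E[r^2] = f * d^2 + 4 sigma^2,
    with f = 2/3 for uniform orientations (``scale_calibration`` may be a
    custom factor for other orientation priors, or None to disable).
    """
    pts_list = [_center(np.asarray(getattr(p, "positions_nm", p), float))
                for p in particles]
    if len(pts_list) < 5:
        raise ValueError("need at least 5 particles to reconstruct a class")
    k = n_blobs or pts_list[0].shape[0]
    if any(p.shape[0] != k for p in pts_list):
        raise ValueError("all particles of a class must have the same "
                         "number of fluorophores")
    if init_sd_nm is None:
        init_sd_nm = float(np.sqrt(np.mean(
            [np.mean((p ** 2).sum(1)) for p in pts_list])))

    def sweep_temperature(s):
        frac = s / max(n_outer - 1, 1)
        return t_start_deg * (t_end_deg / t_start_deg) ** frac

    def run_sweeps(X, rotations, costs, first_sweep, last_sweep, history):
        for s in range(first_sweep, last_sweep):
            Ts = sweep_temperature(s)
            for i, Y in enumerate(pts_list):
                R, c = _anneal_rotation(X, Y, rng, steps_per_sweep,
                                        t_start_deg=Ts,
                                        t_end_deg=max(0.3 * Ts, 0.5),
                                        R0=rotations[i])
                cur = (_sa_cost(rotations[i], X, Y)
                       if rotations[i] is not None else math.inf)
                if c < cur:
                    rotations[i], costs[i] = R, c
                else:
                    costs[i] = cur
            A_rows = [[] for _ in range(k)]
            b_rows = [[] for _ in range(k)]
            for i, Y in enumerate(pts_list):
                R = rotations[i]
                proj = _center(_project(R, X))
                _, cols = _corresponded_rmsd2(proj, Y)
                for j in range(k):
                    A_rows[j].append(R[:2, :])
                    b_rows[j].append(Y[cols[j]])
            X_new = np.empty_like(X)
            for j in range(k):
                sol, *_ = np.linalg.lstsq(np.vstack(A_rows[j]),
                                          np.concatenate(b_rows[j]),
                                          rcond=None)
                X_new[j] = sol
            X_new -= X_new.mean(0)
            new_costs = np.array([_sa_cost(rotations[i], X_new, Y)
                                  for i, Y in enumerate(pts_list)])
            if new_costs.mean() <= costs.mean():
                X = X_new
                costs = new_costs
            history.append(float(costs.mean()))
        return X, rotations, costs, history

    pilot = min(pilot_sweeps, n_outer)
    candidates = []
    for _ in range(max(n_init, 1)):
        X0 = rng.normal(0.0, init_sd_nm / math.sqrt(3.0), size=(k, 3))
        candidates.append(run_sweeps(
            X0, [None] * len(pts_list), np.full(len(pts_list), np.inf),
            0, pilot, []))
    X, rotations, costs, history = min(candidates,
                                       key=lambda c: c[2].mean())
    X, rotations, costs, history = run_sweeps(X, rotations, costs,
                                              pilot, n_outer, history)

    sigma = (noise_sigma_nm if noise_sigma_nm is not None
             else math.sqrt(max(np.mean(costs), 1e-6) / 2.0))

    # EM-style debias: blob update averaged over orientation posteriors
    for _ in range(max(marginal_passes, 0)):
        A_rows = [[] for _ in range(k)]
        b_rows = [[] for _ in range(k)]
        for i, Y in enumerate(pts_list):
            samples = _orientation_posterior_samples(
                X, Y, rotations[i], sigma, rng)
            for R in samples:
                proj = _center(_project(R, X))
                _, cols = _corresponded_rmsd2(proj, Y)
                A = R[:2, :]
                for j in range(k):
                    A_rows[j].append(A)
                    b_rows[j].append(Y[cols[j]])
        for j in range(k):
            sol, *_ = np.linalg.lstsq(np.vstack(A_rows[j]),
                                      np.concatenate(b_rows[j]), rcond=None)
            X[j] = sol
        X -= X.mean(0)
        # re-anchor the point-estimate orientations on the updated map
        for i, Y in enumerate(pts_list):
            R, c = _anneal_rotation(X, Y, rng, 400, t_start_deg=6.0,
                                    t_end_deg=0.5, R0=rotations[i])
            if c < _sa_cost(rotations[i], X, Y):
                rotations[i] = R
        costs = np.array([_sa_cost(rotations[i], X, Y)
                          for i, Y in enumerate(pts_list)])

    # global scale calibration from the projected pairwise statistic
    if scale_calibration is not None:
        f = 2.0 / 3.0 if scale_calibration == "uniform" \
            else float(scale_calibration)
        iu = np.triu_indices(k, 1)

        def mean_sq_pairs(P):
            d = P[iu[0]] - P[iu[1]]
            return float(np.mean((d ** 2).sum(1)))

        m2_data = float(np.mean([mean_sq_pairs(Y) for Y in pts_list]))
        m2_model = mean_sq_pairs(X)
        num = m2_data - 4.0 * sigma ** 2
        if num > 0 and m2_model > 0:
            X = X * math.sqrt(num / (f * m2_model))

    # degenerate depth: the stacked projection rows carry (almost) no
    # information about one model direction
    a_stack = np.vstack([R[:2, :] for R in rotations])
    svals = np.linalg.svd(a_stack, compute_uv=False)
    degenerate = bool(svals[2] / svals[0] < 0.25)
    resid = math.sqrt(max(np.mean(costs), 0.0))
    # canonical frame: principal axes
    _, _, Vt = np.linalg.svd(_center(X), full_matrices=False)
    Xc = _center(X) @ Vt.T
    return Reconstruction3D(class_id, Xc, max(resid, 1e-3), rotations,
                            len(pts_list), history, degenerate)


def reconstruct_class_consensus(particles, rng: np.random.Generator,
                                n_runs: int = 4,
                                **kwargs) -> Reconstruction3D:
    """Consensus of several independent class reconstructions.

    Runs :func:`reconstruct_class` ``n_runs`` times from different random
    initializations, rigidly aligns the resulting blob sets (best
    correspondence and proper/improper rotation) and averages them —
    independent runs share the signal but not the stochastic optimizer
    noise, so the averaged centers are markedly more stable.
    """
    recs = [reconstruct_class(
        particles, np.random.default_rng(int(rng.integers(2 ** 31))),
        **kwargs) for _ in range(max(n_runs, 1))]
    ref = recs[0].blob_centers_nm
    k = ref.shape[0]
    aligned = [ref]
    for rec in recs[1:]:
        X = rec.blob_centers_nm
        best = (math.inf, None)
        for perm in itertools.permutations(range(k)):
            rmsd, R, t = align_point_sets_3d(X[list(perm)], ref)
            if rmsd < best[0]:
                best = (rmsd, (R @ X[list(perm)].T).T + t)
        aligned.append(best[1])
    X = np.mean(np.stack(aligned), axis=0)
    X -= X.mean(0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    out = recs[0]
    return Reconstruction3D(out.class_id, X @ Vt.T,
                            float(np.mean([r.blob_sigma_nm for r in recs])),
                            out.per_particle_rotations, out.n_particles,
                            out.objective_history,
                            any(r.degenerate for r in recs))


# --------------------------------------------------------------------------
# merging


def merge_class_reconstructions(recons: Sequence[Reconstruction3D],
                                accessible_model: PointModel,
                                rmsd_threshold_nm: float = 2.0
                                ) -> dict:
    """Rigid-body fit of each class reconstruction into the accessible
    volume model (site centers) and merge of the aligned blobs.

    Each reconstruction's blobs are matched to the best-fitting subset of
    model sites over all subsets, correspondences, and proper/improper
    rotations.  Sites hit by several classes are averaged.  Fits whose
    RMSD exceeds ``rmsd_threshold_nm`` are flagged.
    """
    recons = list(recons)
    if len(recons) < 2:
        raise ValueError("need at least 2 class reconstructions to merge")
    sites = accessible_model.labels
    n_sites = sites.shape[0]
    merged_positions: dict[int, list[np.ndarray]] = {}
    fits = []
    for rec in recons:
        X = rec.blob_centers_nm
        k = X.shape[0]
        best = (math.inf, None, None)
        for subset in itertools.combinations(range(n_sites), k):
            target = sites[list(subset)]
            for perm in itertools.permutations(range(k)):
                rmsd, R, t = align_point_sets_3d(X[list(perm)], target)
                if rmsd < best[0]:
                    best = (rmsd, (R, t, perm), subset)
        rmsd, (R, t, perm), subset = best
        aligned = (R @ X[list(perm)].T).T + t
        for site, pos in zip(subset, aligned):
            merged_positions.setdefault(site, []).append(pos)
        fits.append({"class_id": rec.class_id, "rmsd_nm": rmsd,
                     "sites": subset,
                     "flagged": rmsd > rmsd_threshold_nm})
    merged = {site: np.mean(np.stack(pos), 0)
              for site, pos in sorted(merged_positions.items())}
    blob_centers = np.stack(list(merged.values()))
    return {"blob_centers_nm": blob_centers,
            "site_index": np.array(list(merged.keys())),
            "fits": fits}


# --------------------------------------------------------------------------
# FSC


@dataclass
class FSCCurve:
    shell_frequencies: np.ndarray        # 1 / nm
    correlation: np.ndarray
    halfbit_threshold: np.ndarray
    resolution_nm: float | None
    n_voxels_per_shell: np.ndarray


def half_bit_threshold(n_voxels: np.ndarray) -> np.ndarray:
    """Half-bit information threshold T(n) per Fourier shell."""
    n_eff = np.maximum(np.asarray(n_voxels, float), 1.0)
    root = np.sqrt(n_eff)
    return (0.2071 + 1.9102 / root) / (1.2071 + 0.9102 / root)


def volume_from_blobs(centers_nm: np.ndarray, box_nm: float,
                      voxel_nm: float = 0.1,
                      sigma_nm: float = 0.5) -> np.ndarray:
    """Voxelize Gaussian blobs into a cubic density grid (normalized)."""
    n = int(round(box_nm / voxel_nm))
    ax = (np.arange(n) + 0.5) * voxel_nm - box_nm / 2.0
    vol = np.zeros((n, n, n), dtype=np.float64)
    for c in np.asarray(centers_nm, float):
        gz = np.exp(-0.5 * ((ax - c[2]) / sigma_nm) ** 2)
        gy = np.exp(-0.5 * ((ax - c[1]) / sigma_nm) ** 2)
        gx = np.exp(-0.5 * ((ax - c[0]) / sigma_nm) ** 2)
        vol += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    s = vol.sum()
    if s > 0:
        vol /= s
    return vol


def fsc(vol_a: np.ndarray, vol_b: np.ndarray, voxel_nm: float) -> FSCCurve:
    """Fourier shell correlation between two equally shaped volumes.

    The resolution is read at the first crossing of the half-bit
    threshold curve; ``None`` if the curve never drops below it.
    """
    a = np.asarray(vol_a, float)
    b = np.asarray(vol_b, float)
    if a.shape != b.shape:
        raise ValueError("volumes must have identical shapes")
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    freqs = [np.fft.fftfreq(s, d=voxel_nm) for s in a.shape]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    kmag = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    nyquist = 0.5 / voxel_nm
    df = 1.0 / (a.shape[0] * voxel_nm)
    edges = np.arange(0.0, nyquist + df, df)
    shell = np.clip(np.digitize(kmag.ravel(), edges) - 1, 0,
                    len(edges) - 2)
    num = np.bincount(shell, (Fa * np.conj(Fb)).real.ravel(),
                      minlength=len(edges) - 1)
    den_a = np.bincount(shell, (np.abs(Fa) ** 2).ravel(),
                        minlength=len(edges) - 1)
    den_b = np.bincount(shell, (np.abs(Fb) ** 2).ravel(),
                        minlength=len(edges) - 1)
    counts = np.bincount(shell, minlength=len(edges) - 1)
    den = np.sqrt(den_a * den_b)
    corr = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = half_bit_threshold(counts)
    resolution = None
    for i in range(1, len(corr)):
        if counts[i] == 0:
            continue
        if corr[i] < thr[i]:
            resolution = float(1.0 / centers[i])
            break
    return FSCCurve(centers, corr, thr, resolution, counts)
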