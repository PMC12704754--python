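"""Sub-pixel PSF localization and particle assembly.

Each on-frame of a polarization state yields one localization event by a
maximum-likelihood 2D-Gaussian fit under Poisson noise; aggregating the
events of a state gives a fluorophore position whose precision improves as
1/sqrt(n_events).  Fluorophore positions from one diffraction-limited spot
are finally assembled into a 2D-resolved particle, subject to the particle
filters (at least three polarization states, maximum pairwise extent
10 nm) used to select intact ring-shaped oligomers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .simkit import ImageStackPair, OpticsConfig
from .traces import EmitterTrace, StateAssignment

__all__ = [
    "LocalizationEvent",
    "FluorophorePosition",
    "Particle2D",
    "fit_psf",
    "state_position",
    "assemble_particle",
    "precision_summary",
    "localize_states",
    "theoretical_precision_nm",
]


@dataclass
class LocalizationEvent:
    frame: int
    x_px: float
    y_px: float
    photons: float
    background: float            # photons / pixel
    fit_ok: bool = True


@dataclass
class FluorophorePosition:
    """Photon-weighted mean position of one polarization state."""

    state_label: int
    x_nm: float
    y_nm: float
    precision_x_nm: float
    precision_y_nm: float
    n_events: int
    total_photons: float
    single_event: bool = False

    @property
    def precision_nm(self) -> float:
        """Combined per-axis precision sqrt((sx^2 + sy^2) / 2)."""
        return math.sqrt((self.precision_x_nm ** 2
                          + self.precision_y_nm ** 2) / 2.0)


@dataclass
class Particle2D:
    particle_id: int
    positions: list                  # FluorophorePosition
    max_pairwise_nm: float
    pass_filters: bool
    reject_reason: str | None = None
    spot_xy_px: tuple = field(default=(0.0, 0.0))

    @property
    def positions_nm(self) -> np.ndarray:
        return np.array([[p.x_nm, p.y_nm] for p in self.positions])

    @property
    def precisions_nm(self) -> np.ndarray:
        return np.array([p.precision_nm for p in self.positions])


def theoretical_precision_nm(photons: float, optics: OpticsConfig) -> float:
    """Shot-noise-limited single-event precision sigma_psf / sqrt(N)."""
    return optics.psf_sigma_nm / math.sqrt(max(photons, 1.0))


# --------------------------------------------------------------------------
# PSF fitting


def _pixel_gauss(center_px: float, n_px: int, sigma_px: float) -> np.ndarray:
    from scipy.special import erf
    edges = np.arange(n_px + 1, dtype=float)
    z = (edges - center_px) / (sigma_px * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def _pixel_gauss_grad(center_px: float, n_px: int, sigma_px: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-integrated Gaussian profile and its derivative w.r.t. the
    center coordinate."""
    from scipy.special import erf
    edges = np.arange(n_px + 1, dtype=float)
    s2 = sigma_px * math.sqrt(2.0)
    z = (edges - center_px) / s2
    cdf = 0.5 * (1.0 + erf(z))
    pdf = np.exp(-z * z) / (sigma_px * math.sqrt(2.0 * math.pi))
    return np.diff(cdf), -np.diff(pdf)


def fit_psf(roi: np.ndarray, sigma_px: float,
            initial_guess: tuple[float, float] | None = None,
            min_photons: float = 10.0) -> LocalizationEvent:
    """Maximum-likelihood 2D-Gaussian localization under Poisson noise.

    ``roi`` is a small photon-count image containing one spot; the PSF
    width ``sigma_px`` is treated as known.  Fits sub-pixel center (the
    position refers to ROI pixel-edge coordinates, i.e. the center of
    pixel (0, 0) is at (0.5, 0.5)), total photons and a flat background.
    Returns ``fit_ok=False`` on non-convergence or a photon count below
    ``min_photons``.
    """
    roi = np.asarray(roi, float)
    if roi.ndim != 2 or min(roi.shape) < 5:
        raise ValueError("ROI must be a 2D image of at least 5x5 pixels")
    H, W = roi.shape
    bg0 = max(float(np.median(roi)), 1e-3)
    net = np.clip(roi - bg0, 0.0, None)
    total = float(net.sum())
    if total < min_photons:
        return LocalizationEvent(-1, W / 2, H / 2, total, bg0, False)
    if initial_guess is None:
        rr, cc = np.mgrid[0:H, 0:W] + 0.5
        x0 = float((net * cc).sum() / total)
        y0 = float((net * rr).sum() / total)
    else:
        x0, y0 = initial_guess

    def nll_grad(p):
        x, y, logN, logb = p
        N, b = math.exp(logN), math.exp(logb)
        px, dpx = _pixel_gauss_grad(x, W, sigma_px)
        py, dpy = _pixel_gauss_grad(y, H, sigma_px)
        shape = np.outer(py, px)
        mu = N * shape + b
        w = 1.0 - roi / mu
        g_x = N * float((w * np.outer(py, dpx)).sum())
        g_y = N * float((w * np.outer(dpy, px)).sum())
        g_logN = N * float((w * shape).sum())
        g_logb = b * float(w.sum())
        val = float(mu.sum() - np.sum(roi * np.log(mu)))
        return val, np.array([g_x, g_y, g_logN, g_logb])

    p0 = np.array([x0, y0, math.log(max(total, min_photons)),
                   math.log(bg0)])
    res = minimize(nll_grad, p0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, W), (0.0, H), (math.log(1e-2), 20.0),
                           (math.log(1e-4), 15.0)],
                   options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
    x, y, logN, logb = res.x
    photons = math.exp(logN)
    ok = bool(res.success) and photons >= min_photons \
        and 0 <= x <= W and 0 <= y <= H
    return LocalizationEvent(-1, float(x), float(y), float(photons),
                             float(math.exp(logb)), ok)


# --------------------------------------------------------------------------
# aggregation


def state_position(events: Sequence[LocalizationEvent],
                   pixel_size_nm: float,
                   state_label: int = 0,
                   optics: OpticsConfig | None = None,
                   trim_outliers: bool = False
                   ) -> FluorophorePosition:
    """Photon-weighted mean of accepted events with weighted-SEM precision.

    A single event gets the theoretical per-event precision (flagged)
    because a standard error cannot be estimated from one sample.
    ``trim_outliers`` drops events beyond 4 robust SDs of the median
    position before averaging — contaminated frames (a second emitter
    faintly on) are not Gaussian and otherwise bias the mean.
    """
    ev = [e for e in events if e.fit_ok]
    if not ev:
        raise ValueError("no accepted events for this state")
    if trim_outliers and len(ev) >= 10:
        x = np.array([e.x_px for e in ev])
        y = np.array([e.y_px for e in ev])
        r = np.hypot(x - np.median(x), y - np.median(y))
        sd = max(1.4826 * float(np.median(r)), 1e-6)
        keep = r <= 4.0 * sd
        if keep.sum() >= 3:
            ev = [e for e, k in zip(ev, keep) if k]
    x = np.array([e.x_px for e in ev]) * pixel_size_nm
    y = np.array([e.y_px for e in ev]) * pixel_size_nm
    w = np.array([e.photons for e in ev])
    n = len(ev)
    xm = float(np.average(x, weights=w))
    ym = float(np.average(y, weights=w))
    if n == 1:
        o = optics or OpticsConfig(pixel_size_nm=pixel_size_nm)
        p = theoretical_precision_nm(w[0], o)
        return FluorophorePosition(state_label, xm, ym, p, p, 1,
                                   float(w.sum()), single_event=True)
    # weighted SEM per axis
    vx = float(np.average((x - xm) ** 2, weights=w)) * n / (n - 1)
    vy = float(np.average((y - ym) ** 2, weights=w)) * n / (n - 1)
    return FluorophorePosition(state_label, xm, ym,
                               math.sqrt(vx / n), math.sqrt(vy / n),
                               n, float(w.sum()))


def assemble_particle(positions: Sequence[FluorophorePosition],
                      particle_id: int = 0, min_states: int = 3,
                      max_extent_nm: float = 10.0,
                      spot_xy_px: tuple = (0.0, 0.0)) -> Particle2D:
    """Apply the particle filters: >= min_states polarization components
    within a maximum pairwise distance of max_extent_nm."""
    pos = list(positions)
    if len(pos) >= 2:
        pts = np.array([[p.x_nm, p.y_nm] for p in pos])
        iu = np.triu_indices(len(pos), 1)
        diff = pts[iu[0]] - pts[iu[1]]
        max_pair = float(np.sqrt((diff ** 2).sum(1)).max())
    else:
        max_pair = 0.0
    if len(pos) < min_states:
        return Particle2D(particle_id, pos, max_pair, False,
                          "too_few_states", spot_xy_px)
    if max_pair > max_extent_nm:
        return Particle2D(particle_id, pos, max_pair, False,
                          "too_spread", spot_xy_px)
    return Particle2D(particle_id, pos, max_pair, True, None, spot_xy_px)


def precision_summary(particles: Sequence[Particle2D]) -> dict:
    """Distribution statistics of per-fluorophore precision and the
    propagated pairwise-distance error sqrt(s1^2 + s2^2)."""
    parts = list(particles)
    if not parts:
        raise ValueError("no particles given")
    prec = np.concatenate([p.precisions_nm for p in parts])
    dist_err = []
    for p in parts:
        s = p.precisions_nm
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                dist_err.append(math.sqrt(s[i] ** 2 + s[j] ** 2))
    out = {
        "n_fluorophores": int(prec.size),
        "median_precision_nm": float(np.median(prec)),
        "p25_precision_nm": float(np.quantile(prec, 0.25)),
        "p75_precision_nm": float(np.quantile(prec, 0.75)),
    }
    if dist_err:
        out["median_distance_error_nm"] = float(np.median(dist_err))
    return out


# --------------------------------------------------------------------------
# pipeline glue


def localize_states(stack_pair: ImageStackPair, trace: EmitterTrace,
                    assignment: StateAssignment,
                    roi_radius_px: int = 4,
                    brightness_keep: float = 0.6,
                    min_events: int = 3,
                    max_events_per_state: int | None = 200,
                    max_precision_nm: float | None = 3.0
                    ) -> list[FluorophorePosition]:
    """Localize every polarization state of one spot.

    For each state, the brightest ``brightness_keep`` fraction of its
    on-frames (the dipole-bias / multi-emitter mitigation filter) are fit
    in the channel-summed image; accepted events are aggregated into one
    fluorophore position.  ``max_events_per_state`` caps the per-state
    fitting work (a few hundred events already reach nanometer
    precision); states whose aggregated precision exceeds
    ``max_precision_nm`` are spurious (mixed or underpopulated) and are
    dropped.
    """
    optics = stack_pair.optics
    sigma_px = optics.psf_sigma_px
    H, W = stack_pair.frame_shape
    cx, cy = int(round(trace.x_px)), int(round(trace.y_px))
    c0, c1 = max(cx - roi_radius_px, 0), min(cx + roi_radius_px + 1, W)
    r0, r1 = max(cy - roi_radius_px, 0), min(cy + roi_radius_px + 1, H)
    on_frames = trace.on_frames()
    totals = trace.total[trace.on_mask]
    positions = []
    for s in range(assignment.n_states):
        frames_s = on_frames[assignment.state_of_frame == s]
        totals_s = totals[assignment.state_of_frame == s]
        if frames_s.size == 0:
            continue
        cut = np.quantile(totals_s, 1.0 - brightness_keep)
        sel = frames_s[totals_s >= cut]
        if max_events_per_state is not None:
            sel = sel[:max_events_per_state]
        events = []
        for f in sel:
            roi = (stack_pair.stack_x[f, r0:r1, c0:c1]
                   + stack_pair.stack_y[f, r0:r1, c0:c1])
            ev = fit_psf(roi, sigma_px)
            if ev.fit_ok:
                ev.frame = int(f)
                ev.x_px += c0
                ev.y_px += r0
                events.append(ev)
        if len(events) >= min_events:
            pos = state_position(events, optics.pixel_size_nm,
                                 state_label=s, optics=optics,
                                 trim_outliers=True)
            if max_precision_nm is None or pos.precision_nm <= max_precision_nm:
                positions.append(pos)
    return positions
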