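"""Spot detection, intensity-pair traces, and polarization-state segmentation.

Each diffraction-limited spot contains several fluorophores whose fixed
transition dipoles split their emission between two orthogonal polarization
channels as I cos^2(theta) / I sin^2(theta).  The per-frame intensity pair
(Ix, Iy) therefore encodes which fluorophore is emitting: the polarization
angle theta is stable within one fluorophore's on-state and jumps between
fluorophores.  Segmenting the angle series into states — divisive 1D
clustering scored by the Bayesian information criterion — assigns every
bright frame to a fluorophore, which is what later lets the localizer
resolve individual positions far below the diffraction limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max
from skimage.transform import AffineTransform, estimate_transform

from .photophysics import auto_threshold
from .simkit import ImageStackPair

__all__ = [
    "EmitterTrace",
    "StateAssignment",
    "detect_spots",
    "register_channels",
    "extract_trace",
    "polarization_angle",
    "segment_polarization_states",
    "extend_assignment",
]


# --------------------------------------------------------------------------
# spot detection


def detect_spots(stack_pair: ImageStackPair, min_photons: float = 100.0,
                 min_separation_px: int = 5,
                 threshold_sigma: float = 5.0) -> np.ndarray:
    """Local maxima of the temporally summed, channel-summed image.

    Returns an (n, 2) array of (x_px, y_px) spot centers (column, row).
    The detection threshold is the background level plus
    ``threshold_sigma`` standard deviations (shot-noise estimate) plus the
    per-frame ``min_photons`` requirement summed over frames.
    """
    if stack_pair.n_frames == 0:
        raise ValueError("empty stack")
    summed = stack_pair.summed_image()
    bg = float(np.median(summed))
    noise = math.sqrt(max(bg, 1.0))
    thr = bg + threshold_sigma * noise
    peaks = peak_local_max(summed, min_distance=min_separation_px,
                           threshold_abs=thr, exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 2))
    # refine by local centroid and apply the photon filter on ROI sums
    out = []
    r = max(2, min_separation_px // 2 + 1)
    H, W = summed.shape
    for row, col in peaks:
        r0, r1 = max(row - r, 0), min(row + r + 1, H)
        c0, c1 = max(col - r, 0), min(col + r + 1, W)
        roi = summed[r0:r1, c0:c1] - bg
        roi = np.clip(roi, 0, None)
        total = roi.sum()
        if total < min_photons:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1] + 0.5    # pixel centers
        out.append(((roi * cc).sum() / total, (roi * rr).sum() / total))
    return np.asarray(out).reshape(-1, 2)


def register_channels(bead_positions_x: np.ndarray,
                      bead_positions_y: np.ndarray
                      ) -> tuple[AffineTransform, float]:
    """Least-squares affine map from channel-y to channel-x coordinates.

    Returns the transform and the RMS residual (px).  Needs at least three
    non-collinear corresponding bead positions.
    """
    src = np.asarray(bead_positions_y, float).reshape(-1, 2)
    dst = np.asarray(bead_positions_x, float).reshape(-1, 2)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need at least 3 corresponding points")
    centered = src - src.mean(0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("bead positions are collinear; affine is degenerate")
    tform = estimate_transform("affine", src, dst)
    resid = tform(src) - dst
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return tform, rms


# --------------------------------------------------------------------------
# traces


@dataclass
class EmitterTrace:
    """Per-frame intensity pair and derived polarization angle of a spot."""

    spot_id: int
    x_px: float
    y_px: float
    Ix: np.ndarray               # photons per frame, background-subtracted
    Iy: np.ndarray
    frame_indices: np.ndarray
    on_mask: np.ndarray = field(default=None)
    estimator: str = "cos2"

    def __post_init__(self):
        self.Ix = np.asarray(self.Ix, float)
        self.Iy = np.asarray(self.Iy, float)
        self.frame_indices = np.asarray(self.frame_indices, int)
        if self.on_mask is None:
            total = self.Ix + self.Iy
            self.on_mask = total > auto_threshold(total)
        self.on_mask = np.asarray(self.on_mask, bool)

    @property
    def total(self) -> np.ndarray:
        return self.Ix + self.Iy

    def theta_deg(self) -> np.ndarray:
        """Polarization angle of the on-frames, degrees in [0, 90]."""
        ix = np.clip(self.Ix[self.on_mask], 0.0, None)
        iy = np.clip(self.Iy[self.on_mask], 0.0, None)
        return polarization_angle(ix, iy, self.estimator)

    def on_frames(self) -> np.ndarray:
        return self.frame_indices[self.on_mask]

    def blink_events(self, max_gap_frames: int = 2) -> list[np.ndarray]:
        """Indices (into the on-frame sequence) of consecutive on-runs.

        All frames of one blink event come from a single emitter, so
        pooling their photons gives a far less noisy polarization angle
        than any individual ~70-photon frame.  Gaps of up to
        ``max_gap_frames`` are bridged: true dark dwells are hundreds of
        frames long, so short interruptions are threshold flicker or
        frames removed by the brightness filter, not new events.
        """
        frames = self.on_frames()
        if frames.size == 0:
            return []
        breaks = np.nonzero(np.diff(frames) > max_gap_frames + 1)[0] + 1
        return np.split(np.arange(frames.size), breaks)

    def event_theta_deg(self, max_gap_frames: int = 2
                        ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Per-blink-event polarization angle from pooled raw photons.

        The unclipped per-frame intensities are summed first — clipping
        before pooling would bias boundary states toward exactly 0 or 90
        degrees — and the sums are clipped only then.
        """
        events = self.blink_events(max_gap_frames)
        ix_on = self.Ix[self.on_mask]
        iy_on = self.Iy[self.on_mask]
        thetas = np.array([
            polarization_angle(max(ix_on[ev].sum(), 0.0),
                               max(iy_on[ev].sum(), 0.0),
                               self.estimator)[0]
            for ev in events])
        return thetas, events

    def bright_subset(self, low_quantile: float = 0.4,
                      high_factor: float = 1.6) -> "EmitterTrace":
        """Restrict the on-frames to a brightness band.

        Drops the dimmest ``low_quantile`` fraction of on-frames (dim
        signals carry large dipole bias and angle noise) and frames
        brighter than ``high_factor`` times the median on level, which
        are dominated by two emitters blinking simultaneously.
        """
        tot = self.total
        on_tot = tot[self.on_mask]
        if on_tot.size == 0:
            return self
        lo = np.quantile(on_tot, low_quantile)
        hi = high_factor * float(np.median(on_tot))
        keep = self.on_mask & (tot >= lo) & (tot <= hi)
        return EmitterTrace(self.spot_id, self.x_px, self.y_px,
                            self.Ix, self.Iy, self.frame_indices,
                            keep, self.estimator)


def extract_trace(stack_pair: ImageStackPair, spot_xy_px,
                  spot_id: int = 0, roi_radius_px: int = 4,
                  estimator: str = "cos2") -> EmitterTrace:
    """Matched-filter intensity pair of one spot, frame by frame.

    Each channel is projected onto the expected PSF profile at the spot
    position (weights p / sum p^2), giving an unbiased photon-amplitude
    estimate with far less background noise than a flat ROI sum.  The
    residual background level is removed via the temporal median — valid
    in the blinking regime, where the spot is dark most of the time.
    """
    from scipy.special import erf

    x, y = float(spot_xy_px[0]), float(spot_xy_px[1])
    H, W = stack_pair.frame_shape
    c0 = max(int(round(x)) - roi_radius_px, 0)
    c1 = min(int(round(x)) + roi_radius_px + 1, W)
    r0 = max(int(round(y)) - roi_radius_px, 0)
    r1 = min(int(round(y)) + roi_radius_px + 1, H)
    sig = stack_pair.optics.psf_sigma_px

    def pix_profile(center, lo, hi):
        edges = np.arange(lo, hi + 1, dtype=float)
        z = (edges - center) / (sig * math.sqrt(2.0))
        cdf = 0.5 * (1.0 + erf(z))
        return np.diff(cdf)

    prof = np.outer(pix_profile(y, r0, r1), pix_profile(x, c0, c1))
    w = (prof / (prof ** 2).sum()).astype(np.float32)
    ix = (stack_pair.stack_x[:, r0:r1, c0:c1]
          * w[None]).sum(axis=(1, 2)).astype(float)
    iy = (stack_pair.stack_y[:, r0:r1, c0:c1]
          * w[None]).sum(axis=(1, 2)).astype(float)
    ix -= np.median(ix)
    iy -= np.median(iy)
    total = ix + iy
    on = total > auto_threshold(total)
    return EmitterTrace(spot_id, x, y, ix, iy,
                        np.arange(stack_pair.n_frames), on, estimator)


def polarization_angle(Ix, Iy, estimator: str = "cos2") -> np.ndarray:
    """Polarization angle theta in degrees on [0, 90].

    estimator "cos2" (default): theta = arctan(sqrt(Iy/Ix)), which exactly
    inverts the cos^2/sin^2 channel splitting of a fixed dipole.
    estimator "ratio": theta = arctan(Iy/Ix), the literal intensity-ratio
    form; retained behind this flag for comparison.
    """
    ix = np.atleast_1d(np.asarray(Ix, float))
    iy = np.atleast_1d(np.asarray(Iy, float))
    if np.any((ix <= 0) & (iy <= 0)):
        raise ValueError("polarization angle undefined for Ix = Iy = 0")
    ix = np.clip(ix, 0.0, None)
    iy = np.clip(iy, 0.0, None)
    if estimator == "cos2":
        theta = np.degrees(np.arctan2(np.sqrt(iy), np.sqrt(ix)))
    elif estimator == "ratio":
        theta = np.degrees(np.arctan2(iy, ix))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return theta


# --------------------------------------------------------------------------
# BIC state segmentation


@dataclass
class StateAssignment:
    n_states: int
    state_of_frame: np.ndarray       # label per on-frame
    state_means_deg: np.ndarray
    state_sds_deg: np.ndarray
    bic_curve: dict                  # k -> BIC along the divisive path


_SD_FLOOR_DEG = 0.5


def _gaussian_bic(values: np.ndarray, labels: np.ndarray) -> float:
    n = values.size
    ll = 0.0
    k = 0
    for lab in np.unique(labels):
        v = values[labels == lab]
        sd = max(v.std(), _SD_FLOOR_DEG)
        ll += float(np.sum(-0.5 * ((v - v.mean()) / sd) ** 2
                           - math.log(sd * math.sqrt(2 * math.pi))
                           + math.log(v.size / n)))
        k += 1
    n_par = 3 * k - 1            # mean + sd per state, k-1 proportions
    return -2.0 * ll + n_par * math.log(n)


def _two_means_1d(v: np.ndarray) -> np.ndarray:
    """Exact 1D 2-means: the optimum is a cut point in sorted order."""
    order = np.argsort(v)
    s = v[order]
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total_sum, total_sq = csum[-1], csq[-1]
    m = np.arange(1, n)                     # left cluster sizes
    left = csq[:-1] - csum[:-1] ** 2 / m
    right = (total_sq - csq[:-1]
             - (total_sum - csum[:-1]) ** 2 / (n - m))
    cut = int(np.argmin(left + right)) + 1
    lab = np.zeros(n, int)
    lab[order[cut:]] = 1
    return lab


def _em_gmm_1d(v: np.ndarray, means_init: np.ndarray,
               sd_floor: float = _SD_FLOOR_DEG, max_iter: int = 200,
               tol: float = 1e-8):
    """EM for a 1D Gaussian mixture with per-state SD (floored)."""
    k = means_init.size
    means = means_init.astype(float).copy()
    sds = np.full(k, max(v.std() / k, sd_floor))
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        z = (v[:, None] - means[None, :]) / sds[None, :]
        logp = (np.log(weights)[None, :] - 0.5 * z * z
                - np.log(sds * math.sqrt(2 * math.pi))[None, :])
        m = logp.max(1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(1, keepdims=True)
        resp = p / tot
        ll = float(np.sum(np.log(tot) + m))
        nk = resp.sum(0) + 1e-12
        weights = nk / v.size
        means = (resp * v[:, None]).sum(0) / nk
        var = (resp * (v[:, None] - means[None, :]) ** 2).sum(0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
        if abs(ll - prev) < tol * (abs(ll) + 1):
            break
        prev = ll
    labels = np.argmax(resp, 1)
    return means, sds, weights, ll, labels


def segment_polarization_states(trace: EmitterTrace | np.ndarray,
                                min_on_frames: int = 20,
                                max_states: int = 10,
                                merge_sd_factor: float = 2.0,
                                unit: str = "frame") -> StateAssignment:
    """Divisive BIC clustering of the polarization angles.

    A divisive hierarchy (exact 1D 2-means cuts) proposes state means for
    each candidate count k; a Gaussian-mixture EM refines each candidate
    and the count is selected at the global minimum of the mixture BIC.
    An agglomerative pass then merges states whose means differ by less
    than ``merge_sd_factor`` times the pooled SD.  This mirrors BIC-based
    state detectors used for intensity traces while acting on angle
    values (order-free).

    ``unit="event"`` clusters per-blink-event values (photons pooled over
    each run of consecutive on-frames, so one sample per emitter visit)
    and then labels every on-frame with its event's state — much more
    robust at the ~70 photons/frame of a fast camera.  Event clustering
    operates on the channel fraction f = sin^2(theta) = Iy / (Ix + Iy)
    rather than on theta itself: shot noise blows up in angle space near
    0 and 90 degrees (d theta / d f diverges), whereas in f space the
    boundary states are the best separated.  ``unit="frame"`` clusters
    raw per-frame angles.
    """
    event_members = None
    if isinstance(trace, EmitterTrace):
        if unit == "event":
            theta, event_members = trace.event_theta_deg()
            if int(trace.on_mask.sum()) < min_on_frames:
                raise ValueError(
                    f"trace has {int(trace.on_mask.sum())} on-frames; "
                    f"need >= {min_on_frames}")
        elif unit == "frame":
            theta = trace.theta_deg()
        else:
            raise ValueError(f"unknown unit {unit!r}")
    else:
        theta = np.asarray(trace, float).reshape(-1)
    if event_members is None and theta.size < min_on_frames:
        raise ValueError(
            f"trace has {theta.size} on-frames; need >= {min_on_frames}")
    if event_members is not None and theta.size < 8:
        raise ValueError(
            f"trace has only {theta.size} blink events; too few to segment")

    if event_members is not None:
        values = np.sin(np.radians(theta)) ** 2      # channel fraction f
        sd_floor = 0.003
    else:
        values = theta
        sd_floor = _SD_FLOOR_DEG

    # divisive hierarchy: repeatedly apply the exact 2-means cut to the
    # cluster with the largest within-cluster sum of squares, recording
    # the candidate partition at every level
    hier_labels = np.zeros(values.size, int)
    labels_by_k = {1: hier_labels.copy()}
    while len(np.unique(hier_labels)) < min(max_states, values.size // 2):
        sses = {lab: float(((values[hier_labels == lab]
                             - values[hier_labels == lab].mean()) ** 2).sum())
                for lab in np.unique(hier_labels)
                if (hier_labels == lab).sum() >= 4}
        if not sses:
            break
        target = max(sses, key=sses.get)
        mask = hier_labels == target
        sub = _two_means_1d(values[mask])
        if len(np.unique(sub)) < 2 or min(np.bincount(sub)) < 2:
            break
        hier_labels = hier_labels.copy()
        hier_labels[mask] = np.where(sub == 0, target,
                                     hier_labels.max() + 1)
        labels_by_k[len(np.unique(hier_labels))] = hier_labels.copy()

    # refine every candidate count with EM and score by mixture BIC
    bic_curve = {}
    fits = {}
    for k, init in labels_by_k.items():
        means0 = np.array([values[init == u].mean()
                           for u in np.unique(init)])
        means, sds, weights, ll, labels = _em_gmm_1d(values, means0,
                                                     sd_floor)
        bic_curve[k] = -2.0 * ll + (3 * k - 1) * math.log(values.size)
        fits[k] = labels
    k_opt = min(bic_curve, key=bic_curve.get)
    labels = fits[k_opt].copy()

    # agglomerative merge of under-separated states
    def summaries(lbl):
        uniq = np.unique(lbl)
        means = np.array([values[lbl == u].mean() for u in uniq])
        sds = np.array([max(values[lbl == u].std(), sd_floor)
                        for u in uniq])
        ns = np.array([(lbl == u).sum() for u in uniq])
        return uniq, means, sds, ns

    while True:
        uniq, means, sds, ns = summaries(labels)
        if uniq.size == 1:
            break
        order = np.argsort(means)
        merged = False
        # examine adjacent pairs in mean order, closest (in SD units) first
        pairs = []
        for a, b in zip(order[:-1], order[1:]):
            pooled = math.sqrt((ns[a] * sds[a] ** 2 + ns[b] * sds[b] ** 2)
                               / (ns[a] + ns[b]))
            sep = abs(means[a] - means[b])
            pairs.append((sep / pooled, sep, pooled, a, b))
        pairs.sort()
        ratio, sep, pooled, a, b = pairs[0]
        if sep < merge_sd_factor * pooled:
            labels[labels == uniq[b]] = uniq[a]
            bic_curve[len(np.unique(labels))] = _gaussian_bic(theta, labels)
            merged = True
        if not merged:
            break

    uniq, means, sds, ns = summaries(labels)
    # relabel in order of increasing mean; report summaries in degrees
    order = np.argsort(means)
    remap = {uniq[o]: i for i, o in enumerate(order)}
    final = np.array([remap[l] for l in labels])
    means = np.array([theta[labels == u].mean() for u in uniq])
    sds = np.array([max(theta[labels == u].std(), 1e-3) for u in uniq])
    if event_members is not None:
        # propagate each event's state to its member on-frames
        n_on = sum(len(ev) for ev in event_members)
        frame_labels = np.empty(n_on, int)
        for lab, ev in zip(final, event_members):
            frame_labels[ev] = lab
        final = frame_labels
    return StateAssignment(uniq.size, final, means[order], sds[order],
                           bic_curve)


def extend_assignment(trace: EmitterTrace,
                      assignment: StateAssignment) -> StateAssignment:
    """Label every on-frame of ``trace`` with its nearest fitted state.

    States are typically fitted on a brightness-filtered trace for
    robustness; this helper transfers them to a larger trace (e.g. one
    that keeps the dim frames) so localization can use all events.
    Assignment is per blink event, by proximity of the event's pooled
    channel fraction to the state means.
    """
    theta_ev, events = trace.event_theta_deg()
    f_ev = np.sin(np.radians(theta_ev)) ** 2
    f_states = np.sin(np.radians(assignment.state_means_deg)) ** 2
    labels_ev = np.array([int(np.argmin(np.abs(f_states - f)))
                          for f in f_ev])
    # consistency gate: drop events far from their state (mixed-emitter
    # or transition events contaminate positions more than they help)
    for s in range(assignment.n_states):
        sel = labels_ev == s
        if sel.sum() < 4:
            continue
        resid = f_ev[sel] - f_states[s]
        sd = max(1.4826 * float(np.median(np.abs(resid
                                                 - np.median(resid)))),
                 5e-3)
        bad = np.abs(resid) > 3.0 * sd
        idx = np.nonzero(sel)[0][bad]
        labels_ev[idx] = -1
    n_on = int(trace.on_mask.sum())
    frame_labels = np.full(n_on, -1, int)
    for lab, ev in zip(labels_ev, events):
        frame_labels[ev] = lab
    # frame-level gate: frames whose own channel fraction contradicts the
    # event's state (another emitter lighting up mid-event) are dropped
    ix_on = np.clip(trace.Ix[trace.on_mask], 0.0, None)
    iy_on = np.clip(trace.Iy[trace.on_mask], 0.0, None)
    tot = ix_on + iy_on
    with np.errstate(invalid="ignore", divide="ignore"):
        f_frame = np.where(tot > 0, iy_on / np.maximum(tot, 1e-9), np.nan)
    for i in range(n_on):
        lab = frame_labels[i]
        if lab < 0 or not np.isfinite(f_frame[i]):
            continue
        if abs(f_frame[i] - f_states[lab]) > 0.18:
            frame_labels[i] = -1
    return StateAssignment(assignment.n_states, frame_labels,
                           assignment.state_means_deg,
                           assignment.state_sds_deg,
                           assignment.bic_curve)
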