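"""Blinking photophysics: dwell-time extraction and distribution fits.

Single fluorophores under cryogenic vacuum blink spontaneously between an
emitting (on) state and dark (off) states.  This module turns intensity
time traces into censoring-aware on/off dwell sets, summarises them by the
off-on median ratio, and fits the two distribution families that describe
them: a continuous power law (closed-form MLE) and a mixture of
exponentials (EM, component count chosen by BIC).  A survival estimator
quantifies photobleaching over the recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DwellSets",
    "PowerLawFit",
    "MultiExpFit",
    "extract_dwells",
    "pool_dwells",
    "off_on_ratio",
    "fit_power_law",
    "power_law_loglik",
    "fit_multi_exponential",
    "survival_fraction",
    "auto_threshold",
]


@dataclass
class DwellSets:
    """On/off dwell durations (seconds) with boundary-censoring flags."""

    on_dwells_s: np.ndarray
    off_dwells_s: np.ndarray
    on_censored: np.ndarray     # bool per on dwell
    off_censored: np.ndarray

    def __post_init__(self):
        self.on_dwells_s = np.asarray(self.on_dwells_s, float).reshape(-1)
        self.off_dwells_s = np.asarray(self.off_dwells_s, float).reshape(-1)
        self.on_censored = np.asarray(self.on_censored, bool).reshape(-1)
        self.off_censored = np.asarray(self.off_censored, bool).reshape(-1)
        if abs(len(self.on_dwells_s) - len(self.off_dwells_s)) > 1:
            raise ValueError("on/off dwell counts must alternate (|diff|<=1)")

    def uncensored_on(self) -> np.ndarray:
        return self.on_dwells_s[~self.on_censored]

    def uncensored_off(self) -> np.ndarray:
        return self.off_dwells_s[~self.off_censored]


def auto_threshold(trace: np.ndarray) -> float:
    """Per-trace on/off threshold: off level + 3 robust SD.

    The off level and its noise are estimated by the median and the
    median absolute deviation of the whole trace — at off-on ratios >> 1
    the off state dominates, so both are insensitive to the on frames.
    """
    trace = np.asarray(trace, float)
    center = float(np.median(trace))
    sd = 1.4826 * float(np.median(np.abs(trace - center)))
    if sd == 0:
        sd = max(1.0, math.sqrt(max(center, 1.0)))   # Poisson floor
    return center + 3.0 * sd


def extract_dwells(trace: np.ndarray, frame_time_s: float,
                   threshold: float | None = None,
                   hysteresis_frames: int = 1) -> DwellSets:
    """Segment an intensity trace into alternating on/off dwells.

    Frames above ``threshold`` (default: :func:`auto_threshold`) are on.
    Runs shorter than ``hysteresis_frames`` that are sandwiched between two
    runs of the opposite state are absorbed, suppressing single-frame
    threshold chatter.  The first and last dwell of a trace are flagged as
    censored because their true start/end lies outside the recording.
    """
    trace = np.asarray(trace, float).reshape(-1)
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 frames")
    if threshold is None:
        threshold = auto_threshold(trace)
    state = trace > threshold
    if state.all() or (~state).all():
        warnings.warn("constant-state trace: single censored dwell")
        dur = np.array([trace.size * frame_time_s])
        cens = np.array([True])
        empty = np.empty(0)
        if state.all():
            return DwellSets(dur, empty, cens, np.empty(0, bool))
        return DwellSets(empty, dur, np.empty(0, bool), cens)

    # run-length encoding
    change = np.nonzero(np.diff(state))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [state.size]])
    runs = ends - starts
    run_state = state[starts]

    if hysteresis_frames > 0 and runs.size > 2:
        # absorb interior runs of <= hysteresis frames into neighbours
        keep_state = [run_state[0]]
        keep_len = [runs[0]]
        for s, ln in zip(run_state[1:], runs[1:]):
            if ln <= hysteresis_frames and keep_state[-1] != s:
                keep_len[-1] += ln           # swallow the blip
            elif s == keep_state[-1]:
                keep_len[-1] += ln
            else:
                keep_state.append(s)
                keep_len.append(ln)
        run_state = np.asarray(keep_state, bool)
        runs = np.asarray(keep_len)

    durations = runs * frame_time_s
    censored = np.zeros(runs.size, bool)
    censored[0] = censored[-1] = True
    on_mask = run_state
    return DwellSets(durations[on_mask], durations[~on_mask],
                     censored[on_mask], censored[~on_mask])


def pool_dwells(dwell_sets: Sequence[DwellSets]) -> DwellSets:
    """Concatenate per-molecule dwell sets into one pooled set."""
    if not dwell_sets:
        raise ValueError("no dwell sets to pool")
    cat = lambda parts: (np.concatenate(parts) if parts
                         else np.empty(0))
    pooled = DwellSets.__new__(DwellSets)
    pooled.on_dwells_s = cat([d.on_dwells_s for d in dwell_sets])
    pooled.off_dwells_s = cat([d.off_dwells_s for d in dwell_sets])
    pooled.on_censored = np.concatenate(
        [d.on_censored for d in dwell_sets]).astype(bool)
    pooled.off_censored = np.concatenate(
        [d.off_censored for d in dwell_sets]).astype(bool)
    return pooled


def off_on_ratio(dwells: DwellSets | Sequence[DwellSets],
                 per_molecule: bool = False) -> float:
    """Median(off) / median(on), censored dwells excluded.

    With a sequence of per-molecule dwell sets, ``per_molecule=True``
    computes the ratio for each molecule and returns the median over
    molecules; otherwise all events are pooled first.
    """
    if isinstance(dwells, DwellSets):
        on = dwells.uncensored_on()
        off = dwells.uncensored_off()
        if on.size == 0 or off.size == 0:
            raise ValueError("need at least one uncensored dwell per class")
        return float(np.median(off) / np.median(on))
    if per_molecule:
        ratios = []
        for d in dwells:
            on, off = d.uncensored_on(), d.uncensored_off()
            if on.size and off.size:
                ratios.append(np.median(off) / np.median(on))
        if not ratios:
            raise ValueError("no molecule has both dwell classes")
        return float(np.median(ratios))
    return off_on_ratio(pool_dwells(list(dwells)))


# --------------------------------------------------------------------------
# power-law fit


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    exponent_se: float
    xmin: float
    n_tail: int
    loglik: float


def power_law_loglik(alpha: float, samples: np.ndarray,
                     xmin: float) -> float:
    """Log-likelihood of a continuous Pareto power law p(x) ~ x^-alpha."""
    x = np.asarray(samples, float)
    x = x[x >= xmin]
    n = x.size
    return (n * math.log(alpha - 1.0) - n * math.log(xmin)
            - alpha * float(np.sum(np.log(x / xmin))))


def fit_power_law(samples: np.ndarray, xmin: float) -> PowerLawFit:
    """Continuous maximum-likelihood power-law exponent.

    alpha_hat = 1 + n / sum ln(x_i / xmin), with standard error
    (alpha_hat - 1) / sqrt(n) (Clauset-style tail fit at fixed xmin).
    """
    x = np.asarray(samples, float)
    x = x[x >= xmin]
    if x.size < 10:
        raise ValueError("need at least 10 samples >= xmin")
    s = float(np.sum(np.log(x / xmin)))
    if s <= 0:
        raise ValueError("all samples equal xmin: exponent diverges")
    alpha = 1.0 + x.size / s
    se = (alpha - 1.0) / math.sqrt(x.size)
    return PowerLawFit(alpha, se, xmin, int(x.size),
                       power_law_loglik(alpha, x, xmin))


# --------------------------------------------------------------------------
# exponential mixture fit


@dataclass(frozen=True)
class MultiExpFit:
    k: int
    rates: np.ndarray          # 1/s, descending
    weights: np.ndarray
    bic: float
    loglik: float
    converged: bool
    bic_by_k: dict


def _em_exponential(x: np.ndarray, k: int, max_iter: int = 500,
                    tol: float = 1e-8,
                    ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n = x.size
    # initialise rates from quantile spread
    qs = np.quantile(x, np.linspace(0.15, 0.85, k))
    rates = 1.0 / np.maximum(qs, 1e-12)
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step in log space
        logp = (np.log(weights)[None, :] + np.log(rates)[None, :]
                - x[:, None] * rates[None, :])
        m = logp.max(1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(1, keepdims=True)
        resp = p / tot
        ll = float(np.sum(np.log(tot) + m))
        # M step
        nk = resp.sum(0)
        weights = nk / n
        rates = nk / (resp * x[:, None]).sum(0)
        if abs(ll - prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        prev = ll
    order = np.argsort(-rates)
    return rates[order], weights[order], ll, converged


def fit_multi_exponential(samples: np.ndarray, k_max: int = 4,
                          max_iter: int = 500) -> MultiExpFit:
    """EM fit of an exponential mixture; component count by minimum BIC."""
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    x = np.asarray(samples, float)
    x = x[x > 0]
    best = None
    bic_by_k = {}
    for k in range(1, k_max + 1):
        if x.size < 10 * (2 * k - 1):
            break
        rates, weights, ll, conv = _em_exponential(x, k, max_iter)
        n_par = 2 * k - 1
        bic = -2.0 * ll + n_par * math.log(x.size)
        bic_by_k[k] = bic
        if best is None or bic < best.bic:
            best = MultiExpFit(k, rates, weights, bic, ll, conv, bic_by_k)
    if best is None:
        raise ValueError("too few samples for even a single component")
    # rebuild with the complete bic curve
    return MultiExpFit(best.k, best.rates, best.weights, best.bic,
                       best.loglik, best.converged, bic_by_k)


# --------------------------------------------------------------------------
# survival


def survival_fraction(traces, t_s: float) -> float:
    """Fraction of molecules not photobleached by time ``t_s``.

    ``traces`` are objects exposing ``bleach_time_s`` and ``duration_s``
    (e.g. :class:`spcold.simkit.StateTrace`).
    """
    if t_s < 0:
        raise ValueError("time must be non-negative")
    spans = np.array([tr.duration_s for tr in traces], float)
    if spans.size == 0:
        raise ValueError("no traces given")
    if t_s > spans.max():
        raise ValueError("t exceeds every observation span")
    ok = spans >= t_s
    bleach = np.array([tr.bleach_time_s for tr in traces], float)[ok]
    return float(np.mean(bleach > t_s))
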