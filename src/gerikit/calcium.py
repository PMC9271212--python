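"""dF/F processing, calcium-event detection, spike inference by nonnegative
AR(1) deconvolution, burst and theta-burst scoring, and the walking filter.

Event detection uses hysteresis: an event starts when dF/F exceeds 3 SD of
the baseline and ends when it returns to within 0.5 SD. Bursts are bins of
summed inferred-spike amplitude above 2.5 (baseline-sd units) per 33-ms bin
(one frame at 30 Hz), consecutive supra-threshold bins merged; theta-burst
events are bursts whose start-to-start interval to the preceding burst
falls in 100-167 ms (6-10 Hz). Grooming-related z-motion artifacts are
handled by restricting analysis to walking (speed > 0.5 cm/s and run
length > 0.5 cm).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .types import BurstEvent, CalciumTrace, PositionTrace, SpikeTrain

THETA_INTERVAL_MS = (100.0, 167.0)  # 6-10 Hz band, start-to-start


def theta_interval_bounds_ms(f_lo_hz: float = 6.0, f_hi_hz: float = 10.0
                             ) -> tuple[float, float]:
    """Interburst-interval band (ms) for a burst-frequency band in Hz.

    1000/10 Hz = 100 ms and 1000/6 Hz = 167 ms (rounded to the printed
    millisecond), the theta band used by the detector.
    """
    return (round(1000.0 / f_hi_hz), round(1000.0 / f_lo_hz))


def robust_sd(x: np.ndarray) -> float:
    """Robust noise sd: 1.4826 * MAD, recomputed after excluding samples
    more than 3 initial sds from the median (transients would otherwise
    inflate the estimate)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    sd0 = 1.4826 * np.median(np.abs(x - med))
    if sd0 > 0:
        sub = x[np.abs(x - med) < 3 * sd0]
        if sub.size:
            sd0 = 1.4826 * np.median(np.abs(sub - np.median(sub)))
    return float(sd0)


def noise_sd(dff: np.ndarray) -> float:
    """Noise sd from robust first differences (sd(diff)/sqrt(2)).

    Differencing removes slow transient decays, so the estimate stays
    calibrated even when calcium events occupy a large fraction of the
    trace; spike-onset jumps are sparse and suppressed by the MAD.
    """
    d = np.diff(np.asarray(dff, dtype=float))
    return robust_sd(d) / np.sqrt(2.0)


# --------------------------------------------------------------------------
# dF/F
# --------------------------------------------------------------------------


def compute_dff(raw: np.ndarray, frame_rate: float = 30.0,
                baseline_percentile: float = 20.0,
                baseline_window_s: float = 30.0,
                bleach_correction: bool = True,
                cell_id: Optional[int] = None) -> CalciumTrace:
    """Baseline-normalized dF/F with photobleaching correction.

    A mono-exponential bleach trend is divided out, then the baseline is a
    running percentile (default 20th over 30 s) and dff = (F - baseline) /
    baseline. baseline_sd is the robust sd (1.4826 * MAD) of dff restricted
    to sub-threshold samples.
    """
    f = np.asarray(raw, dtype=float).copy()
    if f.size < 100:
        raise ValueError("trace too short (< 100 frames)")
    t = np.arange(f.size) / frame_rate

    if bleach_correction and np.ptp(f) > 0:
        def model(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
        try:
            p0 = [max(f[0] - f[-1], 1e-6), max(t[-1] / 2, 1e-3), f[-1]]
            popt, _ = optimize.curve_fit(model, t, f, p0=p0, maxfev=2000)
            trend = model(t, *popt)
            if np.all(trend > 0):
                f = f * (trend[0] / trend)
        except RuntimeError:
            pass  # no discernible bleach trend

    win = max(int(round(baseline_window_s * frame_rate)), 3)
    baseline = ndimage.percentile_filter(f, baseline_percentile, size=win,
                                         mode="nearest")
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline; check raw fluorescence")
    dff = (f - baseline) / baseline

    baseline_sd = robust_sd(dff)
    return CalciumTrace(dff=dff, frame_rate=frame_rate, baseline=baseline,
                        baseline_sd=baseline_sd, cell_id=cell_id)


# --------------------------------------------------------------------------
# event detection (hysteresis)
# --------------------------------------------------------------------------


def detect_events(trace: CalciumTrace, onset_sd: float = 3.0,
                  offset_sd: float = 0.5) -> list[tuple[int, int]]:
    """Hysteresis transient detection; events are half-open [start, end).

    An event begins when dF/F exceeds ``onset_sd`` baseline SDs and ends
    when it returns to within ``offset_sd`` SDs.
    """
    sd = trace.baseline_sd
    if not (np.isfinite(sd) and sd > 0):
        raise ValueError("baseline_sd must be positive")
    events = []
    dff = trace.dff
    in_event = False
    start = 0
    for i, v in enumerate(dff):
        if not in_event and v > onset_sd * sd:
            in_event = True
            start = i
        elif in_event and v < offset_sd * sd:
            events.append((start, i))
            in_event = False
    if in_event:
        events.append((start, len(dff)))
    return events


# --------------------------------------------------------------------------
# spike inference: nonnegative AR(1) deconvolution (pool adjacent violators)
# --------------------------------------------------------------------------


def infer_spikes(trace: CalciumTrace, decay_tau_s: float = 0.5,
                 sparsity: Optional[float] = None) -> SpikeTrain:
    """Sparse nonnegative deconvolution under an AR(1) calcium kernel.

    Solves min 1/2 ||c - dff||^2 + lam * sum(s) subject to
    s_t = c_t - g c_{t-1} >= 0, g = exp(-dt / tau), by the pool-adjacent-
    violators scheme. The L1 penalty defaults to a noise-scaled heuristic
    (lam = baseline_sd); pass ``sparsity`` to override.
    """
    if decay_tau_s <= 0:
        raise ValueError("decay_tau_s must be positive")
    y = np.asarray(trace.dff, dtype=float)
    g = math.exp(-1.0 / (trace.frame_rate * decay_tau_s))
    lam = sparsity if sparsity is not None else (
        trace.baseline_sd if np.isfinite(trace.baseline_sd) else 0.0)
    c = _oasis_ar1(y, g, max(lam, 0.0))
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - g * c[:-1]
    return SpikeTrain(np.clip(s, 0.0, None), frame_rate=trace.frame_rate)


def _oasis_ar1(y: np.ndarray, g: float, lam: float) -> np.ndarray:
    """Pool-adjacent-violators solver for the AR(1) deconvolution problem."""
    T = y.size
    if T == 0:
        return np.empty(0)
    mu = np.full(T, lam * (1.0 - g))
    mu[-1] = lam
    # pools: [value, weight, start, length]
    pools: list[list[float]] = []
    for t in range(T):
        pools.append([y[t] - mu[t], 1.0, t, 1])
        while len(pools) > 1:
            v1, w1, t1, l1 = pools[-2]
            v2, w2, _t2, l2 = pools[-1]
            if v2 / w2 >= (g ** l1) * v1 / w1:
                break
            pools.pop()
            pools.pop()
            pools.append([v1 + (g ** l1) * v2,
                          w1 + (g ** (2 * l1)) * w2, t1, l1 + l2])
    c = np.empty(T)
    for v, w, t0, l in pools:
        h = max(v / w, 0.0)
        c[int(t0):int(t0) + int(l)] = h * g ** np.arange(int(l))
    return c


def reconstruct(spikes: SpikeTrain, decay_tau_s: float = 0.5) -> np.ndarray:
    """Forward model: convolve a spike train with the AR(1) kernel."""
    g = math.exp(-1.0 / (spikes.frame_rate * decay_tau_s))
    out = np.empty_like(spikes.amplitudes)
    acc = 0.0
    for i, s in enumerate(spikes.amplitudes):
        acc = acc * g + s
        out[i] = acc
    return out


# --------------------------------------------------------------------------
# bursts and theta-bursts
# --------------------------------------------------------------------------


def consolidate_spikes(amps: np.ndarray) -> np.ndarray:
    """Move the mass of each contiguous nonzero run onto its peak frame.

    Deconvolution can split one spike's mass across adjacent frames; since
    distinct bursts in the theta band are >= 3 frames apart at 30 Hz,
    merging adjacent-frame mass is unambiguous.
    """
    out = np.zeros_like(amps)
    i = 0
    n = amps.size
    while i < n:
        if amps[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and amps[j + 1] > 0:
            j += 1
        run = amps[i:j + 1]
        # local maxima within the run (ties resolved leftward)
        peaks = [k for k in range(run.size)
                 if (k == 0 or run[k] > run[k - 1])
                 and (k == run.size - 1 or run[k] >= run[k + 1])]
        # basin boundaries at the minimum between consecutive peaks
        bounds = [0]
        for p0, p1 in zip(peaks, peaks[1:]):
            bounds.append(p0 + 1 + int(np.argmin(run[p0 + 1:p1 + 1])))
        bounds.append(run.size)
        for b0, b1, p in zip(bounds, bounds[1:], peaks):
            out[i + p] = run[b0:b1].sum()
        i = j + 1
    return out


def detect_bursts(spikes: SpikeTrain, threshold: float = 2.5,
                  bin_ms: float = 33.0,
                  baseline_sd: Optional[float] = None,
                  mode: str = "amplitude",
                  consolidate: bool = False) -> list[BurstEvent]:
    """Bursts: bins of summed spike amplitude above threshold, merged when
    contiguous.

    The threshold is interpreted in baseline-sd units of the deconvolved
    trace when ``baseline_sd`` is given (then effective threshold =
    threshold * baseline_sd), otherwise in raw amplitude units.
    ``mode="count"`` thresholds the spike count per bin instead.
    ``consolidate`` first merges adjacent-frame spike mass onto peak
    frames (see :func:`consolidate_spikes`), countering deconvolution
    splitting at the one-frame bin width.
    """
    amps = spikes.amplitudes
    if consolidate:
        amps = consolidate_spikes(amps)
    frames_per_bin = max(int(round(bin_ms / 1000.0 * spikes.frame_rate)), 1)
    n_bins = int(np.ceil(amps.size / frames_per_bin))
    padded = np.zeros(n_bins * frames_per_bin)
    padded[:amps.size] = amps
    binned = padded.reshape(n_bins, frames_per_bin)
    if mode == "count":
        stat = (binned > 0).sum(axis=1).astype(float)
        eff = threshold
    else:
        stat = binned.sum(axis=1)
        eff = threshold * baseline_sd if baseline_sd is not None else threshold
    marked = stat > eff

    bursts: list[BurstEvent] = []
    i = 0
    while i < n_bins:
        if marked[i]:
            j = i
            while j + 1 < n_bins and marked[j + 1]:
                j += 1
            bursts.append(BurstEvent(
                start_frame=i * frames_per_bin,
                end_frame=min((j + 1) * frames_per_bin, amps.size) - 1,
                total_amplitude=float(stat[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return bursts


def detect_theta_bursts(bursts: list[BurstEvent], frame_rate: float = 30.0,
                        duration_s: Optional[float] = None,
                        interval_ms: tuple[float, float] = THETA_INTERVAL_MS,
                        ) -> tuple[list[BurstEvent], Optional[float]]:
    """Theta-burst events: bursts whose start-to-start interval to their
    predecessor lies in the 100-167 ms (6-10 Hz) band.

    Returns (theta_events, rate_per_s); the rate is None without a
    duration (pass the walking-masked duration when a mask applies).
    """
    starts = [b.start_frame for b in bursts]
    if any(b1 < b0 for b0, b1 in zip(starts, starts[1:])):
        raise ValueError("bursts must be time-ordered")
    lo, hi = interval_ms
    theta = []
    for prev, cur in zip(bursts, bursts[1:]):
        gap_ms = (cur.start_frame - prev.start_frame) / frame_rate * 1000.0
        if lo <= gap_ms <= hi:
            theta.append(cur)
    rate = len(theta) / duration_s if duration_s else None
    return theta, rate


# --------------------------------------------------------------------------
# walking filter and rates
# --------------------------------------------------------------------------


def walking_mask(position: PositionTrace, speed_min_cm_s: float = 0.5,
                 run_min_cm: float = 0.5,
                 n_frames: Optional[int] = None) -> np.ndarray:
    """Boolean per-frame walking mask: speed > 0.5 cm/s grouped into runs,
    runs with net displacement <= 0.5 cm dropped."""
    speed = position.speed_cm_s()
    if n_frames is not None and speed.size != n_frames:
        raise ValueError("position length does not match trace length")
    moving = speed > speed_min_cm_s
    mask = np.zeros_like(moving)
    dt = 1.0 / position.frame_rate
    i = 0
    while i < moving.size:
        if moving[i]:
            j = i
            while j + 1 < moving.size and moving[j + 1]:
                j += 1
            run_cm = float(speed[i:j + 1].sum() * dt)
            if run_cm > run_min_cm:
                mask[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    return mask


def event_rate(spikes: SpikeTrain, mask: Optional[np.ndarray] = None
               ) -> Optional[float]:
    """Calcium event rate: summed inferred-spike amplitude over time.

    With a walking mask, both the sum and the duration are mask-restricted.
    Returns None for zero masked duration.
    """
    amps = spikes.amplitudes
    if mask is None:
        mask = np.ones(amps.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != amps.size:
        raise ValueError("mask length does not match spike train")
    dur = mask.sum() / spikes.frame_rate
    if dur == 0:
        return None
    return float(amps[mask].sum() / dur)
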