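"""Freezing quantification from segmented mouse-body mask sequences.

The motion signal is the nonoverlapping area (XOR pixel count) between
each pair of consecutive masks; a run of sub-threshold frames lasting at
least the minimum bout duration (0.5 s) is a freezing bout, and the
freezing rate is the fraction of session time spent in bouts. The area
threshold can be calibrated against a manually scored freezing rate by
monotone bisection (the rate is non-decreasing in the threshold).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import FreezingResult


def nonoverlap_area(mask_a: np.ndarray, mask_b: np.ndarray,
                    as_fraction: bool = False) -> float:
    """|A xor B| in pixels (or as a fraction of the mean body area)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    count = int(np.count_nonzero(a ^ b))
    if as_fraction:
        body = 0.5 * (np.count_nonzero(a) + np.count_nonzero(b))
        return count / body if body > 0 else 0.0
    return float(count)


def detect_freezing(masks: np.ndarray, fps: float,
                    area_threshold_px: float,
                    min_duration_s: float = 0.5,
                    as_fraction: bool = False) -> FreezingResult:
    """Freezing bouts from a mask sequence.

    The per-pair nonoverlap series has one value per consecutive frame
    pair; a pair below threshold means "still" for the duration of one
    frame. Runs of still pairs lasting >= ``min_duration_s`` become bouts.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need >= 2 frames of masks")
    n = masks.shape[0]
    series = np.array([nonoverlap_area(masks[i], masks[i + 1], as_fraction)
                       for i in range(n - 1)])
    still = series < area_threshold_px
    # a run of still pairs i..j spans frames i..j+1, i.e. (j - i + 2) frames
    min_frames = max(int(np.ceil(min_duration_s * fps)), 2)

    bouts = []
    i = 0
    while i < still.size:
        if still[i]:
            j = i
            while j + 1 < still.size and still[j + 1]:
                j += 1
            if (j - i + 2) >= min_frames:
                bouts.append((i / fps, (j + 2) / fps))
            i = j + 1
        else:
            i += 1
    total = sum(b - a for a, b in bouts)
    session_s = n / fps
    return FreezingResult(nonoverlap_px=series, bouts_s=bouts,
                          freezing_rate=min(total / session_s, 1.0))


def calibrate_threshold(masks: np.ndarray, fps: float, manual_rate: float,
                        min_duration_s: float = 0.5,
                        max_threshold_px: float | None = None) -> float:
    """Smallest area threshold whose freezing rate reaches the manually
    scored rate.

    Exploits monotonicity (rate non-decreasing in threshold) and searches
    the finite set of achievable thresholds — the distinct nonoverlap
    values of the sequence. Raises when the rate is unreachable, reporting
    the achievable range.
    """
    if not 0.0 <= manual_rate <= 1.0:
        raise ValueError("manual_rate must lie in [0, 1]")
    masks = np.asarray(masks, dtype=bool)
    n = masks.shape[0]
    series = np.array([nonoverlap_area(masks[i], masks[i + 1])
                       for i in range(n - 1)])
    # candidate thresholds: just above each distinct value, plus 0
    cands = np.concatenate([[0.0], np.unique(series) + 0.5])
    if max_threshold_px is not None:
        cands = cands[cands <= max_threshold_px]
        if cands.size == 0:
            cands = np.array([0.0])

    def rate_at(th: float) -> float:
        return detect_freezing(masks, fps, th, min_duration_s).freezing_rate

    rates = np.array([rate_at(th) for th in cands])
    lo_rate, hi_rate = rates.min(), rates.max()
    feasible = np.flatnonzero(rates >= manual_rate)
    if feasible.size == 0:
        raise ValueError(
            f"freezing rate {manual_rate} unreachable; achievable range "
            f"[{lo_rate:.3f}, {hi_rate:.3f}]")
    # smallest threshold reaching the target (bisection over the sorted
    # candidate grid; rates are monotone in the threshold)
    lo, hi = 0, cands.size - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if rates[mid] >= manual_rate:
            hi = mid
        else:
            lo = mid + 1
    return float(cands[lo])
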