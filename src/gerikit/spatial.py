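"""Rate maps, Skaggs spatial information, shuffle-test place-cell
identification and cross-session place-field correlation on a linear track.

The spatial information of a rate map is

    SI = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar)   [bits/event]

with p_i the occupancy fraction of bin i, lam_i its rate, and
lam_bar = sum_i p_i lam_i the occupancy-weighted mean rate. SI is zero iff
the rate is constant over occupied bins and is invariant to rate rescaling.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .types import PositionTrace, RateMap, SpikeTrain


def rate_map(spikes: SpikeTrain, pos: PositionTrace,
             mask: Optional[np.ndarray] = None, n_bins: int = 60,
             smoothing_bins: float = 2.0) -> RateMap:
    """Occupancy-normalized activity map along the track.

    Per-bin summed (walking-masked) spike amplitude divided by per-bin
    masked occupancy; Gaussian smoothing is applied to numerator and
    denominator before the division. Bins never occupied get NaN rate.
    """
    amps = spikes.amplitudes
    x = pos.position_m
    if amps.size != x.size:
        raise ValueError("spike train and position must align")
    if mask is None:
        mask = np.ones(amps.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    edges = np.linspace(0.0, pos.track_length_m, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    occ = np.bincount(idx[mask], minlength=n_bins) / pos.frame_rate
    act = np.bincount(idx[mask], weights=amps[mask], minlength=n_bins)
    if occ.sum() == 0:
        raise ValueError("zero total occupancy")
    if smoothing_bins > 0:
        occ_s = ndimage.gaussian_filter1d(occ, smoothing_bins, mode="wrap")
        act_s = ndimage.gaussian_filter1d(act, smoothing_bins, mode="wrap")
    else:
        occ_s, act_s = occ, act
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 0, act_s / np.where(occ_s > 0, occ_s, 1.0), np.nan)
    rate[occ == 0] = np.nan
    return RateMap(bin_edges_m=edges, occupancy_s=occ, rate=rate,
                   smoothing_bins=smoothing_bins)


def spatial_information(rmap: RateMap) -> Optional[float]:
    """Skaggs spatial information in bits per event; None if no activity."""
    occ = np.asarray(rmap.occupancy_s, dtype=float)
    rate = np.asarray(rmap.rate, dtype=float)
    good = (occ > 0) & np.isfinite(rate)
    if not good.any():
        return None
    p = occ[good] / occ[good].sum()
    lam = rate[good]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return None
    ratio = lam / lam_bar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def identify_place_cells(spikes: SpikeTrain, pos: PositionTrace,
                         mask: Optional[np.ndarray] = None, n_bins: int = 60,
                         smoothing_bins: float = 2.0, n_shuffles: int = 1000,
                         alpha: float = 0.05, min_shift_s: float = 20.0,
                         seed: int = 0) -> tuple[bool, Optional[float]]:
    """Shuffle test on spatial information.

    The spike train is circularly time-shifted (uniform shifts >=
    ``min_shift_s``) and re-scored; a cell is a place cell iff its observed
    SI exceeds the (1 - alpha) quantile of the shuffle distribution.
    Returns (is_place_cell, p_value); p is None for a silent cell.
    """
    n = spikes.amplitudes.size
    if n / spikes.frame_rate <= 60.0:
        raise ValueError("session too short for circular shuffling (> 60 s needed)")
    if spikes.amplitudes.sum() == 0:
        return False, None
    obs_map = rate_map(spikes, pos, mask, n_bins, smoothing_bins)
    obs = spatial_information(obs_map)
    if obs is None:
        return False, None
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * spikes.frame_rate))
    if 2 * min_shift >= n:
        raise ValueError("session too short for the requested minimum shift")
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = int(rng.integers(min_shift, n - min_shift))
        sh = SpikeTrain(np.roll(spikes.amplitudes, shift), spikes.frame_rate)
        si = spatial_information(rate_map(sh, pos, mask, n_bins, smoothing_bins))
        null[k] = -np.inf if si is None else si
    p = float((1 + np.sum(null >= obs)) / (1 + n_shuffles))
    return bool(obs > np.quantile(null, 1 - alpha)), p


def place_field_correlation(map_a: RateMap, map_b: RateMap) -> Optional[float]:
    """Pearson correlation of two rate maps over commonly occupied bins.

    Requires identical binning; returns None with fewer than 3 common bins
    or when either map is constant over them.
    """
    if not np.allclose(map_a.bin_edges_m, map_b.bin_edges_m):
        raise ValueError("rate maps must share binning")
    good = ((map_a.occupancy_s > 0) & (map_b.occupancy_s > 0)
            & np.isfinite(map_a.rate) & np.isfinite(map_b.rate))
    if good.sum() < 3:
        return None
    a, b = map_a.rate[good], map_b.rate[good]
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])
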