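"""3D Gaussian particle fitting, single-mRNA/TS classification, two-channel
colocalization and nascent-transcript counting for smFISH volumes.

The integrated particle intensity is I = A * sx * sy * sz (the integral of
a 3D Gaussian up to a constant factor that cancels in every ratio used
here). The nascent copy number of a transcription site is its integrated
intensity divided by the median integrated intensity of single mRNAs, so
the estimate is invariant to global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .types import ParticleFit

# Labeling arithmetic for the PP7 stem-loop system: 24 PBS repeats in the
# 3' UTR, each bound by a tandem-dimer coat protein carrying 2 GFPs.
PBS_REPEATS = 24
GFPS_PER_BINDING_SITE = 2


def gfp_per_mrna(n_stem_loops: int = PBS_REPEATS,
                 gfps_per_binding_site: int = GFPS_PER_BINDING_SITE) -> int:
    """Maximum GFPs recruited to one mRNA: stem-loops x GFPs per coat dimer."""
    return n_stem_loops * gfps_per_binding_site

def gfp_per_locus(nascent_copies: float, gfps_per_mrna: int | None = None) -> float:
    """GFPs at one transcription site: nascent copy number x GFPs per mRNA."""
    if gfps_per_mrna is None:
        gfps_per_mrna = gfp_per_mrna()
    return nascent_copies * gfps_per_mrna


class FitError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# 3D Gaussian fitting
# --------------------------------------------------------------------------


def fit_particle(subvolume: np.ndarray,
                 init_position_vox: Sequence[float] | None = None,
                 voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1),
                 channel: str = "cds_550",
                 max_nfev: int = 500) -> ParticleFit:
    """Least-squares fit of A*exp(-sum (xi-mu_i)^2 / 2 s_i^2) + b.

    ``subvolume`` is a (z, y, x) crop containing one local maximum;
    positions and widths are returned in micrometres. Raises FitError on
    non-convergence or a structureless crop.
    """
    v = np.asarray(subvolume, dtype=float)
    if v.ndim != 3:
        raise ValueError("subvolume must be 3D")
    if np.ptp(v) <= 0:
        raise FitError("flat subvolume: nothing to fit")
    vsz = np.asarray(voxel_size_um)
    if init_position_vox is None:
        init_position_vox = np.unravel_index(np.argmax(v), v.shape)
    z0, y0, x0 = (float(c) for c in init_position_vox)
    b0 = float(np.percentile(v, 10))
    a0 = float(v.max() - b0)
    if a0 <= 0:
        raise FitError("no positive peak above background")
    s0 = np.maximum(np.asarray(v.shape) * vsz / 6.0, vsz)

    grids = np.indices(v.shape).reshape(3, -1).T * vsz  # um coords
    data = v.ravel()

    def model(p):
        a, mz, my, mx, sz, sy, sx, b = p
        q = (((grids[:, 0] - mz) / sz) ** 2 +
             ((grids[:, 1] - my) / sy) ** 2 +
             ((grids[:, 2] - mx) / sx) ** 2)
        return a * np.exp(-0.5 * q) + b

    p0 = [a0, z0 * vsz[0], y0 * vsz[1], x0 * vsz[2], s0[0], s0[1], s0[2], b0]
    lb = [1e-12, 0, 0, 0, vsz[0] * 0.05, vsz[1] * 0.05, vsz[2] * 0.05, -np.inf]
    ub = [np.inf] + [s * e for s, e in zip(v.shape, vsz)] + \
         [s * e for s, e in zip(v.shape, vsz)] + [np.inf]
    try:
        res = optimize.least_squares(lambda p: model(p) - data, p0,
                                     bounds=(lb, ub), max_nfev=max_nfev)
    except Exception as exc:
        raise FitError(f"fit failed: {exc}") from exc
    if not res.success:
        raise FitError(f"non-convergence: {res.message}")
    a, mz, my, mx, sz, sy, sx, b = res.x
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    return ParticleFit(position_um=(float(mz), float(my), float(mx)),
                       amplitude=float(a),
                       sigma_um=(float(sx), float(sy), float(sz)),
                       background=float(b), channel=channel, residual=rmse)


def particle_intensity(fit: ParticleFit) -> float:
    """Integrated 3D-Gaussian intensity I = A * sx * sy * sz."""
    sx, sy, sz = fit.sigma_um
    return fit.amplitude * sx * sy * sz


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


@dataclass
class ParticleClass:
    fit: ParticleFit
    label: Literal["single", "ts", "rejected"]


def classify_particles(fits: Sequence[ParticleFit],
                       amp_threshold: float,
                       width_threshold: float,
                       width_band: tuple[float, float] | None = None,
                       ) -> list[ParticleClass]:
    """Split fitted particles into single mRNAs, TSs and rejects.

    A particle above both the amplitude and the width threshold (width =
    geometric mean of the three sigmas) is a TS; one below the amplitude
    threshold but inside the single-molecule width band is a single mRNA;
    anything else is rejected. The default band accepts widths up to the
    TS width threshold.
    """
    if width_band is None:
        width_band = (0.0, width_threshold)
    out = []
    for f in fits:
        width = float(np.prod(f.sigma_um)) ** (1.0 / 3.0)
        if f.amplitude > amp_threshold and width > width_threshold:
            out.append(ParticleClass(f, "ts"))
        elif f.amplitude <= amp_threshold and width_band[0] <= width <= width_band[1]:
            out.append(ParticleClass(f, "single"))
        else:
            out.append(ParticleClass(f, "rejected"))
    return out


# --------------------------------------------------------------------------
# colocalization
# --------------------------------------------------------------------------


def colocalize(ts_a: np.ndarray, ts_b: np.ndarray, radius_um: float = 0.3):
    """Mutual-nearest-neighbor matching of TS positions across channels.

    Two sites are the same TS when they are mutual nearest neighbors within
    ``radius_um`` (default 0.3 um, the two-dye identity cap). Returns
    (pairs, fraction_a_matched, fraction_b_matched); fractions are None for
    an empty channel.
    """
    a = np.asarray(ts_a, dtype=float).reshape(-1, 3)
    b = np.asarray(ts_b, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or b.shape[0] == 0:
        fa = None if a.shape[0] == 0 else 0.0
        fb = None if b.shape[0] == 0 else 0.0
        return [], fa, fb
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, distance_upper_bound=radius_um)
    d_ba, j_ba = ta.query(b, distance_upper_bound=radius_um)
    pairs = []
    for i in range(a.shape[0]):
        j = j_ab[i]
        if j < b.shape[0] and j_ba[j] == i and np.isfinite(d_ab[i]):
            pairs.append((i, int(j)))
    return pairs, len(pairs) / a.shape[0], len(pairs) / b.shape[0]


# --------------------------------------------------------------------------
# nascent-transcript counting
# --------------------------------------------------------------------------


def nascent_count(ts_intensity: float | np.ndarray,
                  single_intensities: np.ndarray,
                  denominator: Literal["median", "mean"] = "median",
                  min_singles: int = 20):
    """Nascent mRNA copies per TS: TS intensity over the typical single.

    The canonical denominator is the median single-mRNA integrated
    intensity (the mean is available for comparison). Scalar input returns
    a scalar; array input returns (counts, mean, sd).
    """
    singles = np.asarray(single_intensities, dtype=float)
    if singles.size < min_singles:
        raise ValueError(f"need >= {min_singles} single-mRNA intensities")
    denom = float(np.median(singles) if denominator == "median" else singles.mean())
    if denom == 0:
        raise ValueError("single-mRNA intensity denominator is zero")
    counts = np.asarray(ts_intensity, dtype=float) / denom
    if counts.ndim == 0:
        return float(counts)
    return counts, float(counts.mean()), float(counts.std(ddof=1))
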