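"""Nucleus detection by circle finding, transcription-site detection with
the two-consecutive-z-slices rule, and Arc+/Arc-/ND cell classification.

Nuclei are located by circular Hough voting on per-XY-slice edge maps; the
candidates are grouped across z and the z-centroid/z-radius taken from the
group's vote-weighted extent (an XZ-plane circle fit on the slice profile).
A cell is Arc+ when it shows one or two bright intranuclear spots at the
same XY position in at least two consecutive z slices; cropped cells and
cells with out-of-range nuclear GFP are not determined (ND), and exclusion
precedes positive calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage import feature, transform

from .types import (ARC_NEG, ARC_POS, ND, CellCall, ImageStack, NucleusROI,
                    TSDetection)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# nucleus detection
# --------------------------------------------------------------------------


def find_nuclei(volume: ImageStack,
                radius_range_um: tuple[float, float] = (2.5, 6.0),
                vote_threshold: float = 0.4,
                max_nuclei_per_slice: int = 200) -> list[NucleusROI]:
    """Detect nuclei by circular Hough voting per XY slice, grouped in z.

    Expects the autofluorescence-subtracted green volume. Candidates whose
    xy centers lie within one mean radius of each other across slices are
    grouped into one nucleus; groups spanning a single slice are kept only
    if the volume itself is single-slice. Duplicates closer than one mean
    radius in 3D are merged. Nuclei touching the xy border are flagged
    ``cropped``.
    """
    v = volume.voxels
    if v.size == 0 or v.max() <= 0:
        return []
    vz, vy, vx = volume.voxel_size
    px = 0.5 * (vy + vx)  # xy pixel pitch (assumed ~isotropic in-plane)
    r_lo = max(int(np.floor(radius_range_um[0] / px)), 2)
    r_hi = max(int(np.ceil(radius_range_um[1] / px)), r_lo + 1)
    radii_px = np.arange(r_lo, r_hi + 1)

    cands = []  # (z, y, x, r_px, vote)
    for z in range(v.shape[0]):
        sl = v[z]
        if sl.max() <= 0:
            continue
        edges = feature.canny(sl / sl.max(), sigma=2.0)
        if not edges.any():
            continue
        h = transform.hough_circle(edges, radii_px)
        _acc, cx, cy, rad = transform.hough_circle_peaks(
            h, radii_px, total_num_peaks=max_nuclei_per_slice,
            min_xdistance=r_lo, min_ydistance=r_lo, threshold=vote_threshold)
        for a, x, y, r in zip(_acc, cx, cy, rad):
            cands.append((z, float(y), float(x), float(r), float(a)))
    if not cands:
        return []

    mean_r_px = float(np.mean([c[3] for c in cands]))

    # group across z by xy proximity (< one mean radius), greedy by vote
    cands.sort(key=lambda c: -c[4])
    groups: list[list[tuple]] = []
    for c in cands:
        placed = False
        for g in groups:
            gy = np.mean([m[1] for m in g])
            gx = np.mean([m[2] for m in g])
            zs = {m[0] for m in g}
            if np.hypot(c[1] - gy, c[2] - gx) < mean_r_px and c[0] not in zs:
                g.append(c)
                placed = True
                break
        if not placed:
            groups.append([c])

    single_slice_volume = v.shape[0] == 1
    rois: list[NucleusROI] = []
    for g in groups:
        if len(g) < 2 and not single_slice_volume:
            continue  # an isolated single-slice response is noise
        votes = np.array([m[4] for m in g])
        zs = np.array([m[0] for m in g], dtype=float)
        ys = np.array([m[1] for m in g])
        xs = np.array([m[2] for m in g])
        rs = np.array([m[3] for m in g])
        w = votes / votes.sum()
        zc = float(np.sum(w * zs))
        yc = float(np.sum(w * ys))
        xc = float(np.sum(w * xs))
        # XZ circle fit: radius profile r(z)^2 = R^2 - ((z-zc)*vz/vy_scale)^2;
        # for thin volumes fall back to half the slice extent
        r_xy = float(np.max(rs))
        z_half_um = max((zs.max() - zs.min() + 1) * vz / 2.0, vz / 2.0)
        if len(g) >= 3:
            def resid(p):
                R, z0 = p
                pred = np.sqrt(np.clip(R ** 2 - ((zs - z0) * vz) ** 2, 0, None))
                return pred - rs * px
            try:
                fit = optimize.least_squares(
                    resid, x0=[r_xy * px, zc], max_nfev=200)
                if fit.x[0] > 0:
                    z_half_um = float(abs(fit.x[0]))
                    zc = float(np.clip(fit.x[1], zs.min(), zs.max()))
            except Exception:  # pragma: no cover - fit pathologies
                pass
        rois.append(NucleusROI(
            cell_id=-1,
            centroid_um=(zc * vz, yc * vy, xc * vx),
            radius_xy_um=r_xy * px,
            radius_z_um=z_half_um,
            mean_gfp=float("nan"),
            status="ok",
        ))

    # merge duplicates closer than one mean radius (3D, xy-weighted)
    mean_r_um = mean_r_px * px
    merged: list[NucleusROI] = []
    for roi in sorted(rois, key=lambda r: -r.radius_xy_um):
        dup = False
        for m in merged:
            d = np.linalg.norm(np.subtract(roi.centroid_um, m.centroid_um))
            if d < mean_r_um:
                dup = True
                break
        if not dup:
            merged.append(roi)

    shape_um = np.asarray(v.shape) * np.asarray(volume.voxel_size)
    for i, roi in enumerate(merged):
        roi.cell_id = i
        roi.mean_gfp = _nuclear_mean(volume, roi)
        _z, y, x = roi.centroid_um
        r = roi.radius_xy_um
        if (y - r < 0 or x - r < 0 or y + r > shape_um[1] or x + r > shape_um[2]):
            roi.status = "cropped"
    return merged


def _nucleus_mask(volume: ImageStack, roi: NucleusROI) -> tuple:
    """Voxel slices and boolean ellipsoid mask for a nucleus ROI."""
    vsz = np.asarray(volume.voxel_size)
    c = np.asarray(roi.centroid_um) / vsz
    r = np.array([max(roi.radius_z_um, vsz[0]), roi.radius_xy_um, roi.radius_xy_um]) / vsz
    lo = np.maximum(np.floor(c - r).astype(int), 0)
    hi = np.minimum(np.ceil(c + r).astype(int) + 1, np.asarray(volume.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.ogrid[sl]
    q = sum(((g - cc) / rr) ** 2 for g, cc, rr in zip(grids, c, r))
    return sl, q <= 1.0


def _nuclear_mean(volume: ImageStack, roi: NucleusROI) -> float:
    sl, mask = _nucleus_mask(volume, roi)
    vox = volume.voxels[sl]
    if mask.any():
        return float(vox[mask].mean())
    return float("nan")


# --------------------------------------------------------------------------
# transcription-site detection
# --------------------------------------------------------------------------


def detect_ts(volume: ImageStack, nuclei: list[NucleusROI],
              k_sigma: float = 4.0, xy_tolerance_um: float | None = None,
              max_per_cell: int = 2) -> list[TSDetection]:
    """Detect intranuclear TS spots using the consecutive-z-slices rule.

    Per nucleus, per z slice, local maxima brighter than the nuclear
    background mean + ``k_sigma`` * sd become candidates; candidates in
    adjacent slices within ``xy_tolerance_um`` (default: one in-plane
    voxel) are chained, and chains spanning >= 2 consecutive slices become
    detections. At most ``max_per_cell`` (brightest) are retained — a cell
    shows one or two TSs (one per allele).
    """
    vz, vy, vx = volume.voxel_size
    if xy_tolerance_um is None:
        xy_tolerance_um = 0.5 * (vy + vx)
    out: list[TSDetection] = []
    ts_id = 0
    for roi in nuclei:
        if roi.status != "ok":
            logger.info("skipping nucleus %d with status %s", roi.cell_id, roi.status)
            continue
        sl, mask = _nucleus_mask(volume, roi)
        vox = volume.voxels[sl]
        inside = vox[mask]
        if inside.size < 8:
            continue
        # robust background: exclude the brightest tail (possible TS voxels)
        cut = np.percentile(inside, 90)
        bg = inside[inside <= cut]
        mu, sd = float(bg.mean()), float(bg.std())
        if sd == 0:
            sd = 1e-9
        thresh = mu + k_sigma * sd

        # per-slice candidates
        cands: dict[int, list[tuple[float, float, float]]] = {}
        for zi in range(vox.shape[0]):
            plane = np.where(mask[zi], vox[zi], 0.0)
            if plane.max() <= thresh:
                continue
            peaks = feature.peak_local_max(plane, min_distance=2,
                                           threshold_abs=thresh,
                                           exclude_border=False)
            if peaks.size:
                cands[zi] = [(float(y), float(x), float(plane[y, x]))
                             for y, x in peaks]

        # chain across adjacent z within xy tolerance
        tol_px = xy_tolerance_um / (0.5 * (vy + vx))
        chains: list[list[tuple[int, float, float, float]]] = []
        open_chains: list[list[tuple[int, float, float, float]]] = []
        for zi in sorted(cands):
            next_open = []
            used = set()
            for ch in open_chains:
                lz, ly, lx, _ = ch[-1]
                if zi - lz != 1:
                    chains.append(ch)
                    continue
                best_j, best_d = None, tol_px
                for j, (y, x, inten) in enumerate(cands[zi]):
                    if j in used:
                        continue
                    d = np.hypot(y - ly, x - lx)
                    if d <= best_d:
                        best_j, best_d = j, d
                if best_j is None:
                    chains.append(ch)
                else:
                    used.add(best_j)
                    y, x, inten = cands[zi][best_j]
                    ch.append((zi, y, x, inten))
                    next_open.append(ch)
            for j, (y, x, inten) in enumerate(cands[zi]):
                if j not in used:
                    next_open.append([(zi, y, x, inten)])
            open_chains = next_open
        chains.extend(open_chains)

        dets = []
        for ch in chains:
            if len(ch) < 2:
                continue
            peak = max(ch, key=lambda m: m[3])
            zi, y, x, inten = peak
            pos = ((sl[0].start + zi) * vz, (sl[1].start + y) * vy,
                   (sl[2].start + x) * vx)
            dets.append(TSDetection(
                ts_id=-1, cell_id=roi.cell_id, position_um=pos,
                peak_intensity=inten, z_extent=len(ch),
                snr=(inten - mu) / sd))
        dets.sort(key=lambda d: -d.peak_intensity)
        if len(dets) > max_per_cell:
            logger.info("cell %d: %d spot chains, keeping brightest %d",
                        roi.cell_id, len(dets), max_per_cell)
        for d in dets[:max_per_cell]:
            d.ts_id = ts_id
            ts_id += 1
            out.append(d)
    return out


# --------------------------------------------------------------------------
# cell classification
# --------------------------------------------------------------------------


def classify_cells(nuclei: list[NucleusROI], detections: list[TSDetection],
                   gfp_bounds: tuple[float, float] | None = None,
                   gfp_percentiles: tuple[float, float] = (5.0, 99.0),
                   session_id: int = 0) -> list[CellCall]:
    """Call each nucleus Arc+ / Arc- / ND.

    Exclusion precedes calling: cropped nuclei and nuclei whose mean GFP
    lies outside ``gfp_bounds`` (default: the [5th, 99th] percentile of all
    nuclear means) are ND even if they carry detections.
    """
    n_by_cell: dict[int, int] = {}
    for d in detections:
        n_by_cell[d.cell_id] = n_by_cell.get(d.cell_id, 0) + 1
    if gfp_bounds is None:
        means = np.array([r.mean_gfp for r in nuclei if np.isfinite(r.mean_gfp)])
        if means.size:
            gfp_bounds = tuple(np.percentile(means, gfp_percentiles))
        else:
            gfp_bounds = (-np.inf, np.inf)
    calls = []
    for roi in nuclei:
        usable = (roi.status == "ok"
                  and np.isfinite(roi.mean_gfp)
                  and gfp_bounds[0] <= roi.mean_gfp <= gfp_bounds[1])
        if not usable:
            calls.append(CellCall(roi.cell_id, session_id, ND, 0))
        elif n_by_cell.get(roi.cell_id, 0) >= 1:
            calls.append(CellCall(roi.cell_id, session_id, ARC_POS,
                                  min(n_by_cell[roi.cell_id], 2)))
        else:
            calls.append(CellCall(roi.cell_id, session_id, ARC_NEG, 0))
    return calls


# --------------------------------------------------------------------------
# two-Gaussian intensity threshold
# --------------------------------------------------------------------------


def two_gaussian_threshold(pos_intensities: np.ndarray,
                           neg_intensities: np.ndarray) -> float:
    """Equal-likelihood threshold between two fitted normal densities.

    Fits one normal per labelled group and returns the intersection of the
    two densities lying between the group means (the point where a sample
    is equally likely under either fit). Used to turn a manually labelled
    subset into a global intensity threshold.
    """
    pos = np.asarray(pos_intensities, dtype=float)
    neg = np.asarray(neg_intensities, dtype=float)
    if pos.size < 10 or neg.size < 10:
        raise ValueError("need >= 10 samples per group")
    m1, s1 = float(neg.mean()), float(neg.std(ddof=1))
    m2, s2 = float(pos.mean()), float(pos.std(ddof=1))
    if np.isclose(m1, m2):
        raise ValueError("inseparable: group means coincide")
    if m2 < m1:
        m1, m2, s1, s2 = m2, m1, s2, s1
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    # solve N(x; m1, s1) = N(x; m2, s2): quadratic in x
    a = 1.0 / (2 * s1 ** 2) - 1.0 / (2 * s2 ** 2)
    b = m2 / (s2 ** 2) - m1 / (s1 ** 2)
    c = m1 ** 2 / (2 * s1 ** 2) - m2 ** 2 / (2 * s2 ** 2) + np.log(s2 / s1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        # fall back to the root nearest the midpoint
        inside = roots[np.argsort(np.abs(roots - 0.5 * (m1 + m2)))][:1]
    if inside.size == 0:
        raise ValueError("inseparable: no density intersection found")
    return float(inside[0])


# --------------------------------------------------------------------------
# time-lapse TS linking
# --------------------------------------------------------------------------


def link_ts_timelapse(frames: list[list[TSDetection]], max_jump_um: float,
                      max_gap_frames: int = 1) -> list[dict]:
    """Greedy nearest-neighbor linking of per-frame TS detections.

    Each detection is assigned to the nearest open track within
    ``max_jump_um``; unmatched detections start new tracks. Tracks survive
    up to ``max_gap_frames`` missing frames (gap bridging); the returned
    trace is peak intensity per frame with NaN in gaps.

    Returns one dict per track: {"frames", "positions_um", "intensity"}.
    """
    tracks: list[dict] = []
    open_tracks: list[dict] = []
    for f_idx, dets in enumerate(frames):
        still_open = []
        for tr in open_tracks:
            if f_idx - tr["frames"][-1] > max_gap_frames + 1:
                tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        unmatched = list(range(len(dets)))
        # greedy: closest (track, det) pairs first
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = np.asarray(tr["positions_um"][-1])
            for j in unmatched:
                d = float(np.linalg.norm(last - np.asarray(dets[j].position_um)))
                if d <= max_jump_um:
                    pairs.append((d, ti, j))
        pairs.sort()
        used_t, used_d = set(), set()
        for d, ti, j in pairs:
            if ti in used_t or j in used_d:
                continue
            used_t.add(ti)
            used_d.add(j)
            tr = open_tracks[ti]
            tr["frames"].append(f_idx)
            tr["positions_um"].append(dets[j].position_um)
            tr["intensity"].append(dets[j].peak_intensity)
        for j in unmatched:
            if j not in used_d:
                open_tracks.append({
                    "frames": [f_idx],
                    "positions_um": [dets[j].position_um],
                    "intensity": [dets[j].peak_intensity],
                })
    tracks.extend(open_tracks)

    for tr in tracks:
        n = tr["frames"][-1] - tr["frames"][0] + 1
        trace = np.full(n, np.nan)
        for f, i in zip(tr["frames"], tr["intensity"]):
            trace[f - tr["frames"][0]] = i
        tr["trace"] = trace
    return tracks
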