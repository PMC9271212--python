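"""Rigid motion correction, cross-day alignment, autofluorescence
subtraction, frame averaging and two-ROI stitching.

Translation is estimated by phase cross-correlation against the red
(autofluorescence) channel or a reference frame; cross-day alignment adds an
exhaustive in-plane rotation search. Channel subtraction follows the
max-normalization convention: green/max(green) - red/max(red), clamped at
zero and rescaled to the green channel's original maximum.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .types import ImageStack, RigidTransform


class RegistrationError(RuntimeError):
    pass


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    d = np.linalg.norm(a) * np.linalg.norm(b)
    if d == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / d)


def apply_transform(stack: ImageStack, t: RigidTransform) -> ImageStack:
    """Apply an in-plane rotation followed by a (z, y, x) translation."""
    v = stack.voxels
    if t.rotation_deg != 0.0:
        v = ndimage.rotate(v, t.rotation_deg, axes=(1, 2), reshape=False,
                           order=1, mode="constant")
    if any(abs(s) > 0 for s in t.translation):
        v = ndimage.shift(v, t.translation, order=1, mode="constant")
    return ImageStack(np.clip(v, 0, None), stack.voxel_size, stack.channel,
                      stack.time_index)


def register_translation(moving: ImageStack | np.ndarray,
                         reference: ImageStack | np.ndarray,
                         upsample_factor: int = 10,
                         min_correlation: float = 0.1) -> RigidTransform:
    """Shift (rotation fixed at 0) that maps ``moving`` onto ``reference``.

    The returned translation, applied to ``moving``, maximizes overlap with
    the reference. Raises on structureless input or when the NCC after the
    candidate shift falls below ``min_correlation``.
    """
    mov = moving.voxels if isinstance(moving, ImageStack) else np.asarray(moving, float)
    ref = reference.voxels if isinstance(reference, ImageStack) else np.asarray(reference, float)
    if mov.shape != ref.shape:
        raise ValueError("moving and reference must share a shape")
    if np.ptp(mov) == 0 or np.ptp(ref) == 0:
        raise RegistrationError("no structure: flat correlation surface")
    shift, _err, _ph = phase_cross_correlation(ref, mov,
                                               upsample_factor=upsample_factor,
                                               normalization="phase")
    shifted = ndimage.shift(mov, shift, order=1, mode="constant")
    # score NCC over the valid overlap only (exclude the filled-in margin)
    sl = tuple(slice(int(np.ceil(max(s, 0))), n - int(np.ceil(max(-s, 0))) or None)
               for s, n in zip(shift, mov.shape))
    corr = _ncc(shifted[sl], ref[sl])
    if corr < min_correlation:
        raise RegistrationError(
            f"correlation {corr:.3f} below confidence floor {min_correlation}")
    if mov.ndim == 2:
        shift = np.concatenate([[0.0], shift])
    return RigidTransform(0.0, tuple(float(s) for s in shift), correlation=corr)


def align_sessions(volume_day2: ImageStack, volume_day1: ImageStack,
                   angle_search_deg: Sequence[float] | None = None,
                   min_correlation: float = 0.2) -> RigidTransform:
    """Cross-day rigid alignment: exhaustive in-plane rotation search with
    translation by phase cross-correlation at each candidate angle.

    Default angle grid is +-5 deg in 0.25 deg steps (head-fixed repositioning
    drift is small). Returns the transform mapping day-2 onto day-1.
    """
    if angle_search_deg is None:
        angle_search_deg = np.arange(-5.0, 5.0 + 1e-9, 0.25)
    v2, v1 = volume_day2.voxels, volume_day1.voxels
    if v2.shape != v1.shape:
        raise ValueError("volumes must share a shape")
    # score correlation over a border-cropped core: rotation with constant
    # fill leaves zeroed corners that would otherwise correlate spuriously
    crop = tuple(slice(int(0.2 * n), n - int(0.2 * n) or None)
                 for n in v1.shape)
    best: Optional[RigidTransform] = None
    for ang in angle_search_deg:
        rot = ndimage.rotate(v2, ang, axes=(1, 2), reshape=False, order=1,
                             mode="constant") if ang else v2
        try:
            t = register_translation(rot, v1, min_correlation=0.0)
        except RegistrationError:
            continue
        shifted = ndimage.shift(rot, t.translation, order=1, mode="constant")
        corr = _ncc(shifted[crop], v1[crop])
        if best is None or corr > best.correlation:
            best = RigidTransform(float(ang), t.translation, corr)
    if best is None or best.correlation < min_correlation:
        raise RegistrationError("alignment failed: best correlation below threshold")
    return best


def subtract_autofluorescence(green: ImageStack, red: ImageStack) -> ImageStack:
    """Remove autofluorescence by normalized channel subtraction.

    result = green/max(green) - red/max(red), negatives clamped to zero,
    rescaled back to the green channel's original maximum. If the red
    channel is empty the green stack is returned unchanged with a warning.
    """
    if green.shape != red.shape:
        raise ValueError("channels must be aligned and share a shape")
    gmax = float(green.voxels.max())
    rmax = float(red.voxels.max())
    if gmax <= 0:
        raise ValueError("green channel has no positive maximum")
    if rmax <= 0:
        warnings.warn("red channel is empty; returning green unchanged")
        return ImageStack(green.voxels.copy(), green.voxel_size, "green",
                          green.time_index)
    out = green.voxels / gmax - red.voxels / rmax
    np.clip(out, 0, None, out=out)
    return ImageStack(out * gmax, green.voxel_size, "green", green.time_index)


def average_frames(frames: Sequence[np.ndarray], register: bool = True) -> np.ndarray:
    """Per-pixel mean of 2D frames after registering each to the first.

    Mirrors the 45-frame-per-z-plane averaging used to raise TS SNR.
    """
    if len(frames) == 0:
        raise ValueError("no frames to average")
    first = np.asarray(frames[0], dtype=float)
    acc = first.copy()
    for f in frames[1:]:
        f = np.asarray(f, dtype=float)
        if f.shape != first.shape:
            raise ValueError("frames must share a shape")
        if register and np.ptp(f) > 0 and np.ptp(first) > 0:
            t = register_translation(f, first, min_correlation=0.0)
            f = ndimage.shift(f, t.translation[1:], order=1, mode="constant")
        acc += f
    return acc / len(frames)


def stitch_rois(vol_a: ImageStack, vol_b: ImageStack,
                min_correlation: float = 0.5,
                min_overlap_fraction: float = 0.1) -> ImageStack:
    """Stitch two same-shape ROIs into the union bounding box.

    The inter-ROI offset comes from phase cross-correlation (interpreted on
    the full wrap-around grid, picking the candidate with the best NCC over
    the implied overlap); the overlap region is blended by a linear ramp
    along the dominant offset axis.
    """
    a, b = vol_a.voxels, vol_b.voxels
    if a.shape != b.shape:
        raise ValueError("stitching expects same-shape ROIs")
    # plain (non-phase) correlation: robust when the overlap is partial
    shift, _e, _p = phase_cross_correlation(a, b, normalization=None)
    # resolve wrap-around sign ambiguity per axis by overlap NCC
    cands = [[]]
    for s, n in zip(shift, a.shape):
        s = int(round(s))
        alts = {s, s - n if s > 0 else s + n}
        cands = [c + [x] for c in cands for x in alts]
    best, best_corr = None, -2.0
    for off in cands:
        sl_a, sl_b = [], []
        ok = True
        overlap_vox = 1
        for s, n in zip(off, a.shape):
            lo_a, hi_a = max(s, 0), min(n + s, n)
            if hi_a - lo_a < 2:
                ok = False
                break
            overlap_vox *= hi_a - lo_a
            sl_a.append(slice(lo_a, hi_a))
            sl_b.append(slice(lo_a - s, hi_a - s))
        if not ok or overlap_vox < min_overlap_fraction * a.size:
            continue
        corr = _ncc(a[tuple(sl_a)], b[tuple(sl_b)])
        if corr > best_corr:
            best, best_corr = off, corr
    if best is None or best_corr < min_correlation:
        raise RegistrationError("no correlation peak above floor; ROIs may not overlap")

    off = np.asarray(best)  # position of b's origin relative to a's origin is -off? see below
    # b shifted by `off` aligns with a: voxel b[i] corresponds to a[i + off]
    origin = np.minimum(0, off)
    out_shape = tuple(int(max(n, n + o) - oo) for n, o, oo in zip(a.shape, off, origin))
    out = np.zeros(out_shape)
    wsum = np.zeros(out_shape)

    a_pos = tuple(slice(int(-oo), int(-oo) + n) for oo, n in zip(origin, a.shape))
    b_pos = tuple(slice(int(o - oo), int(o - oo) + n) for o, oo, n in zip(off, origin, b.shape))

    # linear ramp weights along the dominant offset axis
    ax = int(np.argmax(np.abs(off))) if np.any(off) else 0
    ramp_a = np.ones(a.shape)
    ramp_b = np.ones(b.shape)
    n_ax = a.shape[ax]
    w = np.linspace(0, 1, n_ax)
    shape1 = [1] * a.ndim
    shape1[ax] = n_ax
    if off[ax] >= 0:
        ramp_a *= (1 - w).reshape(shape1)
        ramp_b *= w.reshape(shape1)
    else:
        ramp_a *= w.reshape(shape1)
        ramp_b *= (1 - w).reshape(shape1)
    ramp_a += 1e-6
    ramp_b += 1e-6

    out[a_pos] += a * ramp_a
    wsum[a_pos] += ramp_a
    out[b_pos] += b * ramp_b
    wsum[b_pos] += ramp_b
    out = np.where(wsum > 0, out / np.where(wsum > 0, wsum, 1.0), 0.0)
    return ImageStack(out, vol_a.voxel_size, vol_a.channel)
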