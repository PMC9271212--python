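"""Synthetic ground-truth generators for every pipeline input.

Each generator emulates one class of raw data the analysis consumes:

* two-channel two-photon volumes with nuclear-GFP disks, diffraction-limited
  transcription-site (TS) spots and shared autofluorescent structures;
* smFISH particle fields with single mRNAs and multi-copy TSs in two
  spectrally matched channels;
* AR(1)-kernel calcium traces driven by Poisson/theta-burst spiking linked
  to position on a 3-m virtual linear track;
* longitudinal Arc-call tables drawn from a two-state Markov process;
* mouse-silhouette mask videos with planted freezing bouts.

All generators are deterministic per seed and return a ground-truth record
sufficient to score every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ARC_NEG, ARC_POS, ND, ImageStack, ParticleFit, PositionTrace

# --------------------------------------------------------------------------
# two-photon volume generator
# --------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Imaging conditions of a two-photon Arc-transcription volume.

    Defaults reproduce the acquisition geometry of a 250 x 250 x 20 um
    hippocampal volume sampled at 1024 x 1024 x 81 voxels. Tests and the
    acceptance script pass smaller volumes explicitly.
    """

    volume_shape: tuple[int, int, int] = (81, 1024, 1024)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.25, 0.244, 0.244)  # um
    n_nuclei: int = 100
    nucleus_radius_um: tuple[float, float] = (4.0, 0.4)  # mean, sd
    nuclear_gfp_level: tuple[float, float] = (math.log(100.0), 0.25)  # lognormal mu, sigma
    ts_fraction: float = 0.23
    ts_per_cell: int = 1
    ts_amplitude: tuple[float, float] = (400.0, 60.0)  # mean, sd above nucleus
    psf_sigma_um: tuple[float, float, float] = (1.0, 0.25, 0.25)  # (z, y, x)
    autofluorescence_density: float = 20.0  # structures per volume
    autofluorescence_bleed: float = 1.0  # alpha into green after max-normalization
    poisson_scale: float = 0.0  # 0 disables shot noise
    read_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0 or self.autofluorescence_density < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must lie in [0, 1]")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma must be positive")
        if self.ts_per_cell not in (1, 2):
            raise ValueError("ts_per_cell must be 1 or 2")
        extent = np.asarray(self.volume_shape) * np.asarray(self.voxel_size)
        if self.n_nuclei > 0 and np.min(extent[1:]) < 2 * self.nucleus_radius_um[0]:
            raise ValueError("volume too small to contain a nucleus")


@dataclass
class GroundTruth:
    """Latent variables of a generated scene."""

    nucleus_centroids_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    nucleus_radius_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    nucleus_gfp: np.ndarray = field(default_factory=lambda: np.empty(0))
    ts_present: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    ts_coordinates_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    ts_parent: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ts_amplitude: np.ndarray = field(default_factory=lambda: np.empty(0))


def _add_gaussian_spot(vol: np.ndarray, center_vox: np.ndarray,
                       sigma_vox: np.ndarray, amplitude: float) -> None:
    """Add A*exp(-sum((i-c)^2 / 2 s^2)) within a +-4 sigma crop."""
    lo = np.maximum(np.floor(center_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1,
                    np.asarray(vol.shape))
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_vox, sigma_vox))
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


def gen_twophoton_stack(config: SceneConfig) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render a two-channel volume: green = nuclei + TS spots + bleed-through
    autofluorescence + noise; red = autofluorescence + noise.

    The red-channel structures reappear in the green channel (scaled by
    ``autofluorescence_bleed`` after per-channel max normalization) so that
    channel subtraction removes them exactly in the noise-free limit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    vsz = np.asarray(config.voxel_size)
    extent_um = np.asarray(shape) * vsz

    green = np.zeros(shape, dtype=float)
    af = np.zeros(shape, dtype=float)
    truth = GroundTruth()

    # --- nuclei: soft-edged filled spheres of nuclear GFP -----------------
    n = config.n_nuclei
    radii = np.clip(rng.normal(*config.nucleus_radius_um, size=n), 1.0, None)
    levels = rng.lognormal(*config.nuclear_gfp_level, size=n)
    centroids = np.empty((n, 3))
    def _z_draw(r: float) -> float:
        # keep nuclei inside z when the volume is thick enough; otherwise
        # (thin volumes) center them so only the caps crop
        if extent_um[0] > 2 * r:
            return rng.uniform(r, extent_um[0] - r)
        return extent_um[0] / 2.0

    for i in range(n):
        r = radii[i]
        centroids[i] = (_z_draw(r),
                        rng.uniform(r, extent_um[1] - r),
                        rng.uniform(r, extent_um[2] - r))
    # reject strongly overlapping placements with a few resampling passes
    for _ in range(20):
        moved = False
        for i in range(n):
            d = np.linalg.norm((centroids - centroids[i])[np.arange(n) != i] * 1.0, axis=1)
            if d.size and d.min() < 1.6 * radii[i]:
                r = radii[i]
                centroids[i] = (_z_draw(r),
                                rng.uniform(r, extent_um[1] - r),
                                rng.uniform(r, extent_um[2] - r))
                moved = True
        if not moved:
            break

    nuc = np.zeros(shape, dtype=float)
    zz, yy, xx = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, vsz)),
                             indexing="ij")
    for i in range(n):
        r = radii[i]
        c = centroids[i]
        m = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r ** 2
        nuc[m] = np.maximum(nuc[m], levels[i])
    if n:
        nuc = ndimage.gaussian_filter(nuc, sigma=1.0)  # soft edges, ~1 voxel
    green += nuc

    truth.nucleus_centroids_um = centroids
    truth.nucleus_radius_um = radii
    truth.nucleus_gfp = levels

    # --- transcription sites: 3D Gaussian spots inside nuclei -------------
    ts_present = rng.random(n) < config.ts_fraction
    psf_vox = np.asarray(config.psf_sigma_um) / vsz
    ts_pos, ts_parent, ts_amp = [], [], []
    for i in np.flatnonzero(ts_present):
        for _ in range(config.ts_per_cell):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = 0.6 * radii[i] * rng.random() ** (1 / 3)
            pos = centroids[i] + u * rad
            pos[0] = np.clip(pos[0], 0, extent_um[0] - 1e-9)
            amp = max(rng.normal(*config.ts_amplitude), 10.0)
            _add_gaussian_spot(green, pos / vsz, psf_vox, amp)
            ts_pos.append(pos)
            ts_parent.append(i)
            ts_amp.append(amp)
    truth.ts_present = ts_present
    truth.ts_coordinates_um = np.asarray(ts_pos).reshape(-1, 3)
    truth.ts_parent = np.asarray(ts_parent, dtype=int)
    truth.ts_amplitude = np.asarray(ts_amp)

    # --- autofluorescent structures shared between channels ---------------
    n_af = rng.poisson(config.autofluorescence_density)
    for _ in range(n_af):
        c = rng.uniform(0, extent_um)
        s = rng.uniform(0.5, 2.0, size=3)  # um, blobby
        amp = rng.uniform(50.0, 200.0)
        _add_gaussian_spot(af, c / vsz, s / vsz, amp)

    red = af.copy()
    if af.max() > 0 and green.max() > 0:
        # bleed scaled so green/max(green) - red/max(red) cancels structures
        green = green + config.autofluorescence_bleed * (green.max() / af.max()) * af

    # --- noise -------------------------------------------------------------
    for vol in (green, red):
        if config.poisson_scale > 0:
            vol[:] = rng.poisson(vol * config.poisson_scale) / config.poisson_scale
        if config.read_noise_sd > 0:
            vol += rng.normal(0, config.read_noise_sd, size=vol.shape)
        np.clip(vol, 0, None, out=vol)

    gs = ImageStack(green, tuple(config.voxel_size), channel="green")
    rs = ImageStack(red, tuple(config.voxel_size), channel="red")
    return gs, rs, truth


def gen_frame_series(base: np.ndarray, n_frames: int, shift_sd_px: float,
                     noise_sd: float, seed: int = 0) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-frame rigid-motion series of a 2D image (breathing/cardiac jitter).

    Returns the frames and the planted integer (dy, dx) shifts.
    """
    rng = np.random.default_rng(seed)
    shifts = np.round(rng.normal(0, shift_sd_px, size=(n_frames, 2))).astype(int)
    shifts[0] = 0  # first frame is the registration reference
    frames = []
    for k in range(n_frames):
        f = np.roll(base, tuple(shifts[k]), axis=(0, 1)).astype(float)
        if noise_sd > 0:
            f = f + rng.normal(0, noise_sd, size=f.shape)
        frames.append(np.clip(f, 0, None))
    return frames, shifts


# --------------------------------------------------------------------------
# smFISH field generator
# --------------------------------------------------------------------------


def gen_smfish_field(
    n_singles: int,
    n_ts: int,
    copy_dist=lambda rng, size: np.full(size, 15),
    coloc_offset_um: float = 0.1,
    field_um: tuple[float, float, float] = (8.0, 40.0, 40.0),
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.3, 0.9),  # (sx, sy, sz)
    ts_width_factor: float = 1.4,
    single_intensity_cv: float = 0.2,
    n_decoys_b: int = 0,
    seed: int = 0,
):
    """Two spectrally matched smFISH channels of single mRNAs and TSs.

    Singles carry unit-scale integrated intensity (lognormal around 1);
    each TS carries copy_number x median(single intensity). Channel B
    repeats channel A positions displaced by an isotropic offset of
    magnitude ``coloc_offset_um``, plus ``n_decoys_b`` unmatched decoy TSs.

    Returns (channel_a, channel_b, truth): particle lists as lists of
    ParticleFit, and a dict with planted classes, copy numbers and positions.
    """
    if n_singles < 0 or n_ts < 0 or n_decoys_b < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    copies = np.asarray(copy_dist(rng, n_ts), dtype=float)
    if copies.size and np.any(copies < 1):
        raise ValueError("copy numbers must be >= 1")

    sigma = np.asarray(psf_sigma_um)  # (sx, sy, sz)
    svol = float(np.prod(sigma))

    single_I = np.exp(rng.normal(0.0, single_intensity_cv, size=n_singles))
    med = float(np.median(single_I)) if n_singles else 1.0
    ts_I = copies * med

    def _mk(pos, intensity, width_mult, channel):
        s = tuple(sigma * width_mult)
        amp = intensity / (svol * width_mult ** 3)
        return ParticleFit(position_um=tuple(pos), amplitude=float(amp),
                           sigma_um=s, channel=channel)

    ext = np.asarray(field_um)
    pos_single = rng.uniform(0, ext, size=(n_singles, 3))
    pos_ts = rng.uniform(0, ext, size=(n_ts, 3))

    chan_a = [_mk(p, i, 1.0, "cds_550") for p, i in zip(pos_single, single_I)]
    chan_a += [_mk(p, i, ts_width_factor, "cds_550") for p, i in zip(pos_ts, ts_I)]

    u = rng.normal(size=(n_singles + n_ts, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    off = u * coloc_offset_um
    chan_b = [_mk(p + off[j], i, 1.0, "pbs_647")
              for j, (p, i) in enumerate(zip(pos_single, single_I))]
    chan_b += [_mk(p + off[n_singles + j], i, ts_width_factor, "pbs_647")
               for j, (p, i) in enumerate(zip(pos_ts, ts_I))]
    decoy_pos = rng.uniform(0, ext, size=(n_decoys_b, 3))
    chan_b += [_mk(p, med * 10.0, ts_width_factor, "pbs_647") for p in decoy_pos]

    truth = {
        "single_positions_um": pos_single,
        "ts_positions_um": pos_ts,
        "copy_number": copies,
        "single_intensity": single_I,
        "ts_intensity": ts_I,
        "single_median": med,
        "decoy_positions_um": decoy_pos,
    }
    return chan_a, chan_b, truth


# --------------------------------------------------------------------------
# calcium session generator
# --------------------------------------------------------------------------


@dataclass
class CalciumTruth:
    spikes: np.ndarray  # (n_cells, n_frames) planted amplitudes
    theta_event_frames: list  # per cell: frames of bursts inside theta trains
    burst_frames: list  # per cell: all planted burst frames
    place_field_center_m: np.ndarray  # NaN for non-place cells
    position: PositionTrace
    noise_sd: float
    decay_tau_s: float


def gen_calcium_session(
    n_cells: int,
    duration_s: float,
    frame_rate_hz: float = 30.0,
    theta_burst_rate_hz: float | np.ndarray = 0.1,
    burst_amplitude: float = 1.0,
    bursts_per_theta_event: int = 3,
    interburst_ms: float = 125.0,
    background_rate_hz: float = 0.05,
    track_length_m: float = 3.0,
    place_cell_fraction: float = 0.0,
    place_rate_hz: float = 1.0,
    place_field_sd_m: float = 0.15,
    place_field_centers_m: Optional[np.ndarray] = None,
    decay_tau_s: float = 0.5,
    noise_sd: float = 0.05,
    baseline: float = 0.0,
    seed: int = 0,
):
    """Simulate dF/F traces from planted spiking on a virtual linear track.

    Spiking has three components: sparse background Poisson spikes, planted
    theta-burst trains (bursts of amplitude ``burst_amplitude`` repeated at
    ``interburst_ms`` start-to-start spacing, inside the 100-167 ms theta
    band by default), and — for place cells — position-locked Poisson firing
    under a Gaussian place field. Spikes are convolved with a single-
    exponential AR(1) calcium kernel (decay ``decay_tau_s``) and Gaussian
    noise is added. The position trace alternates stationary (< 0.5 cm/s)
    and walking epochs with teleports at the track end.

    Returns (dff, position, truth): dff is (n_cells, n_frames).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    dt = 1.0 / frame_rate_hz

    theta_rate = np.broadcast_to(np.asarray(theta_burst_rate_hz, dtype=float),
                                 (n_cells,)).copy()

    # ---- position: alternating stationary / walking epochs ---------------
    pos = np.zeros(n_frames)
    speeds = np.zeros(n_frames)
    t = 0
    walking = False
    x = 0.0
    while t < n_frames:
        dur = int(round(rng.uniform(2.0, 6.0) * frame_rate_hz))
        v = rng.uniform(5.0, 20.0) / 100.0 if walking else 0.0  # m/s
        for k in range(t, min(t + dur, n_frames)):
            x = (x + v * dt) % track_length_m
            pos[k] = x
            speeds[k] = v
        t += dur
        walking = not walking
    position = PositionTrace(pos, frame_rate=frame_rate_hz,
                             track_length_m=track_length_m)

    # ---- spikes -----------------------------------------------------------
    spikes = np.zeros((n_cells, n_frames))
    theta_event_frames: list[list[int]] = []
    burst_frames: list[list[int]] = []
    if place_field_centers_m is not None:
        centers = np.asarray(place_field_centers_m, dtype=float)
        is_place = np.isfinite(centers)
    else:
        is_place = rng.random(n_cells) < place_cell_fraction
        centers = np.where(is_place,
                           rng.uniform(0.2, track_length_m - 0.2, size=n_cells),
                           np.nan)
    gap = max(int(round(interburst_ms / 1000.0 * frame_rate_hz)), 1)

    for c in range(n_cells):
        tb: list[int] = []
        bf: list[int] = []
        # background singles
        bg = np.flatnonzero(rng.random(n_frames) < background_rate_hz * dt)
        for f in bg:
            spikes[c, f] += burst_amplitude
            bf.append(int(f))
        # theta-burst trains; rejection-sample starts so trains never
        # interleave (interleaving would corrupt the planted interval band)
        n_events = rng.poisson(theta_rate[c] * duration_s)
        train_len = (bursts_per_theta_event - 1) * gap
        taken: list[tuple[int, int]] = []
        for _ in range(n_events):
            f0 = None
            for _try in range(50):
                cand = int(rng.integers(0, max(n_frames - train_len, 1)))
                if all(cand + train_len + 2 * gap < a or cand > b + 2 * gap
                       for a, b in taken):
                    f0 = cand
                    break
            if f0 is None:
                continue
            taken.append((f0, f0 + train_len))
            frames = [int(f0 + j * gap) for j in range(bursts_per_theta_event)]
            frames = [f for f in frames if f < n_frames]
            for j, f in enumerate(frames):
                spikes[c, f] += burst_amplitude
                bf.append(f)
                if j >= 1:  # a burst whose predecessor gap is in-band
                    tb.append(f)
        # place-field firing while walking
        if is_place[c]:
            lam = place_rate_hz * dt * np.exp(
                -0.5 * ((pos - centers[c]) / place_field_sd_m) ** 2)
            lam[speeds <= 0.005] = 0.0
            pf = np.flatnonzero(rng.random(n_frames) < lam)
            for f in pf:
                spikes[c, f] += burst_amplitude
                bf.append(int(f))
        theta_event_frames.append(sorted(tb))
        burst_frames.append(sorted(set(bf)))

    # ---- convolve with AR(1) kernel, add baseline + noise -----------------
    g = math.exp(-dt / decay_tau_s)
    dff = np.empty_like(spikes)
    for c in range(n_cells):
        acc = 0.0
        for f in range(n_frames):
            acc = acc * g + spikes[c, f]
            dff[c, f] = acc
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, size=dff.shape)
    dff = dff + baseline

    truth = CalciumTruth(
        spikes=spikes,
        theta_event_frames=theta_event_frames,
        burst_frames=burst_frames,
        place_field_center_m=centers,
        position=position,
        noise_sd=noise_sd,
        decay_tau_s=decay_tau_s,
    )
    return dff, position, truth


# --------------------------------------------------------------------------
# longitudinal Arc-call table generator
# --------------------------------------------------------------------------


@dataclass
class LongitudinalConfig:
    """Markov model of session-to-session Arc (re)expression.

    A cell active in session k reactivates in k+1 with probability
    ``persistence``; an inactive cell activates with the session's marginal
    ``activation_prob``. Setting persistence equal to the activation
    probability makes the chain memoryless (overlap at chance).
    """

    n_cells: int = 500
    n_sessions: int = 5
    activation_prob: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    persistence: float = 0.2
    nd_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.activation_prob) + [self.persistence, self.nd_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.activation_prob) < self.n_sessions:
            raise ValueError("activation_prob shorter than n_sessions")


def gen_longitudinal_table(config: LongitudinalConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-cell Arc-state sequences and overlay independent ND calls.

    Returns (table, true_state): a long-format call table with columns
    (cell_id, session, call) and the latent boolean state array
    (n_cells, n_sessions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s = config.n_cells, config.n_sessions
    state = np.zeros((n, s), dtype=bool)
    state[:, 0] = rng.random(n) < config.activation_prob[0]
    for k in range(1, s):
        p = np.where(state[:, k - 1], config.persistence, config.activation_prob[k])
        state[:, k] = rng.random(n) < p
    nd = rng.random((n, s)) < config.nd_prob

    rows = []
    for c in range(n):
        for k in range(s):
            call = ND if nd[c, k] else (ARC_POS if state[c, k] else ARC_NEG)
            rows.append((c, k, call))
    table = pd.DataFrame(rows, columns=["cell_id", "session", "call"])
    return table, state


# --------------------------------------------------------------------------
# behavior mask generator
# --------------------------------------------------------------------------


def gen_behavior_masks(
    duration_s: float,
    fps: float = 10.0,
    freezing_intervals: Sequence[tuple[float, float]] = (),
    jitter_px: float = 3.0,
    frame_shape: tuple[int, int] = (64, 64),
    body_radius_px: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Mouse-silhouette mask video with planted freezing bouts.

    Inside a freezing interval consecutive masks are identical; outside,
    the body translates by ~``jitter_px`` per frame. Intervals must be
    disjoint and lie within [0, duration].
    """
    ivs = sorted(freezing_intervals)
    for (a, b) in ivs:
        if not (0.0 <= a <= b <= duration_s):
            raise ValueError("freezing interval outside [0, duration]")
    for (a0, b0), (a1, _b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("overlapping freezing intervals")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    masks = np.zeros((n_frames, h, w), dtype=bool)
    frozen = np.zeros(n_frames, dtype=bool)
    for (a, b) in ivs:
        frozen[int(round(a * fps)):int(round(b * fps))] = True
    for f in range(n_frames):
        # a pair (f-1, f) is still only when both frames are inside the
        # bout, so a bout of b-a seconds yields exactly (b-a)*fps still
        # frames end to end
        if f > 0 and not (frozen[f] and frozen[f - 1]):
            step = rng.normal(0, 1, size=2)
            nrm = np.linalg.norm(step)
            if nrm > 0:
                step = step / nrm * jitter_px
            cy = float(np.clip(cy + step[0], body_radius_px, h - body_radius_px))
            cx = float(np.clip(cx + step[1], body_radius_px, w - body_radius_px))
        # an ellongated body: ellipse with 2:1 aspect
        masks[f] = (((yy - cy) / (2 * body_radius_px)) ** 2 +
                    ((xx - cx) / body_radius_px) ** 2) <= 1.0
    truth = {"freezing_intervals_s": list(ivs), "frozen_frames": frozen,
             "fps": fps}
    return masks, truth
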