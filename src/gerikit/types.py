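"""Shared containers for the imaging/analysis pipeline.

Conventions used throughout the package:

* voxel arrays are ordered (z, y, x), 0-based indices;
* physical positions are in micrometres, computed as index * voxel_size;
* per-cell/per-session call tables are pandas DataFrames with columns
  ``cell_id``, ``session`` and ``call`` in {"arc_pos", "arc_neg", "nd"}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ARC_POS = "arc_pos"
ARC_NEG = "arc_neg"
ND = "nd"
CALLS = (ARC_POS, ARC_NEG, ND)


@dataclass
class ImageStack:
    """A single-channel 3D voxel volume with physical voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    voxel_size : tuple of float
        Micrometres per voxel along (z, y, x).
    channel : str
        "green" (GFP / nuclear + TS signal) or "red" (autofluorescence).
    time_index : int, optional
        Frame number when the stack is one time point of a series.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.25, 0.244, 0.244)
    channel: str = "green"
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("ImageStack expects a 3D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def to_um(self, index: np.ndarray) -> np.ndarray:
        """Convert (z, y, x) voxel indices to micrometre coordinates."""
        return np.asarray(index, dtype=float) * np.asarray(self.voxel_size)


@dataclass
class RigidTransform:
    """In-plane rotation plus a 3D translation, both in voxel units."""

    rotation_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    correlation: float = float("nan")  # NCC at the optimum, for QC

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            translation=tuple(-t for t in self.translation),
            correlation=self.correlation,
        )


@dataclass
class NucleusROI:
    cell_id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    radius_xy_um: float
    radius_z_um: float
    mean_gfp: float
    status: str = "ok"  # ok | cropped | too_dim | too_bright


@dataclass
class TSDetection:
    ts_id: int
    cell_id: int
    position_um: tuple[float, float, float]
    peak_intensity: float
    z_extent: int
    snr: float


@dataclass
class CellCall:
    cell_id: int
    session_id: int
    call: str
    n_ts: int = 0

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.call == ARC_POS and self.n_ts not in (1, 2):
            raise ValueError("arc_pos requires n_ts in {1, 2}")
        if self.call != ARC_POS and self.n_ts != 0:
            raise ValueError("non-positive calls carry n_ts = 0")


@dataclass
class ParticleFit:
    """A 3D-Gaussian-fitted diffraction-limited spot."""

    position_um: tuple[float, float, float]  # (z, y, x), subvoxel
    amplitude: float
    sigma_um: tuple[float, float, float]  # (sx, sy, sz)
    background: float = 0.0
    channel: str = "cds_550"
    residual: float = float("nan")

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if any(s <= 0 for s in self.sigma_um):
            raise ValueError("sigma must be positive per axis")


@dataclass
class CalciumTrace:
    dff: np.ndarray
    frame_rate: float = 30.0
    baseline: Optional[np.ndarray] = None
    baseline_sd: float = float("nan")
    cell_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class SpikeTrain:
    amplitudes: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < -1e-12):
            raise ValueError("spike amplitudes must be non-negative")
        self.amplitudes = np.clip(self.amplitudes, 0.0, None)


@dataclass
class BurstEvent:
    start_frame: int
    end_frame: int  # inclusive
    total_amplitude: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")


@dataclass
class PositionTrace:
    """Position along a linear virtual track.

    position_m wraps at the track end (teleport back to the start);
    speed is stored in cm/s at the imaging frame rate.
    """

    position_m: np.ndarray
    frame_rate: float = 30.0
    track_length_m: float = 3.0

    def __post_init__(self) -> None:
        self.position_m = np.asarray(self.position_m, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def speed_cm_s(self) -> np.ndarray:
        """Instantaneous speed, teleport jumps treated as zero displacement."""
        d = np.diff(self.position_m, prepend=self.position_m[0])
        # a teleport moves the mouse most of the track length in one frame
        d[np.abs(d) > 0.5 * self.track_length_m] = 0.0
        return np.abs(d) * self.frame_rate * 100.0


@dataclass
class RateMap:
    bin_edges_m: np.ndarray
    occupancy_s: np.ndarray
    rate: np.ndarray  # NaN where occupancy == 0
    smoothing_bins: float = 2.0

    @property
    def bin_centers_m(self) -> np.ndarray:
        e = np.asarray(self.bin_edges_m)
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class FreezingResult:
    nonoverlap_px: np.ndarray  # per consecutive-frame pair
    bouts_s: list  # list of (start_s, end_s)
    freezing_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.freezing_rate <= 1.0:
            raise ValueError("freezing_rate must lie in [0, 1]")
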