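"""File-format adapters: multi-page TIFF stacks, JSON transforms, CSV
tables and traces.

Stacks are written one file per channel in ZYX page order (16-bit by
default); call tables and traces are plain CSV with a header row (traces:
rows = frames, columns = cells).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import ImageStack, RigidTransform


def write_stack(path: str | Path, stack: ImageStack, dtype=np.uint16) -> None:
    v = stack.voxels
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        v = np.clip(np.round(v), info.min, info.max)
    tifffile.imwrite(str(path), v.astype(dtype),
                     metadata={"voxel_size_um": list(stack.voxel_size),
                               "channel": stack.channel})


def read_stack(path: str | Path,
               voxel_size: tuple[float, float, float] = (0.25, 0.244, 0.244),
               channel: str = "green") -> ImageStack:
    v = tifffile.imread(str(path))
    if v.ndim == 2:
        v = v[None]
    return ImageStack(np.asarray(v, dtype=float), voxel_size, channel)


def write_transform(path: str | Path, t: RigidTransform) -> None:
    Path(path).write_text(json.dumps({
        "rotation_deg": t.rotation_deg,
        "translation": list(t.translation),
        "correlation": None if np.isnan(t.correlation) else t.correlation,
    }, indent=2))


def read_transform(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(d["rotation_deg"], tuple(d["translation"]),
                          d.get("correlation") or float("nan"))


def write_traces(path: str | Path, dff: np.ndarray) -> None:
    """Traces CSV: rows = frames, columns = cells."""
    df = pd.DataFrame(np.asarray(dff).T,
                      columns=[f"cell_{i}" for i in range(len(dff))])
    df.to_csv(path, index_label="frame")


def read_traces(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, index_col="frame")
    return df.to_numpy().T


def write_calls(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
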