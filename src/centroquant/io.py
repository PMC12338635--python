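"""Reading and writing stacks, tables and configuration.

Stacks are multi-page TIFFs in (channel, z, y, x) order with a YAML sidecar
(`<stem>.yaml`) recording channel names, pixel size, z step and bit depth.
Coordinates everywhere are 0-based (y, x) raster order with pixel centers
at integer positions.  Tables travel as CSV; simulation parameters as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CurationList, LabelMap
from .simgen import ImageStack, SimParams

__all__ = [
    "write_stack",
    "read_stack",
    "write_labelmap",
    "read_curation",
    "write_params",
    "read_params",
    "read_rois",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )
    sidecar = {
        "channels": list(stack.channels),
        "pixel_size_xy_um": float(stack.pixel_size_xy),
        "z_step_um": float(stack.z_step),
        "bit_depth": int(stack.bit_depth),
        "stack_id": stack.stack_id,
        "axes": "CZYX",
        "coordinates": "0-based (y, x), pixel centers at integers",
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"calibration sidecar missing: {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    if data.ndim == 3:  # single channel written without channel axis
        data = data[None]
    return ImageStack(
        data=np.asarray(data),
        channels=tuple(meta["channels"]),
        pixel_size_xy=float(meta["pixel_size_xy_um"]),
        z_step=float(meta["z_step_um"]),
        bit_depth=int(meta["bit_depth"]),
        stack_id=str(meta.get("stack_id", path.stem)),
    )


def write_labelmap(labelmap: LabelMap, stem: str | Path) -> tuple[Path, Path]:
    """Write a label map as 16-bit label TIFF + region-table CSV."""
    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    csv = stem.with_suffix(".csv")
    tifffile.imwrite(tif, labelmap.labels.astype(np.uint16))
    labelmap.table.to_csv(csv, index=False)
    return tif, csv


def read_curation(path: str | Path) -> CurationList:
    """Read a curation list CSV with columns (label, reason)."""
    df = pd.read_csv(path)
    if not {"label", "reason"} <= set(df.columns):
        raise ValueError("curation CSV needs 'label' and 'reason' columns")
    return CurationList.from_frame(df)


def write_params(params: SimParams, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    return path


def read_params(path: str | Path) -> SimParams:
    return SimParams.from_dict(yaml.safe_load(Path(path).read_text()))


def read_rois(path: str | Path):
    """Read densitometry ROIs from CSV (lane, target, x, y, width, height)."""
    from .densito import BandROI

    df = pd.read_csv(path)
    needed = {"lane", "target", "x", "y", "width", "height"}
    if not needed <= set(df.columns):
        raise ValueError(f"ROI CSV needs columns {sorted(needed)}")
    return [
        BandROI(
            lane=str(r.lane),
            target=str(r.target),
            x=int(r.x),
            y=int(r.y),
            width=int(r.width),
            height=int(r.height),
        )
        for r in df.itertuples(index=False)
    ]
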