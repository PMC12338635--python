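"""Western-blot densitometry: fixed-ROI band measurement and normalization.

Reproduces the manual ImageJ workflow: a rectangle of fixed size is drawn
around every band (bound protein and loading control alike), the mean grey
value is measured, a background rectangle of the same size directly below
each band is subtracted, each band is divided by its loading control, and
finally every lane is divided by the average of the wild-type lanes — so
the wild-type normalized values average exactly 1.

ROIs are explicit inputs (lane, target, x, y, width, height); there is no
automatic band detection.  Film scans put dark bands on a light field, so
an ``invert`` option measures ``white_level - image`` instead; its use is
recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["BandROI", "measure_band", "measure_lanes", "normalize_bands"]


@dataclass(frozen=True)
class BandROI:
    """One measurement rectangle: ``target`` is 'band' or 'loading'."""

    lane: str
    target: str
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.target not in ("band", "loading"):
            raise ValueError("target must be 'band' or 'loading'")
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have positive width and height")


def _rect_mean(image: np.ndarray, x: int, y: int, w: int, h: int) -> float:
    H, W = image.shape
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(
            f"rectangle (x={x}, y={y}, w={w}, h={h}) lies outside the "
            f"{H}x{W} image"
        )
    return float(np.asarray(image[y : y + h, x : x + w], dtype=float).mean())


def measure_band(
    image: np.ndarray,
    roi: BandROI,
    background_offset: int | None = None,
) -> tuple[float, float, float]:
    """Mean grey values for one band and its below-band background.

    The background rectangle is the band rectangle translated straight down
    by ``background_offset`` pixels (default: its own height, i.e. the
    region immediately below the band).  Returns (raw_mean,
    background_mean, net); a negative net is returned as-is.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("blot image must be 2-D grayscale")
    off = roi.height if background_offset is None else int(background_offset)
    raw = _rect_mean(image, roi.x, roi.y, roi.width, roi.height)
    bg = _rect_mean(image, roi.x, roi.y + off, roi.width, roi.height)
    return raw, bg, raw - bg


def _check_fixed_size(rois: Sequence[BandROI]) -> None:
    sizes = {(r.width, r.height) for r in rois}
    if len(sizes) > 1:
        raise ValueError(
            f"all rectangles in one analysis must share a fixed size; got {sizes}"
        )


def measure_lanes(
    image: np.ndarray,
    rois: Iterable[BandROI],
    invert: bool = False,
    background_offset: int | None = None,
) -> pd.DataFrame:
    """Measure every lane's band and loading-control rectangles.

    Returns one row per lane with raw/background/net for both targets.
    ``invert=True`` measures ``max_level - image`` (dark bands on light
    film become positive signal); the flag is recorded in the frame attrs.
    """
    rois = list(rois)
    _check_fixed_size(rois)
    image = np.asarray(image, dtype=float)
    if invert:
        white = 255.0 if image.max() <= 255 else 65535.0
        image = white - image
    by_lane: dict[str, dict[str, BandROI]] = {}
    for r in rois:
        slot = by_lane.setdefault(str(r.lane), {})
        if r.target in slot:
            raise ValueError(f"duplicate {r.target!r} ROI for lane {r.lane!r}")
        slot[r.target] = r
    rows = []
    for lane, slot in by_lane.items():
        if "band" not in slot or "loading" not in slot:
            raise ValueError(f"lane {lane!r} needs both a band and a loading ROI")
        raw, bg, net = measure_band(image, slot["band"], background_offset)
        lraw, lbg, lnet = measure_band(image, slot["loading"], background_offset)
        rows.append(
            {
                "lane": lane,
                "raw_mean": raw,
                "background_mean": bg,
                "net": net,
                "loading_raw": lraw,
                "loading_background": lbg,
                "loading_net": lnet,
                "negative_net": net < 0 or lnet < 0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["inverted"] = bool(invert)
    return out


def normalize_bands(records: pd.DataFrame, wt_lanes: Iterable[str]) -> pd.DataFrame:
    """Loading-control then wild-type-average normalization.

    ``ratio = net / loading_net``; ``normalized = ratio / mean(WT ratios)``.
    The mean of the wild-type normalized values is exactly 1.  Negative nets
    are kept (clipping would bias ratios) but remain flagged.
    """
    wt = {str(v) for v in wt_lanes}
    if not wt:
        raise ValueError("wt_lanes must be non-empty")
    missing = wt - set(records["lane"].astype(str))
    if missing:
        raise ValueError(f"wt_lanes not present in records: {sorted(missing)}")
    bad = records.loc[records["loading_net"] <= 0, "lane"].tolist()
    if bad:
        raise ValueError(f"non-positive loading-control net in lanes {bad}")
    out = records.copy()
    out["ratio"] = out["net"] / out["loading_net"]
    wt_mean = out.loc[out["lane"].astype(str).isin(wt), "ratio"].mean()
    if wt_mean == 0:
        raise ValueError("mean WT ratio is zero; normalization undefined")
    out["normalized"] = out["ratio"] / wt_mean
    out["is_wt"] = out["lane"].astype(str).isin(wt)
    return out
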