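"""Segmentation of centromere foci on maximum-intensity projections.

The procedure mirrors the quantification workflow used for sperm-nucleus
immunofluorescence: project the z-stack, flat-field the centromere-marker
channel by dividing it by a broad median-filtered copy of itself, threshold
the normalized image to a centromere mask, keep connected components whose
pixel count lies within the centromere size gate (5-25 px inclusive by
default), and optionally apply a curation list that stands in for manual
inspection.  Nucleus segmentation of the DNA channel exists to enforce the
"at least N nuclei" sampling rule and to attribute each focus to a nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects

from .simgen import ImageStack

__all__ = [
    "Projection",
    "LabelMap",
    "CurationList",
    "max_project",
    "median_normalize",
    "threshold_foci",
    "label_and_size_filter",
    "segment_nuclei",
    "assign_foci_to_nuclei",
    "apply_curation",
]


@dataclass
class Projection:
    """Named 2-D maximum-intensity projections of one stack."""

    channels: dict[str, np.ndarray]
    source_id: str = ""

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class CurationList:
    """Labels to reject from a label map, with a reason per label.

    Reifies the manual-inspection step as a reproducible input file: the
    same curation list always produces the same curated map.
    """

    rejections: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CurationList":
        return cls({int(r.label): str(r.reason) for r in df.itertuples(index=False)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.rejections), "reason": list(self.rejections.values())}
        )


_REGION_COLUMNS = [
    "label",
    "size_px",
    "centroid_y",
    "centroid_x",
    "bbox_y0",
    "bbox_x0",
    "bbox_y1",
    "bbox_x1",
    "touches_border",
]


@dataclass
class LabelMap:
    """2-D integer label image plus a per-region table.

    ``labels`` uses 0 for background.  ``table`` has one row per region:
    label, size_px, centroid, bounding box, border flag and (after
    assignment) a nullable ``nucleus_id``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    connectivity: int = 2

    @classmethod
    def from_labels(cls, labels: np.ndarray, connectivity: int = 2) -> "LabelMap":
        labels = np.asarray(labels)
        h, w = labels.shape
        rows = []
        for r in measure.regionprops(labels):
            y0, x0, y1, x1 = r.bbox
            rows.append(
                {
                    "label": int(r.label),
                    "size_px": int(r.area),
                    "centroid_y": float(r.centroid[0]),
                    "centroid_x": float(r.centroid[1]),
                    "bbox_y0": y0,
                    "bbox_x0": x0,
                    "bbox_y1": y1,
                    "bbox_x1": x1,
                    "touches_border": bool(
                        y0 == 0 or x0 == 0 or y1 == h or x1 == w
                    ),
                }
            )
        table = pd.DataFrame(rows, columns=_REGION_COLUMNS)
        return cls(labels=labels.astype(np.int32), table=table,
                   connectivity=connectivity)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def label_ids(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def check_consistency(self) -> None:
        """Verify the region table against the label image (raises on drift)."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        if not np.array_equal(ids, np.sort(self.label_ids)):
            raise ValueError("region table labels do not match label image")
        sizes = self.table.set_index("label")["size_px"]
        if not all(sizes[i] == c for i, c in zip(ids, counts)):
            raise ValueError("region sizes do not match label image")


def max_project(stack: ImageStack) -> Projection:
    """Per-pixel maximum over z for every channel."""
    if stack.n_z < 1 or stack.data.size == 0:
        raise ValueError("cannot project an empty stack")
    channels = {
        name: stack.channel(name).max(axis=0) for name in stack.channels
    }
    return Projection(channels=channels, source_id=stack.stack_id)


def _median_filter(img: np.ndarray, kernel_radius: int) -> np.ndarray:
    """Exact square-window median with replicated edges.

    Row-blocked sliding-window partition; equivalent to
    ``scipy.ndimage.median_filter(img, size=2r+1, mode='nearest')`` but
    several-fold faster for the wide windows used here, without the full
    window-stack memory.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    k = 2 * kernel_radius + 1
    h, w = img.shape
    # integer-valued images (the usual case: camera counts) partition much
    # faster in a narrow integer dtype; the window count k*k is odd, so the
    # median is an element of the window and no averaging is needed
    work = img
    if np.all(np.mod(img, 1) == 0) and img.min() >= 0 and img.max() < 2**31:
        work = img.astype(np.int32 if img.max() >= 2**16 else np.uint16)
    pad = np.pad(work, kernel_radius, mode="edge")
    out = np.empty((h, w), dtype=float)
    mid = (k * k) // 2
    block = max(1, int(2**22 // (w * k * k)))  # ~32 MB of window copies
    for y0 in range(0, h, block):
        y1 = min(h, y0 + block)
        win = sliding_window_view(pad[y0 : y1 + k - 1], (k, k))
        win = win.reshape(y1 - y0, w, k * k)
        part = np.partition(win, mid, axis=2)
        out[y0:y1] = part[..., mid]
    return out


def median_normalize(image: np.ndarray, kernel_radius: int = 10) -> np.ndarray:
    """Flat-field an image by dividing it by its own median-filtered copy.

    The median window (a square of side ``2 * kernel_radius + 1``, edges
    replicated) estimates the smooth local background; division maps the
    background to ~1 and leaves foci as dimensionless local contrast.  The
    kernel must be wider than a focus so a spot does not inflate its own
    background estimate.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    filtered = _median_filter(img, kernel_radius)
    bad = filtered <= 0
    if np.any(bad):
        y, x = np.argwhere(bad)[0]
        raise ValueError(
            f"median-filtered background is <= 0 at pixel (y={y}, x={x}); "
            "offset the image above zero before normalizing"
        )
    return img / filtered


def threshold_foci(
    normalized_marker: np.ndarray,
    method: str = "otsu",
    level: float | None = None,
    min_contrast: float = 1.5,
) -> np.ndarray:
    """Binary centromere mask from the normalized marker image.

    A robust-contrast guard (99th percentile over median below
    ``min_contrast``) returns an empty mask for blank fields instead of
    thresholding noise.
    """
    img = np.asarray(normalized_marker, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if method == "absolute" and level is None:
        raise ValueError("method='absolute' requires a level")
    p50, p99 = np.percentile(img, [50, 99])
    contrast = np.inf if p50 <= 0 else p99 / p50
    if contrast < min_contrast:
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        thr = threshold_otsu(img)
    elif method == "absolute":
        thr = float(level)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > thr


def label_and_size_filter(
    mask: np.ndarray,
    min_px: int = 5,
    max_px: int = 25,
    connectivity: int = 2,
) -> LabelMap:
    """Connected components of a mask, gated to the centromere size range.

    Components whose pixel count falls outside ``[min_px, max_px]``
    (bounds inclusive: regions *larger or smaller* than the cut-offs are
    removed) are discarded; survivors are renumbered 1..k in raster order
    of their first pixel.
    """
    if min_px > max_px:
        raise ValueError("min_px must be <= max_px")
    mask = np.asarray(mask, dtype=bool)
    raw = measure.label(mask, connectivity=connectivity)
    if raw.max() == 0:
        return LabelMap.from_labels(np.zeros_like(raw), connectivity)
    counts = np.bincount(raw.ravel())
    keep = np.flatnonzero((counts >= min_px) & (counts <= max_px))
    keep = keep[keep > 0]
    # raster order of each surviving component's first pixel
    flat = raw.ravel()
    order = {}
    first = np.full(raw.max() + 1, flat.size, dtype=np.int64)
    seen_ids, first_idx = np.unique(flat, return_index=True)
    first[seen_ids] = first_idx
    keep = keep[np.argsort(first[keep], kind="stable")]
    relabel = np.zeros(raw.max() + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return LabelMap.from_labels(relabel[raw], connectivity)


def segment_nuclei(
    dna_projection: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 50,
    min_contrast: float = 1.2,
) -> LabelMap:
    """Segment nuclei in the DNA projection: smooth, Otsu, fill, size-filter.

    Returns an empty map for blank fields (same robust-contrast guard idea
    as focus thresholding, at a laxer level because nuclei are large).
    """
    img = np.asarray(dna_projection, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    p50, p99 = np.percentile(smoothed, [50, 99])
    contrast = np.inf if p50 <= 0 else p99 / p50
    blank = (p99 <= 0) or (contrast < min_contrast)
    if blank:
        return LabelMap.from_labels(np.zeros(img.shape, dtype=np.int32))
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = ndimage.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    labels = measure.label(mask, connectivity=2)
    return LabelMap.from_labels(labels)


def assign_foci_to_nuclei(foci: LabelMap, nuclei: LabelMap) -> LabelMap:
    """Attach a ``nucleus_id`` to each focus by its centroid position.

    A focus whose centroid falls outside every nucleus keeps a null id and
    is flagged (``outside_nucleus``); downstream QC counts only assigned
    foci toward the per-nucleus sampling rule.
    """
    if foci.labels.shape != nuclei.labels.shape:
        raise ValueError("focus and nucleus maps must share the image frame")
    table = foci.table.copy()
    h, w = nuclei.labels.shape
    ids = []
    for r in table.itertuples(index=False):
        y = min(h - 1, max(0, int(round(r.centroid_y))))
        x = min(w - 1, max(0, int(round(r.centroid_x))))
        ids.append(int(nuclei.labels[y, x]))
    ids = pd.array([i if i > 0 else pd.NA for i in ids], dtype="Int64")
    table["nucleus_id"] = ids
    table["outside_nucleus"] = ids.isna()
    return LabelMap(labels=foci.labels, table=table, connectivity=foci.connectivity)


def apply_curation(
    foci: LabelMap, curation: CurationList, missing: str = "error"
) -> LabelMap:
    """Remove curated labels; surviving labels keep their original numbers.

    Stable identity matters for audit: a focus keeps the same label before
    and after curation.  ``missing`` controls what happens when a listed
    label is absent from the map: ``"error"`` (default, catches typos) or
    ``"ignore"`` (makes re-applying the same list a no-op).
    """
    unknown = set(curation.rejections) - set(int(v) for v in foci.label_ids)
    if unknown and missing == "error":
        raise KeyError(f"curation lists unknown labels: {sorted(unknown)}")
    if not curation.rejections:
        return foci
    labels = foci.labels.copy()
    rejected = np.array(sorted(curation.rejections), dtype=labels.dtype)
    labels[np.isin(labels, rejected)] = 0
    table = foci.table[~foci.table["label"].isin(curation.rejections)].reset_index(
        drop=True
    )
    out = LabelMap(labels=labels, table=table, connectivity=foci.connectivity)
    out.curation_log = curation.to_frame()  # type: ignore[attr-defined]
    return out
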