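"""Independent brute-force oracles used to validate the pipeline's fast paths.

Everything here is deliberately naive (BFS flood fill, per-pixel
accumulation, textbook formulas) and shares no code with the package.
"""

from collections import deque

import numpy as np


def flood_fill_components(mask, connectivity=2):
    """Connected components by BFS flood fill.

    Returns a list of frozensets of (y, x) pixels, one per component,
    ordered by their first pixel in raster order.  connectivity=1 is
    4-neighbour, 2 is 8-neighbour.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 1:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = []
                q = deque([(y, x)])
                seen[y, x] = True
                while q:
                    cy, cx = q.popleft()
                    comp.append((cy, cx))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


def size_filtered_components(mask, min_px, max_px, connectivity=2):
    """Flood-fill components whose size lies in [min_px, max_px]."""
    return [c for c in flood_fill_components(mask, connectivity)
            if min_px <= len(c) <= max_px]


def brute_force_region_means(labels, image):
    """Per-label mean via explicit per-pixel accumulation."""
    sums, counts = {}, {}
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=float)
    for y in range(labels.shape[0]):
        for x in range(labels.shape[1]):
            lab = int(labels[y, x])
            if lab > 0:
                sums[lab] = sums.get(lab, 0.0) + image[y, x]
                counts[lab] = counts.get(lab, 0) + 1
    return {lab: sums[lab] / counts[lab] for lab in sums}


def welch_closed_form(a, b):
    """Direct evaluation of the Welch t, df and two-tailed p formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def recovered_fraction(truth, label_image, radius=2):
    """Fraction of ground-truth foci with a labelled pixel within ``radius``."""
    h, w = label_image.shape
    hit = 0
    for row in truth.itertuples():
        y, x = int(round(row.y)), int(round(row.x))
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        if (label_image[y0:y1, x0:x1] > 0).any():
            hit += 1
    return hit / len(truth)


def false_positive_fraction(truth, label_table, radius=3):
    """Surviving regions whose centroid is far from every planted focus,
    as a fraction of the planted count."""
    from scipy.spatial import cKDTree

    if len(label_table) == 0:
        return 0.0
    tree = cKDTree(truth[["y", "x"]].to_numpy())
    pts = label_table[["centroid_y", "centroid_x"]].to_numpy()
    d, _ = tree.query(pts)
    return float((d > radius).sum()) / len(truth)
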