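"""Per-centromere intensity measurement and hierarchical replicate statistics.

The measurement unit is the centromere focus; the statistical unit is the
biological replicate.  Per-focus mean intensities are taken on the raw
maximum-intensity projection under the marker-derived label map, normalized
to the reference (wild-type) condition, averaged per replicate, and the
per-condition comparison is a Welch unpaired two-tailed t-test on the
replicate means (the "superplot" convention: the per-focus dots are shown,
but inference never treats foci as independent samples).

Background handling
-------------------
``measure_foci`` records, for every focus and channel, both the mean raw
intensity under the label and a local background estimate (the median of
an annulus around the focus, excluding all focus pixels).  Ratio estimates
of a fold change are biased toward 1 by any additive pedestal (camera
offset + diffuse background), so ``normalize_to_reference`` subtracts the
local background by default; pass ``background="none"`` for plain raw-mean
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imaging import LabelMap, Projection

__all__ = [
    "WelchResult",
    "FoldChange",
    "ReplicateSummary",
    "measure_foci",
    "normalize_to_reference",
    "summarize_replicates",
    "welch_test",
    "qc_sampling",
    "estimate_fold_change",
]


# ---------------------------------------------------------------------------
# measurement


def _local_background(
    image: np.ndarray,
    labels: np.ndarray,
    any_focus_dilated: np.ndarray,
    row,
    inner: int,
    outer: int,
) -> float:
    """Median intensity in an annulus around one focus, foci excluded."""
    h, w = labels.shape
    pad = outer + 1
    y0 = max(0, int(row.bbox_y0) - pad)
    x0 = max(0, int(row.bbox_x0) - pad)
    y1 = min(h, int(row.bbox_y1) + pad)
    x1 = min(w, int(row.bbox_x1) + pad)
    region = labels[y0:y1, x0:x1] == row.label
    ring = ndimage.binary_dilation(region, iterations=outer)
    ring &= ~ndimage.binary_dilation(region, iterations=inner)
    ring &= ~any_focus_dilated[y0:y1, x0:x1]
    vals = image[y0:y1, x0:x1][ring]
    if vals.size == 0:
        return float(np.median(image))
    return float(np.median(vals))


def measure_foci(
    foci: LabelMap,
    projection: Projection,
    channels: list[str] | None = None,
    background: str = "local",
    bg_inner: int = 2,
    bg_outer: int = 5,
) -> pd.DataFrame:
    """Mean raw projection intensity per focus and channel.

    Returns one row per focus with ``mean_<channel>`` columns and, when
    ``background="local"``, ``bg_<channel>`` columns holding the annulus
    median (ring between ``bg_inner`` and ``bg_outer`` dilations of the
    focus, all focus pixels excluded).
    """
    if channels is None:
        channels = list(projection.channels)
    for ch in channels:
        if ch not in projection.channels:
            raise KeyError(f"channel {ch!r} not present in projection")
        if projection.channels[ch].shape != foci.labels.shape:
            raise ValueError("label map and projection must share the frame")

    table = foci.table.copy()
    out = table[[c for c in table.columns]].copy()
    out.insert(0, "stack_id", projection.source_id)
    ids = foci.label_ids
    imgs = {ch: np.asarray(projection.channels[ch], dtype=float) for ch in channels}
    for ch in channels:
        if len(ids):
            means = ndimage.mean(imgs[ch], labels=foci.labels, index=ids)
        else:
            means = np.array([])
        out[f"mean_{ch}"] = means
    if background == "local" and len(ids):
        any_focus = ndimage.binary_dilation(foci.labels > 0, iterations=1)
        for ch in channels:
            out[f"bg_{ch}"] = [
                _local_background(imgs[ch], foci.labels, any_focus, row,
                                  bg_inner, bg_outer)
                for row in table.itertuples(index=False)
            ]
    elif background == "local":
        for ch in channels:
            out[f"bg_{ch}"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_to_reference(
    foci: pd.DataFrame,
    target_channel: str = "target",
    reference: str = "WT",
    scope: str = "per_replicate",
    background: str = "local",
) -> pd.DataFrame:
    """Normalize per-focus target intensity to the reference condition.

    ``normalized_value = net / mean(net of reference foci in scope)`` where
    ``net`` is the target mean minus its local background (or the raw mean
    with ``background="none"``).  With ``scope="per_replicate"`` each
    replicate is divided by its own reference mean, which cancels
    multiplicative batch effects; ``scope="pooled"`` uses one global
    reference mean.  Reference normalized values average exactly 1 within
    each scope.
    """
    if scope not in ("per_replicate", "pooled"):
        raise ValueError("scope must be 'per_replicate' or 'pooled'")
    for col in ("condition", "replicate"):
        if col not in foci.columns:
            raise KeyError(f"foci table lacks a {col!r} column")
    mean_col = f"mean_{target_channel}"
    if mean_col not in foci.columns:
        raise KeyError(f"foci table lacks {mean_col!r}; was the channel measured?")
    quant = foci.copy()
    if background == "local":
        bg_col = f"bg_{target_channel}"
        if bg_col not in quant.columns:
            raise KeyError(
                f"background='local' requires {bg_col!r}; re-measure with "
                "background='local' or pass background='none'"
            )
        quant["net"] = quant[mean_col] - quant[bg_col]
    elif background == "none":
        quant["net"] = quant[mean_col]
    else:
        raise ValueError("background must be 'local' or 'none'")

    is_ref = quant["condition"] == reference
    if scope == "pooled":
        if not is_ref.any():
            raise ValueError(f"reference condition {reference!r} absent from table")
        ref_mean = quant.loc[is_ref, "net"].mean()
        if ref_mean <= 0:
            raise ValueError("reference mean net intensity is not positive")
        quant["normalized_value"] = quant["net"] / ref_mean
    else:
        reps = sorted(quant["replicate"].unique())
        missing = [
            int(r) for r in reps
            if not ((quant["replicate"] == r) & is_ref).any()
        ]
        if missing:
            raise ValueError(
                f"reference condition {reference!r} missing in replicates {missing}"
            )
        ref_means = (
            quant[is_ref].groupby("replicate")["net"].mean().rename("ref_mean")
        )
        if (ref_means <= 0).any():
            bad = list(ref_means.index[ref_means <= 0])
            raise ValueError(f"non-positive reference mean in replicates {bad}")
        quant = quant.merge(ref_means, on="replicate", how="left")
        quant["normalized_value"] = quant["net"] / quant["ref_mean"]
        quant = quant.drop(columns="ref_mean")
    return quant


# ---------------------------------------------------------------------------
# replicate summaries and statistics


@dataclass
class ReplicateSummary:
    """Replicate-level means and condition-level grand means.

    ``replicates``: per (condition, replicate) the mean normalized value,
    focus and nucleus counts.  ``conditions``: grand mean (mean of
    replicate means), SEM over replicate means, replicate count.
    """

    replicates: pd.DataFrame
    conditions: pd.DataFrame

    def replicate_means(self, condition: str) -> np.ndarray:
        df = self.replicates
        return df.loc[df["condition"] == condition, "replicate_mean"].to_numpy()


def summarize_replicates(quant: pd.DataFrame) -> ReplicateSummary:
    """Mean normalized value per replicate; grand mean and SEM per condition.

    SEM is the standard deviation of the replicate means over the square
    root of the replicate count — the error bar of the superplot, never a
    per-focus SEM.  Conditions with fewer than two replicates raise.
    """
    if "normalized_value" not in quant.columns:
        raise KeyError("quant table lacks 'normalized_value'; normalize first")
    grp = quant.groupby(["condition", "replicate"], sort=True)
    reps = grp.agg(
        replicate_mean=("normalized_value", "mean"),
        n_foci=("normalized_value", "size"),
    ).reset_index()
    if "nucleus_id" in quant.columns:
        nuc = grp["nucleus_id"].nunique(dropna=True).rename("n_nuclei").reset_index()
        reps = reps.merge(nuc, on=["condition", "replicate"])
    else:
        reps["n_nuclei"] = pd.NA

    conds = []
    for condition, sub in reps.groupby("condition", sort=True):
        m = sub["replicate_mean"].to_numpy(dtype=float)
        if len(m) < 2:
            raise ValueError(
                f"condition {condition!r} has {len(m)} replicate(s); "
                "replicate statistics need at least 2"
            )
        conds.append(
            {
                "condition": condition,
                "grand_mean": float(m.mean()),
                "sem": float(m.std(ddof=1) / np.sqrt(len(m))),
                "n_replicates": len(m),
            }
        )
    return ReplicateSummary(replicates=reps, conditions=pd.DataFrame(conds))


@dataclass
class WelchResult:
    """Welch unpaired two-tailed t-test result on two sets of means."""

    t: float
    df: float
    p: float
    n_a: int
    n_b: int


def welch_test(means_a, means_b) -> WelchResult:
    """Welch's unpaired two-tailed t-test, closed form.

    t = (x̄_a − x̄_b) / sqrt(s_a²/n_a + s_b²/n_b); degrees of freedom by
    Welch–Satterthwaite; p is the two-tailed Student-t tail probability.
    Degenerate conventions: both variances zero → p = 1 if the means are
    equal, else p = 0 (with a warning) — a measured difference with no
    observed variability.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0, n_a=na, n_b=nb)
        warnings.warn(
            "zero variance in both groups with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.inf if ma > mb else -np.inf
        return WelchResult(t=t, df=float(na + nb - 2), p=0.0, n_a=na, n_b=nb)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)),
                       n_a=na, n_b=nb)


def qc_sampling(
    quant: pd.DataFrame, min_foci: int = 100, min_nuclei: int = 10
) -> pd.DataFrame:
    """Check the sampling rule: per condition and replicate, at least
    ``min_foci`` centromeres among at least ``min_nuclei`` nuclei.

    Returns a report frame; failing rows are warnings for the pipeline,
    never hard errors (the counts describe evidence, not validity).
    """
    cols = ["condition", "replicate", "n_foci", "n_nuclei",
            "pass_foci", "pass_nuclei", "passed"]
    if quant.empty:
        return pd.DataFrame(columns=cols)
    grp = quant.groupby(["condition", "replicate"], sort=True)
    rows = []
    for (condition, rep), sub in grp:
        n_foci = len(sub)
        if "nucleus_id" in sub.columns:
            n_nuclei = int(sub["nucleus_id"].nunique(dropna=True))
        else:
            n_nuclei = 0
        ok_f = n_foci >= min_foci
        ok_n = n_nuclei >= min_nuclei
        rows.append(
            {
                "condition": condition,
                "replicate": rep,
                "n_foci": n_foci,
                "n_nuclei": n_nuclei,
                "pass_foci": ok_f,
                "pass_nuclei": ok_n,
                "passed": ok_f and ok_n,
            }
        )
    return pd.DataFrame(rows, columns=cols)


@dataclass
class FoldChange:
    """Ratio of condition grand mean to reference grand mean, with CI."""

    fold: float
    ci_low: float
    ci_high: float
    df: float
    confidence: float


def estimate_fold_change(
    summary: ReplicateSummary,
    condition: str,
    reference: str = "WT",
    confidence: float = 0.95,
) -> FoldChange:
    """Fold change of a condition relative to the reference.

    fold = grand_mean(condition) / grand_mean(reference).  The confidence
    interval uses the first-order delta method for a ratio of independent
    means — var(f) ≈ s_c²/(n_c g_r²) + g_c² s_r²/(n_r g_r⁴) — with a
    t-quantile on Welch–Satterthwaite degrees of freedom over the two
    variance contributions.  When the reference was itself the
    normalization scope (per-replicate), its replicate means are constant
    and the interval reduces to a one-sample t-interval on the condition.
    """
    mc = summary.replicate_means(condition)
    mr = summary.replicate_means(reference)
    if len(mc) < 2 or len(mr) < 2:
        raise ValueError("both conditions must have >= 2 replicates")
    gc, gr = mc.mean(), mr.mean()
    if gr == 0:
        raise ValueError("reference grand mean is zero; fold change undefined")
    fold = gc / gr
    nc, nr = len(mc), len(mr)
    vc, vr = mc.var(ddof=1), mr.var(ddof=1)
    term_c = vc / nc / gr**2
    term_r = gc**2 * vr / nr / gr**4
    var_f = term_c + term_r
    if var_f == 0:
        return FoldChange(fold=float(fold), ci_low=float(fold),
                          ci_high=float(fold), df=float(nc + nr - 2),
                          confidence=confidence)
    denom = 0.0
    if term_c > 0:
        denom += term_c**2 / (nc - 1)
    if term_r > 0:
        denom += term_r**2 / (nr - 1)
    df = var_f**2 / denom
    half = stats.t.ppf(0.5 + confidence / 2.0, df) * np.sqrt(var_f)
    return FoldChange(
        fold=float(fold),
        ci_low=float(fold - half),
        ci_high=float(fold + half),
        df=float(df),
        confidence=confidence,
    )
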