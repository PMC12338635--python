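"""End-to-end orchestration: segment -> measure -> normalize -> statistics.

The pipeline is driven by a design table (one row per stack: path,
condition, replicate, optional per-stack channel names and curation file)
and a :class:`PipelineConfig`.  Every run emits a manifest capturing the
fully-resolved configuration, software version, input checksums and
warnings, so that "default" is never ambiguous and a rerun with the same
inputs reproduces byte-identical tables.

Warnings (sampling-QC failures, foci outside nuclei, negative nets) never
abort a run by default; ``strict=True`` promotes them to errors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    LabelMap,
    Projection,
    apply_curation,
    assign_foci_to_nuclei,
    label_and_size_filter,
    max_project,
    median_normalize,
    segment_nuclei,
    threshold_foci,
)
from .io import read_curation, read_stack
from .quant import (
    estimate_fold_change,
    measure_foci,
    normalize_to_reference,
    qc_sampling,
    summarize_replicates,
    welch_test,
)
from .simgen import ImageStack

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "validate_design",
    "segment_stack",
    "quantify_stacks",
    "analyze",
    "run_pipeline",
]

DESIGN_REQUIRED = ("stack_path", "condition", "replicate")


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis, with the defaults used throughout.

    kernel_radius is the half-width (px) of the median-filter window used
    for flat-fielding; min_px/max_px bound the centromere size gate
    (inclusive); the reference condition anchors normalization and every
    statistical contrast.
    """

    dna_channel: str = "dna"
    marker_channel: str = "marker"
    target_channel: str = "target"
    kernel_radius: int = 10
    threshold_method: str = "otsu"
    threshold_level: float | None = None
    min_contrast: float = 1.5
    min_px: int = 5
    max_px: int = 25
    connectivity: int = 2
    threshold_on_normalized: bool = True
    measure_channels: tuple[str, ...] | None = None
    background: str = "local"
    reference: str = "WT"
    scope: str = "per_replicate"
    min_foci: int = 100
    min_nuclei: int = 10
    reject_outside_nuclei: bool = False
    strict: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["measure_channels"] is not None:
            d["measure_channels"] = list(d["measure_channels"])
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def validate_design(
    design: pd.DataFrame,
    config: PipelineConfig | None = None,
    check_paths: bool = True,
) -> list[str]:
    """Validate a design table; returns a list of problems (empty = valid).

    Checks required columns, duplicate (condition, replicate, stack) rows,
    presence of the reference condition, resolvable stack and curation
    paths, and known channel names.
    """
    config = config or PipelineConfig()
    problems: list[str] = []
    missing = [c for c in DESIGN_REQUIRED if c not in design.columns]
    if missing:
        return [f"design table lacks required columns: {missing}"]
    dup = design.duplicated(subset=["condition", "replicate", "stack_path"])
    if dup.any():
        problems.append(
            f"duplicate (condition, replicate, stack) rows at index {list(design.index[dup])}"
        )
    if config.reference not in set(design["condition"]):
        problems.append(
            f"reference condition {config.reference!r} absent from design"
        )
    if check_paths:
        for p in design["stack_path"]:
            if not Path(p).exists():
                problems.append(f"stack path does not exist: {p}")
        if "curation_path" in design.columns:
            for p in design["curation_path"].dropna():
                if p and not Path(p).exists():
                    problems.append(f"curation path does not exist: {p}")
    for col in ("dna", "marker", "target"):
        if col in design.columns:
            if design[col].isna().any():
                problems.append(f"channel-map column {col!r} has missing values")
    return problems


def segment_stack(
    stack: ImageStack, config: PipelineConfig | None = None
) -> tuple[LabelMap, LabelMap, Projection]:
    """Segment one stack into curated-ready foci and nuclei label maps.

    Projection -> median-normalize the marker -> threshold -> size gate;
    nuclei from the DNA projection; foci get nucleus assignments.
    Returns (foci, nuclei, projection).
    """
    config = config or PipelineConfig()
    proj = max_project(stack)
    marker = proj[config.marker_channel]
    normalized = median_normalize(marker, kernel_radius=config.kernel_radius)
    source = normalized if config.threshold_on_normalized else marker.astype(float)
    mask = threshold_foci(
        source,
        method=config.threshold_method,
        level=config.threshold_level,
        min_contrast=config.min_contrast,
    )
    foci = label_and_size_filter(
        mask, min_px=config.min_px, max_px=config.max_px,
        connectivity=config.connectivity,
    )
    nuclei = segment_nuclei(proj[config.dna_channel])
    foci = assign_foci_to_nuclei(foci, nuclei)
    if config.reject_outside_nuclei and foci.table["outside_nucleus"].any():
        keep = ~foci.table["outside_nucleus"]
        labels = foci.labels.copy()
        dropped = foci.table.loc[~keep, "label"].to_numpy()
        labels[np.isin(labels, dropped)] = 0
        foci = LabelMap(labels=labels, table=foci.table[keep].reset_index(drop=True),
                        connectivity=foci.connectivity)
    return foci, nuclei, proj


def quantify_stacks(
    stacks: Iterable[tuple[ImageStack, str, int]] | Mapping[tuple[str, int], ImageStack],
    config: PipelineConfig | None = None,
    curations: Mapping[tuple[str, int], object] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Segment and measure a collection of stacks in memory.

    ``stacks`` is either a mapping ``(condition, replicate) -> ImageStack``
    or an iterable of ``(stack, condition, replicate)``.  Returns the
    concatenated per-focus table (with condition/replicate columns) and a
    list of warnings.
    """
    config = config or PipelineConfig()
    if isinstance(stacks, Mapping):
        items = [(s, c, r) for (c, r), s in stacks.items()]
    else:
        items = list(stacks)
    frames = []
    warnings_list: list[str] = []
    for stack, condition, replicate in items:
        try:
            foci, nuclei, proj = segment_stack(stack, config)
            if curations:
                cur = curations.get((condition, replicate))
                if cur is not None:
                    foci = apply_curation(foci, cur)
            channels = config.measure_channels or tuple(proj.channels)
            table = measure_foci(
                foci, proj, channels=list(channels), background=config.background
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(
                f"stack {stack.stack_id or '?'} ({condition}, rep {replicate}): {exc}"
            ) from exc
        table.insert(1, "condition", condition)
        table.insert(2, "replicate", replicate)
        n_out = int(table["outside_nucleus"].sum()) if "outside_nucleus" in table else 0
        if n_out:
            warnings_list.append(
                f"{stack.stack_id}: {n_out} foci outside any nucleus"
            )
        frames.append(table)
    if not frames:
        raise PipelineError("no stacks to quantify")
    return pd.concat(frames, ignore_index=True), warnings_list


def analyze(
    foci_table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Normalize, summarize and test a measured per-focus table.

    Returns a dict with keys ``quant`` (per-focus normalized table),
    ``summary`` (:class:`~centroquant.quant.ReplicateSummary`), ``qc``
    (sampling report), ``stats`` (per non-reference condition: Welch t, df,
    p and fold change vs the reference) and ``warnings``.
    """
    config = config or PipelineConfig()
    quant = normalize_to_reference(
        foci_table,
        target_channel=config.target_channel,
        reference=config.reference,
        scope=config.scope,
        background=config.background,
    )
    summary = summarize_replicates(quant)
    qc = qc_sampling(quant, min_foci=config.min_foci, min_nuclei=config.min_nuclei)
    warnings_list = [
        f"sampling QC failed for ({r.condition}, rep {r.replicate}): "
        f"{r.n_foci} foci, {r.n_nuclei} nuclei"
        for r in qc.itertuples(index=False)
        if not r.passed
    ]
    stats_out = {}
    ref_means = summary.replicate_means(config.reference)
    for condition in summary.conditions["condition"]:
        if condition == config.reference:
            continue
        res = welch_test(summary.replicate_means(condition), ref_means)
        fc = estimate_fold_change(summary, condition, config.reference)
        stats_out[str(condition)] = {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "n": [res.n_a, res.n_b],
            "fold_change": fc.fold,
            "fold_ci": [fc.ci_low, fc.ci_high],
            "reference": config.reference,
            "test": "Welch unpaired two-tailed t-test on replicate means",
            "multiple_testing_correction": "none (pairwise contrasts reported as-is)",
        }
    return {
        "quant": quant,
        "summary": summary,
        "qc": qc,
        "stats": stats_out,
        "warnings": warnings_list,
    }


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    design: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path = ".",
    make_plot: bool = False,
) -> dict:
    """Run the full analysis from a design table of stack files on disk.

    Writes foci.csv, quant.csv, replicates.csv, conditions.csv, qc.csv,
    stats.json and manifest.json into ``out_dir`` (plus superplot.png when
    ``make_plot``).  Fails fast on design problems before reading any
    image.  Returns the :func:`analyze` result dict plus the manifest.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    problems = validate_design(design, config)
    if problems:
        raise PipelineError("design validation failed: " + "; ".join(problems))

    items = []
    curations: dict[tuple[str, int], object] = {}
    for row in design.itertuples(index=False):
        stack = read_stack(row.stack_path)
        items.append((stack, str(row.condition), int(row.replicate)))
        cur_path = getattr(row, "curation_path", None)
        if cur_path and not pd.isna(cur_path):
            curations[(str(row.condition), int(row.replicate))] = read_curation(cur_path)

    foci_table, warn_segment = quantify_stacks(items, config, curations=curations)
    result = analyze(foci_table, config)
    all_warnings = warn_segment + result["warnings"]
    if config.strict and all_warnings:
        raise PipelineError("strict mode: " + "; ".join(all_warnings))

    foci_table.to_csv(out / "foci.csv", index=False)
    result["quant"].to_csv(out / "quant.csv", index=False)
    result["summary"].replicates.to_csv(out / "replicates.csv", index=False)
    result["summary"].conditions.to_csv(out / "conditions.csv", index=False)
    result["qc"].to_csv(out / "qc.csv", index=False)
    (out / "stats.json").write_text(json.dumps(result["stats"], indent=2))

    manifest = {
        "software": {"name": "centroquant", "version": __version__},
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "inputs": {
            str(r.stack_path): _sha256_file(Path(r.stack_path))
            for r in design.itertuples(index=False)
        },
        "design": design.to_dict(orient="records"),
        "warnings": all_warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if make_plot:
        from .plotting import superplot

        fig = superplot(result["quant"], result["summary"])
        fig.savefig(out / "superplot.png", dpi=150)

    result["manifest"] = manifest
    result["warnings"] = all_warnings
    return result
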