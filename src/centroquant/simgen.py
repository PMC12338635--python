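"""Synthetic immunofluorescence z-stack generator with known ground truth.

Emulates confocal imaging of sperm nuclei in egg extract: a DNA channel
(nucleus blobs), a centromere-marker channel (CENP-A-like foci), and a
target channel (e.g. tagged M18BP1) whose per-focus amplitude is scaled by
a condition-specific fold change relative to a reference (wild-type)
condition.  The generator exists so that the downstream segmentation and
quantification stages can be validated by parameter recovery: every focus
it renders is recorded in a ground-truth table.

Imaging model
-------------
Foci are anisotropic 3-D Gaussians on a flat diffuse background; the whole
field is modulated by a smooth multiplicative shading profile; photon shot
noise is Poisson, the camera adds a constant offset plus Gaussian read
noise, and the result is quantized to the configured bit depth:

    image = clip( round( offset + N(0, read_sd)
                         + Poisson( shading * (background + sum of foci) ) ) )

Per-focus amplitudes are lognormal around the condition mean (right-skewed,
as real centromere intensities are); biological replicates carry a shared
multiplicative lognormal batch factor, which is what makes per-replicate
reference normalization downstream non-trivial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "ImageStack",
    "SimulationError",
    "simulate_replicate",
    "simulate_experiment",
    "render_truth",
]

CHANNELS = ("dna", "marker", "target")

TRUTH_COLUMNS = [
    "focus_id",
    "nucleus_id",
    "x",
    "y",
    "z",
    "amplitude_marker",
    "amplitude_target",
    "condition",
    "replicate",
]


class SimulationError(RuntimeError):
    """Raised when the requested geometry cannot be realised."""


@dataclass
class ImageStack:
    """Multi-channel 3-D intensity volume with acquisition calibration.

    ``data`` is indexed ``(channel, z, y, x)`` and stores unsigned integers
    in ``[0, 2**bit_depth - 1]``.  ``channels`` names the first axis.
    """

    data: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    pixel_size_xy: float = 0.11
    z_step: float = 0.2
    bit_depth: int = 16
    stack_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channel, z, y, x)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel axis does not match channel names")

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_xy(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel volume ``(z, y, x)`` by name."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (has {self.channels})"
            ) from None
        return self.data[idx]


@dataclass
class SimParams:
    """Acquisition and ground-truth parameters for one synthetic experiment.

    Defaults reproduce the study geometry: 41 z-sections at 0.2 µm
    (an 8 µm axial span), 16-bit digitization, and per condition and
    replicate at least 10 nuclei carrying at least 100 centromere foci
    in total.  Pixel size (0.11 µm, a 60x/1.4 oil system) and camera gain
    (unity) are not constrained by the study and are placeholders.

    ``condition_fold_changes`` maps condition name to the mean target-channel
    amplitude relative to the reference condition (which must map to 1.0).
    """

    image_shape_xy: tuple[int, int] = (256, 256)
    n_z: int = 41
    z_step: float = 0.2
    n_nuclei: int = 13
    foci_per_nucleus: int = 8
    nucleus_radius: float = 18.0
    focus_sigma_xy: float = 1.2
    focus_sigma_z: float = 1.5
    base_amplitude_marker: float = 2000.0
    base_amplitude_target: float = 2000.0
    condition_fold_changes: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0}
    )
    amplitude_cv: float = 0.3
    background_level: float = 50.0
    shading_amplitude: float = 0.3
    read_noise_sd: float = 3.0
    camera_offset: float = 100.0
    bit_depth: int = 16
    seed: int = 0
    # --- plumbing beyond the acquisition description ---
    replicate_batch_sd: float = 0.1
    dna_amplitude: float = 800.0
    min_focus_separation: float = 6.5
    shot_noise: bool = True
    pixel_size_xy: float = 0.11
    reference_condition: str = "WT"

    @property
    def z_span(self) -> float:
        """Axial extent covered by the stack (first to last section), in µm."""
        return (self.n_z - 1) * self.z_step

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def validate(self) -> None:
        if self.n_z < 1 or min(self.image_shape_xy) < 8:
            raise ValueError("stack geometry too small")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        for name in (
            "base_amplitude_marker",
            "base_amplitude_target",
            "background_level",
            "read_noise_sd",
            "camera_offset",
            "amplitude_cv",
            "shading_amplitude",
            "replicate_batch_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        ref = self.reference_condition
        if ref not in self.condition_fold_changes:
            raise ValueError(f"reference condition {ref!r} missing from fold map")
        if not np.isclose(self.condition_fold_changes[ref], 1.0):
            raise ValueError("reference condition fold change must equal 1.0")
        if any(v < 0 for v in self.condition_fold_changes.values()):
            raise ValueError("fold changes must be nonnegative")
        if self.n_nuclei < 1 or self.foci_per_nucleus < 1:
            raise ValueError("need at least one nucleus and one focus")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape_xy"] = list(self.image_shape_xy)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        d = dict(d)
        if "image_shape_xy" in d:
            d["image_shape_xy"] = tuple(d["image_shape_xy"])
        return cls(**d)


# ---------------------------------------------------------------------------
# RNG plumbing: one independent stream per (condition, replicate) so adding
# a condition never perturbs the images of another.


def _stream(seed: int, *keys) -> np.random.Generator:
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf8")))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(n)
    sig2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sig2 / 2.0, sigma=np.sqrt(sig2), size=n)


def _place_nuclei(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping nucleus centres (y, x), uniform with a border margin."""
    h, w = params.image_shape_xy
    r = params.nucleus_radius
    margin = r + 2.0
    if 2 * margin >= min(h, w):
        raise SimulationError(
            f"nucleus_radius {r} too large for image {params.image_shape_xy}"
        )
    # keep a small gap between footprints so nuclei stay resolvable
    min_d2 = (2 * r + 6) ** 2
    for _ in range(40):  # whole-layout restarts
        centers = np.empty((params.n_nuclei, 2))
        n = 0
        tries = 0
        while n < params.n_nuclei and tries < 400 * params.n_nuclei:
            tries += 1
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            d2 = (centers[:n, 0] - cy) ** 2 + (centers[:n, 1] - cx) ** 2
            if n == 0 or d2.min() >= min_d2:
                centers[n] = (cy, cx)
                n += 1
        if n == params.n_nuclei:
            return centers
    raise SimulationError(
        f"could not place {params.n_nuclei} non-overlapping nuclei of radius "
        f"{r} in a {params.image_shape_xy} field; reduce n_nuclei or "
        "nucleus_radius"
    )


def _place_foci_in_nucleus(
    params: SimParams, rng: np.random.Generator, center: np.ndarray
) -> np.ndarray:
    """Subpixel focus centres (y, x, z) inside one nucleus footprint.

    Foci keep a minimum lateral separation so that neighbouring diffraction
    spots remain resolvable, and sit in the central half of the axial range
    (chromatin does not fill the whole acquisition span).
    """
    r_spread = 0.8 * params.nucleus_radius
    sep2 = params.min_focus_separation**2
    z_lo, z_hi = 0.25 * (params.n_z - 1), 0.75 * (params.n_z - 1)
    if z_hi <= z_lo:
        z_lo = z_hi = (params.n_z - 1) / 2.0
    for _ in range(60):  # per-nucleus layout restarts
        pts = np.empty((params.foci_per_nucleus, 3))
        n = 0
        tries = 0
        limit = 400 * params.foci_per_nucleus
        while n < params.foci_per_nucleus and tries < limit:
            tries += 1
            rad = r_spread * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            y = center[0] + rad * np.sin(theta)
            x = center[1] + rad * np.cos(theta)
            d2 = (pts[:n, 0] - y) ** 2 + (pts[:n, 1] - x) ** 2
            if n == 0 or d2.min() >= sep2:
                z = rng.uniform(z_lo, z_hi) if z_hi > z_lo else z_lo
                pts[n] = (y, x, z)
                n += 1
        if n == params.foci_per_nucleus:
            return pts
    raise SimulationError(
        f"could not place {params.foci_per_nucleus} foci with separation "
        f"{params.min_focus_separation} px inside a nucleus of radius "
        f"{params.nucleus_radius}; reduce foci_per_nucleus or separation"
    )


def _shading_field(params: SimParams) -> np.ndarray:
    """Multiplicative shading: 1 + amplitude * centred 2-D cosine bump."""
    h, w = params.image_shape_xy
    if params.shading_amplitude == 0:
        return np.ones((h, w))
    y = np.cos(np.pi * (np.arange(h) / max(h - 1, 1) - 0.5))
    x = np.cos(np.pi * (np.arange(w) / max(w - 1, 1) - 0.5))
    return 1.0 + params.shading_amplitude * np.outer(y, x)


def _add_gaussian_focus(
    vol: np.ndarray,
    y: float,
    x: float,
    z: float,
    amplitude: float,
    sigma_xy: float,
    sigma_z: float,
) -> None:
    """Accumulate one anisotropic 3-D Gaussian into ``vol`` (z, y, x)."""
    nz, h, w = vol.shape
    ry = int(np.ceil(4 * sigma_xy))
    rz = int(np.ceil(4 * sigma_z))
    y0, y1 = max(0, int(y) - ry), min(h, int(y) + ry + 2)
    x0, x1 = max(0, int(x) - ry), min(w, int(x) + ry + 2)
    z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 2)
    if y0 >= y1 or x0 >= x1 or z0 >= z1:
        return
    yy = np.arange(y0, y1) - y
    xx = np.arange(x0, x1) - x
    zz = np.arange(z0, z1) - z
    gy = np.exp(-(yy**2) / (2 * sigma_xy**2))
    gx = np.exp(-(xx**2) / (2 * sigma_xy**2))
    gz = np.exp(-(zz**2) / (2 * sigma_z**2))
    vol[z0:z1, y0:y1, x0:x1] += (
        amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def render_truth(
    params: SimParams,
    truth: pd.DataFrame,
    nucleus_centers: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    stack_id: str = "",
) -> ImageStack:
    """Render an :class:`ImageStack` from an explicit ground-truth table.

    ``truth`` needs columns x, y, z, amplitude_marker, amplitude_target
    (amplitudes are final, all multiplicative factors applied).  Exposed
    publicly so that analytic renders (hand-placed foci, noise off) can be
    produced for validation.
    """
    params.validate()
    h, w = params.image_shape_xy
    nz = params.n_z
    signal = np.zeros((3, nz, h, w))

    # DNA channel: soft ellipsoidal nucleus blobs centred mid-stack.
    if nucleus_centers is not None and params.dna_amplitude > 0:
        z_sigma = max(2.0, nz / 6.0)
        zc = (nz - 1) / 2.0
        gz = np.exp(-((np.arange(nz) - zc) ** 2) / (2 * z_sigma**2))
        plane = np.zeros((h, w))
        r = params.nucleus_radius
        ext = int(np.ceil(1.6 * r))
        for cy, cx in nucleus_centers:
            y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
            x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
            yy = np.arange(y0, y1) - cy
            xx = np.arange(x0, x1) - cx
            d2 = yy[:, None] ** 2 + xx[None, :] ** 2
            # super-Gaussian: flat interior, soft few-pixel rim
            plane[y0:y1, x0:x1] += params.dna_amplitude * np.exp(
                -((d2 / r**2) ** 3)
            )
        signal[0] = gz[:, None, None] * plane[None, :, :]

    for row in truth.itertuples(index=False):
        _add_gaussian_focus(
            signal[1], row.y, row.x, row.z, row.amplitude_marker,
            params.focus_sigma_xy, params.focus_sigma_z,
        )
        _add_gaussian_focus(
            signal[2], row.y, row.x, row.z, row.amplitude_target,
            params.focus_sigma_xy, params.focus_sigma_z,
        )

    signal += params.background_level
    shading = _shading_field(params)
    signal *= shading[None, None, :, :]

    if params.shot_noise:
        if rng is None:
            rng = _stream(params.seed, "render", stack_id)
        signal = rng.poisson(signal).astype(float)
    image = signal + params.camera_offset
    if params.read_noise_sd > 0:
        if rng is None:
            rng = _stream(params.seed, "render", stack_id)
        image = image + rng.normal(0.0, params.read_noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, params.max_intensity)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return ImageStack(
        data=image.astype(dtype),
        channels=CHANNELS,
        pixel_size_xy=params.pixel_size_xy,
        z_step=params.z_step,
        bit_depth=params.bit_depth,
        stack_id=stack_id,
    )


def simulate_replicate(
    params: SimParams,
    condition: str,
    replicate: int,
    batch_factor: float = 1.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate one z-stack for one (condition, replicate) with ground truth.

    Deterministic given ``(params.seed, condition, replicate)``.  The target
    channel amplitude of every focus is
    ``base_amplitude_target * fold_change * batch_factor * lognormal``;
    the marker channel carries no condition effect (fold 1).
    """
    params.validate()
    if condition not in params.condition_fold_changes:
        raise KeyError(
            f"condition {condition!r} not in condition_fold_changes "
            f"({sorted(params.condition_fold_changes)})"
        )
    fold = params.condition_fold_changes[condition]
    rng = _stream(params.seed, condition, replicate)

    nucleus_centers = _place_nuclei(params, rng)
    rows = []
    fid = 0
    for nid, center in enumerate(nucleus_centers, start=1):
        pts = _place_foci_in_nucleus(params, rng, center)
        for y, x, z in pts:
            fid += 1
            rows.append((fid, nid, x, y, z))
    n = len(rows)
    lm = _lognormal_factors(rng, params.amplitude_cv, n)
    lt = _lognormal_factors(rng, params.amplitude_cv, n)
    truth = pd.DataFrame(rows, columns=["focus_id", "nucleus_id", "x", "y", "z"])
    truth["amplitude_marker"] = params.base_amplitude_marker * batch_factor * lm
    truth["amplitude_target"] = (
        params.base_amplitude_target * fold * batch_factor * lt
    )
    truth["condition"] = condition
    truth["replicate"] = replicate

    stack_id = f"{condition}_r{replicate}"
    stack = render_truth(
        params, truth, nucleus_centers=nucleus_centers, rng=rng, stack_id=stack_id
    )
    return stack, truth[TRUTH_COLUMNS]


def replicate_batch_factors(params: SimParams, n_replicates: int) -> np.ndarray:
    """Per-replicate multiplicative batch factors (unit-mean lognormal).

    Drawn from a stream keyed only on (seed, replicate index): the factor a
    replicate receives does not depend on which conditions are simulated,
    mirroring a day/extract batch effect shared across conditions.
    """
    rng = _stream(params.seed, "batch")
    return _lognormal_factors(rng, params.replicate_batch_sd, n_replicates)


def simulate_experiment(
    params: SimParams,
    conditions: Sequence[str] | None = None,
    n_replicates: int = 3,
) -> tuple[dict[tuple[str, int], ImageStack], pd.DataFrame, pd.DataFrame]:
    """Simulate a full multi-condition, multi-replicate experiment.

    Returns ``(stacks, truth, design)`` where ``stacks`` maps
    ``(condition, replicate)`` to an :class:`ImageStack`, ``truth``
    concatenates all ground-truth rows and ``design`` links every stack id
    to its condition and replicate.
    """
    params.validate()
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (replicate statistics undefined)")
    if conditions is None:
        conditions = list(params.condition_fold_changes)
    for c in conditions:
        if c not in params.condition_fold_changes:
            raise KeyError(f"condition {c!r} not in condition_fold_changes")

    batch = replicate_batch_factors(params, n_replicates)
    stacks: dict[tuple[str, int], ImageStack] = {}
    truths = []
    design_rows = []
    for condition in conditions:
        for rep in range(1, n_replicates + 1):
            stack, truth = simulate_replicate(
                params, condition, rep, batch_factor=batch[rep - 1]
            )
            stacks[(condition, rep)] = stack
            truths.append(truth)
            design_rows.append(
                {
                    "stack_id": stack.stack_id,
                    "condition": condition,
                    "replicate": rep,
                    "batch_factor": batch[rep - 1],
                }
            )
    truth = pd.concat(truths, ignore_index=True)
    design = pd.DataFrame(design_rows)
    return stacks, truth, design
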