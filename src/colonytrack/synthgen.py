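"""Synthetic brightfield Z-stack and assay-data generator.

Emulates the imaging conditions of an automated colony-forming assay in a
3D matrix: dark blob-like objects (single cells, clusters of 2-14 cells,
colonies of >= 15 cells) suspended at random focal depths in a stack of
slices, imaged in brightfield with defocus blur growing linearly with the
distance to the focal plane, small per-slice positional drift, and
additive Gaussian sensor noise. Ground truth mirrors the annotation rule
used for such assays: an object within the depth of field of a slice is
labeled with its true class; further out (but still visible) it is an
out-of-focus *candidate*; beyond that it is absent from the slice.

The generator also provides growth dynamics (seeded geometric branching
per hour, scaled down by a drug-inhibition factor) and dose-response
tables (4PL curve plus noise), so the downstream counting and IC50
machinery is testable end to end without microscope data.

All randomness flows from explicit integer seeds through per-call
``numpy.random.Generator`` instances; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .boxes import BoundingBox
from .classes import CANDIDATE, class_from_cell_count
from .doseresponse import four_param_logistic

__all__ = [
    "SceneObject",
    "SceneConfig",
    "GroundTruth",
    "GTEntry",
    "GrowthConfig",
    "sample_scene",
    "render_stack",
    "simulate_growth",
    "simulate_dose_response",
    "plan_dataset",
    "radius_from_cell_count",
    "slice_z_positions",
]


def radius_from_cell_count(cell_count: int, cell_radius_um: float) -> float:
    """In-focus equivalent radius (µm): projected area grows linearly with
    the number of cell-equivalents, so radius ~ sqrt(count)."""
    return cell_radius_um * math.sqrt(cell_count)


@dataclass(frozen=True)
class SceneObject:
    """One ground-truth 3D object in the field.

    ``drift_px`` holds the per-slice (dx, dy) center offsets in pixels,
    shape (n_slices, 2); zeros when the scene is drift-free.
    """

    object_id: int
    center_xy: tuple[float, float]  # µm within the field
    focal_z: float  # µm
    cell_count: int
    radius: float  # µm, in focus
    true_class: str
    drift_px: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def with_cell_count(self, cell_count: int, cell_radius_um: float) -> "SceneObject":
        return replace(
            self,
            cell_count=cell_count,
            radius=radius_from_cell_count(cell_count, cell_radius_um),
            true_class=class_from_cell_count(cell_count),
        )


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry and imaging parameters.

    Defaults mirror the assay's Z-stack protocol: 19 slices at 30 µm
    separation (total axial height = n_slices x slice_spacing), brightfield
    at a field scale where one pixel is 2 µm. Objects within ``dof`` µm of
    a slice are in focus; out to ``candidate_depth`` they are visible but
    blurred (annotated as candidates); beyond that they leave no annotation.
    """

    n_slices: int = 19
    slice_spacing: float = 30.0  # µm
    image_size: tuple[int, int] = (256, 256)  # (width, height) px
    pixel_size: float = 2.0  # µm per px
    object_counts: dict[str, int] = field(
        default_factory=lambda: {"cell": 5, "cluster": 3, "colony": 2}
    )
    drift_sigma: float = 0.5  # px per slice, random-walk step
    noise_sigma: float = 0.01  # intensity units (image range [0, 1])
    blur_slope: float = 0.08  # blur-µm per defocus-µm
    base_blur: float = 1.0  # µm, residual blur at perfect focus
    dof: float = 20.0  # µm, in-focus half depth
    candidate_depth: float = 100.0  # µm, visibility half depth
    cell_radius: float = 6.0  # µm, radius of one cell-equivalent
    min_separation: float = 12.0  # µm gap enforced between object rims
    background: float = 0.85  # brightfield background intensity
    absorbance: float = 0.55  # in-focus intensity dip of an object
    cluster_count_range: tuple[int, int] = (3, 12)
    colony_count_range: tuple[int, int] = (18, 30)
    render_depth_factor: float = 1.5  # render objects out to this x candidate_depth
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (self.candidate_depth > self.dof > 0):
            raise ValueError("require candidate_depth > dof > 0")
        unknown = set(self.object_counts) - {"cell", "cluster", "colony"}
        if unknown:
            raise ValueError(f"unknown object classes: {sorted(unknown)}")

    @property
    def total_height(self) -> float:
        """Axial stack height in µm (n_slices x spacing convention)."""
        return self.n_slices * self.slice_spacing

    @property
    def max_blur_um(self) -> float:
        """Blur width at the deepest defocus an object is still rendered."""
        return self.base_blur + self.blur_slope * self.candidate_depth * self.render_depth_factor

    @property
    def field_um(self) -> tuple[float, float]:
        return (
            self.image_size[0] * self.pixel_size,
            self.image_size[1] * self.pixel_size,
        )


def slice_z_positions(config: SceneConfig) -> np.ndarray:
    """Axial position (µm) of each slice's focal plane: slice i sits at
    (i + 1/2) x spacing, so the stack spans the full total height."""
    return (np.arange(config.n_slices) + 0.5) * config.slice_spacing


@dataclass(frozen=True)
class GTEntry:
    object_id: int
    bbox: BoundingBox
    label: str


@dataclass
class GroundTruth:
    """Per-slice ground-truth annotations for one rendered scene."""

    entries: dict[int, list[GTEntry]]  # slice_index -> entries
    n_slices: int
    image_size: tuple[int, int]

    def object_ids(self) -> set[int]:
        return {e.object_id for lst in self.entries.values() for e in lst}

    def total_boxes(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_frames(self) -> dict[int, dict[int, BoundingBox]]:
        """object_id -> {slice_index -> box}, the track-shaped view used
        by the evaluation module."""
        out: dict[int, dict[int, BoundingBox]] = {}
        for sl, lst in self.entries.items():
            for e in lst:
                out.setdefault(e.object_id, {})[sl] = e.bbox
        return out

    def labels_by_object(self) -> dict[int, dict[int, str]]:
        out: dict[int, dict[int, str]] = {}
        for sl, lst in self.entries.items():
            for e in lst:
                out.setdefault(e.object_id, {})[sl] = e.label
        return out


def _gt_box(
    obj: SceneObject, slice_index: int, dz: float, config: SceneConfig
) -> BoundingBox | None:
    """Ground-truth box of an object on one slice (None if off-image)."""
    sigma_um = config.base_blur + config.blur_slope * abs(dz)
    half_um = obj.radius + sigma_um
    dx, dy = (
        obj.drift_px[slice_index]
        if obj.drift_px.size
        else (0.0, 0.0)
    )
    cx = obj.center_xy[0] / config.pixel_size + dx
    cy = obj.center_xy[1] / config.pixel_size + dy
    half_px = half_um / config.pixel_size
    box = BoundingBox(cx - half_px, cy - half_px, 2 * half_px, 2 * half_px)
    try:
        return box.clip(config.image_size[0], config.image_size[1])
    except ValueError:
        return None


def _build_ground_truth(
    objects: list[SceneObject], config: SceneConfig
) -> GroundTruth:
    z = slice_z_positions(config)
    entries: dict[int, list[GTEntry]] = {i: [] for i in range(config.n_slices)}
    for obj in objects:
        for i in range(config.n_slices):
            dz = abs(z[i] - obj.focal_z)
            if dz <= config.dof:
                label = obj.true_class
            elif dz <= config.candidate_depth:
                label = CANDIDATE
            else:
                continue
            box = _gt_box(obj, i, dz, config)
            if box is not None:
                entries[i].append(GTEntry(obj.object_id, box, label))
    return GroundTruth(entries, config.n_slices, config.image_size)


def sample_scene(config: SceneConfig) -> tuple[list[SceneObject], GroundTruth]:
    """Draw a scene of non-overlapping objects and its ground truth.

    Object counts per class follow ``config.object_counts`` exactly.
    Placement is rejection-sampled so that the *visible footprints* —
    rims expanded by the blur width at the deepest rendered defocus —
    stay ``min_separation`` µm apart; two objects at different depths
    therefore never overlap on any slice, however blurred. Focal depths
    are uniform over the slice range, which guarantees every object is
    in focus on at least one slice when dof >= spacing/2. Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    field_w, field_h = config.field_um
    z_lo, z_hi = 0.5 * config.slice_spacing, (config.n_slices - 0.5) * config.slice_spacing

    spec: list[tuple[str, int]] = []
    for cls in ("cell", "cluster", "colony"):
        spec += [(cls, k) for k in range(config.object_counts.get(cls, 0))]

    objects: list[SceneObject] = []
    for object_id, (cls, _) in enumerate(spec):
        if cls == "cell":
            count = 1
        elif cls == "cluster":
            lo, hi = config.cluster_count_range
            count = int(rng.integers(lo, hi + 1))
        else:
            lo, hi = config.colony_count_range
            count = int(rng.integers(lo, hi + 1))
        radius = radius_from_cell_count(count, config.cell_radius)
        footprint = radius + config.max_blur_um
        margin = radius + config.min_separation
        if 2 * margin >= min(field_w, field_h):
            raise ValueError("field too small for requested objects")
        for _attempt in range(10_000):
            cx = rng.uniform(margin, field_w - margin)
            cy = rng.uniform(margin, field_h - margin)
            ok = all(
                math.hypot(cx - o.center_xy[0], cy - o.center_xy[1])
                >= footprint + o.radius + config.max_blur_um + config.min_separation
                for o in objects
            )
            if ok:
                break
        else:
            raise ValueError("could not place objects without overlap")
        focal_z = float(rng.uniform(z_lo, z_hi))
        if config.drift_sigma > 0:
            steps = rng.normal(0.0, config.drift_sigma, size=(config.n_slices, 2))
            steps[0] = 0.0
            drift = np.cumsum(steps, axis=0)
        else:
            drift = np.zeros((config.n_slices, 2))
        objects.append(
            SceneObject(
                object_id=object_id,
                center_xy=(cx, cy),
                focal_z=focal_z,
                cell_count=count,
                radius=radius,
                true_class=class_from_cell_count(count),
                drift_px=drift,
            )
        )
    return objects, _build_ground_truth(objects, config)


def _render_object(
    canvas: np.ndarray, obj: SceneObject, slice_index: int, dz: float, config: SceneConfig
) -> None:
    """Accumulate one object's absorbance on a slice canvas (in place).

    The object is a uniform dark disk convolved with an isotropic Gaussian
    whose width grows linearly with defocus; convolution conserves total
    absorbance, so peak contrast fades as blur spreads it out.
    """
    h, w = canvas.shape
    dx, dy = obj.drift_px[slice_index] if obj.drift_px.size else (0.0, 0.0)
    cx = obj.center_xy[0] / config.pixel_size + dx
    cy = obj.center_xy[1] / config.pixel_size + dy
    r_px = obj.radius / config.pixel_size
    sigma_px = (config.base_blur + config.blur_slope * dz) / config.pixel_size

    pad = int(math.ceil(r_px + 4 * sigma_px)) + 2
    x0, x1 = int(math.floor(cx)) - pad, int(math.floor(cx)) + pad + 1
    y0, y1 = int(math.floor(cy)) - pad, int(math.floor(cy)) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (
        ((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2) <= r_px**2
    ).astype(float) * config.absorbance
    blurred = ndimage.gaussian_filter(disk, sigma_px) if sigma_px > 0 else disk
    canvas[y0c:y1c, x0c:x1c] += blurred[y0c - y0 : y1c - y0, x0c - x0 : x1c - x0]


def render_stack(objects: list[SceneObject], config: SceneConfig) -> np.ndarray:
    """Render the grayscale image stack, shape (n_slices, height, width),
    float in [0, 1]. Deterministic given ``config.seed`` (noise only)."""
    config.validate()
    w, h = config.image_size
    z = slice_z_positions(config)
    noise_rng = np.random.default_rng(config.seed + 1)  # decoupled from placement
    stack = np.empty((config.n_slices, h, w), dtype=np.float64)
    for i in range(config.n_slices):
        canvas = np.zeros((h, w), dtype=np.float64)
        for obj in objects:
            dz = abs(z[i] - obj.focal_z)
            if dz <= config.candidate_depth * config.render_depth_factor:  # faint past GT cutoff
                _render_object(canvas, obj, i, dz, config)
        img = config.background - canvas
        if config.noise_sigma > 0:
            img = img + noise_rng.normal(0.0, config.noise_sigma, size=img.shape)
        stack[i] = np.clip(img, 0.0, 1.0)
    return stack


@dataclass(frozen=True)
class GrowthConfig:
    """Stochastic growth of object cell counts over assay timepoints.

    ``base_rate`` is the per-cell division probability per hour in the
    uninhibited condition; ``inhibition`` maps a drug concentration (nM)
    to a factor in [0, 1] (1 = full inhibition, growth stops). The default
    rate gives an expected doubling every 12 h, so a single cell is
    expected to pass the 15-cell colony threshold at about 60 h, matching
    the observed onset of colony formation in untreated assays.
    """

    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0)
    base_rate: float = 2.0 ** (1.0 / 12.0) - 1.0  # divisions/hour, doubling per 12 h
    inhibition: Callable[[float], float] = lambda concentration: 0.0
    step_hours: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")


def simulate_growth(
    initial_objects: list[SceneObject],
    growth: GrowthConfig,
    concentration: float,
    cell_radius_um: float = 6.0,
) -> dict[float, list[SceneObject]]:
    """Evolve cell counts by seeded geometric branching.

    Each cell divides independently per ``step_hours`` step with
    probability base_rate x (1 - inhibition(concentration)) x step; counts
    therefore grow stochastically exponentially and never decrease. The
    class and radius of each object are re-derived from its count at every
    timepoint. Returns {timepoint -> object list}.
    """
    growth.validate()
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    inhib = float(growth.inhibition(concentration))
    inhib = min(max(inhib, 0.0), 1.0)
    p_step = min(1.0, growth.base_rate * (1.0 - inhib) * growth.step_hours)
    rng = np.random.default_rng(growth.seed)

    counts = np.array([o.cell_count for o in initial_objects], dtype=np.int64)
    out: dict[float, list[SceneObject]] = {}
    t = growth.timepoints[0] if growth.timepoints else 0.0
    for tp in growth.timepoints:
        while t + growth.step_hours <= tp + 1e-9:
            if p_step > 0:
                counts = counts + rng.binomial(counts, p_step)
            t += growth.step_hours
        out[tp] = [
            o.with_cell_count(int(c), cell_radius_um)
            for o, c in zip(initial_objects, counts)
        ]
    return out


def simulate_dose_response(
    truth: dict[str, float],
    concentrations: list[float],
    n_rep: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Normalized cluster+colony responses from a known 4PL ground truth.

    ``truth`` holds top, bottom, logIC50, hill; responses are the 4PL
    evaluated at log10(concentration) plus iid Gaussian noise of sd
    ``noise_sd``. Returns a tidy table (concentration_nM, replicate,
    response).
    """
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        mu = four_param_logistic(
            math.log10(c), truth["top"], truth["bottom"], truth["logIC50"], truth["hill"]
        )
        for rep in range(n_rep):
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"concentration_nM": c, "replicate": rep, "response": y})
    return pd.DataFrame(rows)


def plan_dataset(n_base: int, n_aug_per_base: int) -> int:
    """Total training images after augmenting each base image
    ``n_aug_per_base`` times: n_base x (1 + n_aug_per_base)."""
    if n_base < 0 or n_aug_per_base < 0:
        raise ValueError("dataset sizes must be non-negative")
    return n_base * (1 + n_aug_per_base)
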