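"""Channel preprocessing and object segmentation.

The grain-detection chain enhances point-like structure with a 3-D
difference of Gaussians (sigma 0.7 and 2 in pixel units), finds an initial
threshold with the Ridler-Calvard (ISODATA) algorithm, then segments
iteratively: at each successive threshold (+25 intensity units per step)
connected components whose physical volume falls inside the grain gate
(0.03-0.1 um^3) are accepted and removed, components still larger than the
gate are carried to the next, higher threshold, and iteration stops once no
component exceeds the upper gate.  Broad-spectrum lipofuscin aggregates are
segmented from the autofluorescence channel with a single Ridler-Calvard
pass, and any grain sharing a voxel with a lipofuscin object is excluded as
a potential false positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateInputError, GeometryError
from .geometry import AcquisitionGeometry
from .stack import VoxelStack

__all__ = [
    "DoGParams",
    "GateParams",
    "SegmentedObject",
    "LabeledObjectSet",
    "dog_filter",
    "ridler_calvard_threshold",
    "segment_at",
    "iterative_grain_segmentation",
    "segment_lipofuscin",
    "exclude_overlapping",
    "fixed_normalized_threshold",
    "normalize_exposure",
    "gate_voxel_range",
]


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians sigmas, in x/y pixel units.

    The z sigma is scaled by ``dx / dz`` so smoothing is isotropic in
    micrometres despite anisotropic voxels.
    """

    sigma_small: float = 0.7
    sigma_large: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_small < self.sigma_large:
            raise ValueError(
                "require 0 < sigma_small < sigma_large, got "
                f"({self.sigma_small}, {self.sigma_large})"
            )


@dataclass(frozen=True)
class GateParams:
    """Volume gate and threshold increment for iterative grain segmentation."""

    v_min: float = 0.03  # um^3
    v_max: float = 0.1  # um^3
    step: float = 25.0  # intensity units per iteration

    def __post_init__(self) -> None:
        if not 0 < self.v_min < self.v_max:
            raise ValueError(f"require 0 < v_min < v_max, got ({self.v_min}, {self.v_max})")
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")


@dataclass
class SegmentedObject:
    """One connected 3-D component."""

    id: int
    coords: np.ndarray  # (n, 3) integer voxel indices, (z, y, x)
    voxel_count: int
    volume_um3: float
    centroid_um: np.ndarray  # (x, y, z) micrometres, voxel-centre convention
    threshold: float | None = None  # intensity at which the object was accepted

    def xy_points_um(self, dx: float, dy: float) -> np.ndarray:
        """Unique in-plane footprint as (x, y) voxel-centre coordinates, um."""
        xy = np.unique(self.coords[:, [2, 1]], axis=0).astype(float)
        return (xy + 0.5) * np.array([dx, dy])


@dataclass
class LabeledObjectSet:
    """Pairwise voxel-disjoint 3-D objects on a common grid."""

    objects: list[SegmentedObject]
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # (dx, dy, dz) um

    def __len__(self) -> int:
        return len(self.objects)

    def __iter__(self):
        return iter(self.objects)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def total_voxels(self) -> int:
        return int(sum(o.voxel_count for o in self.objects))

    def mask(self) -> np.ndarray:
        """Boolean union of all object voxels."""
        out = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            out[tuple(obj.coords.T)] = True
        return out

    def label_volume(self, dtype=np.int32) -> np.ndarray:
        out = np.zeros(self.shape, dtype=dtype)
        for obj in self.objects:
            out[tuple(obj.coords.T)] = obj.id
        return out

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "id": o.id,
                "voxel_count": o.voxel_count,
                "volume_um3": o.volume_um3,
                "centroid_x_um": o.centroid_um[0],
                "centroid_y_um": o.centroid_um[1],
                "centroid_z_um": o.centroid_um[2],
                "accept_threshold": np.nan if o.threshold is None else o.threshold,
            }
            for o in self.objects
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "voxel_count",
                "volume_um3",
                "centroid_x_um",
                "centroid_y_um",
                "centroid_z_um",
                "accept_threshold",
            ],
        )


def _empty_set(stack: VoxelStack) -> LabeledObjectSet:
    return LabeledObjectSet(objects=[], shape=stack.shape, voxel_size=(stack.dx, stack.dy, stack.dz))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_exposure(stack: VoxelStack) -> VoxelStack:
    """Convert intensities to counts per millisecond.

    Dividing by the exposure time puts channels acquired with different
    exposures on a common photometric scale; the result carries
    ``exposure_ms = 1``.
    """
    if not stack.exposure_ms or stack.exposure_ms <= 0:
        raise ValueError(f"exposure_ms must be a positive number, got {stack.exposure_ms!r}")
    values = np.asarray(stack.intensities, dtype=np.float64) / stack.exposure_ms
    return stack.with_intensities(values, exposure_ms=1.0)


def dog_filter(stack: VoxelStack, params: DoGParams = DoGParams()) -> VoxelStack:
    """3-D difference of Gaussians used to build the segmentation channel.

    Sigmas are given in x/y pixel units; the z sigma is ``sigma * dx / dz``
    so the physical smoothing length is the same along all axes.  The output
    is the raw (signed) difference; thresholding entry points clamp
    negatives to zero.
    """
    values = np.asarray(stack.intensities, dtype=np.float64)

    def smooth(sigma_px: float) -> np.ndarray:
        sigma_zyx = (sigma_px * stack.dx / stack.dz, sigma_px, sigma_px)
        return ndi.gaussian_filter(values, sigma=sigma_zyx, mode="reflect")

    out = smooth(params.sigma_small) - smooth(params.sigma_large)
    return stack.with_intensities(out)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def ridler_calvard_threshold(stack: VoxelStack | np.ndarray, nbins: int = 256) -> float:
    """Ridler-Calvard / ISODATA automatic threshold.

    Iterates ``T <- (mean(values < T) + mean(values >= T)) / 2`` starting
    from the global mean, on a ``nbins``-bin histogram over the intensity
    range, until the update moves by less than half a bin width.
    """
    values = stack.intensities if isinstance(stack, VoxelStack) else np.asarray(stack)
    values = values.ravel().astype(np.float64)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise DegenerateInputError("constant image: no threshold separates two classes")

    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    weighted = hist * centers

    t = float(weighted.sum() / hist.sum())  # global mean
    for _ in range(10_000):
        below = centers < t
        n0, n1 = hist[below].sum(), hist[~below].sum()
        if n0 == 0 or n1 == 0:
            # all mass on one side: nudge to the occupied side's midpoint
            break
        mu0 = weighted[below].sum() / n0
        mu1 = weighted[~below].sum() / n1
        t_new = 0.5 * (mu0 + mu1)
        if abs(t_new - t) < 0.5 * width:
            return float(t_new)
        t = t_new
    return float(t)


def fixed_normalized_threshold(stack: VoxelStack, fraction: float) -> LabeledObjectSet:
    """Segment at a threshold normalized to the stack's intensity range.

    ``threshold = min + fraction * (max - min)``.  Used for cross-treatment
    comparisons (e.g. quencher experiments) where an automatic threshold
    would absorb global intensity shifts between conditions.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    values = stack.intensities
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise DegenerateInputError("constant image: normalized threshold undefined")
    return segment_at(stack, lo + fraction * (hi - lo))


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _label_deterministic(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int, np.ndarray]:
    """Label ``mask``; return labels, count and label order.

    ``order`` lists the raw scipy labels sorted by the C-order (lexicographic
    (z, y, x)) index of each component's first voxel, which makes object
    numbering deterministic across runs and platforms.
    """
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    if n == 0:
        return labels, 0, np.empty(0, dtype=np.int64)
    flat_index = np.arange(labels.size, dtype=np.int64).reshape(labels.shape)
    first = ndi.minimum(flat_index, labels, index=np.arange(1, n + 1))
    order = np.argsort(np.asarray(first), kind="stable") + 1
    return labels, n, order


def _objects_from_labels(
    labels: np.ndarray,
    order: Sequence[int],
    stack: VoxelStack,
    threshold: float | None,
    start_id: int = 1,
) -> list[SegmentedObject]:
    voxel_volume = stack.voxel_volume_um3
    scale = np.array([stack.dx, stack.dy, stack.dz])
    slices = ndi.find_objects(labels)
    out: list[SegmentedObject] = []
    for new_id, raw_label in enumerate(order, start=start_id):
        slc = slices[raw_label - 1]
        local = np.argwhere(labels[slc] == raw_label)
        offset = np.array([s.start for s in slc])
        coords = local + offset
        centroid_zyx = coords.mean(axis=0) + 0.5  # voxel-centre convention
        centroid_um = centroid_zyx[::-1] * scale  # (x, y, z)
        out.append(
            SegmentedObject(
                id=new_id,
                coords=coords,
                voxel_count=coords.shape[0],
                volume_um3=coords.shape[0] * voxel_volume,
                centroid_um=centroid_um,
                threshold=threshold,
            )
        )
    return out


def segment_at(
    stack: VoxelStack, threshold: float, connectivity: int = 26
) -> LabeledObjectSet:
    """Connected components of ``{voxels >= threshold}``.

    Components are numbered in lexicographic order of their first (z, y, x)
    voxel so labeling is reproducible.
    """
    mask = stack.intensities >= threshold
    labels, n, order = _label_deterministic(mask, connectivity)
    if n == 0:
        return _empty_set(stack)
    objects = _objects_from_labels(labels, order, stack, threshold)
    return LabeledObjectSet(
        objects=objects, shape=stack.shape, voxel_size=(stack.dx, stack.dy, stack.dz)
    )


# ---------------------------------------------------------------------------
# iterative volume-gated grain segmentation
# ---------------------------------------------------------------------------

def gate_voxel_range(
    geometry_or_stack: AcquisitionGeometry | VoxelStack, gate: GateParams = GateParams()
) -> tuple[int, int]:
    """Inclusive voxel-count range corresponding to the physical gate."""
    v = geometry_or_stack.voxel_volume_um3
    lo = int(np.ceil(gate.v_min / v - 1e-12))
    hi = int(np.floor(gate.v_max / v + 1e-12))
    return max(lo, 1), hi


def iterative_grain_segmentation(
    dog_stack: VoxelStack,
    gate: GateParams = GateParams(),
    connectivity: int = 26,
    record_thresholds: list | None = None,
) -> LabeledObjectSet:
    """Size-gated iterative segmentation of FISH grains.

    Starting from the Ridler-Calvard threshold of the (non-negative part of
    the) DoG channel, segment at ``T0 + k * step`` for k = 0, 1, ...; at each
    pass accept components whose volume lies inside ``[v_min, v_max]`` and
    remove their voxels, drop components below ``v_min`` (they can only
    shrink at higher thresholds), and continue while any component exceeds
    ``v_max``.  Each accepted object records the threshold that produced it.

    ``record_thresholds``, if given, collects the per-iteration threshold
    values for audit logging.
    """
    values = np.clip(np.asarray(dog_stack.intensities, dtype=np.float64), 0.0, None)
    if values.max() == values.min():
        warnings.warn("degenerate (constant) segmentation channel; returning no objects")
        return _empty_set(dog_stack)

    voxel_volume = dog_stack.voxel_volume_um3
    if voxel_volume > gate.v_min:
        warnings.warn(
            f"voxel volume {voxel_volume:.4g} um^3 exceeds the lower gate "
            f"{gate.v_min} um^3: grains at this resolution fall below the "
            "voxel gate and cannot be resolved reliably"
        )
    lo_vox, hi_vox = gate_voxel_range(dog_stack, gate)

    t0 = ridler_calvard_threshold(values)
    remaining = values.copy()
    accepted: list[SegmentedObject] = []
    k = 0
    while True:
        t = t0 + k * gate.step
        if record_thresholds is not None:
            record_thresholds.append(t)
        mask = remaining >= t
        if not mask.any():
            break
        labels, n, order = _label_deterministic(mask, connectivity)
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        in_gate = order[(counts[order - 1] >= lo_vox) & (counts[order - 1] <= hi_vox)]
        if in_gate.size:
            new = _objects_from_labels(
                labels, in_gate, dog_stack, threshold=t, start_id=len(accepted) + 1
            )
            accepted.extend(new)
        # accepted and undersized components leave the race; only oversized
        # components remain to be re-segmented at the next threshold
        oversized = np.flatnonzero(counts > hi_vox) + 1
        if oversized.size == 0:
            break
        keep = np.isin(labels, oversized)
        remaining[~keep] = 0.0
        k += 1

    return LabeledObjectSet(
        objects=accepted, shape=dog_stack.shape, voxel_size=(dog_stack.dx, dog_stack.dy, dog_stack.dz)
    )


def segment_lipofuscin(af_stack: VoxelStack, connectivity: int = 26) -> LabeledObjectSet:
    """Single-pass Ridler-Calvard segmentation of lipofuscin aggregates.

    ``af_stack`` is the autofluorescence channel after the same DoG
    preprocessing as the grain channel (negatives clamped here); there is no
    size gate -- aggregates of any size count.
    """
    values = np.clip(np.asarray(af_stack.intensities, dtype=np.float64), 0.0, None)
    if values.max() == values.min():
        warnings.warn("degenerate (constant) autofluorescence channel; returning no objects")
        return _empty_set(af_stack)
    t = ridler_calvard_threshold(values)
    return segment_at(af_stack.with_intensities(values), t, connectivity=connectivity)


# ---------------------------------------------------------------------------
# lipofuscin exclusion
# ---------------------------------------------------------------------------

def exclude_overlapping(
    grains: LabeledObjectSet, lipofuscin: LabeledObjectSet
) -> LabeledObjectSet:
    """Drop every grain sharing at least one voxel with a lipofuscin object.

    Controls for broad-spectrum autofluorescence: lipofuscin appears in all
    channels, so any grain-channel object intersecting a lipofuscin mask is
    a potential false positive.
    """
    if grains.shape != lipofuscin.shape or not np.allclose(
        grains.voxel_size, lipofuscin.voxel_size
    ):
        raise GeometryError(
            f"grain grid {grains.shape}/{grains.voxel_size} does not match "
            f"lipofuscin grid {lipofuscin.shape}/{lipofuscin.voxel_size}"
        )
    lipo_mask = lipofuscin.mask()
    survivors = [
        obj for obj in grains.objects if not lipo_mask[tuple(obj.coords.T)].any()
    ]
    renumbered = [
        SegmentedObject(
            id=i,
            coords=o.coords,
            voxel_count=o.voxel_count,
            volume_um3=o.volume_um3,
            centroid_um=o.centroid_um,
            threshold=o.threshold,
        )
        for i, o in enumerate(survivors, start=1)
    ]
    return LabeledObjectSet(objects=renumbered, shape=grains.shape, voxel_size=grains.voxel_size)
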