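"""Cell-mask validation, unbiased counting frames, and density estimation.

Cell masks (pre-drawn label volumes) are validated against the criteria a
histologist would apply before counting: the mask must contain a nucleus,
span several contiguous z-planes, and its centre plane -- the plane of
largest cross-sectional area -- must not sit on the first or last plane of
the stack.  Counting uses the classical unbiased (Gundersen) frame: an
object is counted iff it intersects the frame and touches neither exclusion
edge nor their extensions, so each object is countable in exactly one frame
position when frames tile the section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import AcquisitionGeometry
from .segmentation import LabeledObjectSet, SegmentedObject

__all__ = [
    "CellRecord",
    "CountingFrame",
    "DensityResult",
    "cells_from_labels",
    "validate_cell_mask",
    "frame_filter",
    "frame_contains_points",
    "assign_grains_to_cells",
    "classify_sst_cells_60x",
    "classify_sst_cells_20x",
    "cell_density",
    "tissue_grain_density",
]


@dataclass
class CellRecord:
    """A candidate cell mask spanning z-planes."""

    cell_id: int
    coords: np.ndarray  # (n, 3) voxel indices (z, y, x)
    z_extent: tuple[int, int]  # inclusive plane range
    center_plane: int  # plane of largest cross-sectional area
    has_nucleus: bool | None = None
    grain_count: int = 0
    grain_ids: list[int] = field(default_factory=list)
    cluster_count: int | None = None
    sst_class: bool | None = None  # True = SST-positive
    accepted: bool | None = None
    reasons: list[str] = field(default_factory=list)
    frame_included: bool | None = None

    @property
    def voxel_count(self) -> int:
        return int(self.coords.shape[0])

    def xy_points_um(self, dx: float, dy: float) -> np.ndarray:
        xy = np.unique(self.coords[:, [2, 1]], axis=0).astype(float)
        return (xy + 0.5) * np.array([dx, dy])


def cells_from_labels(cell_labels: np.ndarray, geometry: AcquisitionGeometry) -> list[CellRecord]:
    """Build cell records from a 3-D label volume (0 = background).

    The centre plane is the z-plane with the largest cross-sectional area
    (ties broken toward the lower plane index, deterministically).
    """
    from scipy import ndimage as ndi

    labels = np.asarray(cell_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    records: list[CellRecord] = []
    slices = ndi.find_objects(labels)
    for cid in ids:
        slc = slices[int(cid) - 1]
        if slc is None:
            continue
        local = np.argwhere(labels[slc] == cid)
        coords = local + np.array([s.start for s in slc])
        z_values = coords[:, 0]
        plane_counts = np.bincount(z_values, minlength=geometry.n_z)
        center_plane = int(np.argmax(plane_counts))  # argmax -> lowest tie
        records.append(
            CellRecord(
                cell_id=int(cid),
                coords=coords,
                z_extent=(int(z_values.min()), int(z_values.max())),
                center_plane=center_plane,
            )
        )
    return records


def validate_cell_mask(
    cell: CellRecord,
    nuclear_mask: np.ndarray,
    n_planes: int,
    min_z_planes: int = 3,
) -> tuple[bool, list[str]]:
    """Apply the counting criteria to one cell mask.

    Accepted iff the mask overlaps the nuclear segmentation, spans at least
    ``min_z_planes`` contiguous planes, and its centre plane is interior to
    the stack.  Returns (accepted, reasons); never raises on a failing cell.
    """
    if cell.voxel_count == 0:
        raise ValueError("cell mask is empty")
    reasons: list[str] = []
    if not nuclear_mask[tuple(cell.coords.T)].any():
        reasons.append("no nuclear overlap")
    z_lo, z_hi = cell.z_extent
    spanned = np.unique(cell.coords[:, 0])
    if len(spanned) < min_z_planes or len(spanned) != (z_hi - z_lo + 1):
        reasons.append(f"not continuous across >= {min_z_planes} z-planes")
    if cell.center_plane <= 0 or cell.center_plane >= n_planes - 1:
        reasons.append("center on boundary plane")
    cell.accepted = not reasons
    cell.reasons = reasons
    return cell.accepted, reasons


# ---------------------------------------------------------------------------
# counting frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountingFrame:
    """Axis-aligned unbiased counting frame.

    By default the max-x ("right") and max-y ("top") edges are inclusion
    lines and the min-x/min-y edges are exclusion lines whose extensions --
    upward from the top-left corner, downward from the bottom-right corner --
    reach the field boundary.  ``exclusion_edges`` may be set to
    ``("right", "top")`` to mirror the convention.
    """

    origin_x_um: float
    origin_y_um: float
    width_um: float
    height_um: float
    exclusion_edges: tuple[str, str] = ("left", "bottom")

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError("frame width and height must be > 0")
        if set(self.exclusion_edges) not in ({"left", "bottom"}, {"right", "top"}):
            raise ValueError(
                "exclusion_edges must be ('left','bottom') or ('right','top')"
            )

    @classmethod
    def centered(
        cls, geometry: AcquisitionGeometry, width_um: float, height_um: float, **kw
    ) -> "CountingFrame":
        return cls(
            origin_x_um=(geometry.field_x_um - width_um) / 2,
            origin_y_um=(geometry.field_y_um - height_um) / 2,
            width_um=width_um,
            height_um=height_um,
            **kw,
        )

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def check_inside_field(self, geometry: AcquisitionGeometry) -> None:
        if (
            self.origin_x_um < 0
            or self.origin_y_um < 0
            or self.origin_x_um + self.width_um > geometry.field_x_um + 1e-9
            or self.origin_y_um + self.height_um > geometry.field_y_um + 1e-9
        ):
            raise GeometryError("counting frame extends outside the imaged field")


def frame_contains_points(frame: CountingFrame, points_xy_um: np.ndarray) -> bool:
    """Unbiased-frame decision for one object given its (x, y) point set.

    Included iff some point lies in the frame (inclusion edges count as
    inside) and no point touches an exclusion edge or its extension.
    """
    pts = np.atleast_2d(np.asarray(points_xy_um, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    x0, y0 = frame.origin_x_um, frame.origin_y_um
    x1, y1 = x0 + frame.width_um, y0 + frame.height_um
    inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if not inside.any():
        return False
    if set(frame.exclusion_edges) == {"left", "bottom"}:
        # forbidden line: left edge + upward extension, bottom edge +
        # downward extension at the bottom-right corner
        touches = ((x <= x0) & (y >= y0)) | ((y <= y0) & (x >= x0))
    else:
        touches = ((x >= x1) & (y <= y1)) | ((y >= y1) & (x <= x1))
    return not touches.any()


def frame_filter(objects, frame: CountingFrame, dx: float, dy: float):
    """Subset of ``objects`` counted by the unbiased frame.

    Objects may be :class:`CellRecord` / :class:`SegmentedObject` instances
    (their full in-plane voxel footprint is used) or raw (x, y) coordinate
    arrays for point objects.
    """
    included = []
    for obj in objects:
        if isinstance(obj, (CellRecord, SegmentedObject)):
            pts = obj.xy_points_um(dx, dy)
        else:
            pts = np.atleast_2d(np.asarray(obj, dtype=float))
        keep = frame_contains_points(frame, pts)
        if isinstance(obj, CellRecord):
            obj.frame_included = keep
        if keep:
            included.append(obj)
    return included


# ---------------------------------------------------------------------------
# grain assignment and classification
# ---------------------------------------------------------------------------

def assign_grains_to_cells(
    grains: LabeledObjectSet, cells: list[CellRecord]
) -> tuple[list[CellRecord], list[SegmentedObject]]:
    """Assign each grain to the cell mask it overlaps.

    A grain overlapping exactly one cell belongs to it; a grain overlapping
    several is assigned to the cell with the largest voxel overlap (ties to
    the lowest cell id); grains touching no cell are returned unassigned.
    Conservation: assigned + unassigned == total grains.
    """
    label_volume = np.zeros(grains.shape, dtype=np.int32)
    for cell in cells:
        label_volume[tuple(cell.coords.T)] = cell.cell_id
    by_id = {cell.cell_id: cell for cell in cells}
    for cell in cells:
        cell.grain_count = 0
        cell.grain_ids = []

    unassigned: list[SegmentedObject] = []
    for grain in grains:
        hits = label_volume[tuple(grain.coords.T)]
        hits = hits[hits > 0]
        if hits.size == 0:
            unassigned.append(grain)
            continue
        ids, counts = np.unique(hits, return_counts=True)
        winner = ids[np.lexsort((ids, -counts))][0]  # max overlap, tie -> lowest id
        cell = by_id[int(winner)]
        cell.grain_count += 1
        cell.grain_ids.append(grain.id)
    return cells, unassigned


def classify_sst_cells_60x(cells: list[CellRecord], min_grains: int = 20) -> list[CellRecord]:
    """High-resolution rule: SST-positive iff grain_count >= min_grains."""
    for cell in cells:
        cell.sst_class = cell.grain_count >= min_grains
    return cells


def _single_linkage_clusters(points_um: np.ndarray, link_radius_um: float) -> int:
    """Number of single-linkage clusters at the given linking distance."""
    n = len(points_um)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = np.sum((points_um[:, None, :] - points_um[None, :, :]) ** 2, axis=-1)
    link = d2 <= link_radius_um**2
    for i in range(n):
        for j in range(i + 1, n):
            if link[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(n)})


def classify_sst_cells_20x(
    cells: list[CellRecord],
    grains: LabeledObjectSet,
    min_clusters: int = 10,
    cluster_link_radius_um: float = 1.5,
) -> list[CellRecord]:
    """Low-resolution rule: SST-positive iff >= min_clusters grain clusters.

    At 20x individual grains blur into cluster-like structures, so each
    cell's assigned grain objects are merged by single linkage at
    ``cluster_link_radius_um`` before counting.
    """
    by_id = {g.id: g for g in grains}
    for cell in cells:
        pts = np.array([by_id[g].centroid_um for g in cell.grain_ids]) if cell.grain_ids else np.zeros((0, 3))
        cell.cluster_count = _single_linkage_clusters(pts, cluster_link_radius_um)
        cell.sst_class = cell.cluster_count >= min_clusters
    return cells


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass
class DensityResult:
    """Counted objects over a stereological reference volume."""

    counted: int
    reference_volume_mm3: float
    density_per_mm3: float
    per_stack: list[tuple[int, float]] = field(default_factory=list)  # (count, volume)


def cell_density(
    counts_per_stack: list[int],
    frames: list[CountingFrame],
    thickness_um: float,
) -> DensityResult:
    """Cells per mm^3 from frame counts: sum(counts) / sum(area x thickness)."""
    if len(counts_per_stack) != len(frames):
        raise ValueError("one counting frame per stack is required")
    volumes = [f.area_um2 * thickness_um * 1e-9 for f in frames]
    total_volume = float(sum(volumes))
    if total_volume <= 0:
        raise ValueError("zero stereological reference volume")
    counted = int(sum(counts_per_stack))
    return DensityResult(
        counted=counted,
        reference_volume_mm3=total_volume,
        density_per_mm3=counted / total_volume,
        per_stack=list(zip(counts_per_stack, volumes)),
    )


def tissue_grain_density(
    grain_counts_per_stack: list[int], geometry: AcquisitionGeometry
) -> DensityResult:
    """Grains per mm^3 of imaged tissue (field area x section thickness)."""
    volume = geometry.stack_volume_mm3()
    if volume <= 0:
        raise ValueError("zero imaged tissue volume")
    total_volume = volume * len(grain_counts_per_stack)
    if total_volume <= 0:
        raise ValueError("no stacks provided")
    counted = int(sum(grain_counts_per_stack))
    return DensityResult(
        counted=counted,
        reference_volume_mm3=total_volume,
        density_per_mm3=counted / total_volume,
        per_stack=[(c, volume) for c in grain_counts_per_stack],
    )
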