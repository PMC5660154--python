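"""Synthetic multichannel 3-D stacks with known ground truth.

Emulates wide-field FISH acquisitions of human cortex: nucleated somata
(nuclear + somatic counterstain channels), punctate mRNA grains rendered as
anti-aliased spheres with target volumes inside the physical grain gate,
and bright, irregular lipofuscin aggregates that -- like real lipofuscin --
appear in *every* channel and so act as broad-spectrum false positives.
Signal is forward-blurred by a Gaussian PSF, scaled by per-channel
exposure, and corrupted by Poisson shot noise plus Gaussian read noise.

Cohort generation produces two subject groups with configurable
multiplicative effects on labeled-cell density and grains per cell, with
per-subject child seeds split deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .geometry import AcquisitionGeometry
from .groupstats import SubjectRecord
from .stack import StackSet, VoxelStack, stack_from_geometry

__all__ = [
    "SimParams",
    "GroundTruth",
    "CohortSubject",
    "generate_stack",
    "generate_cohort",
]

GROUP_NAMES = ("young", "older")


@dataclass(frozen=True)
class SimParams:
    """Tissue and camera model parameters.

    Densities are per mm^3 of imaged volume; intensities are photon rates in
    counts per millisecond of exposure; sizes are micrometres.  Defaults
    describe a cortical field at full 60x scale: ~9e4 detectable somata/mm^3
    of which ~5% express the target transcript at ~40 grains per cell, over
    a sparse extracellular grain background, with age-accumulated
    lipofuscin aggregates several-fold brighter than single grains.
    """

    cell_density: float = 9.0e4  # somata / mm^3
    sst_fraction: float = 0.05  # fraction of somata expressing the target mRNA
    grains_per_sst_cell_mean: float = 40.0  # Poisson rate, expressing cells
    grains_per_other_cell_mean: float = 2.0  # Poisson rate, background cells
    extracellular_grain_rate: float = 2.0e5  # grains / mm^3 outside somata
    grain_volume_range: tuple[float, float] = (0.04, 0.09)  # um^3
    grain_min_separation_um: float = 0.7  # hard-core spacing of grains in a soma
    grain_intensity: float = 1200.0  # counts / ms at grain centre
    lipofuscin_count_rate: float = 2.0e4  # aggregates / mm^3
    lipofuscin_volume_range: tuple[float, float] = (0.5, 3.0)  # um^3
    lipofuscin_intensity: float = 2500.0  # counts / ms, >= 2x grain intensity
    cell_radius_um: float = 5.0
    cell_min_separation_um: float = 8.0  # hard-core spacing of soma centres
    nucleus_radius_fraction: float = 0.5
    cell_intensity: float = 250.0  # somatic counterstain, counts / ms
    nuclear_intensity: float = 400.0  # nuclear stain, counts / ms
    background_rate: float = 20.0  # counts / ms, all channels
    psf_sigma_xy: float = 0.13  # um
    psf_sigma_z: float = 0.30  # um
    noise_sd: float = 30.0  # Gaussian read noise, counts
    shot_noise: bool = True
    group_effects: tuple[float, float] = (0.36, 1.0)  # (cell density, grains/cell)
    seed: int = 0

    def __post_init__(self) -> None:
        non_negative = (
            "cell_density", "grains_per_sst_cell_mean", "grains_per_other_cell_mean",
            "extracellular_grain_rate", "lipofuscin_count_rate", "background_rate",
            "noise_sd",
        )
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.sst_fraction <= 1.0:
            raise ValueError(f"sst_fraction must be in [0, 1], got {self.sst_fraction}")
        for name in ("grain_volume_range", "lipofuscin_volume_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lower < upper, got ({lo}, {hi})")
        for eff in self.group_effects:
            if eff < 0:
                raise ValueError(f"group_effects must be >= 0, got {self.group_effects}")


@dataclass
class GroundTruth:
    """Generator bookkeeping for one stack.

    ``cells`` has one row per soma: id, centre (um), radius, is_sst flag and
    the grain count drawn for it.  ``grain_centroids_um`` is (n, 3) in
    (x, y, z); ``grain_owner`` holds the owning cell id (0 = extracellular).
    Volumetric arrays are ``None`` when the stack was book-kept but not
    rendered.
    """

    cells: pd.DataFrame
    grain_centroids_um: np.ndarray
    grain_owner: np.ndarray
    cell_labels: np.ndarray | None = None  # int16 label volume, 0 = background
    lipofuscin_mask: np.ndarray | None = None
    lipofuscin_centroids_um: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sst_cells(self) -> int:
        return int(self.cells["is_sst"].sum()) if len(self.cells) else 0

    def sst_density_per_mm3(self, geometry: AcquisitionGeometry) -> float:
        return self.n_sst_cells / _imaged_volume_mm3(geometry)

    def total_density_per_mm3(self, geometry: AcquisitionGeometry) -> float:
        return self.n_cells / _imaged_volume_mm3(geometry)


def _imaged_volume_mm3(geometry: AcquisitionGeometry) -> float:
    return geometry.field_x_um * geometry.field_y_um * geometry.depth_um * 1e-9


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _ball_box(center_um, radius_um, geometry):
    """Bounding index ranges and voxel-centre distance field for a sphere."""
    cx, cy, cz = center_um
    pitch = (geometry.dx, geometry.dy, geometry.dz)
    n = (geometry.n_x, geometry.n_y, geometry.n_z)
    los, his, axes = [], [], []
    for c, d, size in zip((cz, cy, cx), (geometry.dz, geometry.dy, geometry.dx),
                          (geometry.n_z, geometry.n_y, geometry.n_x)):
        lo = max(int(np.floor((c - radius_um) / d - 1)), 0)
        hi = min(int(np.ceil((c + radius_um) / d + 1)), size)
        los.append(lo)
        his.append(hi)
        axes.append((np.arange(lo, hi) + 0.5) * d - c)
    if any(lo >= hi for lo, hi in zip(los, his)):
        return None
    az, ay, ax = axes
    dist = np.sqrt(
        az[:, None, None] ** 2 + ay[None, :, None] ** 2 + ax[None, None, :] ** 2
    )
    box = (slice(los[0], his[0]), slice(los[1], his[1]), slice(los[2], his[2]))
    return box, dist


def _add_soft_ball(volume, center_um, radius_um, amplitude, geometry):
    """Accumulate an anti-aliased solid sphere into ``volume``."""
    hit = _ball_box(center_um, radius_um, geometry)
    if hit is None:
        return
    box, dist = hit
    edge = (geometry.dx * geometry.dy * geometry.dz) ** (1.0 / 3.0)
    coverage = np.clip(0.5 + (radius_um - dist) / edge, 0.0, 1.0)
    volume[box] += amplitude * coverage


def _paint_hard_ball(labels, center_um, radius_um, value, geometry):
    """Write ``value`` into unclaimed voxels whose centre lies in the sphere."""
    hit = _ball_box(center_um, radius_um, geometry)
    if hit is None:
        return
    box, dist = hit
    region = labels[box]
    sel = (dist <= radius_um) & (region == 0)
    region[sel] = value


def _radius_from_volume(volume_um3: float) -> float:
    return (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# tissue sampling (shared by rendered and bookkeeping-only paths)
# ---------------------------------------------------------------------------

def _dart_throw_in_ball(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    k: int,
    min_separation: float,
    max_attempts_per_point: int = 60,
) -> np.ndarray:
    """``k`` points uniform in a ball, rejecting points closer than
    ``min_separation`` to an accepted one; if the hard-core constraint jams,
    remaining points are placed unconstrained so the count is always met."""
    placed: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_point * k
    while len(placed) < k and attempts < budget:
        attempts += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p = center + direction * radius * rng.uniform() ** (1.0 / 3.0)
        if min_separation > 0 and placed:
            d2 = np.sum((np.asarray(placed) - p) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        placed.append(p)
    while len(placed) < k:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        placed.append(center + direction * radius * rng.uniform() ** (1.0 / 3.0))
    return np.asarray(placed)


def _dart_throw_in_box(
    rng: np.random.Generator,
    extent: np.ndarray,
    k: int,
    min_separation: float,
    max_attempts_per_point: int = 60,
) -> np.ndarray:
    """``k`` points uniform in a box with a hard-core minimum separation
    (somata do not interpenetrate); falls back to unconstrained placement if
    the constraint jams so the drawn count is always realized."""
    placed: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_point * max(k, 1)
    while len(placed) < k and attempts < budget:
        attempts += 1
        p = rng.uniform(0.0, 1.0, size=3) * extent
        if min_separation > 0 and placed:
            d2 = np.sum((np.asarray(placed) - p) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        placed.append(p)
    while len(placed) < k:
        placed.append(rng.uniform(0.0, 1.0, size=3) * extent)
    return np.asarray(placed) if placed else np.zeros((0, 3))


def _sample_tissue(geometry: AcquisitionGeometry, params: SimParams, rng: np.random.Generator):
    """Draw cells, grains and lipofuscin aggregates for one field."""
    extent = np.array([geometry.field_x_um, geometry.field_y_um, geometry.depth_um])
    vol_mm3 = _imaged_volume_mm3(geometry)

    n_cells = rng.poisson(params.cell_density * vol_mm3)
    centers = _dart_throw_in_box(rng, extent, n_cells, params.cell_min_separation_um)
    is_sst = rng.uniform(size=n_cells) < params.sst_fraction
    grain_means = np.where(
        is_sst, params.grains_per_sst_cell_mean, params.grains_per_other_cell_mean
    )
    grain_counts = rng.poisson(grain_means) if n_cells else np.zeros(0, dtype=int)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "x_um": centers[:, 0] if n_cells else np.zeros(0),
            "y_um": centers[:, 1] if n_cells else np.zeros(0),
            "z_um": centers[:, 2] if n_cells else np.zeros(0),
            "radius_um": np.full(n_cells, params.cell_radius_um),
            "is_sst": is_sst,
            "n_grains": grain_counts,
        }
    )

    # intracellular grains, uniform within 0.85 r so masks own their grains;
    # a hard-core minimum separation models discrete, resolvable amplified
    # grains rather than arbitrarily coincident points
    grain_pos, grain_owner = [], []
    for row in cells.itertuples():
        k = int(row.n_grains)
        if k == 0:
            continue
        center = np.array([row.x_um, row.y_um, row.z_um])
        pos = _dart_throw_in_ball(
            rng, center, 0.85 * row.radius_um, k, params.grain_min_separation_um
        )
        grain_pos.append(pos)
        grain_owner.append(np.full(k, row.cell_id))

    n_free = rng.poisson(params.extracellular_grain_rate * vol_mm3)
    if n_free:
        grain_pos.append(rng.uniform(0.0, 1.0, size=(n_free, 3)) * extent)
        grain_owner.append(np.zeros(n_free, dtype=int))

    if grain_pos:
        grain_pos = np.vstack(grain_pos)
        grain_owner = np.concatenate(grain_owner)
        inside = np.all((grain_pos >= 0) & (grain_pos < extent), axis=1)
        grain_pos, grain_owner = grain_pos[inside], grain_owner[inside]
    else:
        grain_pos = np.zeros((0, 3))
        grain_owner = np.zeros(0, dtype=int)
    grain_volumes = rng.uniform(*params.grain_volume_range, size=len(grain_pos))

    n_lipo = rng.poisson(params.lipofuscin_count_rate * vol_mm3)
    lipo_centers = rng.uniform(0.0, 1.0, size=(n_lipo, 3)) * extent
    lipo_volumes = rng.uniform(*params.lipofuscin_volume_range, size=n_lipo)
    lipo_lobes = rng.integers(2, 6, size=n_lipo)

    return cells, grain_pos, grain_owner, grain_volumes, lipo_centers, lipo_volumes, lipo_lobes


# ---------------------------------------------------------------------------
# stack generation
# ---------------------------------------------------------------------------

def generate_stack(
    geometry: AcquisitionGeometry,
    params: SimParams,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[StackSet, GroundTruth]:
    """Render one four-channel stack and its ground truth.

    Channels: ``nuclear`` (DAPI-like), ``grain`` (FISH fluorophore),
    ``somatic`` (Nissl-like counterstain), ``autofluorescence``.  Lipofuscin
    is added to all four.  Identical (geometry, params, seed) inputs yield
    bit-identical stacks.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    (cells, grain_pos, grain_owner, grain_volumes,
     lipo_centers, lipo_volumes, lipo_lobes) = _sample_tissue(geometry, params, rng)

    shape = geometry.shape
    rates = {name: np.full(shape, params.background_rate, dtype=np.float64)
             for name in ("nuclear", "grain", "somatic", "autofluorescence")}
    cell_labels = np.zeros(shape, dtype=np.int16)

    for row in cells.itertuples():
        center = (row.x_um, row.y_um, row.z_um)
        _paint_hard_ball(cell_labels, center, row.radius_um, int(row.cell_id), geometry)
        _add_soft_ball(rates["somatic"], center, row.radius_um, params.cell_intensity, geometry)
        _add_soft_ball(
            rates["nuclear"], center,
            params.nucleus_radius_fraction * row.radius_um,
            params.nuclear_intensity, geometry,
        )

    for pos, vol in zip(grain_pos, grain_volumes):
        _add_soft_ball(rates["grain"], pos, _radius_from_volume(vol), params.grain_intensity, geometry)

    lipo_coverage = np.zeros(shape, dtype=np.float64)
    for center, vol, n_lobes in zip(lipo_centers, lipo_volumes, lipo_lobes):
        # irregular aggregate: union of overlapping lobes around the centre
        lobe_volume = 1.3 * vol / n_lobes  # overlap makes the union ~= vol
        lobe_radius = _radius_from_volume(lobe_volume)
        offsets = rng.normal(scale=0.7 * lobe_radius, size=(n_lobes, 3))
        offsets[0] = 0.0
        for off in offsets:
            _add_soft_ball(lipo_coverage, np.asarray(center) + off, lobe_radius, 1.0, geometry)
    lipo_coverage = np.clip(lipo_coverage, 0.0, 1.0)
    for name in rates:
        rates[name] += params.lipofuscin_intensity * lipo_coverage

    sigma_vox = (
        params.psf_sigma_z / geometry.dz,
        params.psf_sigma_xy / geometry.dy,
        params.psf_sigma_xy / geometry.dx,
    )
    channels: dict[str, VoxelStack] = {}
    for name in ("nuclear", "grain", "somatic", "autofluorescence"):
        exposure = geometry.exposure_ms.get(name, 1.0)
        signal = ndi.gaussian_filter(rates[name] * exposure, sigma=sigma_vox, mode="reflect")
        if params.shot_noise:
            signal = rng.poisson(np.clip(signal, 0.0, None)).astype(np.float64)
        if params.noise_sd > 0:
            signal = signal + rng.normal(0.0, params.noise_sd, size=shape)
        channels[name] = stack_from_geometry(
            signal.astype(np.float32), geometry, channel_name=name
        )

    truth = GroundTruth(
        cells=cells,
        grain_centroids_um=grain_pos,
        grain_owner=grain_owner,
        cell_labels=cell_labels,
        lipofuscin_mask=lipo_coverage >= 0.5,
        lipofuscin_centroids_um=lipo_centers,
    )
    return StackSet(channels=channels, geometry=geometry), truth


def ground_truth_only(
    geometry: AcquisitionGeometry, params: SimParams,
    seed: int | np.random.SeedSequence | None = None,
) -> GroundTruth:
    """Bookkeeping-only stack: tissue sampled, nothing rasterized."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cells, grain_pos, grain_owner, _, lipo_centers, _, _ = _sample_tissue(geometry, params, rng)
    return GroundTruth(
        cells=cells, grain_centroids_um=grain_pos, grain_owner=grain_owner,
        lipofuscin_centroids_um=lipo_centers,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """One simulated subject: metadata plus per-stack data."""

    record: SubjectRecord
    stacks: list[StackSet] | None
    truths: list[GroundTruth]


#: covariate model: field -> (mean_group1, mean_group2, sd)
DEFAULT_COVARIATE_MODEL = {
    "age": (24.0, 71.0, 4.0),
    "pmi": (14.0, 14.0, 5.0),
    "rin": (7.5, 7.5, 0.8),
    "ph": (6.6, 6.6, 0.2),
}


def _group_params(params: SimParams, group_index: int) -> SimParams:
    if group_index == 0:
        return params
    f_density, f_grains = params.group_effects
    return replace(
        params,
        cell_density=params.cell_density * f_density,
        grains_per_sst_cell_mean=params.grains_per_sst_cell_mean * f_grains,
    )


def generate_cohort(
    geometry: AcquisitionGeometry,
    params: SimParams,
    n_per_group: int = 5,
    n_stacks: int = 20,
    master_seed: int | None = None,
    covariate_model: dict | None = None,
    group_names: Sequence[str] = GROUP_NAMES,
    render: bool = True,
) -> list[CohortSubject]:
    """Simulate a two-group cohort of subjects with ``n_stacks`` fields each.

    The second group's cell density and grains-per-cell rate are scaled by
    ``params.group_effects``.  Per-subject and per-stack seeds are split
    deterministically from ``master_seed`` so cohorts of any size are
    reproducible.  With ``render=False`` only ground-truth bookkeeping is
    sampled (fast path for calibration studies).
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 subjects per group (group statistics undefined)")
    if n_stacks < 1:
        raise ValueError("need at least one stack per subject")
    covariate_model = dict(DEFAULT_COVARIATE_MODEL, **(covariate_model or {}))
    master = np.random.SeedSequence(
        params.seed if master_seed is None else master_seed
    )
    subject_seeds = master.spawn(2 * n_per_group)

    subjects: list[CohortSubject] = []
    volume_mm3 = _imaged_volume_mm3(geometry)
    for g, group in enumerate(group_names[:2]):
        g_params = _group_params(params, g)
        for i in range(n_per_group):
            ss = subject_seeds[g * n_per_group + i]
            meta_seed, *stack_seeds = ss.spawn(n_stacks + 1)
            meta_rng = np.random.default_rng(meta_seed)
            covs = {
                name: float(meta_rng.normal(mu[g], mu[2]))
                for name, mu in covariate_model.items()
            }
            record = SubjectRecord(
                id=f"{group}_{i + 1:02d}", group=group,
                age=covs["age"], pmi=max(covs["pmi"], 1.0),
                rin=float(np.clip(covs["rin"], 1.0, 10.0)),
                ph=covs["ph"],
            )
            stacks: list[StackSet] | None = [] if render else None
            truths: list[GroundTruth] = []
            for s_seed in stack_seeds:
                if render:
                    st, truth = generate_stack(geometry, g_params, seed=s_seed)
                    stacks.append(st)
                else:
                    truth = ground_truth_only(geometry, g_params, seed=s_seed)
                truths.append(truth)
            n_sst = sum(t.n_sst_cells for t in truths)
            n_all = sum(t.n_cells for t in truths)
            sst_grains = [
                int(c) for t in truths for c in t.cells.loc[t.cells["is_sst"], "n_grains"]
            ]
            record.measurements.update(
                {
                    "true_sst_density": n_sst / (n_stacks * volume_mm3),
                    "true_total_density": n_all / (n_stacks * volume_mm3),
                    "true_grains_per_sst_cell": float(np.mean(sst_grains)) if sst_grains else float("nan"),
                }
            )
            subjects.append(CohortSubject(record=record, stacks=stacks, truths=truths))
    return subjects
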