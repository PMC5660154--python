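"""End-to-end study orchestration.

``run_simulated_study`` executes the whole desk-scale workflow: simulate a
two-group cohort, segment every stack (exposure normalization, DoG,
iterative gated grain segmentation, lipofuscin segmentation and exclusion),
validate and frame-filter the pre-drawn cell masks, assign grains, classify
cells, estimate densities, and compare groups by ANCOVA.
``run_on_stacks`` runs the same stages minus simulation on stacks exported
to disk.  Stage artifacts (CSV tables, JSON report) are written eagerly so
any stage can be inspected or re-run from intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .geometry import AcquisitionGeometry
from .groupstats import ComparisonResult, SubjectRecord, ancova_compare
from .qc import QCSummary, exclusion_bookkeeping, grain_histogram
from .segmentation import (
    LabeledObjectSet,
    dog_filter,
    exclude_overlapping,
    iterative_grain_segmentation,
    normalize_exposure,
    segment_lipofuscin,
)
from .stack import StackSet
from .stereology import (
    CountingFrame,
    assign_grains_to_cells,
    cell_density,
    cells_from_labels,
    classify_sst_cells_20x,
    classify_sst_cells_60x,
    frame_filter,
    tissue_grain_density,
    validate_cell_mask,
)
from .synthetic import CohortSubject, generate_cohort

log = logging.getLogger("grainstack")

MEASUREMENTS = (
    "sst_density",
    "total_density",
    "tissue_grain_density",
    "grains_per_sst_cell",
    "lipofuscin_fraction",
)


@dataclass
class StackResult:
    """Per-stack stage outputs and counts."""

    grains_total: int
    grains_surviving: int
    grains_assigned: int
    grains_unassigned: int
    lipofuscin_objects: int
    cells_total: int
    cells_validated: int
    cells_counted: int
    sst_cells_counted: int
    lipofuscin_fraction: float
    grains: LabeledObjectSet
    cells: list
    frame: CountingFrame
    thresholds: list[float]


@dataclass
class RunReport:
    """Study-level results: per-stage counts, measurements, comparisons."""

    subjects: pd.DataFrame
    stack_summary: pd.DataFrame
    comparisons: list[ComparisonResult]
    stage_counts: dict[str, int]
    config_hash: str
    seed: int
    version: str = __version__
    qc: QCSummary | None = None
    cells: pd.DataFrame | None = None  # per-cell table across all stacks

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "measurement": c.measurement,
                    "group_ref": c.group_names[0],
                    "group_other": c.group_names[1],
                    "mean_ref": c.group_means[0],
                    "mean_other": c.group_means[1],
                    "sd_ref": c.group_sds[0],
                    "sd_other": c.group_sds[1],
                    "effect": c.effect,
                    "percent_change": c.percent_change,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "test": c.test,
                    "covariates_retained": ";".join(c.covariates_retained),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.9g")
        self.subjects.to_csv(outdir / "subjects.csv", **kw)
        self.stack_summary.to_csv(outdir / "stack_summary.csv", **kw)
        self.comparisons_frame().to_csv(outdir / "comparisons.csv", **kw)
        if self.cells is not None:
            self.cells.to_csv(outdir / "cells.csv", **kw)
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "qc": self.qc.to_dict() if self.qc else None,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        return outdir


# ---------------------------------------------------------------------------
# single-stack processing
# ---------------------------------------------------------------------------

def _nuclear_mask(values: np.ndarray) -> np.ndarray:
    """Foreground mask of the nuclear channel.

    Nuclei occupy a small, stack-dependent fraction of the volume, so a
    class-balancing threshold is unstable on sparse fields; instead the
    mask is everything well above the robust background level:
    ``median + max(6 * 1.4826 * MAD, 5% of the range above the median)``.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    rise = float(values.max()) - med
    if rise <= 0:
        return np.zeros(values.shape, dtype=bool)
    return values >= med + max(6.0 * 1.4826 * mad, 0.05 * rise)


def process_stack(
    stacks: StackSet,
    cell_labels: np.ndarray,
    geometry: AcquisitionGeometry,
    config: PipelineConfig,
) -> StackResult:
    """Run segmentation, exclusion, validation, assignment and classification
    on one multichannel stack with pre-drawn cell masks."""
    norm = {name: normalize_exposure(st) for name, st in stacks.items()}

    thresholds: list[float] = []
    grain_dog = dog_filter(norm["grain"], config.dog)
    grains_all = iterative_grain_segmentation(
        grain_dog, config.gate, config.connectivity, record_thresholds=thresholds
    )
    log.debug("grain segmentation thresholds: %s", thresholds)

    af = norm["autofluorescence"]
    af_seg_input = dog_filter(af, config.dog) if config.lipofuscin_on_dog else af
    lipofuscin = segment_lipofuscin(af_seg_input, config.connectivity)
    grains = exclude_overlapping(grains_all, lipofuscin)

    nuclear_mask = _nuclear_mask(norm["nuclear"].intensities)

    cells = cells_from_labels(cell_labels, geometry)
    for cell in cells:
        validate_cell_mask(cell, nuclear_mask, geometry.n_z, config.min_z_planes)

    cells, unassigned = assign_grains_to_cells(grains, cells)
    if config.mode() == "20x":
        classify_sst_cells_20x(
            cells, grains, config.min_clusters, config.cluster_link_radius_um
        )
    else:
        classify_sst_cells_60x(cells, config.min_grains)

    w, h = config.frame_size_um()
    frame = CountingFrame.centered(geometry, w, h, exclusion_edges=tuple(config.exclusion_edges))
    frame.check_inside_field(geometry)
    validated = [c for c in cells if c.accepted]
    frame_filter(validated, frame, geometry.dx, geometry.dy)
    counted = [c for c in validated if c.frame_included]

    lipo_fraction = float(lipofuscin.mask().mean()) if len(lipofuscin) else 0.0
    return StackResult(
        grains_total=len(grains_all),
        grains_surviving=len(grains),
        grains_assigned=len(grains) - len(unassigned),
        grains_unassigned=len(unassigned),
        lipofuscin_objects=len(lipofuscin),
        cells_total=len(cells),
        cells_validated=len(validated),
        cells_counted=len(counted),
        sst_cells_counted=sum(bool(c.sst_class) for c in counted),
        lipofuscin_fraction=lipo_fraction,
        grains=grains,
        cells=cells,
        frame=frame,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

def _subject_measurements(
    record: SubjectRecord,
    results: list[StackResult],
    geometry: AcquisitionGeometry,
) -> None:
    frames = [r.frame for r in results]
    sst = cell_density([r.sst_cells_counted for r in results], frames, geometry.section_thickness)
    total = cell_density([r.cells_counted for r in results], frames, geometry.section_thickness)
    grains = tissue_grain_density([r.grains_surviving for r in results], geometry)
    per_cell = [
        c.grain_count for r in results for c in r.cells if c.accepted and c.sst_class
    ]
    record.measurements.update(
        {
            "sst_density": sst.density_per_mm3,
            "total_density": total.density_per_mm3,
            "tissue_grain_density": grains.density_per_mm3,
            "grains_per_sst_cell": float(np.mean(per_cell)) if per_cell else float("nan"),
            "lipofuscin_fraction": float(np.mean([r.lipofuscin_fraction for r in results])),
        }
    )


def _study_from_results(
    subjects: list[SubjectRecord],
    stack_rows: list[dict],
    config: PipelineConfig,
    outdir: str | Path | None,
    cell_rows: list[dict] | None = None,
) -> RunReport:
    from .groupstats import subjects_to_frame

    subject_frame = subjects_to_frame(subjects)
    stack_summary = pd.DataFrame(stack_rows)
    comparisons = []
    for name in MEASUREMENTS:
        values = subject_frame[name]
        groups_ok = all(
            subject_frame.loc[subject_frame["group"] == g, name].notna().sum() >= 2
            for g in subject_frame["group"].unique()
        )
        if not groups_ok or np.ptp(values.dropna().to_numpy()) == 0:
            continue
        comparisons.append(
            ancova_compare(
                subjects, name,
                covariates=tuple(config.covariates),
                reference_group=config.reference_group,
                alpha=config.alpha,
            )
        )
    stage_counts = {
        "grains_total": int(stack_summary["grains_total"].sum()),
        "grains_after_lipofuscin_exclusion": int(stack_summary["grains_surviving"].sum()),
        "grains_assigned": int(stack_summary["grains_assigned"].sum()),
        "grains_unassigned": int(stack_summary["grains_unassigned"].sum()),
        "cells_total": int(stack_summary["cells_total"].sum()),
        "cells_validated": int(stack_summary["cells_validated"].sum()),
        "cells_counted": int(stack_summary["cells_counted"].sum()),
        "sst_cells_counted": int(stack_summary["sst_cells_counted"].sum()),
    }
    report = RunReport(
        subjects=subject_frame,
        stack_summary=stack_summary,
        comparisons=comparisons,
        stage_counts=stage_counts,
        config_hash=config.config_hash(),
        seed=config.seed,
        cells=pd.DataFrame(cell_rows) if cell_rows is not None else None,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def run_simulated_study(
    config: PipelineConfig, outdir: str | Path | None = None
) -> RunReport:
    """Simulate a cohort and run every stage; identical config + seed give
    identical reports (and byte-identical CSVs)."""
    geometry = config.geometry()
    cohort = generate_cohort(
        geometry, config.sim,
        n_per_group=config.n_per_group,
        n_stacks=config.n_stacks,
        master_seed=config.seed,
    )
    subjects, stack_rows, cell_rows, all_cells = [], [], [], []
    for subject in cohort:
        results = []
        for k, (stacks, truth) in enumerate(zip(subject.stacks, subject.truths)):
            res = process_stack(stacks, truth.cell_labels, geometry, config)
            results.append(res)
            stack_rows.append(_stack_row(subject.record.id, k, res))
            cell_rows.extend(_cell_rows(subject.record.id, k, res))
            all_cells.extend(res.cells)
        _subject_measurements(subject.record, results, geometry)
        subjects.append(subject.record)
    report = _study_from_results(subjects, stack_rows, config, outdir, cell_rows)
    qc = grain_histogram([c for c in all_cells if c.accepted], config.min_grains)
    exclusion_bookkeeping(
        report.stage_counts["grains_total"],
        report.stage_counts["grains_after_lipofuscin_exclusion"],
        qc,
    )
    report.qc = qc
    if outdir is not None:
        report.write(outdir)
    return report


def _cell_rows(subject_id: str, index: int, res: StackResult) -> list[dict]:
    return [
        {
            "subject": subject_id,
            "stack": index,
            "cell_id": c.cell_id,
            "grain_count": c.grain_count,
            "cluster_count": -1 if c.cluster_count is None else c.cluster_count,
            "sst_class": bool(c.sst_class),
            "frame_included": bool(c.frame_included),
            "validated": bool(c.accepted),
            "validation_reasons": ";".join(c.reasons),
        }
        for c in res.cells
    ]


def _stack_row(subject_id: str, index: int, res: StackResult) -> dict:
    return {
        "subject": subject_id,
        "stack": index,
        "grains_total": res.grains_total,
        "grains_surviving": res.grains_surviving,
        "grains_assigned": res.grains_assigned,
        "grains_unassigned": res.grains_unassigned,
        "lipofuscin_objects": res.lipofuscin_objects,
        "cells_total": res.cells_total,
        "cells_validated": res.cells_validated,
        "cells_counted": res.cells_counted,
        "sst_cells_counted": res.sst_cells_counted,
        "lipofuscin_fraction": res.lipofuscin_fraction,
    }


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def export_cohort(cohort: list[CohortSubject], outdir: str | Path) -> Path:
    """Write a simulated cohort to disk in the on-disk study layout.

    ``<outdir>/subjects.csv`` plus
    ``<outdir>/<subject>/stack_<k>/<channel>.ome.tif`` and
    ``cell_labels.tif`` per stack.
    """
    from .groupstats import subjects_to_frame
    from .io import write_label_volume, write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects_to_frame([s.record for s in cohort]).to_csv(
        outdir / "subjects.csv", index=False, float_format="%.9g"
    )
    for subject in cohort:
        for k, (stacks, truth) in enumerate(zip(subject.stacks, subject.truths)):
            stack_dir = outdir / subject.record.id / f"stack_{k:03d}"
            stack_dir.mkdir(parents=True, exist_ok=True)
            for name, st in stacks.items():
                write_stack(st, stack_dir / f"{name}.ome.tif")
            write_label_volume(truth.cell_labels, stack_dir / "cell_labels.tif")
    return outdir


def run_on_stacks(
    root: str | Path, config: PipelineConfig, outdir: str | Path | None = None
) -> RunReport:
    """Run all stages minus simulation on an exported cohort directory."""
    from .io import read_label_volume, read_stack
    from .stack import StackSet

    root = Path(root)
    subjects_csv = root / "subjects.csv"
    if not subjects_csv.exists():
        raise OSError(f"missing subject table: {subjects_csv}")
    table = pd.read_csv(subjects_csv)
    geometry = config.geometry()

    core = ("id", "group", "age", "pmi", "rin", "ph")
    extra_columns = [c for c in table.columns if c not in core]
    subjects, stack_rows, cell_rows = [], [], []
    for row in table.itertuples():
        record = SubjectRecord(
            id=row.id, group=row.group, age=row.age, pmi=row.pmi, rin=row.rin, ph=row.ph,
            measurements={c: getattr(row, c) for c in extra_columns},
        )
        results = []
        stack_dirs = sorted((root / row.id).glob("stack_*"))
        for k, stack_dir in enumerate(stack_dirs):
            channels = {}
            for tif in sorted(stack_dir.glob("*.ome.tif")):
                name = tif.name.replace(".ome.tif", "")
                channels[name] = read_stack(tif)
            labels = read_label_volume(stack_dir / "cell_labels.tif")
            res = process_stack(StackSet(channels=channels, geometry=geometry), labels, geometry, config)
            results.append(res)
            stack_rows.append(_stack_row(record.id, k, res))
            cell_rows.extend(_cell_rows(record.id, k, res))
        _subject_measurements(record, results, geometry)
        subjects.append(record)
    return _study_from_results(subjects, stack_rows, config, outdir, cell_rows)
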