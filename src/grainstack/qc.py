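"""Diagnostic summaries: grain-per-cell distributions, lipofuscin burden,
and exclusion bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import AcquisitionGeometry
from .segmentation import LabeledObjectSet
from .stereology import CellRecord

__all__ = ["QCSummary", "grain_histogram", "lipofuscin_burden", "exclusion_bookkeeping"]


@dataclass
class QCSummary:
    """Accumulating QC report fragments."""

    grain_histogram: dict[int, int] = field(default_factory=dict)
    suggested_threshold: int | None = None
    tissue_lipofuscin_fraction: float | None = None
    cell_lipofuscin_fractions: dict[int, float] = field(default_factory=dict)
    grains_removed_by_exclusion: int | None = None
    channel_intensity_summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grain_histogram": {str(k): v for k, v in self.grain_histogram.items()},
            "suggested_threshold": self.suggested_threshold,
            "tissue_lipofuscin_fraction": self.tissue_lipofuscin_fraction,
            "cell_lipofuscin_fractions": {str(k): v for k, v in self.cell_lipofuscin_fractions.items()},
            "grains_removed_by_exclusion": self.grains_removed_by_exclusion,
            "channel_intensity_summary": self.channel_intensity_summary,
        }


def grain_histogram(
    cells: list[CellRecord], min_grains: int = 20, summary: QCSummary | None = None
) -> QCSummary:
    """Integer histogram of grains per cell, marking the classification cut.

    In a well-behaved preparation the distribution is bimodal -- background
    cells near zero, expressing cells far above -- and the configured
    ``min_grains`` threshold sits in the valley between the modes.
    """
    summary = summary or QCSummary()
    counts = [cell.grain_count for cell in cells]
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    summary.grain_histogram = dict(sorted(hist.items()))
    summary.suggested_threshold = min_grains
    return summary


def lipofuscin_burden(
    lipofuscin: LabeledObjectSet,
    cells: list[CellRecord],
    geometry: AcquisitionGeometry,
    summary: QCSummary | None = None,
) -> QCSummary:
    """Lipofuscin voxel fraction at tissue level and within each cell mask.

    Voxel fractions (not integrated intensity) are robust to exposure
    differences between channels and subjects.
    """
    summary = summary or QCSummary()
    if lipofuscin.shape != geometry.shape:
        raise ValueError(
            f"lipofuscin grid {lipofuscin.shape} does not match geometry {geometry.shape}"
        )
    mask = lipofuscin.mask()
    summary.tissue_lipofuscin_fraction = float(mask.mean())
    for cell in cells:
        inside = mask[tuple(cell.coords.T)]
        summary.cell_lipofuscin_fractions[cell.cell_id] = float(inside.mean())
    return summary


def exclusion_bookkeeping(
    total_grains: int, surviving_grains: int, summary: QCSummary | None = None
) -> QCSummary:
    """Record grains removed by lipofuscin exclusion (total - surviving)."""
    if surviving_grains > total_grains:
        raise ValueError("surviving grains cannot exceed total grains")
    summary = summary or QCSummary()
    summary.grains_removed_by_exclusion = total_grains - surviving_grains
    return summary


def intensity_summary(stacks, summary: QCSummary | None = None) -> QCSummary:
    """Per-channel min/mean/max intensities."""
    summary = summary or QCSummary()
    for name, stack in stacks.items():
        v = stack.intensities
        summary.channel_intensity_summary[name] = {
            "min": float(v.min()), "mean": float(v.mean()), "max": float(v.max()),
        }
    return summary
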