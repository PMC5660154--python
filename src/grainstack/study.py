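"""Desk-scale study definitions.

One place defines the reduced-size simulation conditions used by the
analysis scripts and validation studies, so every entry point (tests,
acceptance script, analysis drivers) runs the same study.

Problem sizes are deliberately scaled down from a full acquisition: fields
of 256 x 256 pixels at the 60x pixel pitch with 20 planes at 0.5 um
(a 27.7 x 27.7 x 10 um volume), somata of 3.5 um radius, and a cell density
chosen so each field holds a handful of somata -- the same counting
statistics per field a full-size field would give.  The two-group design
mirrors a 5 + 5 subject cohort with 20 sampled stacks per subject and a
planted multiplicative reduction of labeled-cell density in the older
group.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .geometry import FIELD_60X_UM, AcquisitionGeometry
from .groupstats import ancova_compare
from .pipeline import RunReport, run_simulated_study
from .synthetic import SimParams, generate_cohort

__all__ = [
    "scaled_geometry",
    "scaled_sim_params",
    "scaled_study_config",
    "recovery_study",
    "null_rejection_rate",
]


def scaled_geometry(n_xy: int = 256, n_z: int = 20) -> dict:
    """Custom-geometry kwargs for the desk-scale field."""
    dxy = FIELD_60X_UM / 1024
    return dict(
        n_x=n_xy, n_y=n_xy, n_z=n_z, dx=dxy, dy=dxy, dz=0.5,
        section_thickness=n_z * 0.5,
    )


def scaled_sim_params(seed: int = 0, **overrides) -> SimParams:
    """Desk-scale tissue model: miniature somata at a density preserving
    counts per field, realistic always-present lipofuscin, and
    post-deconvolution-grade noise."""
    defaults = dict(
        cell_density=9.0e5,
        sst_fraction=0.5,
        cell_radius_um=3.5,
        cell_min_separation_um=4.5,
        extracellular_grain_rate=5.0e5,
        lipofuscin_count_rate=1.2e6,
        noise_sd=10.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def scaled_study_config(
    seed: int = 0,
    n_per_group: int = 5,
    n_stacks: int = 20,
    group_effects: tuple[float, float] = (0.36, 1.0),
    **sim_overrides,
) -> PipelineConfig:
    sim = scaled_sim_params(seed=seed, group_effects=group_effects, **sim_overrides)
    return PipelineConfig(
        geometry_preset="custom",
        custom_geometry=scaled_geometry(),
        sim=sim,
        frame_width_um=20.0,
        frame_height_um=20.0,
        classification_mode="60x",
        n_per_group=n_per_group,
        n_stacks=n_stacks,
        seed=seed,
    )


def recovery_study(seed: int = 0, outdir=None, **kw) -> tuple[RunReport, float]:
    """Run the planted-reduction study; return (report, estimated % reduction
    of SST-cell density in the older group)."""
    config = scaled_study_config(seed=seed, **kw)
    report = run_simulated_study(config, outdir=outdir)
    row = report.comparisons_frame().set_index("measurement").loc["sst_density"]
    return report, float(row["percent_change"])


def null_rejection_rate(
    seed: int = 0,
    n_reps: int = 100,
    n_per_group: int = 5,
    n_stacks: int = 20,
    measurement: str = "true_sst_density",
    alpha: float = 0.05,
) -> float:
    """Type-I error of the group comparison under the null design.

    Repeats the cohort draw with ``group_effects = (1, 1)`` using the
    generator's ground-truth bookkeeping (no rendering -- the group test's
    calibration does not depend on the imaging stages) and runs the standard
    covariate-adjusted comparison each time.
    """
    geometry = AcquisitionGeometry(**scaled_geometry())
    params = scaled_sim_params(seed=seed, group_effects=(1.0, 1.0))
    master = np.random.SeedSequence(seed)
    rep_seeds = master.generate_state(n_reps).astype(np.int64) % (2**31)
    rejections = 0
    for rep_seed in rep_seeds:
        cohort = generate_cohort(
            geometry, params,
            n_per_group=n_per_group, n_stacks=n_stacks,
            master_seed=int(rep_seed), render=False,
        )
        result = ancova_compare([s.record for s in cohort], measurement)
        rejections += result.p_value < alpha
    return rejections / n_reps
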