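#!/usr/bin/env python
"""Segment grains and lipofuscin on a handful of ground-truthed stacks.

Runs the detection chain (exposure normalization -> difference of Gaussians
-> Ridler-Calvard -> iterative volume-gated segmentation -> lipofuscin
exclusion) on noise-free stacks at the 60x voxel pitch, reports precision
and recall against the generator's ground truth, and writes the per-object
table of one stack to ``results/02_grain_objects.csv``.
"""

from pathlib import Path

import numpy as np

from grainstack.geometry import AcquisitionGeometry
from grainstack.metrics import match_centroids
from grainstack.segmentation import (
    dog_filter,
    exclude_overlapping,
    iterative_grain_segmentation,
    normalize_exposure,
    segment_lipofuscin,
)
from grainstack.synthetic import SimParams, generate_stack

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1

GEOM = AcquisitionGeometry(
    n_x=256, n_y=256, n_z=48, dx=111 / 1024, dy=111 / 1024, dz=0.25,
    section_thickness=12.0,
)


def main() -> None:
    params = SimParams(
        cell_density=3e5, sst_fraction=1.0, cell_radius_um=5.0,
        extracellular_grain_rate=2e5, lipofuscin_count_rate=1e5,
        noise_sd=0.0, shot_noise=False,
    )
    tp = n_det = n_true = removed = 0
    last = None
    for seed in (SEED, SEED + 1, SEED + 2):
        stacks, truth = generate_stack(GEOM, params, seed=seed)
        grains = iterative_grain_segmentation(dog_filter(normalize_exposure(stacks["grain"])))
        lipofuscin = segment_lipofuscin(
            dog_filter(normalize_exposure(stacks["autofluorescence"]))
        )
        surviving = exclude_overlapping(grains, lipofuscin)
        removed += len(grains) - len(surviving)
        det = np.array([o.centroid_um for o in surviving]) if len(surviving) else np.zeros((0, 3))
        matches = match_centroids(det, truth.grain_centroids_um, max_dist_um=0.5)
        tp += len(matches)
        n_det += len(det)
        n_true += len(truth.grain_centroids_um)
        last = surviving

    RESULTS.mkdir(exist_ok=True)
    last.to_dataframe().to_csv(RESULTS / "02_grain_objects.csv", index=False,
                               float_format="%.9g")
    print(f"3 noise-free stacks at 60x pitch: {n_true} true grains, "
          f"{n_det} detected after lipofuscin exclusion ({removed} removed)")
    print(f"precision {tp / n_det:.3f}, recall {tp / n_true:.3f} "
          f"(one-to-one centroid matching at 0.5 um)")
    volumes = [o.volume_um3 for o in last]
    print(f"accepted volumes span {min(volumes):.3f}-{max(volumes):.3f} um^3 "
          f"(gate 0.03-0.1)")


if __name__ == "__main__":
    main()
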