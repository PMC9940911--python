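"""Connectivity R-map analysis on a synthetic voxel cohort.

Takes the per-subject max-session exploration change from
02_behaviour_stats.py for 14 subjects, plants it into synthetic
seed-connectivity voxel maps, and runs the full network-mapping
procedure: voxelwise R-map, spatial-similarity prediction of the
behavioural change, and a 1000-fold permutation test.  Also builds the
stimulation-volume n-map (heat map) and its weighted overlap with two
synthetic pallidal region masks on a shared grid.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rlddm.rmap import (VoxelMapStack, heatmap_overlap, permutation_test,
                        predict_behaviour, spatial_similarity, voxelwise_rmap)
from rlddm.task import synth_stim_volumes, synth_voxel_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240

N_SUBJECTS = 14          # electrode reconstructions available for 14/18
GRID = (12, 12, 12)
EFFECT_SIZE = 0.6
NOISE_SD = 1.0
N_PERM = 1000


def main():
    rng = np.random.default_rng(SEED)
    delta = pd.read_csv(OUT / "delta_pexplore.csv").head(N_SUBJECTS)
    behaviour = delta["max_session"].to_numpy()

    mask = np.zeros(GRID, bool)
    mask[3:9, 3:9, 3:9] = True   # the connectivity network carrying the effect
    stack_arr, behaviour = synth_voxel_cohort(
        N_SUBJECTS, GRID, mask, EFFECT_SIZE, NOISE_SD, rng, behaviour=behaviour)
    stack = VoxelMapStack(stack_arr, voxel_size=(2.0, 2.0, 2.0))

    rmap = voxelwise_rmap(stack, behaviour)
    sims = np.array([spatial_similarity(stack.data[s], rmap)
                     for s in range(N_SUBJECTS)])
    r2, p = predict_behaviour(sims, behaviour)
    perm = permutation_test(stack, behaviour, n_perm=N_PERM, rng=rng)

    print(f"similarity prediction: R^2 = {r2:.2f}, p = {p:.3f}")
    print(f"permutation test: R = {perm.observed_r:.2f}, "
          f"p(directional) = {perm.p_directional:.3f}, "
          f"p(|R|) = {perm.p_two_sided:.3f} ({N_PERM} permutations)")

    result = {"n_subjects": N_SUBJECTS, "effect_size": EFFECT_SIZE,
              "r2": r2, "p": p, "observed_r": perm.observed_r,
              "perm_p_directional": perm.p_directional,
              "perm_p_two_sided": perm.p_two_sided, "n_perm": N_PERM}
    with open(OUT / "rmap_prediction.json", "w") as fh:
        json.dump(result, fh, indent=2)

    # --- stimulation-volume heat map ----------------------------------
    vols = synth_stim_volumes(N_SUBJECTS, GRID, rng, radius=2.5, jitter=1.5)
    centre = np.array(GRID) / 2.0
    coords = np.stack(np.meshgrid(*[np.arange(d) for d in GRID],
                                  indexing="ij"), axis=-1)
    gpi_like = np.sum((coords - centre) ** 2, axis=-1) <= 3.0 ** 2
    gpe_like = (np.sum((coords - (centre + [3, 0, 0])) ** 2, axis=-1) <= 3.0 ** 2) & ~gpi_like
    nmap, scores = heatmap_overlap(vols, {"GPi_like": gpi_like,
                                          "GPe_like": gpe_like})
    print(f"n-map peak covers {int(nmap.max())}/{N_SUBJECTS} subjects; "
          f"weighted overlap: {scores}")
    with open(OUT / "heatmap_overlap.json", "w") as fh:
        json.dump({"scores": scores, "nmap_max": int(nmap.max())}, fh, indent=2)


if __name__ == "__main__":
    main()
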