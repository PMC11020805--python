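"""Movement-specific cortical loci from searchlight RSA with test-retest
persistence.

For each movement and limb side, correlates 3-voxel-radius sphere RDMs with
the binary movement-of-interest code RDM (Spearman), thresholds each random
half-cohort map with a max-statistic permutation null (corrected p < 0.01),
and keeps voxels whose test/retest conjunction persists across repetitions,
as clusters of at least five voxels. Desk scale: 12 subjects split 6/6, 5
repetitions, 500 permutations (persistence cutoff 4/5). Writes the locus
table (movement, side, peak MNI coordinates, size) and the locus label
volume, and checks the somatotopic ordering against the simulated ground
truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from limbloci import glm
from limbloci import simulate as sim
from limbloci.grid import write_volume
from limbloci.rsa import SearchlightRSA, condition_patterns, identify_loci


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-subjects", type=int, default=12)
    ap.add_argument("--n-perm", type=int, default=500)
    ap.add_argument("--n-reps", type=int, default=5)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    cfg = sim.SimConfig(seed=args.seed, spike_prob=0.0)
    mask = sim.make_pcl_mask()
    truth = sim.make_ground_truth(mask, cfg)
    sl = SearchlightRSA(mask, radius_vox=3)
    rdms, labels = [], None
    for i, child in enumerate(np.random.SeedSequence(args.seed).spawn(args.n_subjects)):
        s = sim.simulate_subject(
            truth, cfg, "healthy", np.random.default_rng(child), f"s{i}"
        )
        pat, labels = condition_patterns(glm.fit_subject(s, mask))
        rdms.append(sl.subject_rdms(pat))

    half = args.n_subjects // 2
    results = identify_loci(
        rdms, labels, mask, sim.MOVEMENTS, sim.SIDES,
        n_reps=args.n_reps, split=(half, args.n_subjects - half),
        n_perm=args.n_perm, alpha=0.01,
        persistence_cutoff=max(1, int(np.ceil(0.8 * args.n_reps))),
        min_cluster=5, seed=args.seed + 1,
    )

    frames, label_vol = [], np.zeros(mask.grid.shape, dtype=np.int16)
    code = 0
    for (movement, side), res in results.items():
        code += 1
        frame = res.loci.to_frame()
        frames.append(frame)
        for c in res.loci.clusters:
            label_vol[tuple(c.indices.T)] = code
        tc = truth.loci[(movement, side)].center_mni
        status = "EMPTY" if not res.loci.clusters else (
            f"{int(res.final_mask.sum())} voxels, top cluster COM "
            f"{np.round(max(res.loci.clusters, key=lambda c: c.size).com_mni, 1)}"
        )
        print(f"{movement:20s} {side:5s}: {status}  (truth centre {np.round(tc, 1)})")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out_dir / "rsa_loci.tsv", sep="\t", index=False)
    write_volume(args.scratch / "rsa_loci_labels.nii", label_vol, mask.grid)

    for side in sim.SIDES:
        zs = []
        for movement in sim.MOVEMENTS:
            clusters = results[(movement, side)].loci.clusters
            if clusters:
                zs.append(max(clusters, key=lambda c: c.size).com_mni[2])
        ordered = zs == sorted(zs)
        print(f"{side} limb somatotopic ordering toe->knee along z: "
              f"{'preserved' if ordered else 'violated'} ({np.round(zs, 1)})")


if __name__ == "__main__":
    main()
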