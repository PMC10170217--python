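#!/usr/bin/env python
"""Cluster pruning and flat-map distance assignment.

Loads the per-vertex fits, removes clusters of above-threshold
vertices whose size could arise by chance (1000 relocation
permutations, 1% level), computes every surviving vertex's normalized
distance between the map's low and high edges, bins distances in 0.05
steps and writes the bin-level dataset that feeds the group models
(results/topography/bin_dataset.csv).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from magmap import inference as inf
from magmap import surface as sf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    patch, roi = sf.patch_from_json((ROOT / "simulation" / "patch.json").read_text())
    dists = sf.normalized_distances(patch.flat_coords, roi)
    adj = patch.adjacency()
    out_dir = ROOT / "topography"
    out_dir.mkdir(parents=True, exist_ok=True)

    in_roi = np.zeros(patch.n_vertices, bool)
    in_roi[roi.vertices] = True

    rows = []
    rng_seeds = iter(range(args.seed, args.seed + 10_000))
    for path in sorted((ROOT / "fits").glob("fits_sub*_*.csv")):
        fits = pd.read_csv(path)
        mask = fits["passed"].to_numpy()
        if 0 < mask.sum() < len(mask):
            pruned, min_size = sf.cluster_permutation_prune(
                mask, patch.faces, seed=next(rng_seeds), adjacency=adj)
        else:  # nothing above threshold, or the whole patch: nothing to prune
            pruned, min_size = mask.copy(), int(mask.sum())
        keep = pruned & in_roi
        kept = fits[keep].copy()
        if kept.empty:
            print(f"{path.name}: no vertices survive; skipped")
            continue
        kept["distance"] = dists[keep]
        if "mu" in kept.columns:  # reduced baseline fits carry one mu
            axis = "mu_d" if kept["condition"].iloc[0] == "T" else "mu_n"
            kept[axis] = kept["mu"]
        rows.append(kept)
        print(f"{path.name}: {mask.sum()} passed -> {pruned.sum()} after "
              f"pruning, {keep.sum()} inside the map "
              f"(min surviving cluster {min_size})")
    vertices = pd.concat(rows, ignore_index=True)
    vertices.to_csv(out_dir / "vertex_dataset.csv", index=False)

    bins = inf.build_bin_dataset(vertices, response_cols=("mu_d", "mu_n"))
    bins = inf.orient_bin_dataset(bins, "mean_mu_d")
    bins.to_csv(out_dir / "bin_dataset.csv", index=False)
    print(f"\nbin dataset: {len(bins)} non-empty subject x condition x bin "
          f"cells over {vertices.shape[0]} vertices -> {out_dir}")


if __name__ == "__main__":
    main()
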