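#!/usr/bin/env python
"""Fit population receptive fields to the simulated BOLD.

Regenerates the dataset from the stored provenance, preprocesses every
run (discrete-cosine high-pass, percent signal change) and estimates
tuning per vertex: the reduced 1-D Gaussian for the baseline
conditions (the response is modelled as invariant to the unvaried
magnitude) and the full five-parameter bivariate Gaussian for the
congruent and incongruent conditions.  Applies the 25% variance
threshold and writes one tidy fit table per subject x condition under
results/fits/.
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from magmap import fit as ft
from magmap import model as md
from magmap import simulate as sim

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    args = ap.parse_args()

    prov = json.loads((ROOT / "simulation" / "provenance.json").read_text())
    spec = sim.GroundTruthSpec(**prov["spec"])
    ds = sim.generate_dataset(spec)
    out_dir = ROOT / "fits"
    out_dir.mkdir(parents=True, exist_ok=True)

    caches = {c: ft.combined_design(s) for c, s in ds.sequences.items()}
    rows = []
    for (s, cond), raw in ds.bold.items():
        t0 = time.time()
        data = md.preprocess(raw)
        seq = ds.sequences[cond]
        if cond in ("T", "N"):
            axis = 0 if cond == "T" else 1
            fits = ft.fit_vertices_1d(data, seq, axis)
        else:
            fits = ft.fit_vertices(data, seq)
        fits.insert(0, "vertex", np.arange(len(fits)))
        fits.insert(1, "subject", s)
        fits.insert(2, "condition", cond)
        fits.to_csv(out_dir / f"fits_sub{s}_{cond}.csv", index=False)
        rows.append({
            "subject": s, "condition": cond, "n_vertices": len(fits),
            "pass_rate": float(fits["passed"].mean()),
            "median_r2": float(fits["r2"].median()),
            "fit_seconds": round(time.time() - t0, 1),
        })
        print(f"sub{s} {cond}: pass {rows[-1]['pass_rate']:.0%}, "
              f"median R2 {rows[-1]['median_r2']:.2f} "
              f"({rows[-1]['fit_seconds']}s)")
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "fit_summary.csv", index=False)
    print(f"\noverall: {summary.pass_rate.mean():.0%} of vertices pass the "
          f"25% variance threshold; tables in {out_dir}")


if __name__ == "__main__":
    main()
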