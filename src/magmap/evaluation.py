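"""End-to-end evaluation studies on synthetic ground truth.

Each function here runs one self-contained study — parameter recovery,
permutation calibration, Weber correlations, tuning-shape contrasts,
mixed-model calibration and bootstrap coverage — and returns its
headline numbers as a small dict.  The test suite asserts on these and
the reproduction script reports them; both call the same code.

All randomness is derived from a single integer seed per study.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fit as ft
from . import inference as inf
from . import mapstats as ms
from . import model as md
from . import simulate as sim
from . import stimulus as st
from . import surface as sf

logger = logging.getLogger(__name__)


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# Design-level checks


def eval_stimulus_targets(seed: int = 0) -> dict:
    """Fraction of target trials in a generated run (percent)."""
    seq = st.build_run("T", seed=seed)
    frac = np.mean([e.is_target for e in seq.events])
    return {"value": 100.0 * float(frac), "n": len(seq.events)}

def eval_duration_level_2() -> dict:
    """Second duration level under geometric spacing (seconds)."""
    levels = st.make_levels(st.DURATION_AXIS)
    return {"value": float(np.round(levels[1], 3)), "n": len(levels)}


# ---------------------------------------------------------------------------
# Parameter recovery


def _probe_sequences(seed: int) -> list[st.StimulusSequence]:
    """One run of each condition, fitted jointly.

    The crossed sweeps of the two interaction runs alone leave the
    bivariate Gaussian exactly under-determined (its restriction to two
    crossing lines fixes only five of the six degrees of freedom), so
    the recovery studies probe with all four runs, as a subject's full
    session would."""
    s1, s2, s3, s4 = _seeds(seed, 4)
    return [st.build_run("T", seed=s1), st.build_run("N", seed=s2),
            st.build_run("C", seed=s3), st.build_run("I", seed=s4)]


def _simulate_probe_data(truth: pd.DataFrame, seqs, noise_sd: float, seed: int,
                         amplitude: float = 1.0,
                         noise: np.ndarray | None = None) -> np.ndarray:
    """Preprocessed (DCT high-pass + percent signal change) data for the
    probe runs, concatenated along time.  ``noise`` optionally supplies
    pre-drawn standard-normal deviates (for common-random-number SNR
    ladders)."""
    rng = np.random.default_rng(seed)
    parts = []
    col = 0
    for seq in seqs:
        raw = sim.simulate_bold(truth, seq, noise_sd=0.0, amplitude=amplitude)
        if noise_sd > 0:
            if noise is None:
                eps = rng.standard_normal(raw.shape)
            else:
                eps = noise[:, col : col + raw.shape[1]]
                col += raw.shape[1]
            raw = raw + 1000.0 * (noise_sd / 100.0) * eps
        parts.append(md.preprocess(raw))
    return np.concatenate(parts, axis=1)


def recovery_study(seed: int, n_vertices: int = 400, noise_sd: float = 0.0,
                   refine: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate jointly tuned vertices, fit them and return
    (truth, fits) aligned row by row."""
    n_side = int(np.ceil(np.sqrt(n_vertices)))
    spec = sim.GroundTruthSpec(n_side=max(n_side, 4), seed=seed, noise_sd=noise_sd)
    patch, _ = sim.make_patch(spec.n_side)
    truth = sim.make_truth(patch, spec, "C",
                           np.random.default_rng(_seeds(seed, 1)[0])).iloc[:n_vertices]
    seqs = _probe_sequences(seed)
    data = _simulate_probe_data(truth, seqs, noise_sd, _seeds(seed + 1, 1)[0])
    fits = ft.fit_vertices(data, seqs, refine=refine)
    return truth.reset_index(drop=True), fits.reset_index(drop=True)


def baseline_recovery_study(seed: int, n_vertices: int, noise_sd: float,
                            noise: dict | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Baseline-map construction on known truth: duration-tuned truth
    fitted on a T run and numerosity-tuned truth on an N run, both with
    the reduced 1-D model.  Returns (truth_T, fits_T, truth_N, fits_N).
    ``noise`` optionally supplies pre-drawn deviates per condition."""
    n_side = max(4, int(np.ceil(np.sqrt(n_vertices))))
    spec = sim.GroundTruthSpec(n_side=n_side, seed=seed, noise_sd=noise_sd)
    patch, _ = sim.make_patch(n_side)
    s_truth, s_run, s_noise = _seeds(seed, 3)
    out = []
    for cond, axis in (("T", 0), ("N", 1)):
        truth = sim.make_truth(
            patch, spec, cond, np.random.default_rng(s_truth + axis)
        ).iloc[:n_vertices]
        seq = st.build_run(cond, seed=s_run + axis)
        raw = sim.simulate_bold(truth, seq, noise_sd=0.0, amplitude=spec.amplitude)
        if noise_sd > 0:
            eps = (noise[cond] if noise is not None
                   else np.random.default_rng(s_noise + axis).standard_normal(raw.shape))
            raw = raw + spec.baseline_level * (noise_sd / 100.0) * eps
        data = md.preprocess(raw)
        fits = ft.fit_vertices_1d(data, seq, axis)
        out.extend([truth.reset_index(drop=True), fits.reset_index(drop=True)])
    return tuple(out)


def eval_noiseless_recovery(seed: int = 0, n_vertices: int = 400) -> dict:
    """Noiseless self-consistency of the map construction: fraction of
    vertices whose preferred duration (T baseline) and preferred
    numerosity (N baseline) are both recovered within 1 arbitrary unit,
    plus the median variance explained."""
    truth_t, fits_t, truth_n, fits_n = baseline_recovery_study(seed, n_vertices, 0.0)
    err = np.maximum(np.abs(fits_t["mu"] - truth_t["mu_d"]),
                     np.abs(fits_n["mu"] - truth_n["mu_n"]))
    return {
        "value": 100.0 * float(np.mean(err < 1.0)),
        "median_r2": float(pd.concat([fits_t["r2"], fits_n["r2"]]).median()),
        "n": n_vertices,
    }


def eval_snr_ladder(seed: int = 0, n_vertices: int = 200,
                    noise_levels=(2.4, 1.2, 0.6, 0.3)) -> dict:
    """Median absolute preference error across a descending-noise
    ladder (common random numbers across rungs)."""
    n_side = max(4, int(np.ceil(np.sqrt(n_vertices))))
    rng = np.random.default_rng(_seeds(seed + 1, 1)[0])
    eps = None
    medians = []
    for nl in noise_levels:
        if eps is None:
            seq_t = st.build_run("T")
            seq_n = st.build_run("N")
            eps = {"T": rng.standard_normal((n_vertices, seq_t.n_volumes)),
                   "N": rng.standard_normal((n_vertices, seq_n.n_volumes))}
        truth_t, fits_t, truth_n, fits_n = baseline_recovery_study(
            seed, n_vertices, nl, noise=eps)
        err = np.concatenate([
            np.abs(fits_t["mu"] - truth_t["mu_d"]),
            np.abs(fits_n["mu"] - truth_n["mu_n"]),
        ])
        medians.append(float(np.median(err)))
    diffs = np.diff(medians)
    return {
        "medians": medians,
        "noise_levels": list(noise_levels),
        "monotone_non_increasing": bool(np.all(diffs <= 1e-9)),
        "value": medians[0] - medians[-1],
        "n": n_vertices,
    }


# ---------------------------------------------------------------------------
# Cluster-permutation calibration


def eval_cluster_calibration(seed: int = 0, n_runs: int = 500, n_side: int = 30,
                             density: float = 0.05, n_perm: int = 1000,
                             alpha: float = 0.01) -> dict:
    """How often pruning retains anything on pure-noise masks.

    The retention rate should be at or below ~alpha; a two-sided
    binomial test against alpha quantifies agreement.
    """
    patch, _ = sim.make_patch(n_side)
    adj = patch.adjacency()
    rng = np.random.default_rng(seed)
    sub = _seeds(seed + 1, n_runs)
    retained = 0
    effective = 0
    for i in range(n_runs):
        mask = rng.random(patch.n_vertices) < density
        if not mask.any():
            continue
        effective += 1
        pruned, _ = sf.cluster_permutation_prune(
            mask, patch.faces, n_perm=n_perm, alpha=alpha, seed=sub[i], adjacency=adj
        )
        retained += bool(pruned.any())
    p = sps.binomtest(retained, effective, alpha).pvalue
    return {
        "value": 100.0 * retained / effective,
        "binomial_p": float(p),
        "n": effective,
    }


# ---------------------------------------------------------------------------
# Flat-map geometry


def eval_distance_example() -> dict:
    """Hand-checkable normalized-distance geometry: a point at (2, 1)
    between two vertical edges five units apart sits at fraction 0.4."""
    roi = sf.ROIDefinition(
        vertices=np.arange(1),
        edge_a=np.array([[0.0, 0.0], [0.0, 4.0]]),
        edge_b=np.array([[5.0, 0.0], [5.0, 4.0]]),
    )
    return {"value": sf.normalized_distance(np.array([2.0, 1.0]), roi), "n": 1}


# ---------------------------------------------------------------------------
# Weber-law correlations


def eval_weber(seed: int = 0, n_vertices: int = 500) -> dict:
    """Kendall tau between preferred duration and the duration-axis
    tuning width on duration-baseline-like truth (orientation near 90
    deg, where the duration-axis width is sigma_n), against a
    permutation null."""
    n_side = int(np.ceil(np.sqrt(n_vertices)))
    spec = sim.GroundTruthSpec(n_side=n_side, seed=seed)
    patch, _ = sim.make_patch(n_side)
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    truth = sim.make_truth(patch, spec, "T", rng).iloc[:n_vertices].copy()
    table = ms.weber_correlations(truth, min_n=10)
    row = table[(table["theta_group"] == "60-120") & (table["pair"] == "mu_d-sigma_n")]
    tau = float(row["tau"].iloc[0])
    permuted = truth.copy()
    permuted["sigma_n"] = rng.permutation(permuted["sigma_n"].to_numpy())
    table_p = ms.weber_correlations(permuted, min_n=10)
    row_p = table_p[(table_p["theta_group"] == "60-120") & (table_p["pair"] == "mu_d-sigma_n")]
    return {
        "value": tau,
        "tau_permuted": float(row_p["tau"].iloc[0]),
        "n": int(row["n"].iloc[0]),
    }


# ---------------------------------------------------------------------------
# Tuning-shape direction (aspect ratio)


def aspect_study(seed: int = 0, n_subjects: int = 6, n_rois: int = 2,
                 vertices_per_cell: int = 40, noise_sd: float = 0.3) -> pd.DataFrame:
    """Fit every condition's truth with the full bivariate model probed
    by the interaction runs; return per subject x roi x condition mean
    fitted aspect ratios."""
    seqs = _probe_sequences(seed)
    n_side = max(4, int(np.ceil(np.sqrt(vertices_per_cell))))
    patch, _ = sim.make_patch(n_side)
    spec = sim.GroundTruthSpec(n_side=n_side, seed=seed, noise_sd=noise_sd)
    cell_seeds = iter(_seeds(seed + 2, n_subjects * n_rois * 4 * 2))
    shift_rng = np.random.default_rng(_seeds(seed + 3, 1)[0])

    blocks, labels = [], []
    for s in range(n_subjects):
        shift = shift_rng.normal(0.0, spec.subject_sd, size=2)
        for r in range(n_rois):
            for cond in st.CONDITIONS:
                truth = sim.make_truth(
                    patch, spec, cond, np.random.default_rng(next(cell_seeds))
                ).iloc[:vertices_per_cell]
                data = _simulate_probe_data(
                    truth, seqs, noise_sd, next(cell_seeds),
                    amplitude=spec.amplitude,
                )
                blocks.append(data)
                labels.extend([(s, f"roi{r}", cond)] * len(truth))
    data = np.concatenate(blocks, axis=0)
    fits = ft.fit_vertices(data, seqs)
    lab = pd.DataFrame(labels, columns=["subject", "roi", "condition"])
    fits = pd.concat([lab, fits.reset_index(drop=True)], axis=1)
    fits["aspect_ratio"] = ms.aspect_ratio(fits["sigma_d"], fits["sigma_n"])
    kept = fits[fits["passed"]]
    return (kept.groupby(["subject", "roi", "condition"], observed=True)["aspect_ratio"]
            .mean().reset_index())


def eval_aspect_direction(seed: int = 0, **kwargs) -> dict:
    """Baseline-like (1-D tuned) fits should be more elongated than
    jointly tuned fits, and the mixed model's combined-minus-baseline
    contrasts should be negative and significant."""
    table = aspect_study(seed, **kwargs)
    res = inf.fit_lme_aspect(table, seed=seed)
    means = table.groupby("condition", observed=True)["aspect_ratio"].mean()
    base = float(means[["T", "N"]].mean())
    joint = float(means[["C", "I"]].mean())
    # condition pairs sorted alphabetically: C-I, C-N, C-T, I-N, I-T, N-T
    combined_vs_baseline = res.mm_differences[
        res.mm_differences["pair"].isin(["C-N", "C-T", "I-N", "I-T"])
    ]
    all_neg = bool((combined_vs_baseline["estimate"] < 0).all())
    all_sig = bool((combined_vs_baseline["p_bonf"] < 0.05).all())
    cond_p = float(res.anova.loc[res.anova["term"] == "condition", "p"].iloc[0])
    return {
        "value": base - joint,
        "baseline_mean": base,
        "joint_mean": joint,
        "contrasts_negative": all_neg,
        "contrasts_significant": all_sig,
        "condition_effect_p": cond_p,
        "n": len(table),
    }


# ---------------------------------------------------------------------------
# Mixed-model calibration and coverage


def _simulate_bins(rng: np.random.Generator, n_subjects: int = 6,
                   cond_offsets=None, cond_slopes=None,
                   subject_sd: float = 5.0, noise_sd: float = 3.0) -> pd.DataFrame:
    """Bin-level dataset with known fixed effects: one row per subject x
    condition x distance bin."""
    conditions = list(st.CONDITIONS)
    cond_offsets = cond_offsets or {c: 0.0 for c in conditions}
    cond_slopes = cond_slopes or {c: 30.0 for c in conditions}
    d = sf.bin_centre(np.arange(sf.N_BINS))
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        for c in conditions:
            y = (b + cond_offsets[c] + cond_slopes[c] * d
                 + rng.normal(0.0, noise_sd, size=len(d)))
            rows.append(pd.DataFrame({
                "subject": s, "condition": c, "distance": d, "mean_mu_d": y,
            }))
    return pd.concat(rows, ignore_index=True)


def eval_lme_type1(seed: int = 0, n_sims: int = 500, alpha: float = 0.05) -> dict:
    """Type-I error of the Type III condition test under a null with
    real subject heterogeneity (percent of rejections)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        bins = _simulate_bins(rng)
        res = inf.fit_lme_condition(bins, compute_contrasts=False, n_boot=0)
        p = float(res.anova.loc[res.anova["term"] == "condition", "p"].iloc[0])
        rejections += p < alpha
    return {"value": 100.0 * rejections / n_sims, "n": n_sims}


def eval_bootstrap_coverage(seed: int = 0, n_reps: int = 200,
                            n_boot: int = 999) -> dict:
    """Coverage of 95% percentile bootstrap CIs for marginal-mean and
    slope differences under known condition effects (percent of
    pair-replicates covered)."""
    offsets = {"T": 0.0, "N": 5.0, "C": 20.0, "I": 10.0}
    slopes = {"T": 40.0, "N": 40.0, "C": 20.0, "I": 30.0}
    xbar = float(np.mean(sf.bin_centre(np.arange(sf.N_BINS))))
    pairs = [("C", "I"), ("C", "N"), ("C", "T"), ("I", "N"), ("I", "T"), ("N", "T")]
    true_mm = {f"{a}-{b}": (offsets[a] - offsets[b]) + (slopes[a] - slopes[b]) * xbar
               for a, b in pairs}
    true_slope = {f"{a}-{b}": slopes[a] - slopes[b] for a, b in pairs}
    rng = np.random.default_rng(seed)
    boot_seeds = _seeds(seed + 1, n_reps)
    mm_cov, slope_cov = [], []
    for r in range(n_reps):
        bins = _simulate_bins(rng, cond_offsets=offsets, cond_slopes=slopes)
        res = inf.fit_lme_condition(bins, n_boot=n_boot, seed=boot_seeds[r])
        for _, row in res.mm_differences.iterrows():
            t = true_mm[row["pair"]]
            mm_cov.append(row["boot_ci_low"] <= t <= row["boot_ci_high"])
        for _, row in res.slope_differences.iterrows():
            t = true_slope[row["pair"]]
            slope_cov.append(row["boot_ci_low"] <= t <= row["boot_ci_high"])
    return {
        "value": 100.0 * float(np.mean(slope_cov)),
        "mm_coverage": 100.0 * float(np.mean(mm_cov)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# Full-pipeline smoke study


def pipeline_study(seed: int = 0, n_side: int = 16, roi_cols: int = 7,
                   n_subjects: int = 4, noise_sd: float = 0.3) -> dict:
    """Run the whole pipeline end to end on a small synthetic study.

    A tuned map occupies the left ``roi_cols`` columns of the patch; the
    remaining vertices carry noise only, as the cortex surrounding a
    real map would.  Both baseline conditions are simulated per
    subject, fitted with the reduced 1-D model, thresholded, cluster
    pruned, located on the flat map, binned and passed to the group
    model.  Returns the headline results plus the vertex-conservation
    check (everything entering inference passed threshold and
    pruning)."""
    spec = sim.GroundTruthSpec(n_side=n_side, n_subjects=n_subjects,
                               noise_sd=noise_sd, seed=seed)
    patch, _ = sim.make_patch(n_side)
    x = patch.flat_coords[:, 0]
    in_roi = x <= roi_cols - 1
    roi = sf.ROIDefinition(
        vertices=np.flatnonzero(in_roi),
        edge_a=np.array([[0.0, 0.0], [0.0, n_side - 1.0]]),
        edge_b=np.array([[roi_cols - 1.0, 0.0], [roi_cols - 1.0, n_side - 1.0]]),
        name="map",
    )
    roi_dist = np.clip(x / (roi_cols - 1.0), 0.0, 1.0)
    amplitude = np.where(in_roi, spec.amplitude, 0.0)
    adj = patch.adjacency()

    s_truth, s_run = _seeds(seed, 2)
    shift_rng = np.random.default_rng(_seeds(seed + 3, 1)[0])
    noise_rngs = iter(np.random.default_rng(_seeds(seed + 4, 1)[0]).spawn(
        n_subjects * 2))
    prune_seeds = iter(_seeds(seed + 5, n_subjects * 2))

    rows, taus, shifts_d = [], [], []
    n_passing_total = 0
    for cond, axis in (("T", 0), ("N", 1)):
        truth = sim.make_truth(patch, spec, cond,
                               np.random.default_rng(s_truth + axis),
                               distances=roi_dist)
        seq = st.build_run(cond, seed=s_run + axis)
        cache = ft.combined_design(seq)
        for s in range(n_subjects):
            shift = shift_rng.normal(0.0, spec.subject_sd, size=2)
            if cond == "T":
                shifts_d.append(shift[0])
            raw = sim.simulate_bold(truth, seq, noise_sd=spec.noise_sd,
                                    subject_shift=tuple(shift),
                                    amplitude=amplitude, rng=next(noise_rngs))
            fits = ft.fit_vertices_1d(md.preprocess(raw), seq, axis)
            mask = ft.apply_threshold(fits).to_numpy()
            pruned, _ = sf.cluster_permutation_prune(
                mask, patch.faces, seed=next(prune_seeds), adjacency=adj)
            keep = pruned & in_roi
            kept = fits[keep]
            n_passing_total += int(mask.sum())
            if cond == "T" and len(kept) > 2:
                taus.append(sps.kendalltau(kept["mu"], kept["sigma"]).statistic)
            rows.append(pd.DataFrame({
                "subject": s, "condition": cond,
                "mu_d": kept["mu"].to_numpy(), "distance": roi_dist[keep],
                "passed_and_pruned": True,
            }))
    vertices = pd.concat(rows, ignore_index=True)
    bins = inf.build_bin_dataset(vertices, response_cols=("mu_d",))
    res = inf.fit_lme_condition(bins, "mean_mu_d", n_boot=199, seed=seed)
    slope = float(np.polyfit(bins["distance"], bins["mean_mu_d"], 1)[0])
    # duration-map endpoints against the matching bin-centre truth
    tbins = bins[bins["condition"] == "T"]
    lo_bin, hi_bin = tbins["bin"].min(), tbins["bin"].max()
    span = spec.gradient_d[1] - spec.gradient_d[0]
    # the realised subject-shift mean is part of the known truth
    shift_mean = float(np.mean(shifts_d))
    return {
        "distance_F_p": float(res.anova.loc[res.anova["term"] == "distance", "p"].iloc[0]),
        "progression_slope": slope,
        "edge_low_mean": float(tbins[tbins["bin"] == lo_bin]["mean_mu_d"].mean()),
        "edge_low_truth": spec.gradient_d[0] + float(sf.bin_centre(lo_bin)) * span
        + shift_mean,
        "edge_high_mean": float(tbins[tbins["bin"] == hi_bin]["mean_mu_d"].mean()),
        "edge_high_truth": spec.gradient_d[0] + float(sf.bin_centre(hi_bin)) * span
        + shift_mean,
        "tau_mu_sigma_T": float(np.mean(taus)) if taus else np.nan,
        "conserved": bool(vertices["passed_and_pruned"].all()),
        "n_bins": len(bins),
        "n_vertices_entering": len(vertices),
    }
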