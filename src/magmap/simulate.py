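"""Synthetic ground-truth cortex: surface patches, tuning-parameter
fields with the statistical structure the analysis assumes, and noisy
BOLD, so the whole pipeline is testable with known truth.

The generator emulates, per condition, the features the analysis is
built to detect: a topographic gradient of preferred magnitude between
the ROI's two edges, Weber-law scaling of tuning width with preference
(sigma = w*mu + c plus noise), condition-specific orientation
structure (baselines unimodal near 90 deg, congruent bimodal at
45/135 deg, incongruent trimodal), per-subject random preference
offsets, and additive white Gaussian BOLD noise at a controllable
level.  Baseline-condition receptive fields are strongly elongated
along the irrelevant magnitude (high aspect ratio); jointly tuned
fields are closer to circular.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import model as md
from .model import HRFSpec
from .stimulus import CONDITIONS, TimingConfig, build_run
from .surface import ROIDefinition, SurfacePatch

logger = logging.getLogger(__name__)

#: Orientation mixture per condition (mode centres in degrees).
THETA_MODES = {
    "T": (90.0,),
    "N": (90.0,),
    "C": (45.0, 135.0),
    "I": (30.0, 90.0, 150.0),
}


@dataclass(frozen=True)
class GroundTruthSpec:
    """Study conditions of the synthetic experiment."""

    n_side: int = 20  # vertices per patch side (n_side**2 vertices)
    #: columns (from the left) forming the tuned map; None tunes the whole
    #: patch.  A map embedded in silent cortex is what the cluster
    #: permutation step is designed for.
    roi_cols: int | None = None
    gradient_d: tuple[float, float] = (20.0, 80.0)  # mu_d at edge A, edge B
    gradient_n: tuple[float, float] = (20.0, 80.0)  # mu_n at edge A, edge B
    weber_slope: float = 0.3  # sigma = slope*mu + intercept ...
    weber_intercept: float = 5.0
    sigma_noise_sd: float = 2.0  # jitter around the Weber line (units)
    theta_jitter_sd: float = 10.0  # wrapped jitter around C/I modes (deg)
    sigma_cap: float = 75.0  # irrelevant-axis width; keeps truth inside fit bounds
    subject_sd: float = 5.0  # SD of per-subject preference offsets (units)
    noise_sd: float = 0.3  # BOLD noise SD, percent-signal units
    amplitude: float = 1.0  # response amplitude, percent-signal units
    baseline_level: float = 1000.0  # raw scanner-unit run mean
    n_subjects: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_side < 4:
            raise ValueError("patch needs at least 4 vertices per side")
        if self.noise_sd < 0:
            raise ValueError("noise SD cannot be negative")
        mus = np.array(self.gradient_d + self.gradient_n)
        if np.any(self.weber_slope * mus + self.weber_intercept <= 0):
            raise ValueError("Weber line gives non-positive widths over the gradient")


def make_patch(n_side: int) -> tuple[SurfacePatch, ROIDefinition]:
    """Regular triangulated grid with flat coordinates; edge A is the
    left boundary column, edge B the right one."""
    if n_side < 4:
        raise ValueError("patch needs at least 4 vertices per side")
    xs, ys = np.meshgrid(np.arange(n_side, dtype=float),
                         np.arange(n_side, dtype=float), indexing="xy")
    coords = np.column_stack([xs.ravel(), ys.ravel()])  # v = y*n + x
    faces = []
    n = n_side
    for y in range(n - 1):
        for x in range(n - 1):
            v00 = y * n + x
            v10 = v00 + 1
            v01 = v00 + n
            v11 = v01 + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    left = coords[:, 0] == 0
    right = coords[:, 0] == n - 1
    roi = ROIDefinition(
        vertices=np.arange(n * n),
        edge_a=np.array([[0.0, 0.0], [0.0, n - 1.0]]),
        edge_b=np.array([[n - 1.0, 0.0], [n - 1.0, n - 1.0]]),
        lateral_edges=(
            np.array([[0.0, 0.0], [n - 1.0, 0.0]]),
            np.array([[0.0, n - 1.0], [n - 1.0, n - 1.0]]),
        ),
        name=f"grid{n}",
    )
    return SurfacePatch(np.asarray(faces, int), coords), roi


def _draw_theta(modes, n: int, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    pick = rng.integers(0, len(modes), size=n)
    th = np.asarray(modes, float)[pick] + rng.normal(0.0, jitter_sd, size=n)
    return np.mod(th, 180.0)


def make_truth(patch: SurfacePatch, spec: GroundTruthSpec, condition: str,
               rng: np.random.Generator | None = None,
               shuffle_degrade: bool = False,
               distances: np.ndarray | None = None) -> pd.DataFrame:
    """Per-vertex true tuning parameters for one condition.

    Preferred magnitudes vary linearly with each vertex's normalized
    distance between the spec's edge values; widths follow the Weber
    line of the relevant magnitude(s).  Baseline populations are
    modelled as invariant to the irrelevant magnitude: orientation is a
    point mass at 90 deg (principal axis 1 along numerosity), the width
    along the irrelevant axis sits at ``sigma_cap`` and the irrelevant
    preference is parked mid-range.  Jointly tuned (C/I) populations
    draw orientations from the condition's mode mixture with wrapped
    Gaussian jitter.  ``shuffle_degrade`` permutes preferences across
    vertices, flattening the topography while preserving marginals.
    ``distances`` overrides the per-vertex normalized distance (useful
    when the tuned ROI spans only part of the patch).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = rng or np.random.default_rng(spec.seed)
    if distances is None:
        x = patch.flat_coords[:, 0]
        dist = (x - x.min()) / (x.max() - x.min())
    else:
        dist = np.clip(np.asarray(distances, float), 0.0, 1.0)
    n_v = patch.n_vertices
    mu_d = spec.gradient_d[0] + dist * (spec.gradient_d[1] - spec.gradient_d[0])
    mu_n = spec.gradient_n[0] + dist * (spec.gradient_n[1] - spec.gradient_n[0])

    def weber(mu):
        w = spec.weber_slope * mu + spec.weber_intercept
        return np.clip(w + rng.normal(0.0, spec.sigma_noise_sd, size=n_v),
                       2.0, spec.sigma_cap)

    if condition in ("T", "N"):
        # invariant baselines: orientation exactly 90 deg, so principal
        # axis 1 (sigma_d) lies along numerosity, axis 2 (sigma_n)
        # along duration; the irrelevant axis is maximally broad
        theta = np.full(n_v, 90.0)
        if condition == "T":
            mu_n = np.full(n_v, 50.0)  # irrelevant preference, mid-range
            sigma_n = weber(mu_d)  # width along duration
            sigma_d = np.full(n_v, spec.sigma_cap)
        else:
            mu_d = np.full(n_v, 50.0)
            sigma_d = weber(mu_n)  # width along numerosity
            sigma_n = np.full(n_v, spec.sigma_cap)
    else:
        theta = _draw_theta(THETA_MODES[condition], n_v, spec.theta_jitter_sd, rng)
        sigma_d = weber(mu_d)
        sigma_n = weber(mu_n)

    if shuffle_degrade:
        perm = rng.permutation(n_v)
        mu_d, mu_n = mu_d[perm], mu_n[perm]

    return pd.DataFrame({
        "vertex": np.arange(n_v), "distance": dist,
        "mu_d": mu_d, "mu_n": mu_n,
        "sigma_d": sigma_d, "sigma_n": sigma_n, "theta": theta,
    })


def simulate_bold(truth: pd.DataFrame, seq, hrf: HRFSpec | None = None,
                  noise_sd: float = 0.3, subject_shift: tuple[float, float] = (0.0, 0.0),
                  amplitude: float = 1.0, baseline_level: float = 1000.0,
                  rng: np.random.Generator | None = None,
                  lock: str = "offset") -> np.ndarray:
    """Raw BOLD matrix (vertices x volumes) for one run.

    Each vertex's series is the forward prediction of its
    (subject-shifted) true parameters, scaled to ``amplitude`` percent
    signal about ``baseline_level`` (a scalar, or one value per vertex
    — zero silences a vertex), plus white Gaussian noise of
    ``noise_sd`` percent signal.  Deterministic given the generator.
    """
    if noise_sd < 0:
        raise ValueError("noise SD cannot be negative")
    rng = rng or np.random.default_rng(0)
    design, dn = md.unique_stimulus_design(seq, hrf, lock)
    nr = md.neural_response_grid(
        truth["mu_d"].to_numpy() + subject_shift[0],
        truth["mu_n"].to_numpy() + subject_shift[1],
        truth["sigma_d"].to_numpy(), truth["sigma_n"].to_numpy(),
        truth["theta"].to_numpy(), dn,
    )  # (V, U)
    amp = np.asarray(amplitude, float)
    signal_pct = (amp[:, None] if amp.ndim else amp) * (nr @ design.T)  # (V, T)
    raw = baseline_level * (1.0 + signal_pct / 100.0)
    if noise_sd > 0:
        raw = raw + baseline_level * (noise_sd / 100.0) * rng.standard_normal(raw.shape)
    return raw


@dataclass
class SyntheticDataset:
    """A complete synthetic study: geometry, truths, runs and raw BOLD."""

    spec: GroundTruthSpec
    patch: SurfacePatch
    roi: ROIDefinition
    sequences: dict  # condition -> StimulusSequence
    truths: dict  # condition -> truth DataFrame
    bold: dict  # (subject, condition) -> raw BOLD (V, T)
    subject_shifts: dict  # subject -> (delta mu_d, delta mu_n)

    @property
    def provenance(self) -> dict:
        return {"spec": asdict(self.spec), "generator": "magmap.simulate.generate_dataset"}

    def save_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2)


def generate_dataset(spec: GroundTruthSpec,
                     conditions=CONDITIONS,
                     timing: TimingConfig | None = None,
                     hrf: HRFSpec | None = None) -> SyntheticDataset:
    """Generate the full study: one run per condition per subject.

    All randomness derives from ``spec.seed`` through named
    SeedSequence spawns, so regeneration from the stored spec is
    bitwise reproducible.
    """
    timing = timing or TimingConfig()
    root = np.random.SeedSequence(spec.seed)
    ss_truth, ss_subj, ss_noise, ss_runs = root.spawn(4)
    patch, roi = make_patch(spec.n_side)
    if spec.roi_cols is not None:
        if not 2 <= spec.roi_cols <= spec.n_side:
            raise ValueError("roi_cols must lie in [2, n_side]")
        x = patch.flat_coords[:, 0]
        in_roi = x <= spec.roi_cols - 1
        roi = ROIDefinition(
            vertices=np.flatnonzero(in_roi),
            edge_a=np.array([[0.0, 0.0], [0.0, spec.n_side - 1.0]]),
            edge_b=np.array([[spec.roi_cols - 1.0, 0.0],
                             [spec.roi_cols - 1.0, spec.n_side - 1.0]]),
            name=f"map{spec.roi_cols}of{spec.n_side}",
        )
        distances = np.clip(x / (spec.roi_cols - 1.0), 0.0, 1.0)
        amplitude = np.where(in_roi, spec.amplitude, 0.0)
    else:
        distances = None
        amplitude = spec.amplitude

    run_seeds = ss_runs.generate_state(len(conditions))
    sequences = {
        c: build_run(c, timing, seed=int(run_seeds[i]) % (2**31))
        for i, c in enumerate(conditions)
    }
    truth_rngs = {c: np.random.default_rng(s) for c, s in
                  zip(conditions, ss_truth.spawn(len(conditions)))}
    truths = {c: make_truth(patch, spec, c, truth_rngs[c], distances=distances)
              for c in conditions}

    subj_rng = np.random.default_rng(ss_subj)
    shifts = {
        s: tuple(subj_rng.normal(0.0, spec.subject_sd, size=2))
        for s in range(spec.n_subjects)
    }
    noise_rngs = np.random.default_rng(ss_noise).spawn(spec.n_subjects * len(conditions))
    bold = {}
    k = 0
    for s in range(spec.n_subjects):
        for c in conditions:
            bold[(s, c)] = simulate_bold(
                truths[c], sequences[c], hrf,
                noise_sd=spec.noise_sd, subject_shift=shifts[s],
                amplitude=amplitude, baseline_level=spec.baseline_level,
                rng=noise_rngs[k],
            )
            k += 1
    return SyntheticDataset(spec, patch, roi, sequences, truths, bold, shifts)
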