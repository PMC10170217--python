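"""Descriptive statistics over vertex populations.

Condition overlap of map vertex sets, tuning-shape summaries (aspect
ratio, axial orientation densities) and the Weber-law check: within
orientation groups, Kendall correlations between preferred magnitude
and tuning width, which under the scalar property should be positive
for the magnitude the receptive field is actually tuned to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

#: Orientation groups (degrees).  0/90/180-adjacent groups collect
#: receptive fields sensitive to a single magnitude; the 45- and
#: 135-centred groups collect jointly tuned fields.
THETA_GROUPS = (
    ("0-30", 0.0, 30.0),
    ("30-60", 30.0, 60.0),
    ("60-120", 60.0, 120.0),
    ("120-150", 120.0, 150.0),
    ("150-180", 150.0, 180.0),
)

MU_SIGMA_PAIRS = (
    ("mu_d", "sigma_d"), ("mu_d", "sigma_n"),
    ("mu_n", "sigma_d"), ("mu_n", "sigma_n"),
)


def overlap_fraction(set_a, set_b) -> float:
    """Fraction of map vertices shared between two conditions, as the
    Jaccard index |A & B| / |A | B|."""
    a, b = set(np.asarray(list(set_a)).tolist()), set(np.asarray(list(set_b)).tolist())
    union = a | b
    if not union:
        raise ValueError("overlap of two empty vertex sets is undefined")
    return len(a & b) / len(union)


def overlap_matrix(vertex_sets: dict) -> pd.DataFrame:
    """Pairwise overlap fractions between named vertex sets."""
    names = list(vertex_sets)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            v = overlap_fraction(vertex_sets[x], vertex_sets[y])
            out.loc[x, y] = out.loc[y, x] = v
    return out


def aspect_ratio(sigma_d, sigma_n) -> np.ndarray | float:
    """Major-to-minor axis ratio of the tuning function: 1 is a perfect
    circle (equal sensitivity to both magnitudes), large values an
    oblong field sensitive to one."""
    sd = np.asarray(sigma_d, float)
    sn = np.asarray(sigma_n, float)
    if np.any(sd <= 0) or np.any(sn <= 0):
        raise ValueError("tuning widths must be positive")
    out = np.maximum(sd, sn) / np.minimum(sd, sn)
    return float(out) if out.ndim == 0 else out


def major_axis_theta(sigma_d, sigma_n, theta) -> np.ndarray | float:
    """Orientation of the tuning function's major axis in [0, 180).

    The parametrisation (sigma_d, sigma_n, theta) and its relabelling
    (sigma_n, sigma_d, theta + 90) describe the same Gaussian; the
    major-axis angle is the label-free orientation.
    """
    sd = np.asarray(sigma_d, float)
    sn = np.asarray(sigma_n, float)
    th = np.mod(np.asarray(theta, float), 180.0)
    out = np.where(sd >= sn, th, np.mod(th + 90.0, 180.0))
    return float(out) if out.ndim == 0 else out


def theta_density(thetas, bandwidth: float = 15.0,
                  grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Axial kernel density of receptive-field orientations.

    Gaussian kernels of the given bandwidth (degrees) wrapped on the
    180-degree axial circle; the density integrates to 1 over [0, 180).
    Returns (grid, density).
    """
    th = np.asarray(thetas, float)
    if th.size == 0:
        raise ValueError("no orientations given")
    if np.any(th < 0) or np.any(th >= 180):
        th = np.mod(th, 180.0)
    x = np.arange(0.0, 180.0, 0.5) if grid is None else np.asarray(grid, float)
    # sum Gaussian images at theta + 180k; |k| <= 3 covers bandwidths
    # far wider than the 15-degree default
    diff = x[:, None] - th[None, :]
    dens = np.zeros_like(x)
    for k in range(-3, 4):
        dens += np.exp(-0.5 * ((diff + 180.0 * k) / bandwidth) ** 2).sum(axis=1)
    dens /= th.size * bandwidth * np.sqrt(2.0 * np.pi)
    return x, dens


def assign_theta_group(theta) -> np.ndarray | str:
    """Orientation-group label(s) for theta in [0, 180); intervals are
    half-open, the last closed at 180."""
    th = np.asarray(theta, float)
    if np.any(th < 0) or np.any(th >= 180):
        raise ValueError("theta must lie in [0, 180)")
    labels = np.empty(th.shape, dtype=object)
    for name, lo, hi in THETA_GROUPS:
        sel = (th >= lo) & (th < hi)
        labels[sel] = name
    return str(labels[()]) if th.ndim == 0 else labels.astype(str)


def weber_correlations(fits: pd.DataFrame,
                       groupby: list[str] | None = None,
                       min_n: int = 10) -> pd.DataFrame:
    """Kendall tau (tie-corrected, tau-b) between every preferred
    magnitude and every tuning width, within orientation groups.

    ``fits`` needs columns mu_d, mu_n, sigma_d, sigma_n, theta (plus any
    ``groupby`` columns such as roi/condition); rows should already be
    thresholded.  Groups smaller than ``min_n`` are flagged unreliable.
    """
    df = fits.copy()
    df["theta_group"] = assign_theta_group(df["theta"].to_numpy())
    keys = (groupby or []) + ["theta_group"]
    rows = []
    for key, g in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for mu_col, sg_col in MU_SIGMA_PAIRS:
            n = len(g)
            if n >= 2:
                tau = kendalltau(g[mu_col], g[sg_col]).statistic
            else:
                tau = np.nan
            rows.append(dict(zip(keys, key)) | {
                "pair": f"{mu_col}-{sg_col}",
                "tau": float(tau) if np.isfinite(tau) else np.nan,
                "n": n,
                "reliable": n >= min_n,
            })
    return pd.DataFrame(rows)
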