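"""Population receptive field forward model.

A vertex's neural response to a dot array showing ``n`` dots for ``d``
seconds is modelled as an unnormalised bivariate Gaussian over the
(duration, numerosity) plane, both expressed in arbitrary units:

    nr(d, n) = exp(-1/2 * x' S^-1 x),   x = (d - mu_d, n - mu_n)
    S = R(theta) diag(sigma_d^2, sigma_n^2) R(theta)'

(mu_d, mu_n) is the preferred magnitude pair, (sigma_d, sigma_n) the
tuning widths along the function's principal axes, and theta the
orientation of those axes in the plane — 0/90/180 deg mean sensitivity
to a single dimension, 45/135 deg joint sensitivity.  The peak response
is exactly 1; overall response amplitude is left to the GLM stage.

The predicted BOLD series places one neural impulse per trial (at
stimulus offset by default), convolves with a canonical two-gamma HRF
and samples at the TR.  Preprocessing mirrors the measurement pipeline:
a discrete-cosine high-pass (first six non-constant components removed)
followed by percent signal change about the pre-filtering run mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .stimulus import StimulusSequence, stimulus_units

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TuningParams:
    """Five-parameter bivariate Gaussian tuning of one vertex.

    Angles are degrees; theta is axial (theta and theta+180 describe the
    same Gaussian) and is stored wrapped into [0, 180).
    """

    mu_d: float
    mu_n: float
    sigma_d: float
    sigma_n: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_d > 0 and self.sigma_n > 0):
            raise ValueError("tuning widths must be positive")
        object.__setattr__(self, "theta", wrap_theta(self.theta))

    @property
    def covariance(self) -> np.ndarray:
        th = math.radians(self.theta)
        r = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        return r @ np.diag([self.sigma_d**2, self.sigma_n**2]) @ r.T


@dataclass(frozen=True)
class GLMCoefficients:
    """Linear scaling of the pRF prediction to the measured signal."""

    amplitude: float
    baseline: float


def wrap_theta(theta) -> float | np.ndarray:
    """Wrap orientation(s) into [0, 180) — the Gaussian is axial."""
    wrapped = np.mod(theta, 180.0)
    return float(wrapped) if np.ndim(theta) == 0 else wrapped


def _quad_coeffs(sigma_d, sigma_n, theta_deg):
    """Coefficients (a, b, c) of the quadratic form
    a*dx^2 + 2*b*dx*dy + c*dy^2 = 1/2 * x' S^-1 x."""
    th = np.radians(theta_deg)
    ct2, st2 = np.cos(th) ** 2, np.sin(th) ** 2
    s2 = np.sin(2.0 * th)
    inv_d = 1.0 / (2.0 * np.asarray(sigma_d, float) ** 2)
    inv_n = 1.0 / (2.0 * np.asarray(sigma_n, float) ** 2)
    a = ct2 * inv_d + st2 * inv_n
    b = 0.5 * s2 * (inv_d - inv_n)
    c = st2 * inv_d + ct2 * inv_n
    return a, b, c


def neural_response(params: TuningParams, d, n):
    """Neural response in (0, 1] at duration ``d``, numerosity ``n``
    (arbitrary units; broadcastable arrays allowed)."""
    a, b, c = _quad_coeffs(params.sigma_d, params.sigma_n, params.theta)
    dx = np.asarray(d, float) - params.mu_d
    dy = np.asarray(n, float) - params.mu_n
    out = np.exp(-(a * dx**2 + 2.0 * b * dx * dy + c * dy**2))
    return float(out) if out.ndim == 0 else out


def neural_response_grid(mu_d, mu_n, sigma_d, sigma_n, theta, stim_dn: np.ndarray) -> np.ndarray:
    """Vectorised response of many parameter combinations at many stimuli.

    Parameters are broadcastable 1-D arrays of length K; ``stim_dn`` is
    (S, 2).  Returns (K, S).
    """
    a, b, c = _quad_coeffs(np.asarray(sigma_d, float), np.asarray(sigma_n, float),
                           np.asarray(theta, float))
    dx = stim_dn[:, 0][None, :] - np.asarray(mu_d, float)[:, None]
    dy = stim_dn[:, 1][None, :] - np.asarray(mu_n, float)[:, None]
    return np.exp(-(a[:, None] * dx**2 + 2.0 * b[:, None] * dx * dy + c[:, None] * dy**2))


def neural_response_1d(mu, sigma, x):
    """Reduced model for the baseline conditions: a 1-D Gaussian along
    the varying magnitude, invariant to the irrelevant one."""
    if sigma <= 0:
        raise ValueError("tuning width must be positive")
    return np.exp(-0.5 * ((np.asarray(x, float) - mu) / sigma) ** 2)


# ---------------------------------------------------------------------------
# Haemodynamics


@dataclass(frozen=True)
class HRFSpec:
    """Canonical two-gamma haemodynamic response (SPM parametrisation:
    response peak 6 s, undershoot peak 16 s, undershoot ratio 1/6)."""

    dt: float = 0.05
    duration: float = 32.0
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.1:
            raise ValueError("HRF sampling step must be in (0, 0.1] s")
        if self.duration < 20.0:
            raise ValueError("HRF kernel must cover at least 20 s")

    def kernel(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of the kernel on its fine grid, peak-normalised."""
        t = np.arange(0.0, self.duration + self.dt / 2, self.dt)
        h = _gamma_pdf(t, self.peak_delay) - self.ratio * _gamma_pdf(t, self.undershoot_delay)
        h = h / h.max()
        return t, h


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    """Gamma density without the scipy.stats dispatch overhead."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp((shape - 1.0) * np.log(tp) - tp - gammaln(shape)) / scale
    return out


def event_times(seq: StimulusSequence, lock: str = "offset") -> np.ndarray:
    """Neural event times, one per trial.  ``offset`` (default) places
    the impulse when the stimulus ends — the moment its duration is fully
    determined; ``onset`` places it at stimulus onset."""
    if lock not in ("onset", "offset"):
        raise ValueError("lock must be 'onset' or 'offset'")
    on = np.array([e.onset for e in seq.events])
    if lock == "onset":
        return on
    return on + np.array([e.duration for e in seq.events])


def hrf_design(seq: StimulusSequence, hrf: HRFSpec | None = None,
               lock: str = "offset") -> np.ndarray:
    """(n_volumes, n_events) matrix whose column j is the TR-sampled HRF
    shifted to event j; a predicted series is this matrix times the
    per-event neural impulse heights."""
    hrf = hrf or HRFSpec()
    tk, hk = hrf.kernel()
    times = event_times(seq, lock)
    lag = seq.frame_times[:, None] - times[None, :]
    return np.interp(lag, tk, hk, left=0.0, right=0.0)


def unique_stimulus_design(seq: StimulusSequence, hrf: HRFSpec | None = None,
                           lock: str = "offset") -> tuple[np.ndarray, np.ndarray]:
    """Collapse the event design by unique (duration, numerosity) pair.

    Returns ``(design, stim_dn)`` with ``design`` (n_volumes, U) summing
    the HRF columns of identical stimuli and ``stim_dn`` (U, 2) the
    unique magnitudes in arbitrary units.  A prediction is then
    ``design @ nr(stim_dn)`` — the workhorse of the vectorised grid fit.
    """
    full = hrf_design(seq, hrf, lock)
    dn = stimulus_units(seq)
    uniq, inv = np.unique(np.round(dn, 9), axis=0, return_inverse=True)
    design = np.zeros((full.shape[0], len(uniq)))
    np.add.at(design.T, inv, full.T)
    return design, uniq


def predict_bold(params: TuningParams, seq: StimulusSequence,
                 hrf: HRFSpec | None = None, lock: str = "offset") -> np.ndarray:
    """Predicted BOLD series (unit amplitude, zero baseline)."""
    design, dn = unique_stimulus_design(seq, hrf, lock)
    return design @ neural_response(params, dn[:, 0], dn[:, 1])


def predict_bold_1d(mu: float, sigma: float, seq: StimulusSequence, axis: int,
                    hrf: HRFSpec | None = None, lock: str = "offset") -> np.ndarray:
    """Predicted BOLD under the reduced 1-D model along ``axis``
    (0 = duration, 1 = numerosity)."""
    design, dn = unique_stimulus_design(seq, hrf, lock)
    return design @ neural_response_1d(mu, sigma, dn[:, axis])


# ---------------------------------------------------------------------------
# Preprocessing


def dct_basis(n: int, n_components: int) -> np.ndarray:
    """(n, n_components) orthonormal DCT-II basis, lowest non-constant
    frequencies first."""
    k = np.arange(1, n_components + 1)
    t = np.arange(n)
    basis = np.cos(np.pi * (2 * t[:, None] + 1) * k[None, :] / (2 * n))
    return basis * math.sqrt(2.0 / n)


def dct_highpass(series: np.ndarray, n_components: int = 6) -> np.ndarray:
    """Remove the first ``n_components`` discrete-cosine components.

    The constant term is not counted and not removed, so the series mean
    is preserved (percent signal change needs it).  Works on 1-D series
    or (n_series, n_timepoints) matrices; idempotent.
    """
    y = np.asarray(series, float)
    n = y.shape[-1]
    if n <= n_components + 1:
        raise ValueError("series too short for the requested DCT basis")
    basis = dct_basis(n, n_components)
    coeffs = y @ basis
    return y - coeffs @ basis.T


def percent_signal_change(series: np.ndarray, run_mean=None) -> np.ndarray:
    """100 * (y - m) / m about the pre-filtering run mean ``m``.

    Pass ``run_mean`` when the series has already been high-pass
    filtered (the filter preserves the mean, so either way m is the raw
    run mean).  A near-zero mean signals data that are not raw BOLD
    intensities and is refused.
    """
    y = np.asarray(series, float)
    m = np.mean(y, axis=-1, keepdims=True) if run_mean is None else np.asarray(run_mean, float)
    m = np.atleast_1d(m)
    if m.ndim < y.ndim:
        m = m[..., None]
    scale = np.maximum(np.max(np.abs(y), axis=-1, keepdims=True), 1.0)
    if np.any(np.abs(m) < 1e-8 * scale):
        raise ValueError("series mean is (near) zero; percent signal change undefined")
    out = 100.0 * (y - m) / m
    return out.reshape(np.shape(series))


def preprocess(series: np.ndarray, n_components: int = 6) -> np.ndarray:
    """Measurement-pipeline preprocessing: DCT high-pass then percent
    signal change about the raw run mean."""
    y = np.asarray(series, float)
    m = np.mean(y, axis=-1, keepdims=True)
    return percent_signal_change(dct_highpass(y, n_components), m)
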