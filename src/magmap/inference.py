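"""Group-level mixed-model inference on binned map preferences.

The group datasets have one row per subject x condition (or ROI) x
distance bin, holding the mean preferred magnitude of that bin's
vertices.  Three random-intercept linear mixed models are run on them:

    preference  ~ Condition * Distance + (1 | subject)   (within-ROI)
    preference  ~ ROI * Distance       + (1 | subject)   (across-ROI)
    aspect      ~ ROI * Condition      + (1 | subject)   (tuning shape)

Fixed effects are tested with Type III F-tests whose denominator
degrees of freedom use Satterthwaite's approximation; estimated
marginal (least-squares) means are compared pairwise with
Bonferroni-corrected t-tests, and pairwise marginal-mean and
distance-slope differences carry percentile confidence intervals from
a 999-draw bootstrap (parametric by default, matching lme4's
``confint(method="boot")``; resampling subjects with replacement is
available as an option).  Satterthwaite is used for the marginal-mean
difference df as well; every result table carries a note flagging that
choice (the Kenward-Roger adjustment is not implemented).

The REML fit itself is profiled over the single variance ratio of the
random-intercept model and works entirely from per-subject sufficient
statistics, which makes the hundreds of thousands of refits behind the
bootstrap and the calibration studies cheap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .surface import bin_centre, bin_distance

logger = logging.getLogger(__name__)

SATTERTHWAITE_NOTE = (
    "degrees of freedom: Satterthwaite approximation "
    "(Kenward-Roger not implemented; flagged deviation)"
)


def bonferroni(p, m: int | None = None) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, m*p) over a family of m tests."""
    arr = np.asarray(p, float)
    m = m if m is not None else arr.size
    out = np.minimum(1.0, m * arr)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Bin-level dataset


def build_bin_dataset(fits: pd.DataFrame,
                      response_cols: tuple[str, ...] = ("mu_d", "mu_n"),
                      keys: tuple[str, ...] = ("subject", "condition", "roi"),
                      distance_col: str = "distance") -> pd.DataFrame:
    """Average vertex preferences per distance bin.

    ``fits`` holds one thresholded vertex per row with its normalized
    distance.  Returns one row per non-empty (keys..., bin) cell with
    mean preferences, the bin-centre distance and the vertex count.
    """
    df = fits.copy()
    keys = tuple(k for k in keys if k in df.columns)
    df["bin"] = bin_distance(df[distance_col].to_numpy())
    grouped = df.groupby([*keys, "bin"], sort=True, observed=True)
    out = grouped[list(response_cols)].mean()
    out = out.rename(columns={c: f"mean_{c}" for c in response_cols})
    out["n_vertices"] = grouped.size()
    out = out.reset_index()
    out["distance"] = bin_centre(out["bin"].to_numpy())
    return out


def orient_bin_dataset(bins: pd.DataFrame, response: str,
                       by: tuple[str, ...] = ("subject", "condition", "roi"),
                       distance_col: str = "distance") -> pd.DataFrame:
    """Reverse the distance axis of any map whose preference decreases
    with distance, so mislabelled low/high edges cannot inflate the
    condition x distance interaction.  Adds a ``reversed`` flag."""
    from .surface import orient_progression

    by = tuple(k for k in by if k in bins.columns)
    out = bins.copy()
    out["reversed"] = False
    for key, g in bins.groupby(list(by), sort=False, observed=True):
        try:
            d, rev = orient_progression(g[distance_col].to_numpy(), g[response].to_numpy())
        except ValueError:
            continue
        out.loc[g.index, distance_col] = d
        out.loc[g.index, "reversed"] = rev
    return out


# ---------------------------------------------------------------------------
# Random-intercept REML engine


class RandomInterceptLME:
    """REML fit of ``y = X b + u_group + noise`` with a scalar random
    intercept per group, profiled over the variance ratio.

    Works from per-group sufficient statistics so that refits with new
    responses or resampled groups (bootstrap) cost microseconds.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 colnames: list[str] | None = None) -> None:
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(X) != len(y) or len(y) != len(groups):
            raise ValueError("X, y, groups must align")
        self.colnames = colnames or [f"x{i}" for i in range(X.shape[1])]
        self.p = X.shape[1]
        uniq, inv = np.unique(groups, return_inverse=True)
        self.group_levels = uniq
        G = len(uniq)
        p = self.p
        self._n = np.zeros(G)
        self._A = np.zeros((G, p, p))
        self._a = np.zeros((G, p))
        self._b = np.zeros((G, p))
        self._s = np.zeros(G)
        self._q = np.zeros(G)
        self._X_groups = []
        for g in range(G):
            sel = inv == g
            Xi, yi = X[sel], y[sel]
            self._n[g] = sel.sum()
            self._A[g] = Xi.T @ Xi
            self._a[g] = Xi.sum(axis=0)
            self._b[g] = Xi.T @ yi
            self._s[g] = yi.sum()
            self._q[g] = yi @ yi
            self._X_groups.append(Xi)
        self.n_obs = len(y)
        self.fitted_ = False

    # -- assembly from sufficient statistics --------------------------------

    def _assemble(self, lam: float, block_idx=None, ystats=None):
        sl = slice(None) if block_idx is None else np.asarray(block_idx)
        b_, s_, q_ = ystats if ystats is not None else (self._b, self._s, self._q)
        n, a, s = self._n[sl], self._a[sl], s_[sl]
        w = lam / (1.0 + n * lam)
        M = self._A[sl].sum(axis=0) - np.einsum("g,gi,gj->ij", w, a, a)
        v = b_[sl].sum(axis=0) - (w * s) @ a
        Q = q_[sl].sum() - w @ s**2
        logdetV0 = np.log1p(n * lam).sum()
        return M, v, Q, logdetV0, int(n.sum())

    def _profile(self, lam: float, block_idx=None, ystats=None):
        M, v, Q, logdetV0, n = self._assemble(lam, block_idx, ystats)
        try:
            beta = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            return None
        rss = max(Q - beta @ v, 1e-300)
        sigma2 = rss / (n - self.p)
        sign, logdetM = np.linalg.slogdet(M)
        crit = (n - self.p) * np.log(sigma2) + logdetV0 + logdetM
        return dict(beta=beta, sigma2=sigma2, M=M, crit=crit, n=n, lam=lam)

    def fit(self, block_idx=None, ystats=None) -> "RandomInterceptLME":
        def objective(u):
            prof = self._profile(np.exp(u), block_idx, ystats)
            return prof["crit"] if prof is not None else np.inf

        sol = minimize_scalar(objective, bounds=(-14.0, 14.0), method="bounded",
                              options={"xatol": 1e-6})
        best = self._profile(np.exp(sol.x), block_idx, ystats)
        zero = self._profile(0.0, block_idx, ystats)
        if zero is not None and (best is None or zero["crit"] <= best["crit"] + 1e-10):
            best = zero
        if best is None:
            raise np.linalg.LinAlgError("singular fixed-effects design")
        self._block_idx = block_idx
        self._ystats = ystats
        self.lam = best["lam"]
        self.sigma2 = best["sigma2"]
        self.tau2 = self.lam * self.sigma2
        self.beta = best["beta"]
        self._M = best["M"]
        self.cov_beta = self.sigma2 * np.linalg.inv(best["M"])
        self.df_resid = best["n"] - self.p
        self.ols_fallback = self.lam < 1e-10
        if self.ols_fallback:
            logger.warning("random-intercept variance estimated at zero; "
                           "falling back to fixed-effects inference")
        self.fitted_ = True
        return self

    # -- REML log-likelihood in (sigma2, tau2), for the Satterthwaite cov --

    def _neg2_reml(self, sigma2: float, tau2: float) -> float:
        lam = tau2 / sigma2
        M, v, Q, logdetV0, n = self._assemble(lam, self._block_idx,
                                              getattr(self, "_ystats", None))
        beta = np.linalg.solve(M, v)
        rss = max(Q - beta @ v, 1e-300)
        sign, logdetM = np.linalg.slogdet(M)
        return ((n - self.p) * np.log(sigma2) + logdetV0 + logdetM + rss / sigma2)

    def _varpar_cov(self) -> np.ndarray | None:
        """Asymptotic covariance of (sigma2, tau2) from the numerically
        differentiated REML information; None at the tau2 boundary."""
        if self.ols_fallback:
            return None
        th = np.array([self.sigma2, self.tau2])
        h = np.maximum(1e-7, 1e-4 * th)

        def f(x):
            return 0.5 * self._neg2_reml(max(x[0], 1e-12), max(x[1], 0.0))

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    f(th + ei + ej) - f(th + ei - ej) - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or cov[0, 0] <= 0 or cov[1, 1] <= 0:
            return None
        return cov

    def _satterthwaite_df_1(self, ell: np.ndarray, varpar_cov) -> float:
        """Satterthwaite df of a single contrast ell' beta."""
        if self.ols_fallback or varpar_cov is None:
            return float(self.df_resid)
        th = np.array([self.sigma2, self.tau2])
        h = np.maximum(1e-7, 1e-4 * th)

        def fvar(x):
            lam = max(x[1], 0.0) / x[0]
            M, _, _, _, _ = self._assemble(lam, self._block_idx)
            return x[0] * float(ell @ np.linalg.solve(M, ell))

        g = np.array([
            (fvar(th + np.eye(2)[i] * h[i]) - fvar(th - np.eye(2)[i] * h[i])) / (2 * h[i])
            for i in range(2)
        ])
        fval = fvar(th)
        denom = float(g @ varpar_cov @ g)
        if denom <= 0:
            return float(self.df_resid)
        df = 2.0 * fval**2 / denom
        return float(np.clip(df, 1.0, 1e7))

    # -- tests ---------------------------------------------------------------

    def contrast_t(self, ell: np.ndarray, varpar_cov=None) -> dict:
        """t-test of a single contrast with Satterthwaite df and 95% CI."""
        ell = np.asarray(ell, float)
        est = float(ell @ self.beta)
        se = float(np.sqrt(ell @ self.cov_beta @ ell))
        cov = varpar_cov if varpar_cov is not None else self._varpar_cov()
        df = self._satterthwaite_df_1(ell, cov)
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        half = sps.t.ppf(0.975, df) * se
        return dict(estimate=est, se=se, df=df, t=t, p=p,
                    ci_low=est - half, ci_high=est + half)

    def contrast_F(self, L: np.ndarray, varpar_cov=None) -> dict:
        """Type III F-test of the joint hypothesis L beta = 0 with a
        multi-contrast Satterthwaite denominator df."""
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        C = L @ self.cov_beta @ L.T
        Lb = L @ self.beta
        F = float(Lb @ np.linalg.solve(C, Lb)) / q
        if self.ols_fallback:
            df2 = float(self.df_resid)
        else:
            cov = varpar_cov if varpar_cov is not None else self._varpar_cov()
            evals, evecs = np.linalg.eigh(C)
            keep = evals > 1e-12 * evals.max()
            dfs = [
                self._satterthwaite_df_1(evecs[:, i] @ L, cov)
                for i in np.flatnonzero(keep)
            ]
            good = [d for d in dfs if d > 2.0]
            E = sum(d / (d - 2.0) for d in good)
            if good and E > q:
                df2 = float(2.0 * E / (E - q))
            else:
                df2 = float(max(min(dfs), 1.0)) if dfs else float(self.df_resid)
        p = sps.f.sf(F, q, df2)
        return dict(F=F, df1=q, df2=df2, p=float(p))

    def nakagawa_r2(self, X: np.ndarray) -> tuple[float, float]:
        """Marginal and conditional variance explained by the model."""
        fitted = X @ self.beta
        vf = float(np.var(fitted))
        tot = vf + self.tau2 + self.sigma2
        return vf / tot, (vf + self.tau2) / tot


# ---------------------------------------------------------------------------
# Sum-coded designs


def _sum_code(level, levels) -> np.ndarray:
    """Deviation (sum-to-zero) coding: k-1 columns, last level = -1."""
    k = len(levels)
    out = np.zeros(k - 1)
    i = list(levels).index(level)
    if i < k - 1:
        out[i] = 1.0
    else:
        out[:] = -1.0
    return out


class FactorCovariateDesign:
    """Design for ``y ~ factor * covariate`` with sum-coded factor."""

    def __init__(self, factor_levels, covariate_name: str = "distance") -> None:
        self.levels = list(factor_levels)
        self.covariate_name = covariate_name
        k = len(self.levels)
        self.colnames = (
            ["(intercept)"]
            + [f"f[{l}]" for l in self.levels[:-1]]
            + [covariate_name]
            + [f"f[{l}]:{covariate_name}" for l in self.levels[:-1]]
        )
        self.terms = {
            "factor": list(range(1, k)),
            covariate_name: [k],
            f"factor:{covariate_name}": list(range(k + 1, 2 * k)),
        }

    def row(self, level, cov_value: float) -> np.ndarray:
        code = _sum_code(level, self.levels)
        return np.concatenate([[1.0], code, [cov_value], code * cov_value])

    def matrix(self, factor_values, cov_values) -> np.ndarray:
        return np.array([self.row(l, c) for l, c in zip(factor_values, cov_values)])

    def slope_row(self, level) -> np.ndarray:
        """d(prediction)/d(covariate) for one factor level."""
        code = _sum_code(level, self.levels)
        return np.concatenate([[0.0], 0.0 * code, [1.0], code])


class TwoFactorDesign:
    """Design for ``y ~ f1 * f2`` with both factors sum-coded."""

    def __init__(self, levels1, levels2, names=("f1", "f2")) -> None:
        self.levels1 = list(levels1)
        self.levels2 = list(levels2)
        self.names = names
        k1, k2 = len(self.levels1), len(self.levels2)
        self.colnames = (
            ["(intercept)"]
            + [f"{names[0]}[{l}]" for l in self.levels1[:-1]]
            + [f"{names[1]}[{l}]" for l in self.levels2[:-1]]
            + [f"{names[0]}[{a}]:{names[1]}[{b}]"
               for a in self.levels1[:-1] for b in self.levels2[:-1]]
        )
        i1 = list(range(1, k1))
        i2 = list(range(k1, k1 + k2 - 1))
        ii = list(range(k1 + k2 - 1, k1 + k2 - 1 + (k1 - 1) * (k2 - 1)))
        self.terms = {names[0]: i1, names[1]: i2, f"{names[0]}:{names[1]}": ii}

    def row(self, l1, l2) -> np.ndarray:
        c1 = _sum_code(l1, self.levels1)
        c2 = _sum_code(l2, self.levels2)
        return np.concatenate([[1.0], c1, c2, np.outer(c1, c2).ravel()])

    def matrix(self, v1, v2) -> np.ndarray:
        return np.array([self.row(a, b) for a, b in zip(v1, v2)])


def _term_L(terms: dict, term: str, p: int) -> np.ndarray:
    idx = terms[term]
    L = np.zeros((len(idx), p))
    for r, c in enumerate(idx):
        L[r, c] = 1.0
    return L


# ---------------------------------------------------------------------------
# Result container and the three model runners


@dataclass
class LMEResult:
    anova: pd.DataFrame
    marginal_means: pd.DataFrame
    mm_differences: pd.DataFrame
    slope_differences: pd.DataFrame | None
    sigma2: float
    tau2: float
    r2_marginal: float
    r2_conditional: float
    ols_fallback: bool
    notes: list[str] = field(default_factory=list)

    def to_json_summary(self) -> dict:
        import json

        def records(df):
            return json.loads(df.to_json(orient="records")) if df is not None else None

        return {
            "anova": records(self.anova),
            "marginal_means": records(self.marginal_means),
            "mm_differences": records(self.mm_differences),
            "slope_differences": records(self.slope_differences),
            "sigma2": float(self.sigma2), "tau2": float(self.tau2),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "ols_fallback": bool(self.ols_fallback), "notes": list(self.notes),
        }


def _bootstrap_percentile_cis(model: RandomInterceptLME, contrasts: list[np.ndarray],
                              n_boot: int, seed: int,
                              method: str = "parametric") -> np.ndarray:
    """95% percentile bootstrap CIs for fixed-effect contrasts.

    ``parametric`` (default, the lme4 ``confint(method="boot")``
    behaviour the published analysis pipeline relies on) simulates new
    responses from the fitted model — subject intercepts from
    N(0, tau2), noise from N(0, sigma2) — and refits.  ``subjects``
    resamples whole subjects with replacement; at a handful of subjects
    it is known to undercover.  Returns (len(contrasts), 2).
    """
    rng = np.random.default_rng(seed)
    est = np.empty((n_boot, len(contrasts)))
    worker = RandomInterceptLME.__new__(RandomInterceptLME)
    worker.__dict__.update(model.__dict__)
    if method == "parametric":
        mu_groups = [Xi @ model.beta for Xi in model._X_groups]
        sd_u, sd_e = np.sqrt(model.tau2), np.sqrt(model.sigma2)
        G = len(model._X_groups)
        for b in range(n_boot):
            bs = np.zeros((G, model.p))
            ss = np.zeros(G)
            qs = np.zeros(G)
            for g, Xi in enumerate(model._X_groups):
                y = (mu_groups[g] + rng.normal(0.0, sd_u)
                     + rng.normal(0.0, sd_e, size=len(Xi)))
                bs[g] = Xi.T @ y
                ss[g] = y.sum()
                qs[g] = y @ y
            try:
                worker.fit(ystats=(bs, ss, qs))
                est[b] = [c @ worker.beta for c in contrasts]
            except np.linalg.LinAlgError:
                est[b] = np.nan
    elif method == "subjects":
        n_groups = len(model.group_levels)
        for b in range(n_boot):
            draw = rng.integers(0, n_groups, size=n_groups)
            try:
                worker.fit(block_idx=list(draw))
                est[b] = [c @ worker.beta for c in contrasts]
            except np.linalg.LinAlgError:
                est[b] = np.nan
    else:
        raise ValueError("bootstrap method must be 'parametric' or 'subjects'")
    return np.nanpercentile(est, [2.5, 97.5], axis=0).T


def fit_lme_factor_distance(bins: pd.DataFrame, response: str,
                            factor: str = "condition",
                            covariate: str = "distance",
                            subject: str = "subject",
                            n_boot: int = 999,
                            seed: int = 0,
                            boot_method: str = "parametric",
                            compute_contrasts: bool = True) -> LMEResult:
    """``response ~ factor * covariate + (1 | subject)`` with Type III
    Satterthwaite F-tests, pairwise marginal-mean differences at the
    mean covariate value, and factor differences in the covariate slope
    with bootstrap CIs.  All pairwise p-values are Bonferroni-adjusted
    within their family.
    """
    df = bins.dropna(subset=[response]).copy()
    levels = sorted(df[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least two factor levels")
    if df[subject].nunique() < 3:
        raise ValueError("need at least three subjects")
    design = FactorCovariateDesign(levels, covariate)
    X = design.matrix(df[factor], df[covariate].to_numpy(float))
    model = RandomInterceptLME(X, df[response].to_numpy(float),
                               df[subject].to_numpy(), design.colnames).fit()
    vcov = model._varpar_cov()

    p = X.shape[1]
    anova = pd.DataFrame([
        {"term": term, **model.contrast_F(_term_L(design.terms, term, p), vcov)}
        for term in ("factor", covariate, f"factor:{covariate}")
    ]).replace({"term": {"factor": factor, f"factor:{covariate}": f"{factor}:{covariate}"}})

    xbar = float(df[covariate].mean())
    mm_rows, diff_rows, slope_rows = [], [], []
    mm_contrasts, slope_contrasts = [], []
    if compute_contrasts:
        for l in levels:
            r = model.contrast_t(design.row(l, xbar), vcov)
            mm_rows.append({"level": l, **r})
        pairs = list(itertools.combinations(levels, 2))
        for a, b in pairs:
            ell = design.row(a, xbar) - design.row(b, xbar)
            r = model.contrast_t(ell, vcov)
            diff_rows.append({"pair": f"{a}-{b}", **r})
            mm_contrasts.append(ell)
            slope_ell = design.slope_row(a) - design.slope_row(b)
            rs = model.contrast_t(slope_ell, vcov)
            slope_rows.append({"pair": f"{a}-{b}", **rs})
            slope_contrasts.append(slope_ell)
        m = len(pairs)
        for rows in (diff_rows, slope_rows):
            for row in rows:
                row["p_bonf"] = bonferroni(row["p"], m)
        if n_boot > 0:
            cis = _bootstrap_percentile_cis(
                model, mm_contrasts + slope_contrasts, n_boot, seed, boot_method
            )
            for row, (lo, hi) in zip(diff_rows + slope_rows, cis):
                row["boot_ci_low"], row["boot_ci_high"] = float(lo), float(hi)

    r2m, r2c = model.nakagawa_r2(X)
    return LMEResult(
        anova=anova,
        marginal_means=pd.DataFrame(mm_rows),
        mm_differences=pd.DataFrame(diff_rows),
        slope_differences=pd.DataFrame(slope_rows) if slope_rows else None,
        sigma2=model.sigma2, tau2=model.tau2,
        r2_marginal=r2m, r2_conditional=r2c,
        ols_fallback=model.ols_fallback,
        notes=[SATTERTHWAITE_NOTE]
        + (["random-effect variance zero: fixed-effects fallback"]
           if model.ols_fallback else []),
    )


def fit_lme_condition(bins: pd.DataFrame, response: str = "mean_mu_d",
                      **kwargs) -> LMEResult:
    """Within-ROI model: preference ~ Condition * Distance + (1|subject)."""
    return fit_lme_factor_distance(bins, response, factor="condition", **kwargs)


def fit_lme_roi(bins: pd.DataFrame, response: str = "mean_mu_d",
                **kwargs) -> LMEResult:
    """Across-ROI model for one condition:
    preference ~ ROI * Distance + (1|subject)."""
    return fit_lme_factor_distance(bins, response, factor="roi", **kwargs)


def fit_lme_aspect(aspect: pd.DataFrame, response: str = "aspect_ratio",
                   roi: str = "roi", condition: str = "condition",
                   subject: str = "subject", seed: int = 0) -> LMEResult:
    """Tuning-shape model on subject x ROI x condition mean aspect
    ratios: AspectRatio ~ ROI * Condition + (1|subject), with pairwise
    condition contrasts within each ROI (Bonferroni over the family)."""
    df = aspect.dropna(subset=[response]).copy()
    rois = sorted(df[roi].unique())
    conds = sorted(df[condition].unique())
    design = TwoFactorDesign(rois, conds, names=(roi, condition))
    X = design.matrix(df[roi], df[condition])
    model = RandomInterceptLME(X, df[response].to_numpy(float),
                               df[subject].to_numpy(), design.colnames).fit()
    vcov = model._varpar_cov()
    p = X.shape[1]
    anova = pd.DataFrame([
        {"term": term, **model.contrast_F(_term_L(design.terms, term, p), vcov)}
        for term in (roi, condition, f"{roi}:{condition}")
    ])

    mm_rows = [
        {"roi": r_, "condition": c_, **model.contrast_t(design.row(r_, c_), vcov)}
        for r_ in rois for c_ in conds
    ]
    pairs = [(r_, a, b) for r_ in rois for a, b in itertools.combinations(conds, 2)]
    diff_rows = []
    for r_, a, b in pairs:
        ell = design.row(r_, a) - design.row(r_, b)
        res = model.contrast_t(ell, vcov)
        diff_rows.append({"roi": r_, "pair": f"{a}-{b}", **res})
    for row in diff_rows:
        row["p_bonf"] = bonferroni(row["p"], len(pairs))

    r2m, r2c = model.nakagawa_r2(X)
    return LMEResult(
        anova=anova,
        marginal_means=pd.DataFrame(mm_rows),
        mm_differences=pd.DataFrame(diff_rows),
        slope_differences=None,
        sigma2=model.sigma2, tau2=model.tau2,
        r2_marginal=r2m, r2_conditional=r2c,
        ols_fallback=model.ols_fallback,
        notes=[SATTERTHWAITE_NOTE]
        + (["random-effect variance zero: fixed-effects fallback"]
           if model.ols_fallback else []),
    )
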