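"""ROI group statistics: robust ROI summaries, volume residualization,
linear mixed-effects modelling with Satterthwaite degrees of freedom,
FDR-corrected post hoc contrasts, effect sizes with cluster bootstrap, exact
nonparametric tests, and partial correlation.

The mixed model is y = X beta + Z b + e with a random intercept per animal
(b ~ N(0, sigma_a^2), e ~ N(0, sigma_e^2)), estimated by restricted maximum
likelihood.  Fixed effects use sum-to-zero coding so type III F tests reduce
to testing each term's coefficients; denominator degrees of freedom follow
the Satterthwaite approach (per-contrast variance gradients against the
REML information matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "roi_robust_mean",
    "residualize_on_volume",
    "GenotypeROIModel",
    "LMEMResult",
    "fit_lmem_genotype_roi",
    "posthoc_genotype_by_roi",
    "PosthocResult",
    "hedges_g_bootstrap",
    "mann_whitney_exact",
    "fisher_exact_2x2",
    "partial_correlation",
]


# ---------------------------------------------------------------------------
# ROI summaries and residualization
# ---------------------------------------------------------------------------


def roi_robust_mean(
    values: np.ndarray,
    roi_mask: np.ndarray,
    csf_mask: np.ndarray | None = None,
    trim: float = 0.05,
    method: str = "trim",
) -> tuple[float, int]:
    """Robust ROI mean: CSF voxels removed, then two-sided 5% trimming.

    ``method='trim'`` removes the floor(n*trim) lowest and highest values
    (exclusion of the regional extremes); ``method='winsorize'`` clamps them
    to the cut values instead.  Returns (robust mean, effective voxel count
    after CSF removal).
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    mask = roi_mask.astype(bool)
    if csf_mask is not None:
        mask = mask & ~csf_mask.astype(bool)
    vox = np.asarray(values)[mask]
    if vox.size == 0:
        raise ValueError("ROI is empty after CSF exclusion")
    k = int(np.floor(vox.size * trim))
    srt = np.sort(vox)
    if method == "trim":
        kept = srt[k : vox.size - k] if k > 0 else srt
    elif method == "winsorize":
        kept = np.clip(srt, srt[k], srt[vox.size - 1 - k])
    else:
        raise ValueError("method must be 'trim' or 'winsorize'")
    if kept.size == 0:
        raise ValueError("trimming removed every voxel")
    return float(kept.mean()), int(vox.size)


def residualize_on_volume(table: pd.DataFrame, metric: str) -> pd.Series:
    """Residualize one metric on ROI indicators plus ROI volume (pooled OLS).

    Including the ROI indicators removes every ROI main effect exactly (the
    downstream mixed-model ROI F statistic is 0 by construction), so the
    model stage isolates genotype and genotype-by-ROI effects.  Returns the
    residuals aligned with the input rows for that metric.
    """
    sub = table[table["metric"] == metric]
    if len(sub) < 3:
        raise ValueError("need at least 3 rows per metric")
    rois = sorted(sub["roi"].unique())
    x_roi = np.stack([(sub["roi"] == r).to_numpy(float) for r in rois], axis=1)
    vol = sub["roi_volume"].to_numpy(float)
    x = np.column_stack([x_roi, vol - vol.mean()])
    y = sub["value"].to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "residualization design is rank-deficient (ROI volume collinear "
            "with ROI indicators; volumes may be constant within ROI)"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return pd.Series(y - x @ beta, index=sub.index, name=f"{metric}_resid")


# ---------------------------------------------------------------------------
# linear mixed-effects model (random animal intercept, REML)
# ---------------------------------------------------------------------------


def _effects_coding(levels: list, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns; the last
    level gets -1 in every column."""
    cols = []
    for lev in levels[:-1]:
        c = np.where(values == lev, 1.0, 0.0)
        c[values == levels[-1]] = -1.0
        cols.append(c)
    return np.column_stack(cols) if cols else np.empty((values.size, 0))


@dataclass
class LMEMResult:
    """REML fit of residual ~ genotype * ROI + (1 | animal).

    ``anova`` holds one row per fixed-effect term with type III F,
    numerator df, Satterthwaite denominator df and p-value;
    ``varcomp`` holds the animal-intercept and residual variances.
    """

    anova: pd.DataFrame
    varcomp: dict[str, float]
    beta: np.ndarray
    cov_beta: np.ndarray
    term_slices: dict[str, slice]
    design_info: dict
    singular: bool
    _theta: np.ndarray = field(repr=False, default=None)
    _theta_cov: np.ndarray = field(repr=False, default=None)
    _model: "GenotypeROIModel" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Linear mixed model (REML): value ~ genotype * roi + (1 | animal)"]
        lines.append(
            "variance components: animal %.4g, residual %.4g%s"
            % (
                self.varcomp["animal"],
                self.varcomp["residual"],
                "  [boundary fit]" if self.singular else "",
            )
        )
        lines.append(self.anova.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class GenotypeROIModel:
    """Mixed model of residualized ROI values: genotype x ROI fixed effects
    with a random intercept per animal.

    Parameters
    ----------
    table : DataFrame
        Long-format rows with columns ``animal``, ``genotype``, ``roi`` and
        a value column (default ``value``), one row per animal x ROI.
    """

    def __init__(self, table: pd.DataFrame, value_col: str = "value"):
        required = {"animal", "genotype", "roi", value_col}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table is missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.value_col = value_col
        self.genotypes = sorted(self.table["genotype"].unique())
        self.rois = sorted(self.table["roi"].unique())
        if len(self.genotypes) != 2:
            raise ValueError("need exactly two genotype levels")
        if len(self.rois) < 2:
            raise ValueError("need at least two ROI levels")

        g = self.table["genotype"].to_numpy()
        r = self.table["roi"].to_numpy()
        xg = _effects_coding(self.genotypes, g)
        xr = _effects_coding(self.rois, r)
        inter = np.concatenate(
            [xg[:, [0]] * xr[:, [j]] for j in range(xr.shape[1])], axis=1
        )
        self.x = np.column_stack([np.ones(len(self.table)), xg, xr, inter])
        self.term_slices = {
            "Intercept": slice(0, 1),
            "genotype": slice(1, 1 + xg.shape[1]),
            "roi": slice(1 + xg.shape[1], 1 + xg.shape[1] + xr.shape[1]),
            "genotype:roi": slice(1 + xg.shape[1] + xr.shape[1], self.x.shape[1]),
        }
        self.y = self.table[self.value_col].to_numpy(float)
        animals = self.table["animal"].to_numpy()
        self.groups = [np.flatnonzero(animals == a) for a in pd.unique(animals)]

    # -- REML machinery ------------------------------------------------------

    def _block_inverse_apply(self, theta, m):
        """V^-1 m for V = sigma_e^2 I + sigma_a^2 J within animal blocks."""
        sa2, se2 = theta
        out = np.empty_like(m, dtype=float)
        for idx in self.groups:
            n_i = idx.size
            block = m[idx]
            shrink = sa2 / (se2 + n_i * sa2)
            out[idx] = (block - shrink * block.sum(axis=0)) / se2
        return out

    def _neg2_reml(self, theta) -> float:
        sa2, se2 = theta
        if se2 <= 0 or sa2 < 0:
            return np.inf
        logdet_v = 0.0
        for idx in self.groups:
            n_i = idx.size
            logdet_v += (n_i - 1) * np.log(se2) + np.log(se2 + n_i * sa2)
        vix = self._block_inverse_apply(theta, self.x)
        xtvx = self.x.T @ vix
        viy = self._block_inverse_apply(theta, self.y[:, None])[:, 0]
        xtvy = self.x.T @ viy
        try:
            c = np.linalg.cholesky(xtvx)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        resid_quad = self.y @ viy - xtvy @ beta
        logdet_xtvx = 2.0 * np.sum(np.log(np.diag(c)))
        return logdet_v + logdet_xtvx + resid_quad

    def _profile_start(self) -> np.ndarray:
        """Moment-based starting values from the one-way animal ANOVA."""
        grand = self.y.mean()
        between = np.var([self.y[idx].mean() for idx in self.groups], ddof=1)
        within = np.mean(
            [np.var(self.y[idx], ddof=1) for idx in self.groups if idx.size > 1]
        )
        se2 = max(within, 1e-12 * max(np.var(self.y - grand), 1e-30) + 1e-300)
        n_bar = np.mean([idx.size for idx in self.groups])
        sa2 = max(between - se2 / n_bar, se2 * 1e-4)
        return np.array([sa2, se2])

    def fit(self) -> LMEMResult:
        x0 = self._profile_start()
        scale = max(np.var(self.y), 1e-30)
        res = optimize.minimize(
            lambda t: self._neg2_reml(np.exp(t)),
            np.log(np.maximum(x0, scale * 1e-8)),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        theta = np.exp(res.x)
        # allow the boundary sigma_a^2 = 0: compare against a pure-residual fit
        if self._neg2_reml([0.0, np.exp(res.x[1])]) <= res.fun + 1e-10:
            ols_se2 = optimize.minimize_scalar(
                lambda s: self._neg2_reml([0.0, np.exp(s)]),
                bracket=(np.log(theta[1]) - 2, np.log(theta[1]) + 2),
            )
            if ols_se2.fun <= res.fun + 1e-10:
                theta = np.array([0.0, np.exp(ols_se2.x)])
        singular = theta[0] <= scale * 1e-7

        vix = self._block_inverse_apply(theta, self.x)
        xtvx = self.x.T @ vix
        cov_beta = np.linalg.inv(xtvx)
        viy = self._block_inverse_apply(theta, self.y[:, None])[:, 0]
        beta = cov_beta @ (self.x.T @ viy)

        theta_cov = self._theta_covariance(theta)
        rows = []
        for term in ("genotype", "roi", "genotype:roi"):
            sl = self.term_slices[term]
            f, df1, df2, p = self._term_ftest(term, beta, cov_beta, theta, theta_cov)
            rows.append(
                {"term": term, "F": f, "df_num": df1, "df_den": df2, "p": p}
            )
        anova = pd.DataFrame(rows).set_index("term")
        return LMEMResult(
            anova,
            {"animal": float(theta[0]), "residual": float(theta[1])},
            beta,
            cov_beta,
            self.term_slices,
            {"genotypes": self.genotypes, "rois": self.rois},
            bool(singular),
            theta,
            theta_cov,
            self,
        )

    def _theta_covariance(self, theta) -> np.ndarray:
        """Asymptotic covariance of (sigma_a^2, sigma_e^2): 2 * H^-1 with H
        the finite-difference Hessian of the -2 REML criterion."""
        h = np.zeros((2, 2))
        steps = [max(1e-7, 1e-4 * t) for t in theta]
        f0 = self._neg2_reml(theta)

        def f_at(d0, d1):
            t = np.array([max(theta[0] + d0, 0.0), max(theta[1] + d1, 1e-300)])
            return self._neg2_reml(t)

        for i in range(2):
            for j in range(i, 2):
                di = np.array([steps[0] if i == 0 else 0.0, steps[1] if i == 1 else 0.0])
                dj = np.array([steps[0] if j == 0 else 0.0, steps[1] if j == 1 else 0.0])
                if i == j:
                    h[i, i] = (
                        f_at(*(di + dj)) - 2.0 * f_at(*di) + f0
                    ) / (steps[i] ** 2)
                    # recentre with a symmetric stencil when away from the boundary
                    if theta[i] > steps[i]:
                        h[i, i] = (
                            f_at(*di) - 2.0 * f0 + f_at(*(-di))
                        ) / (steps[i] ** 2)
                else:
                    if theta[0] > steps[0]:
                        h[i, j] = h[j, i] = (
                            f_at(steps[0], steps[1])
                            - f_at(steps[0], -steps[1])
                            - f_at(-steps[0], steps[1])
                            + f_at(-steps[0], -steps[1])
                        ) / (4.0 * steps[0] * steps[1])
                    else:
                        h[i, j] = h[j, i] = (
                            f_at(steps[0], steps[1])
                            - f_at(steps[0], 0.0)
                            - f_at(0.0, steps[1])
                            + f0
                        ) / (steps[0] * steps[1])
        try:
            return 2.0 * np.linalg.inv(h)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)

    def _contrast_var_grad(self, contrast: np.ndarray, theta) -> tuple[float, np.ndarray]:
        """Variance of c'beta and its gradient w.r.t. theta (finite diff)."""

        def var_at(t):
            vix = self._block_inverse_apply(t, self.x)
            cov = np.linalg.inv(self.x.T @ vix)
            return float(contrast @ cov @ contrast)

        v0 = var_at(theta)
        grad = np.zeros(2)
        for i in range(2):
            step = max(1e-7, 1e-4 * theta[i])
            tp = theta.copy()
            tp[i] += step
            if theta[i] >= step:
                tm = theta.copy()
                tm[i] -= step
                grad[i] = (var_at(tp) - var_at(tm)) / (2 * step)
            else:
                grad[i] = (var_at(tp) - v0) / step
        return v0, grad

    def satterthwaite_df(self, contrast: np.ndarray, theta, theta_cov) -> float:
        """Satterthwaite denominator df for a single contrast c'beta."""
        v0, grad = self._contrast_var_grad(np.asarray(contrast, float), theta)
        denom = float(grad @ theta_cov @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(len(self.y) - self.x.shape[1])
        return 2.0 * v0**2 / denom

    def _term_ftest(self, term, beta, cov_beta, theta, theta_cov):
        sl = self.term_slices[term]
        q = sl.stop - sl.start
        l_mat = np.zeros((q, self.x.shape[1]))
        for i, j in enumerate(range(sl.start, sl.stop)):
            l_mat[i, j] = 1.0
        lb = l_mat @ beta
        lcl = l_mat @ cov_beta @ l_mat.T
        f = float(lb @ np.linalg.solve(lcl, lb) / q)
        # multi-df Satterthwaite: eigen-directions of the contrast covariance
        evals, evecs = np.linalg.eigh(lcl)
        nus = []
        for k in range(q):
            c = (evecs[:, k] @ l_mat)
            nu = self.satterthwaite_df(c, theta, theta_cov)
            if nu > 2:
                nus.append(nu)
        e_sum = sum(nu / (nu - 2.0) for nu in nus)
        df2 = 2.0 * e_sum / (e_sum - q) if e_sum > q else float(len(self.y))
        p = float(sps.f.sf(f, q, df2))
        return f, float(q), df2, p


def fit_lmem_genotype_roi(table: pd.DataFrame, value_col: str = "value") -> LMEMResult:
    """Convenience wrapper: fit the genotype x ROI mixed model by REML."""
    return GenotypeROIModel(table, value_col).fit()


# ---------------------------------------------------------------------------
# post hoc contrasts, effect sizes
# ---------------------------------------------------------------------------


@dataclass
class PosthocResult:
    """Per-ROI genotype contrasts with BH-FDR correction and effect sizes."""

    table: pd.DataFrame

    def summary(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def posthoc_genotype_by_roi(
    result: LMEMResult,
    raw_table: pd.DataFrame | None = None,
    value_col: str = "value",
    n_boot: int = 1000,
    seed: int = 0,
) -> PosthocResult:
    """Estimated-marginal-mean genotype contrasts per ROI from the fitted
    mixed model, with Satterthwaite-df t tests and Benjamini-Hochberg
    correction across ROIs; Hedges' g with a cluster (animal-level)
    bootstrap CI is computed from the per-animal values.
    """
    model = result._model
    genotypes = result.design_info["genotypes"]
    rois = result.design_info["rois"]
    # contrast vector for (genotype A - genotype B) within a given roi,
    # in the effects-coded design: difference of the two genotype codes is 2
    # for the genotype main column and 2 * roi_code for interaction columns.
    rows = []
    table = model.table if raw_table is None else raw_table
    for roi in rois:
        c = np.zeros(model.x.shape[1])
        c[model.term_slices["genotype"]] = 2.0
        roi_codes = _effects_coding(rois, np.array([roi]))[0]
        c[model.term_slices["genotype:roi"]] = 2.0 * roi_codes
        est = float(c @ result.beta)
        se = float(np.sqrt(c @ result.cov_beta @ c))
        df = model.satterthwaite_df(c, result._theta, result._theta_cov)
        tval = est / se
        p = 2.0 * float(sps.t.sf(abs(tval), df))
        sub = table[table["roi"] == roi]
        x = sub[sub["genotype"] == genotypes[0]][value_col].to_numpy(float)
        y = sub[sub["genotype"] == genotypes[1]][value_col].to_numpy(float)
        g, (lo, hi) = hedges_g_bootstrap(x, y, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "roi": roi,
                "mean_difference": est,
                "t": tval,
                "df": df,
                "p": p,
                "hedges_g": g,
                "g_ci_low": lo,
                "g_ci_high": hi,
            }
        )
    out = pd.DataFrame(rows).set_index("roi")
    out["p_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return PosthocResult(out)


def hedges_g_bootstrap(
    x: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Hedges' g (bias-corrected standardized mean difference, x - y) with a
    percentile CI from a stratified cluster bootstrap.

    g = J * (mean_x - mean_y) / s_pooled with J = 1 - 3/(4 (n_x + n_y - 2) - 1).
    Resampling draws animals with replacement within each group (the animal
    is the cluster / resampling unit), 1000 iterations by default.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")

    def g_of(a, b):
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if sp2 <= 0:
            return np.nan
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        return j * (a.mean() - b.mean()) / np.sqrt(sp2)

    g = g_of(x, y)
    if not np.isfinite(g):
        raise ValueError("pooled SD is zero; Hedges' g undefined")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        boots[i] = g_of(xb, yb)
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, g), max(hi, g)  # the CI always contains the estimate
    return float(g), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------


def mann_whitney_exact(x, y) -> tuple[float, float, float]:
    """Exact Mann-Whitney U test with rank-biserial effect size.

    U counts pairs with x_i > y_j (ties add 1/2).  The two-sided p-value is
    computed by full enumeration of all C(n_x + n_y, n_x) group labelings of
    the observed pooled values (midranks handle ties), doubling the smaller
    tail and capping at 1.  The rank-biserial correlation is
    r = 1 - 2 U / (n_x n_y), negative when the x group tends to be larger.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    n = nx + ny
    if comb(n, nx) > 5_000_000:
        raise ValueError("group sizes too large for exact enumeration")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0

    u_all = np.asarray(
        [ranks[list(idx)].sum() - nx * (nx + 1) / 2.0 for idx in combinations(range(n), nx)]
    )
    eps = 1e-9
    p_low = np.mean(u_all <= u_obs + eps)
    p_high = np.mean(u_all >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_low, p_high))
    r = 1.0 - 2.0 * u_obs / (nx * ny)
    return float(u_obs), float(p), float(r)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test (two-sided, point-probability rule) for a 2x2
    count table.  Returns (p, odds ratio); zero cells follow the usual
    0 / inf conventions."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("table must hold non-negative integer counts")
        t = t.astype(int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: empty margin")
    res = sps.fisher_exact(t, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with its t-test p-value.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2));
    p from t = r sqrt((n - 3) / (1 - r^2)) on n - 3 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = x.size
    if n < 4 or y.size != n or z.size != n:
        raise ValueError("need matched samples with n >= 4")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    if np.isclose(abs(rxz), 1.0) or np.isclose(abs(ryz), 1.0):
        raise ValueError("covariate is collinear with x or y")
    r = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    r = float(np.clip(r, -1.0, 1.0))
    if np.isclose(abs(r), 1.0):
        return r, 0.0
    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 3))
    return r, p
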