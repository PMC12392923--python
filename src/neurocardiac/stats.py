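"""Inferential machinery.

The workhorse is a random-intercept linear mixed model

    y = b0 + b1 * x + u_participant + e,   u ~ N(0, s_u^2), e ~ N(0, s_e^2)

fitted by maximum likelihood with the intercept-variance ratio profiled
out, so a channel-wise map of 32 fits costs milliseconds. Degrees of
freedom use the residual method (n_obs minus the number of fixed-effect
parameters) and two-sided p-values come from the corresponding
t-distribution. Effect sizes are Cohen's r, either from a t statistic,
r = sign(t) * sqrt(t^2 / (t^2 + df)), or from a standardized rank-test
statistic, r = Z / sqrt(N).

Multiple testing is handled by Benjamini-Hochberg step-up adjustment; the
adjustment family is all channels of one t-map, or all cells of the HR
feature x predictor interaction grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .containers import LMEResult

__all__ = [
    "fit_lme_random_intercept", "bh_adjust", "cohens_r_from_t",
    "cohens_r_from_z", "build_t_map", "fit_sex_interaction", "rank_tests",
    "RankTestResult",
]


# ---------------------------------------------------------------- LME ----

def _profile_negloglik(rho: float, groups: list[tuple[np.ndarray, np.ndarray]],
                       n: int, p: int) -> tuple[float, np.ndarray, float, float]:
    """Profiled ML deviance at variance ratio rho = s_u^2 / s_e^2.

    For a single grouping factor, V = s_e^2 (I + rho Z Z') is block diagonal
    and (I + rho J_m)^{-1} = I - rho/(1 + rho m) J_m, so all GLS sums reduce
    to within-group totals. beta and s_e^2 are solved in closed form given
    rho; only rho is optimized numerically.
    """
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for X, y in groups:
        m = X.shape[0]
        a = rho / (1.0 + rho * m)
        sx = X.sum(axis=0)
        sy = y.sum()
        xtvx += X.T @ X - a * np.outer(sx, sx)
        xtvy += X.T @ y - a * sx * sy
        ytvy += y @ y - a * sy * sy
        logdet += np.log1p(rho * m)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    sigma2 = max(rss / n, 1e-300)
    nll = 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return nll, beta, sigma2, xtvx


def fit_lme_random_intercept(y, x, participant_ids) -> LMEResult:
    """ML fit of ``y ~ x + (1 | participant)``; returns the slope row.

    Raises on degenerate input: fewer than two participants, a constant
    predictor, or a constant response.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ids = np.asarray(participant_ids)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length 1-d arrays")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("y and x must be finite")
    uniq = np.unique(ids)
    if uniq.size < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")

    X = np.column_stack([np.ones_like(x), x])
    n, p = X.shape
    groups = [(X[ids == g], y[ids == g]) for g in uniq]
    if min(g[0].shape[0] for g in groups) < 1:
        raise ValueError("empty group")

    def nll(log_rho: float) -> float:
        return _profile_negloglik(np.exp(log_rho), groups, n, p)[0]

    # Profile over log rho; include the rho -> 0 boundary (plain OLS).
    res = optimize.minimize_scalar(nll, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    nll0, *_ = _profile_negloglik(0.0, groups, n, p)
    if nll0 <= res.fun:
        rho = 0.0
        nll_min, beta, sigma2, xtvx = nll0, *_
    else:
        rho = float(np.exp(res.x))
        nll_min, beta, sigma2, xtvx = _profile_negloglik(rho, groups, n, p)

    cov = sigma2 * np.linalg.inv(xtvx)
    se = float(np.sqrt(cov[1, 1]))
    df = n - p
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    t = float(beta[1] / se)
    pval = float(2.0 * sps.t.sf(abs(t), df))
    return LMEResult(
        estimate=float(beta[1]), se=se, tvalue=t, df=df,
        pvalue=max(pval, np.finfo(float).tiny),
        random_intercept_var=float(rho * sigma2), resid_var=float(sigma2),
        n_obs=n, loglik=float(-nll_min),
    )


# ------------------------------------------------- corrections, effects ----

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_r_from_t(t: float, df: float) -> float:
    """Cohen's r from a t statistic: sign(t) * sqrt(t^2 / (t^2 + df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(np.sign(t) * np.sqrt(t * t / (t * t + df)))


def cohens_r_from_z(z: float, n_total: int) -> float:
    """Cohen's r from a standardized statistic: Z / sqrt(N)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return float(z / np.sqrt(n_total))


# ------------------------------------------------------------ rank tests ----

@dataclass
class RankTestResult:
    statistic: float
    z: float
    pvalue: float
    r: float
    n_total: int
    method: str


def _signed_rank_z(d: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank: (T+, z) with tie correction and continuity."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = (counts ** 3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
    if sigma == 0:
        return t_plus, 0.0
    delta = t_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma if delta != 0 else 0.0
    return t_plus, float(z)


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U for sample a: (U, z) with ties and continuity."""
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie))
    if sigma == 0:
        return u, 0.0
    delta = u - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma if delta != 0 else 0.0
    return u, float(z)


def rank_tests(group_a, group_b, paired: bool = False,
               exact_limit: int = 25) -> RankTestResult:
    """Two-sided Wilcoxon rank test with a Cohen's r effect size.

    Signed-rank for ``paired=True`` (N = number of non-zero pair
    differences), rank-sum otherwise (N = n_a + n_b). Exact p-values are
    used for samples up to ``exact_limit`` without ties; larger samples use
    the normal approximation with continuity correction. All-tied input
    yields p = 1, r = 0 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if a.size < 5:
            raise ValueError("need at least 5 pairs")
        d = a - b
        nz = d[d != 0]
        n_total = int(nz.size)
        if nz.size == 0:
            return RankTestResult(0.0, 0.0, 1.0, 0.0, 0, "signed-rank")
        stat, z = _signed_rank_z(d)
        has_ties = np.unique(np.abs(nz)).size < nz.size
        if nz.size <= exact_limit and not has_ties:
            p = float(sps.wilcoxon(nz, alternative="two-sided",
                                   method="exact").pvalue)
        else:
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "signed-rank"
    else:
        if min(a.size, b.size) < 5:
            raise ValueError("need at least 5 observations per group")
        n_total = int(a.size + b.size)
        if np.ptp(np.concatenate([a, b])) == 0:
            return RankTestResult(float(a.size * b.size / 2), 0.0, 1.0, 0.0,
                                  n_total, "rank-sum")
        stat, z = _rank_sum_z(a, b)
        has_ties = np.unique(np.concatenate([a, b])).size < n_total
        if max(a.size, b.size) <= exact_limit and not has_ties:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue)
        else:
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "rank-sum"
    p = min(p, 1.0)
    r = cohens_r_from_z(z, n_total) if n_total > 0 else 0.0
    return RankTestResult(float(stat), z, p, r, n_total, method)


# ----------------------------------------------------------------- t-maps ----

def build_t_map(run_features: pd.DataFrame, feature: str, predictor: str,
                sex: str | int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Channel-wise LME t-map for one EEG feature against one predictor.

    ``run_features`` is the run-level table (one row per participant x phase
    x run x channel) with the feature columns plus predictor columns
    (``phase_code``, ``pasa``, ``error_rate``). ``sex`` restricts to one sex
    group (1 = female, 2 = male); None pools everyone.

    Returns one row per channel: estimate, t, df, p, p_adj (BH across the
    map's channels), Cohen's r and a significance flag. Channels whose fit
    fails are kept with NaN statistics and excluded from the BH family.
    """
    df = run_features
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError("no rows for requested sex group")
    rows = []
    for channel, sub in df.groupby("channel", sort=False, observed=True):
        sub = sub.dropna(subset=[feature, predictor])
        try:
            res = fit_lme_random_intercept(
                sub[feature].to_numpy(), sub[predictor].to_numpy(),
                sub["participant"].to_numpy())
            rows.append({"channel": channel, "estimate": res.estimate,
                         "t": res.tvalue, "df": res.df, "p": res.pvalue,
                         "r": cohens_r_from_t(res.tvalue, res.df),
                         "n_obs": res.n_obs,
                         "random_intercept_var": res.random_intercept_var})
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"channel {channel}: LME fit failed ({exc})")
            rows.append({"channel": channel, "estimate": np.nan, "t": np.nan,
                         "df": np.nan, "p": np.nan, "r": np.nan,
                         "n_obs": len(sub), "random_intercept_var": np.nan})
    tmap = pd.DataFrame(rows)
    ok = tmap["p"].notna()
    tmap["p_adj"] = np.nan
    if ok.any():
        tmap.loc[ok, "p_adj"] = bh_adjust(tmap.loc[ok, "p"].to_numpy())
    tmap["significant"] = tmap["p_adj"] < alpha
    tmap.attrs.update(feature=feature, predictor=predictor, sex=sex,
                      alpha=alpha)
    return tmap


# -------------------------------------------------- sex-interaction models ----

def fit_sex_interaction(hr_features: pd.DataFrame, predictors=None,
                        features=None, alpha: float = 0.05) -> pd.DataFrame:
    """OLS models ``feature ~ sex * predictor`` over the HR trajectory grid.

    ``hr_features`` holds one row per participant x phase with the seven
    dip/rebound metrics plus predictor columns (numeric sex coded
    1 = female / 2 = male). Every (feature, predictor) cell is fitted by
    ordinary least squares with main effects and interaction; BH adjustment
    runs across the whole grid of non-intercept terms, mirroring a
    feature x predictor significance heatmap.
    """
    from .containers import HR_FEATURES
    if predictors is None:
        predictors = ["error_rate", "pasa", "phase_code", "relative_rt"]
    if features is None:
        features = [f for f in HR_FEATURES if f in hr_features.columns]
    if hr_features["sex"].nunique() < 2:
        warnings.warn("single-sex input: interaction terms are not estimable")

    rows = []
    for feat in features:
        for pred in predictors:
            data = hr_features.dropna(subset=[feat, pred, "sex"]).copy()
            data = data.rename(columns={feat: "y", pred: "x"})
            if data["y"].nunique() < 2 or data["x"].nunique() < 2:
                continue
            model = smf.ols("y ~ sex * x", data=data).fit()
            if model.df_resid <= 0 or not np.isfinite(model.scale) \
                    or model.scale <= np.finfo(float).tiny:
                warnings.warn(f"{feat} ~ sex*{pred}: degenerate (perfect) fit")
                continue
            term_names = {"sex": "sex", "x": pred, "sex:x": f"sex:{pred}"}
            for term in ("sex", "x", "sex:x"):
                t = float(model.tvalues[term])
                dof = int(model.df_resid)
                rows.append({
                    "feature": feat, "predictor": pred,
                    "term": term_names[term],
                    "estimate": float(model.params[term]), "t": t, "df": dof,
                    "p": float(model.pvalues[term]),
                    "r": cohens_r_from_t(t, dof), "n_obs": int(model.nobs),
                })
    grid = pd.DataFrame(rows)
    if not grid.empty:
        grid["p_adj"] = bh_adjust(grid["p"].to_numpy())
        grid["significant"] = grid["p_adj"] < alpha
    grid.attrs.update(alpha=alpha)
    return grid
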