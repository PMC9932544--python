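"""The statistical battery: F0-ratio tests, group comparisons, the mixed
ANOVA on log F0 amplitudes, brain-behavior correlations, and the
dummy-coded slope-contrast regressions with diagnostics.

Standard test internals (t, Mann-Whitney, Wilcoxon, Shapiro-Wilk,
Breusch-Pagan, Goldfeld-Quandt, OLS) are delegated to scipy/statsmodels;
this module owns the model structure, the log transform of F0 amplitudes,
Bonferroni bookkeeping, the slope-contrast algebra, and the split-plot
decomposition of the 2 x 2 x 2 (SNR x alpha x group) mixed design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RegressionModel",
    "f0_ratio_one_sample",
    "group_compare",
    "conover_posthoc",
    "mixed_anova_f0",
    "rm_anova_2x2",
    "brain_behavior_corr",
    "fit_group_regression",
    "bonferroni",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: float | tuple | None = None
    p_adj: float | None = None
    effect_size: float | None = None  # partial eta squared for ANOVA terms
    extra: dict = field(default_factory=dict)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


# --------------------------------------------------------------------------
# F0-ratio and group tests
# --------------------------------------------------------------------------

def f0_ratio_one_sample(ratios, name: str = "f0_ratio_vs_1") -> TestResult:
    """One-sample t of F0 ratios against 1 (no alpha modulation), two-sided."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 ratios")
    if np.ptp(ratios) == 0:
        raise ValueError("zero variance: one-sample t undefined")
    t, p = sps.ttest_1samp(ratios, popmean=1.0)
    return TestResult(name=name, statistic=float(t), p=float(p), df=ratios.size - 1)


def group_compare(
    x,
    y=None,
    test: str = "mann-whitney",
    n_comparisons: int = 1,
    name: str | None = None,
) -> TestResult:
    """Two-sample / paired comparison with Bonferroni bookkeeping.

    Supported: ``mann-whitney`` (independent), ``wilcoxon-paired``,
    ``welch-t``, ``equal-variance-F`` (two-sample variance ratio, two-
    sided), ``fisher-exact`` (x = 2x2 table).  Conover's post-hoc has its
    own entry point (:func:`conover_posthoc`).
    """
    x = np.asarray(x, dtype=float) if test != "fisher-exact" else np.asarray(x)
    if test == "mann-whitney":
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        df = None
    elif test == "wilcoxon-paired":
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            stat, p = 0.0, 1.0  # no-difference convention
        else:
            stat, p = sps.wilcoxon(x, y)
        df = None
    elif test == "welch-t":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        n1, n2 = len(x), len(y)
        v1, v2 = np.var(x, ddof=1) / n1, np.var(y, ddof=1) / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    elif test == "equal-variance-F":
        v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
        if v2 == 0:
            raise ValueError("zero variance in denominator sample")
        stat = v1 / v2
        df = (len(x) - 1, len(y) - 1)
        cdf = sps.f.cdf(stat, *df)
        p = 2 * min(cdf, 1 - cdf)
    elif test == "fisher-exact":
        stat, p = sps.fisher_exact(x)
        df = None
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        name=name or test,
        statistic=float(stat),
        p=float(p),
        df=df,
        p_adj=bonferroni(float(p), n_comparisons),
    )


def conover_posthoc(groups: list, labels: list | None = None) -> pd.DataFrame:
    """Conover-Iman pairwise rank test with Bonferroni adjustment.

    After ranking all observations jointly (average ranks for ties), the
    pairwise statistic is ``t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N - 1 - H)
    / (N - k) * (1/n_i + 1/n_j))`` with df = N - k, where H is the
    (tie-corrected) Kruskal-Wallis statistic and S^2 the variance of the
    ranks.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    labels = labels or [f"g{i}" for i in range(k)]
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    splits = np.split(ranks, np.cumsum(sizes)[:-1])
    rbar = np.array([s.mean() for s in splits])
    s2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4) / (N - 1)
    h = (np.sum(sizes * (rbar - (N + 1) / 2) ** 2)) / s2
    df = N - k
    scale = s2 * (N - 1 - h) / df
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
            t = (rbar[i] - rbar[j]) / se
            p = 2 * sps.t.sf(abs(t), df)
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "statistic": t,
                    "df": df,
                    "p": p,
                    "p_adj": bonferroni(p, m),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mixed ANOVA (split-plot): 2 within factors x 1 between factor
# --------------------------------------------------------------------------

def _effects_coded_tests(z: np.ndarray, is_g1: np.ndarray):
    """OLS of z on effects-coded group; returns (F_intercept, F_group, df_err).

    With +1/-1 coding the intercept estimates the unweighted mean of the
    two group means (Type-III-style for unbalanced n) and the group slope
    their half-difference.
    """
    z1, z0 = z[is_g1], z[~is_g1]
    n1, n0 = z1.size, z0.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 subjects per group")
    mu = (z1.mean() + z0.mean()) / 2
    gam = (z1.mean() - z0.mean()) / 2
    ss_err = np.sum((z1 - z1.mean()) ** 2) + np.sum((z0 - z0.mean()) ** 2)
    df_err = n1 + n0 - 2
    mse = ss_err / df_err
    var = mse * (1 / n1 + 1 / n0) / 4
    if var == 0:  # degenerate (constant) stratum
        f_int = 0.0 if mu == 0 else np.inf
        f_grp = 0.0 if gam == 0 else np.inf
        return f_int, f_grp, df_err
    return mu**2 / var, gam**2 / var, df_err


def _result(name, F, df_err):
    p = sps.f.sf(F, 1, df_err)
    return TestResult(
        name=name,
        statistic=float(F),
        p=float(p),
        df=(1, df_err),
        effect_size=float(F / (F + df_err)),
    )


def mixed_anova_f0(
    data: pd.DataFrame,
    dv: str = "log_f0",
    within: tuple[str, str] = ("snr", "alpha"),
    between: str = "group",
    subject: str = "participant",
) -> dict:
    """2 x 2 x 2 mixed ANOVA (two within factors, one between factor).

    Subjects are the random factor.  Exact classical split-plot F tests
    are computed from per-subject contrast scores (each within effect in a
    2-level design reduces to a one-degree contrast whose group-level OLS
    under effects coding yields the within effect as the intercept test
    and its group interaction as the slope test).  Effect sizes are
    partial eta squared.  F0 amplitudes should already be log-transformed.
    """
    lev = {f: sorted(data[f].unique()) for f in within}
    for f in within:
        if len(lev[f]) != 2:
            raise ValueError(f"within factor {f!r} must have 2 levels")
    wide = data.pivot_table(
        index=[subject, between], columns=list(within), values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        raise ValueError("missing cells in the factorial design")
    b, w = within
    y00 = wide[(lev[b][0], lev[w][0])].to_numpy()
    y01 = wide[(lev[b][0], lev[w][1])].to_numpy()
    y10 = wide[(lev[b][1], lev[w][0])].to_numpy()
    y11 = wide[(lev[b][1], lev[w][1])].to_numpy()
    groups = wide.index.get_level_values(between).to_numpy()
    glev = sorted(np.unique(groups))
    if len(glev) != 2:
        raise ValueError("between factor must have 2 levels")
    is_g1 = groups == glev[1]

    subj_mean = (y00 + y01 + y10 + y11) / 4
    c_b = (y00 + y01 - y10 - y11) / 2  # main effect of first within factor
    c_w = (y00 - y01 + y10 - y11) / 2  # second within factor
    c_bw = y00 - y01 - y10 + y11  # within-within interaction

    out = {}
    _, f_g, df_b = _effects_coded_tests(subj_mean, is_g1)
    out[between] = _result(between, f_g, df_b)
    for label, z in ((b, c_b), (w, c_w), (f"{b}:{w}", c_bw)):
        f_main, f_int, df_e = _effects_coded_tests(z, is_g1)
        out[label] = _result(label, f_main, df_e)
        out[f"{label}:{between}"] = _result(f"{label}:{between}", f_int, df_e)
    return out


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str = "log_f0",
    within: tuple[str, str] = ("snr", "alpha"),
    subject: str = "participant",
) -> dict:
    """Follow-up fully-within 2 x 2 repeated-measures ANOVA (one group)."""
    lev = {f: sorted(data[f].unique()) for f in within}
    wide = data.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing cells in the factorial design")
    b, w = within
    y00 = wide[(lev[b][0], lev[w][0])].to_numpy()
    y01 = wide[(lev[b][0], lev[w][1])].to_numpy()
    y10 = wide[(lev[b][1], lev[w][0])].to_numpy()
    y11 = wide[(lev[b][1], lev[w][1])].to_numpy()
    out = {}
    for label, z in (
        (b, (y00 + y01 - y10 - y11) / 2),
        (w, (y00 - y01 + y10 - y11) / 2),
        (f"{b}:{w}", y00 - y01 - y10 + y11),
    ):
        n = z.size
        if n < 2:
            raise ValueError("need >= 2 subjects")
        se = z.std(ddof=1) / np.sqrt(n)
        if se == 0:
            F = 0.0 if z.mean() == 0 else np.inf
        else:
            F = (z.mean() / se) ** 2
        out[label] = _result(label, F, n - 1)
    return out


# --------------------------------------------------------------------------
# brain-behavior correlations
# --------------------------------------------------------------------------

def brain_behavior_corr(
    frame: pd.DataFrame,
    brain_cols: list[str],
    behavior_cols: list[str],
) -> pd.DataFrame:
    """Spearman correlations between neural and behavioral measures.

    Rank correlation is used because behavior measures are typically
    non-normal; Shapiro-Wilk normality screens for every variable are
    attached as the rationale.
    """
    rows = []
    for bc in brain_cols:
        for hc in behavior_cols:
            sub = frame[[bc, hc]].dropna()
            if len(sub) < 4:
                raise ValueError(f"need >= 4 complete pairs for {bc} vs {hc}")
            x, y = sub[bc].to_numpy(), sub[hc].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"constant input in {bc} vs {hc}")
            rho, p = sps.spearmanr(x, y)
            rows.append(
                {
                    "brain": bc,
                    "behavior": hc,
                    "rho": float(rho),
                    "p": float(p),
                    "n": len(sub),
                    "shapiro_p_brain": float(sps.shapiro(x).pvalue),
                    "shapiro_p_behavior": float(sps.shapiro(y).pvalue),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# slope-contrast regressions
# --------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """Dummy-coded interaction regression Y ~ X * group (+ age).

    ``group`` is coded 0 (NH) / 1 (HL), so the NH slope is the X
    coefficient, the HL slope is X + X:group, and X:group is the slope
    difference between groups.  Interpretation is gated on the residual
    diagnostics (normality, homoscedasticity) passing.
    """

    formula_id: str  # "base" or "age_adjusted"
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    slope_nh: float
    slope_hl: float
    slope_hl_se: float
    slope_diff: float
    diagnostics: dict
    nobs: int

    @property
    def diagnostics_pass(self) -> bool:
        d = self.diagnostics
        return all(d[k] > 0.05 for k in ("shapiro_p", "breusch_pagan_p", "goldfeld_quandt_p"))


def fit_group_regression(y, x, group, age=None) -> RegressionModel:
    """OLS of Y on X, group (0 = NH, 1 = HL), X x group, and optionally age.

    Refuses single-group data (the interaction column would be collinear).
    Diagnostics: Shapiro-Wilk on residuals, Breusch-Pagan, and
    Goldfeld-Quandt split at the median of X with the middle 20% omitted.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan, het_goldfeldquandt

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    group = np.asarray(group, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group must be coded 0 (NH) / 1 (HL)")
    if np.unique(group).size < 2:
        raise ValueError("single-group data: interaction model not identifiable")
    cols = {"const": np.ones_like(x), "x": x, "group": group, "x:group": x * group}
    formula_id = "base"
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
        formula_id = "age_adjusted"
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()

    cov = fit.cov_params()
    slope_nh = float(fit.params["x"])
    slope_diff = float(fit.params["x:group"])
    slope_hl = slope_nh + slope_diff
    slope_hl_se = float(
        np.sqrt(cov.loc["x", "x"] + cov.loc["x:group", "x:group"] + 2 * cov.loc["x", "x:group"])
    )

    resid = fit.resid
    order = np.argsort(x, kind="stable")
    bp = het_breuschpagan(resid, X.to_numpy())
    gq = het_goldfeldquandt(y[order], X.to_numpy()[order], split=0.5, drop=0.2)
    diagnostics = {
        "shapiro_p": float(sps.shapiro(resid).pvalue),
        "breusch_pagan_p": float(bp[1]),
        "goldfeld_quandt_p": float(gq[1]),
        "resid_vs_fitted_slope": float(np.polyfit(fit.fittedvalues, resid, 1)[0]),
    }
    return RegressionModel(
        formula_id=formula_id,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        slope_nh=slope_nh,
        slope_hl=slope_hl,
        slope_hl_se=slope_hl_se,
        slope_diff=slope_diff,
        diagnostics=diagnostics,
        nobs=int(fit.nobs),
    )
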