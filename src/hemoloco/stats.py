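"""Group comparisons on per-event metric tables.

Implements the study's comparison layer: descriptive summaries (mean, SD, n),
Pearson correlations per vessel group, slope/intercept comparison between two
vessel groups by interaction regression, linear mixed models with a random
intercept per animal and Tukey-adjusted pairwise contrasts, and two-group
rank tests (Wilcoxon signed-rank for paired, Mann-Whitney for unpaired).

The mixed-model solver is standard machinery (statsmodels ``MixedLM``); this
module's contract is the surface: per-factor tests, estimated-marginal-mean
pairwise contrasts with studentized-range (Tukey) adjustment, and exact
agreement with an ordinary fixed-effects ANOVA when the random-effect
variance is forced to zero.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSpec",
    "MixedComparison",
    "SlopeComparison",
    "TwoGroupResult",
    "summarize",
    "correlate",
    "compare_slopes",
    "mixed_compare",
    "two_group_test",
    "normality_report",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare: response metric, fixed factors, random grouping."""

    response: str
    fixed: tuple[str, ...]
    random: str = "animal_id"
    pairwise: bool = True
    alpha: float = 0.05
    interaction: bool = True

    def __post_init__(self) -> None:
        if not self.fixed:
            raise ValueError("at least one fixed factor is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def formula(self) -> str:
        op = " * " if (self.interaction and len(self.fixed) > 1) else " + "
        return f"{self.response} ~ " + op.join(f"C({f})" for f in self.fixed)


@dataclass
class MixedComparison:
    """Fixed-effect tests and Tukey-adjusted pairwise contrasts."""

    factor_tests: pd.DataFrame  # term, statistic, df, p, test
    pairwise: pd.DataFrame  # factor, level_a, level_b, estimate, se, statistic, p_raw, p_tukey
    method: str  # 'mixedlm' | 'ols' | 'ols_fallback'
    converged: bool
    metadata: dict = field(default_factory=dict)


@dataclass
class SlopeComparison:
    """Per-group OLS fits and slope/intercept difference tests."""

    groups: tuple
    slopes: dict
    intercepts: dict
    slope_difference: float
    p_slope: float
    intercept_difference: float  # conditional on a common slope
    p_intercept: float
    n: dict


@dataclass
class TwoGroupResult:
    statistic: float
    pvalue: float
    method: str
    all_tied: bool = False


def summarize(table: pd.DataFrame, response: str, by) -> pd.DataFrame:
    """Arithmetic mean, sample SD (n−1 denominator) and n per group.

    Groups with a single observation get ``sd`` = NaN and are flagged in the
    ``sd_undefined`` column; empty groups are simply absent (logged).
    """
    if response not in table.columns:
        raise KeyError(f"response column {response!r} not in table")
    by = [by] if isinstance(by, str) else list(by)
    grouped = table.groupby(by, observed=True)[response]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd_undefined"] = out["n"] < 2
    n_levels = table[by].drop_duplicates().shape[0]
    if len(out) < n_levels:
        logger.warning("summarize: %d empty group(s) omitted", n_levels - len(out))
    return out


def correlate(
    table: pd.DataFrame,
    x: str = "locomotion_auc",
    y: str = "max_peak",
    by: str = "vessel",
) -> pd.DataFrame:
    """Pearson r and two-sided p between ``x`` and ``y``, per group."""
    rows = []
    for g, sub in table.groupby(by, observed=True):
        xs, ys = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 pairs")
        if np.std(xs) == 0 or np.std(ys) == 0:
            raise ValueError(f"zero variance in group {g!r}")
        r, p = sps.pearsonr(xs, ys)
        rows.append({by: g, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def compare_slopes(table: pd.DataFrame, x: str, y: str, group: str) -> SlopeComparison:
    """Compare the linear relation of ``y`` on ``x`` between two groups.

    Slope equality is the interaction term of ``y ~ x * group``; the intercept
    difference is the group term of the common-slope model ``y ~ x + group``.
    """
    levels = tuple(pd.unique(table[group]))
    if len(levels) != 2:
        raise ValueError("compare_slopes requires exactly two groups")
    per_slope, per_inter, per_n = {}, {}, {}
    for g, sub in table.groupby(group, observed=True):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        if np.std(sub[x].to_numpy(float)) == 0:
            raise ValueError(f"degenerate input: no variance in {x!r} for group {g!r}")
        fit = smf.ols(f"{y} ~ {x}", data=sub).fit()
        per_slope[g], per_inter[g] = float(fit.params[x]), float(fit.params["Intercept"])
        per_n[g] = len(sub)
    inter_fit = smf.ols(f"{y} ~ {x} * C({group})", data=table).fit()
    if inter_fit.df_resid < 1:
        raise ValueError("degenerate input: no residual degrees of freedom")
    iname = [c for c in inter_fit.params.index if ":" in c]
    slope_diff = float(inter_fit.params[iname[0]])
    p_slope = float(inter_fit.pvalues[iname[0]])
    common_fit = smf.ols(f"{y} ~ {x} + C({group})", data=table).fit()
    gname = [c for c in common_fit.params.index if c.startswith(f"C({group})")]
    int_diff = float(common_fit.params[gname[0]])
    p_int = float(common_fit.pvalues[gname[0]])
    if not (np.isfinite(p_slope) and np.isfinite(p_int)):
        raise ValueError("degenerate (collinear) input to slope comparison")
    return SlopeComparison(
        groups=levels,
        slopes=per_slope,
        intercepts=per_inter,
        slope_difference=slope_diff,
        p_slope=p_slope,
        intercept_difference=int_diff,
        p_intercept=p_int,
        n=per_n,
    )


def _tukey_p(stat: np.ndarray, k: int, df: float) -> np.ndarray:
    """Studentized-range (Tukey) p for a pairwise |t|-like statistic."""
    q = np.sqrt(2.0) * np.abs(stat)
    return np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0)


def _emmeans_contrasts(design_info, data, factor, fixed, beta, cov, df, k_is_t):
    """Pairwise contrasts of estimated marginal means for one factor.

    Marginal means are predictions averaged over the reference grid (the
    cartesian product of observed fixed-factor levels), the emmeans
    convention; differences between factor levels give contrast vectors.
    """
    levels = {f: list(pd.unique(data[f])) for f in fixed}
    grid = pd.DataFrame(
        list(itertools.product(*(levels[f] for f in fixed))), columns=list(fixed)
    )
    (dm,) = patsy.build_design_matrices([design_info], grid)
    dm = np.asarray(dm)
    rows = {}
    for lv in levels[factor]:
        sel = (grid[factor] == lv).to_numpy()
        rows[lv] = dm[sel].mean(axis=0)
    recs = []
    k = len(levels[factor])
    for a, b in itertools.combinations(levels[factor], 2):
        c = rows[a] - rows[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        stat = est / se if se > 0 else np.nan
        if k_is_t:
            p_raw = 2.0 * sps.t.sf(abs(stat), df)
        else:
            p_raw = 2.0 * sps.norm.sf(abs(stat))
        recs.append(
            dict(
                factor=factor,
                level_a=a,
                level_b=b,
                estimate=est,
                se=se,
                statistic=stat,
                p_raw=float(p_raw),
                p_tukey=float(_tukey_p(np.array(stat), k, df)),
            )
        )
    return recs


def mixed_compare(
    table: pd.DataFrame,
    spec: ComparisonSpec,
    random_variance_zero: bool = False,
) -> MixedComparison:
    """Fit the comparison model and return factor tests + pairwise contrasts.

    Default: linear mixed model with a random intercept per ``spec.random``
    (animal), Wald chi-square tests per fixed term, and pairwise contrasts of
    estimated marginal means with Tukey (studentized-range) adjustment using a
    residual-df approximation (method recorded in ``metadata``).

    ``random_variance_zero=True`` forces the random-effect variance to zero,
    i.e. fits the ordinary fixed-effects model; its per-term ANOVA F tests
    agree exactly with a standard fixed-effects ANOVA. The same path is used
    as a flagged fallback when the mixed model fails to converge.
    """
    if spec.response not in table.columns:
        raise KeyError(f"response {spec.response!r} not in table")
    for f in spec.fixed:
        if f not in table.columns:
            raise KeyError(f"fixed factor {f!r} not in table")
    data = table.dropna(subset=[spec.response, *spec.fixed]).copy()
    formula = spec.formula()

    method = "ols" if random_variance_zero else "mixedlm"
    converged = True
    res = None
    if not random_variance_zero:
        if data[spec.random].nunique() < 2:
            raise ValueError("random grouping needs >= 2 levels for model fitting")
        model = smf.mixedlm(formula, data=data, groups=data[spec.random])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method="lbfgs")
            converged = bool(getattr(res, "converged", True))
        except (np.linalg.LinAlgError, ValueError):
            converged = False
        if not converged or res is None or not np.all(np.isfinite(res.fe_params)):
            logger.warning("mixed model did not converge; falling back to fixed effects")
            method = "ols_fallback"
            converged = False

    if method == "mixedlm":
        design_info = res.model.data.design_info
        beta = np.asarray(res.fe_params)
        kfe = beta.size
        cov = np.asarray(res.cov_params())[:kfe, :kfe]
        df = float(len(data) - kfe)
        term_tests = []
        for term, sl in design_info.term_name_slices.items():
            if term == "Intercept":
                continue
            idx = np.arange(kfe)[sl]
            b = beta[idx]
            v = cov[np.ix_(idx, idx)]
            chi2 = float(b @ np.linalg.solve(v, b))
            term_tests.append(
                dict(term=term, statistic=chi2, df=len(idx),
                     p=float(sps.chi2.sf(chi2, len(idx))), test="wald_chi2")
            )
        factor_tests = pd.DataFrame(term_tests)
        k_is_t = False
    else:
        ols_res = smf.ols(formula, data=data).fit()
        res = ols_res
        design_info = ols_res.model.data.design_info
        beta = np.asarray(ols_res.params)
        cov = np.asarray(ols_res.cov_params())
        df = float(ols_res.df_resid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = anova_lm(ols_res, typ=2)
        term_tests = [
            dict(term=t, statistic=float(aov.loc[t, "F"]), df=int(aov.loc[t, "df"]),
                 p=float(aov.loc[t, "PR(>F)"]), test="anova_F")
            for t in aov.index
            if t != "Residual"
        ]
        factor_tests = pd.DataFrame(term_tests)
        k_is_t = True

    pairwise_rows = []
    if spec.pairwise:
        for f in spec.fixed:
            if data[f].nunique() < 2:
                continue
            pairwise_rows.extend(
                _emmeans_contrasts(design_info, data, f, spec.fixed, beta, cov, df, k_is_t)
            )
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=["factor", "level_a", "level_b", "estimate", "se", "statistic", "p_raw", "p_tukey"],
    )
    return MixedComparison(
        factor_tests=factor_tests,
        pairwise=pairwise,
        method=method,
        converged=converged,
        metadata={
            "formula": formula,
            "random": None if method != "mixedlm" else spec.random,
            "df_method": "residual-df approximation",
            "n": len(data),
        },
    )


def two_group_test(a, b, paired: bool = False) -> TwoGroupResult:
    """Two-sided rank-based two-group test.

    Wilcoxon signed-rank for paired samples, Mann-Whitney U for unpaired.
    Degenerate all-tied input (every paired difference zero, or both samples
    constant and equal) is flagged and reported with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return TwoGroupResult(np.nan, 1.0, "wilcoxon", all_tied=True)
        stat, p = sps.wilcoxon(a, b, alternative="two-sided")
        return TwoGroupResult(float(stat), float(p), "wilcoxon")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TwoGroupResult(np.nan, 1.0, "mannwhitney", all_tied=True)
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TwoGroupResult(float(stat), float(p), "mannwhitney")


def normality_report(a, b=None) -> dict:
    """Pre-check report: Shapiro-Wilk and Kolmogorov-Smirnov normality p-values
    per sample, plus a two-sided variance-ratio F test when two samples are given.

    This is reported, not branched on: the nonparametric tests above are the
    analysis path, and the choice is a caller decision.
    """
    def one(x):
        x = np.asarray(x, dtype=float)
        sh = sps.shapiro(x)
        ks = sps.kstest((x - x.mean()) / x.std(ddof=1), "norm")
        return {"shapiro_p": float(sh.pvalue), "ks_p": float(ks.pvalue), "n": x.size}

    report = {"sample_a": one(a)}
    if b is not None:
        report["sample_b"] = one(b)
        a_, b_ = np.asarray(a, float), np.asarray(b, float)
        f = np.var(a_, ddof=1) / np.var(b_, ddof=1)
        dfa, dfb = a_.size - 1, b_.size - 1
        p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
        report["variance_F"] = {"F": float(f), "p": float(min(p, 1.0))}
    return report
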