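"""Group-level inference for the attention-modulation analyses.

Covers the 2 x 2 within-subject ANOVA (hemisphere x rhythm predictability)
with omega-squared effect sizes, BIC-approximate Bayes factors,
nonparametric behavioral tests, one-tailed correlations, Huber robust
regression of error proportions on attention-modulation strength, and the
|z| > 3 outlier screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

# omega-squared interpretation bands
OMEGA2_BANDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


def omega2_label(omega2: float) -> str:
    """Verbal label: >0.14 large, 0.06-0.14 medium, 0.01-0.06 small."""
    v = max(float(omega2), 0.0)  # clipped for labeling only
    for threshold, label in OMEGA2_BANDS:
        if v > threshold:
            return label
    return "negligible"


@dataclass(frozen=True)
class EffectResult:
    effect: str
    F: float
    df: tuple
    p: float
    omega2: float  # may be slightly negative; reported raw

    @property
    def omega2_label(self) -> str:
        return omega2_label(self.omega2)


@dataclass
class AnovaResult:
    hemisphere: EffectResult
    predictability: EffectResult
    interaction: EffectResult

    def effects(self):
        return (self.hemisphere, self.predictability, self.interaction)


def rm_anova_2x2(values) -> AnovaResult:
    """2 x 2 repeated-measures ANOVA (classical within-subject SS).

    ``values``: array (n_subjects, 2, 2) of cell means, axis 1 = hemisphere
    (left, right), axis 2 = predictability (high, low). Omega squared per
    effect uses df_eff*(MS_eff - MS_err)/(SS_total + MS_subjects).
    """
    y = np.asarray(values, float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("need a complete n x 2 x 2 within-subject design")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a = y.mean(axis=(0, 2))  # hemisphere means
    b = y.mean(axis=(0, 1))  # predictability means
    ab = y.mean(axis=0)

    ss_subj = 4 * np.sum((subj - grand) ** 2)
    ss_a = 2 * n * np.sum((a - grand) ** 2)
    ss_b = 2 * n * np.sum((b - grand) ** 2)
    ss_ab = n * np.sum(
        (ab - a[:, None] - b[None, :] + grand) ** 2
    )
    # subject x effect interaction (error) terms
    sa = y.mean(axis=2)  # subject x hemisphere
    sb = y.mean(axis=1)  # subject x predictability
    ss_as = 2 * np.sum((sa - subj[:, None] - a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((sb - subj[:, None] - b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    df_eff = 1
    df_err = n - 1
    ms_subj = ss_subj / (n - 1)

    def effect(name, ss_eff, ss_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        omega2 = (df_eff * (ms_eff - ms_err)) / (ss_total + ms_subj)
        return EffectResult(effect=name, F=float(F), df=(df_eff, df_err),
                            p=p, omega2=float(omega2))

    return AnovaResult(
        hemisphere=effect("hemisphere", ss_a, ss_as),
        predictability=effect("predictability", ss_b, ss_bs),
        interaction=effect("interaction", ss_ab, ss_abs),
    )


# ---------------------------------------------------------------------------
# Bayes factors

BF_BANDS = (
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
    (1 / 3.0, "anecdotal"),
    (0.10, "moderate"),
    (0.0, "strong"),
)


def bf_label(bf10: float) -> str:
    """Evidence label; bands partition (0, inf): 0.33-3 anecdotal,
    3-10 / 0.10-0.33 moderate, >10 / <0.10 strong."""
    for threshold, label in BF_BANDS:
        if bf10 > threshold:
            return label
    return "strong"


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    comparison: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def label(self) -> str:
        return bf_label(self.bf10)


def bf_bic_approx(bic_with: float, bic_without: float,
                  comparison: str = "H1 vs H0") -> BayesFactorResult:
    """BIC-approximate Bayes factor: BF10 = exp((BIC_without - BIC_with)/2).

    'with' is the richer model (e.g. including the interaction term),
    'without' the null/main-effects-only model fitted on the same data.
    The approximation is prior-free and will not match default-prior ANOVA
    Bayes factors numerically; labels follow the printed evidence bands.
    """
    bf10 = math.exp((bic_without - bic_with) / 2.0)
    return BayesFactorResult(bf10=bf10, comparison=comparison)


def anova_interaction_bf(values) -> BayesFactorResult:
    """BF for the interaction model vs main-effects-only (BIC approximation).

    Fits the two fixed-effect OLS models with subject dummies on the long
    form of the 2 x 2 table and compares their BICs.
    """
    import pandas as pd
    import statsmodels.formula.api as smf

    y = np.asarray(values, float)
    n = y.shape[0]
    rows = []
    for s in range(n):
        for i, hemi in enumerate(("left", "right")):
            for j, pred in enumerate(("high", "low")):
                rows.append((f"s{s}", hemi, pred, y[s, i, j]))
    df = pd.DataFrame(rows, columns=["subject", "hemi", "pred", "value"])
    full = smf.ols("value ~ C(subject) + C(hemi) * C(pred)", df).fit()
    main = smf.ols("value ~ C(subject) + C(hemi) + C(pred)", df).fit()
    return bf_bic_approx(full.bic, main.bic,
                         comparison="interaction vs main effects (BIC approx)")


# ---------------------------------------------------------------------------
# nonparametric behavioral tests

def friedman_test(values) -> tuple:
    """Friedman test over subject x condition (>= 3 conditions).

    Returns (chi2, df, p)."""
    y = np.asarray(values, float)
    if y.ndim != 2 or y.shape[1] < 3:
        raise ValueError("need subject x >=3 conditions")
    if np.ptp(y, axis=1).max() == 0:
        return 0.0, y.shape[1] - 1, 1.0
    chi2, p = sps.friedmanchisquare(*(y[:, j] for j in range(y.shape[1])))
    return float(chi2), y.shape[1] - 1, float(p)


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> tuple:
    """Wilcoxon signed-rank test on paired data; returns (W, Z, p).

    Z is the normal-approximation statistic (sign carries the direction of
    x - y); p comes from scipy (exact for small samples without ties when
    method permits).
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    res = sps.wilcoxon(d, method=method)
    n = int(np.sum(d != 0))
    mu = n * (n + 1) / 4
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    w_plus = float(np.sum(sps.rankdata(np.abs(d[d != 0]))[d[d != 0] > 0]))
    z = (w_plus - mu) / sigma if sigma > 0 else 0.0
    return float(res.statistic), float(z), float(res.pvalue)


def paired_t(x, y) -> tuple:
    """Paired t test; returns (t, df, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# association analyses

def correlate(x, y, method: str = "pearson", tail: str = "two-sided") -> tuple:
    """Pearson or Spearman correlation with a one- or two-tailed p.

    ``tail``: 'two-sided', 'greater' (positive association) or 'less'.
    Returns (r, p); zero-variance input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input: correlation undefined",
                      RuntimeWarning)
        return float("nan"), float("nan")
    if method == "pearson":
        res = sps.pearsonr(x, y, alternative=tail)
    elif method == "spearman":
        res = sps.spearmanr(x, y, alternative=tail)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RobustFit:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple
    p: float
    converged: bool


def robust_regression(x, y) -> RobustFit:
    """Huber-loss linear regression of y on x (IRLS via statsmodels RLM).

    R^2 is computed from the final Huber weights (weighted SSR over
    weighted SST); F = R^2 (n - 2) / (1 - R^2) with df (1, n - 2).
    """
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5:
        raise ValueError("need n >= 5")
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    converged = bool(np.all(np.isfinite(fit.params)))
    w = fit.weights
    resid = y - fit.fittedvalues
    ybar = np.average(y, weights=w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    ssr = float(np.sum(w * resid**2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    n = len(x)
    F = r2 * (n - 2) / (1 - r2) if r2 < 1 else float("inf")
    p = float(sps.f.sf(F, 1, n - 2))
    return RobustFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(r2),
        F=float(F),
        df=(1, n - 2),
        p=p,
        converged=converged,
    )


def zscore_outlier_screen(values, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of retained subjects (|z| <= threshold).

    z-scores use the full-sample mean and SD; zero SD excludes nobody.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError("need n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.ones(len(v), bool)
    z = (v - v.mean()) / sd
    return np.abs(z) <= threshold


def attention_modulation_strength(ami_left_roi, ami_right_roi) -> float:
    """Mean left-ROI AMI minus mean right-ROI AMI (per subject scalar)."""
    return float(np.mean(ami_left_roi) - np.mean(ami_right_roi))
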