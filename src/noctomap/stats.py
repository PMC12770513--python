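"""Statistical layer: paired comparisons and random-intercept mixed models.

Pairwise comparisons are routed by a Shapiro-Wilk normality test of the
paired differences (alpha = 0.05): normal differences go to a paired t-test,
non-normal ones to a Wilcoxon signed-rank test.

The relationships between movement magnitude, HR peak and PWA trough are
modelled with linear mixed-effects models

    y_ij = beta0 + beta1 * x_ij + u_j + eps_ij,   u_j ~ N(0, var_subject),

with subject-specific random intercepts u_j; beta1 is tested with a z-test.
Marginal (pooled Pearson) correlations and per-subject correlations are
reported alongside, since both views are informative at small N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

SHAPIRO_ALPHA = 0.05


class PairedTestKind(str, Enum):
    PAIRED_T = "paired_t"
    WILCOXON = "wilcoxon_signed_rank"


@dataclass
class PairedTestResult:
    test_used: PairedTestKind
    statistic: float
    p: float
    n: int
    shapiro_p: float


@dataclass
class MixedModelFit:
    beta0: float
    beta1: float
    se_beta1: float
    z: float
    p: float
    var_subject: float
    var_resid: float
    n_obs: int
    n_subjects: int
    marginal_r: float
    marginal_r_p: float


def paired_compare(x, y, alpha: float = SHAPIRO_ALPHA) -> PairedTestResult:
    """Normality-routed paired comparison of two matched samples.

    Differences passing Shapiro-Wilk at ``alpha`` use a paired t-test,
    otherwise a Wilcoxon signed-rank test. All-zero differences are a
    degenerate null case reported as p = 1 under the t route.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return PairedTestResult(PairedTestKind.PAIRED_T, 0.0, 1.0, n, 1.0)
    if np.ptp(d) == 0:
        # constant nonzero difference: Shapiro undefined; treat as normal
        sw_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_p = float(sps.shapiro(d).pvalue)
    if sw_p >= alpha:
        if np.ptp(d) == 0:
            # zero-variance nonzero shift: t statistic is infinite
            return PairedTestResult(PairedTestKind.PAIRED_T, np.inf, 0.0, n, sw_p)
        res = sps.ttest_rel(x, y)
        return PairedTestResult(PairedTestKind.PAIRED_T,
                                float(res.statistic), float(res.pvalue), n, sw_p)
    res = sps.wilcoxon(x, y)
    return PairedTestResult(PairedTestKind.WILCOXON,
                            float(res.statistic), float(res.pvalue), n, sw_p)


def fit_random_intercept(y, x, subject_ids,
                         force_zero_var: bool = False,
                         reml: bool = False) -> MixedModelFit:
    """Fit ``y = beta0 + beta1*x + u_subject + eps`` by maximum likelihood.

    With ``force_zero_var`` the random-intercept variance is pinned at zero,
    in which case the fit reduces exactly to ordinary least squares — a
    useful limit-case check. The slope is tested with a z-test
    (z = beta1/se, normal reference), and the pooled Pearson correlation
    between x and y is reported as ``marginal_r``.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    subject_ids = np.asarray(subject_ids)
    if not (y.size == x.size == subject_ids.size):
        raise ValueError("y, x, subject_ids must align")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant predictor")
    n_subj = np.unique(subject_ids).size
    if n_subj < 2 and not force_zero_var:
        raise ValueError("need at least 2 subjects for a random intercept")
    r, r_p = sps.pearsonr(x, y)
    X = sm.add_constant(x)
    if force_zero_var:
        ols = sm.OLS(y, X).fit()
        beta0, beta1 = ols.params
        se = ols.bse[1]
        z = beta1 / se
        return MixedModelFit(float(beta0), float(beta1), float(se), float(z),
                             float(2 * sps.norm.sf(abs(z))), 0.0,
                             float(ols.scale), y.size, n_subj,
                             float(r), float(r_p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=subject_ids)
        fit = model.fit(reml=reml)
    beta0, beta1 = fit.fe_params
    se = fit.bse_fe[1]
    z = beta1 / se
    p = float(2 * sps.norm.sf(abs(z)))
    var_subject = float(np.asarray(fit.cov_re).ravel()[0])
    return MixedModelFit(float(beta0), float(beta1), float(se), float(z), p,
                         var_subject, float(fit.scale), y.size, n_subj,
                         float(r), float(r_p))


def per_subject_correlations(df: pd.DataFrame, xcol: str, ycol: str,
                             subject_col: str = "subject",
                             alpha: float = 0.05,
                             min_n: int = 3) -> pd.DataFrame:
    """Pearson r per subject with a significance flag."""
    rows = []
    for s, g in df.groupby(subject_col):
        if len(g) < min_n or g[xcol].nunique() < 2 or g[ycol].nunique() < 2:
            continue
        r, p = sps.pearsonr(g[xcol], g[ycol])
        rows.append({"subject": s, "r": r, "p": p, "n": len(g),
                     "significant": p < alpha})
    return pd.DataFrame(rows)


#: model pairs reported per category/state: (x, y, short name)
MODEL_PAIRS = [
    ("magnitude_mg", "hr_peak_pct", "hr_peak~magnitude"),
    ("magnitude_mg", "pwa_trough_pct", "pwa_trough~magnitude"),
    ("hr_peak_pct", "pwa_trough_pct", "pwa_trough~hr_peak"),
]


def correlation_report(events: pd.DataFrame,
                       by: tuple[str, ...] = ("category", "state"),
                       subject_col: str = "subject",
                       min_events: int = 3) -> pd.DataFrame:
    """Mixed-model fits and correlations per movement stratum.

    ``events`` needs columns ``subject``, ``magnitude_mg``, ``hr_peak_pct``,
    ``pwa_trough_pct`` plus the stratification columns. Emits, per stratum
    and model pair, beta1 with its z-test, the marginal Pearson r, and the
    number of subjects with an individually significant correlation. Strata
    with fewer than ``min_events`` events are skipped.
    """
    rows = []
    groups = [("all", events)] if not by else list(events.groupby(list(by)))
    for key, g in groups:
        if len(g) < min_events:
            continue
        for xcol, ycol, name in MODEL_PAIRS:
            sub = g.dropna(subset=[xcol, ycol])
            if len(sub) < min_events or sub[xcol].nunique() < 2:
                continue
            n_subj = sub[subject_col].nunique()
            try:
                if n_subj >= 2:
                    fit = fit_random_intercept(sub[ycol], sub[xcol],
                                               sub[subject_col])
                else:
                    fit = fit_random_intercept(sub[ycol], sub[xcol],
                                               sub[subject_col],
                                               force_zero_var=True)
            except (ValueError, np.linalg.LinAlgError):
                continue
            per_subj = per_subject_correlations(sub, xcol, ycol, subject_col)
            rows.append({
                "stratum": key if isinstance(key, str) else "/".join(map(str, key)),
                "pair": name,
                "beta1": fit.beta1, "se_beta1": fit.se_beta1,
                "z": fit.z, "p": fit.p,
                "var_subject": fit.var_subject, "var_resid": fit.var_resid,
                "r": fit.marginal_r, "r_p": fit.marginal_r_p,
                "n_events": len(sub), "n_subjects": n_subj,
                "n_subjects_significant": int(per_subj["significant"].sum())
                if len(per_subj) else 0,
            })
    return pd.DataFrame(rows)
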