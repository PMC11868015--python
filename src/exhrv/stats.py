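"""Group-comparison statistics.

Continuous variables are summarised as median (25th-75th percentile) and
compared between the CAC+ and CAC- groups with the two-sided Mann-Whitney
test; the reported U is the first (CAC-) sample's statistic, i.e. its rank
sum minus n1(n1+1)/2 with midranks for ties. Small tie-free samples
(n1 + n2 <= 16) use the exact null distribution; larger or tied samples use
the normal approximation with tie and continuity corrections. Categorical
variables use the chi-square test with Yates continuity correction.
Significance is two-tailed at alpha = 0.05 with no multiple-testing
correction.

Multivariable logistic regression (binary CAC status as outcome) is fitted
by unpenalised maximum likelihood; effects are reported per unit of the
untransformed predictor as odds ratios with Wald 95% confidence intervals
exp(beta +/- 1.96 SE).

Walker detection classifies a subject as having dismounted on the climb
when power output is zero (or, lacking a power meter, speed is below a
walking threshold) for a sustained contiguous fraction of the climb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import logger

ALPHA = 0.05
EXACT_MAX_N = 16
WALK_SPEED_MPS = 1.8
WALK_FRAC = 0.20


@dataclass
class GroupComparison:
    variable: str
    median1: float
    q25_1: float
    q75_1: float
    median2: float
    q25_2: float
    q75_2: float
    n1: int
    n2: int
    U: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class LogisticFit:
    predictors: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    odds_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    converged: bool
    n: int
    separated: list[str] = field(default_factory=list)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q25, q75) with linear-interpolation quantiles."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("median_iqr needs at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return float(med), float(q25), float(q75)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of the first sample, p).

    Exact p for tie-free samples with n1 + n2 <= 16, otherwise the normal
    approximation with tie correction and 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across both samples; p = 1")
        return x.size * y.size / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and x.size + y.size <= EXACT_MAX_N) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square(table) -> tuple[float, float]:
    """Chi-square test with Yates continuity correction on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(df: pd.DataFrame, variable: str,
                   group_col: str = "group",
                   groups: tuple[str, str] = ("CAC-", "CAC+")) -> GroupComparison:
    """Median(IQR) per group plus Mann-Whitney U and p for one variable."""
    x = df.loc[df[group_col] == groups[0], variable].dropna().to_numpy(float)
    y = df.loc[df[group_col] == groups[1], variable].dropna().to_numpy(float)
    m1, a1, b1 = median_iqr(x)
    m2, a2, b2 = median_iqr(y)
    U, p = mann_whitney(x, y)
    return GroupComparison(variable=variable, median1=m1, q25_1=a1, q75_1=b1,
                           median2=m2, q25_2=a2, q75_2=b2,
                           n1=x.size, n2=y.size, U=U, p=p)


def logistic_regression(X: pd.DataFrame, y) -> LogisticFit:
    """Unpenalised ML logistic fit with Wald odds ratios and 95% CIs.

    Rows with any missing predictor are dropped (complete-case analysis).
    Predictors with quasi-complete separation are flagged and their odds
    ratios suppressed.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X, index=pd.RangeIndex(len(y))).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    keep = ~X.isna().any(axis=1) if X.shape[1] else pd.Series(True, index=X.index)
    X, y = X.loc[keep], y[np.asarray(keep)]
    n = len(X)
    if X.shape[1] and n <= 10 * X.shape[1]:
        logger.warning("n = %d for %d predictors: below the 10:1 heuristic",
                       n, X.shape[1])
    names = list(X.columns)
    # complete separation makes the likelihood unbounded and the fit fail;
    # flag the offending predictors and fit the rest
    separated = []
    for k in names:
        v0, v1 = X.loc[y == 0, k], X.loc[y == 1, k]
        if len(v0) and len(v1) and (v0.max() < v1.min() or v1.max() < v0.min()):
            separated.append(k)
    if separated:
        logger.warning("perfect separation for predictor(s): %s; "
                       "odds ratios suppressed", separated)
    design = sm.add_constant(X.drop(columns=separated), has_constant="add")
    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    coef = {k: float(fit.params[k]) for k in design.columns}
    se = {k: float(fit.bse[k]) for k in design.columns}
    for k in names:
        quasi = k in design.columns and (se.get(k, 0) > 50.0
                                         or abs(coef.get(k, 0)) > 25.0)
        if quasi and k not in separated:
            separated.append(k)
            logger.warning("quasi-separation suspected for %s", k)
    coef.update({k: float("nan") for k in separated})
    se.update({k: float("nan") for k in separated})
    fitted = {
        "odds_ratio": {}, "ci_low": {}, "ci_high": {}, "p": {},
    }
    for k in names:
        if k in separated:
            fitted["odds_ratio"][k] = np.nan
            fitted["ci_low"][k] = np.nan
            fitted["ci_high"][k] = np.nan
            fitted["p"][k] = np.nan
            continue
        fitted["odds_ratio"][k] = float(np.exp(coef[k]))
        fitted["ci_low"][k] = float(np.exp(coef[k] - 1.959963984540054 * se[k]))
        fitted["ci_high"][k] = float(np.exp(coef[k] + 1.959963984540054 * se[k]))
        fitted["p"][k] = float(fit.pvalues[k])
    return LogisticFit(
        predictors=names, coef=coef, se=se,
        odds_ratio=fitted["odds_ratio"], ci_low=fitted["ci_low"],
        ci_high=fitted["ci_high"], p=fitted["p"],
        converged=bool(fit.mle_retvals.get("converged", True)), n=n,
        separated=separated,
    )


def detect_walkers(hill_t0: float, hill_t1: float,
                   power: pd.DataFrame | None,
                   walk_frac: float = WALK_FRAC,
                   speed_threshold: float = WALK_SPEED_MPS) -> bool | None:
    """Did the subject dismount and walk part of the climb?

    Walker iff power <= 0 W for a contiguous stretch of at least
    ``walk_frac`` of the climb duration; without a power channel, iff speed
    stays below ``speed_threshold`` for the same stretch. Returns None (and
    logs) when neither channel is present.
    """
    if power is None or power.empty:
        logger.warning("no power/speed channel: walker status undetermined")
        return None
    sel = (power["t_s"] >= hill_t0) & (power["t_s"] < hill_t1)
    seg = power.loc[sel]
    if seg.empty:
        logger.warning("no samples on the climb: walker status undetermined")
        return None
    if "watts" in seg.columns and seg["watts"].notna().any():
        low = (seg["watts"].to_numpy(float) <= 0.0)
    elif "speed_mps" in seg.columns:
        low = (seg["speed_mps"].to_numpy(float) < speed_threshold)
    else:
        logger.warning("neither power nor speed present")
        return None
    need = walk_frac * (hill_t1 - hill_t0)
    dt = np.median(np.diff(seg["t_s"].to_numpy(float))) if len(seg) > 1 else 1.0
    run = best = 0
    for flag in low:
        run = run + 1 if flag else 0
        best = max(best, run)
    return bool(best * dt >= need)


__all__ = [
    "GroupComparison", "LogisticFit", "median_iqr", "mann_whitney",
    "chi_square", "compare_groups", "logistic_regression", "detect_walkers",
    "ALPHA",
]
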