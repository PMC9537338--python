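"""Association statistics and formula-level utilities.

Simple linear regression (closed-form OLS with a two-sided t test on the
slope), one-way ANOVA with Tukey HSD post hoc comparisons (Tukey–Kramer for
unequal group sizes, studentized-range p-values), Welch's two-sided t test,
the delta-delta-Ct qPCR fold-change, and the nuclear-localization
percentage used for quantifying SMAD nuclear translocation in vessel
images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "AnovaTukeyResult",
    "ols_simple",
    "anova_tukey",
    "welch_t",
    "ddct_fold_change",
    "nuclear_localization",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    t_statistic: float
    p_value: float
    n: int


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    group_means: dict
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, q_statistic, p_adj


def ols_simple(x, y) -> RegressionResult:
    """Simple least-squares regression of y on x with a two-sided slope test.

    The p-value uses t = slope / se with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x has zero variance")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    se = np.sqrt(rss / (n - 2) / sxx) if n > 2 else np.nan
    if se == 0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return RegressionResult(float(slope), float(intercept), float(r2),
                            float(se), float(t), float(p), int(n))


def anova_tukey(groups, alpha: float = 0.05, labels=None) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey HSD post hoc comparisons.

    Pairwise adjusted p-values come from the studentized-range distribution
    with pooled within-group variance; unequal group sizes use the
    Tukey–Kramer standard error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    k = len(arrays)
    ns = np.array([g.size for g in arrays])
    N = int(ns.sum())
    means = np.array([g.mean() for g in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    df_b, df_w = k - 1, N - k
    msw = ssw / df_w
    if msw == 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / df_b) / msw
        p = float(sps.f.sf(f, df_b, df_w))

    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        if msw == 0:
            q_stat = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q_stat = abs(diff) / se
            p_adj = float(np.clip(sps.studentized_range.sf(q_stat, k, df_w), 0.0, 1.0))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "mean_diff": float(diff), "q_statistic": float(q_stat),
                     "p_adj": p_adj})
    return AnovaTukeyResult(
        f_statistic=float(f),
        p_value=float(p),
        group_means=dict(zip(labels, means.tolist())),
        tukey=pd.DataFrame(rows),
    )


def welch_t(a, b):
    """Welch's two-sided t test with Satterthwaite degrees of freedom.

    Zero-variance inputs get a variance floor of 1e-12 (with a warning)
    instead of producing NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 or vb <= 0:
        warnings.warn("zero-variance sample; flooring variance at 1e-12")
        va, vb = max(va, _VAR_FLOOR), max(vb, _VAR_FLOOR)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def ddct_fold_change(ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
    """Relative qPCR quantification by the delta-delta-Ct method.

    ddCt = (Ct_target,treated - Ct_ref,treated) - (Ct_target,control -
    Ct_ref,control); fold-change = 2**(-ddCt).
    """
    cts = np.asarray([ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control],
                     dtype=float)
    if not np.all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))


def nuclear_localization(image, nuclear_mask, vessel_mask) -> float:
    """Percent of vessel fluorescence located in nuclei.

    100 * sum(image over nuclear_mask) / sum(image over vessel_mask); the
    nuclear mask must be contained in the vessel mask and the vessel must
    carry positive total intensity.
    """
    image = np.asarray(image, dtype=float)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if image.shape != nuclear_mask.shape or image.shape != vessel_mask.shape:
        raise ValueError("image and masks must share a shape")
    if np.any(nuclear_mask & ~vessel_mask):
        raise ValueError("nuclear_mask must be contained in vessel_mask")
    total = float(image[vessel_mask].sum())
    if total <= 0:
        raise ValueError("total vessel intensity must be > 0")
    return 100.0 * float(image[nuclear_mask].sum()) / total
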