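"""Covariate adjustment, case-control maps, and demographic statistics.

Regional similarity strengths are adjusted for sex, age and total
intracranial volume by an ordinary least-squares model fit per region::

    strength_i = intercept + b1 * sex + b2 * age + b3 * TIV

with the adjusted value defined as residual + intercept so that group means
stay on the original scale (the t statistics are unaffected by the
constant).  Case-control contrasts are two-sample t-tests (case minus
control) with Bonferroni control across regions or networks; demographic
comparisons use pooled-variance t (from summary statistics), chi-square on
2x2 tables without continuity correction, and Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjustmentModel",
    "TMap",
    "TrajectoryFit",
    "adjust_covariates",
    "group_ttest",
    "chi_square_2x2",
    "two_sample_t_summary",
    "mann_whitney",
    "clinical_corr_map",
    "quadratic_trajectory",
    "bh_fdr",
]

_COVARIATE_COLS = ("sex", "age", "tiv")


@dataclass
class AdjustmentModel:
    intercept: np.ndarray        # per-region
    coef: np.ndarray             # per-region x (sex, age, tiv)
    residuals: np.ndarray        # subject x region


@dataclass
class TMap:
    t: np.ndarray
    p: np.ndarray
    corrected_significant: np.ndarray
    df: int
    contrast: str = "case - control"
    alpha: float = 0.05
    m: int = 0


@dataclass
class TrajectoryFit:
    coef: np.ndarray             # (b0, b1, b2) for 1, age, age^2
    pvalues: np.ndarray


def adjust_covariates(values: np.ndarray, covariates: pd.DataFrame):
    """Residualize subject x region values on sex, age and TIV.

    Returns (adjusted values, AdjustmentModel).  Raises on a rank-deficient
    design, naming the offending column.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    # covariates are centred so the intercept is the grand mean and
    # "residual + intercept" stays on the original strength scale;
    # centring changes neither residuals nor downstream t statistics
    cols = [covariates[c].to_numpy(dtype=float) for c in _COVARIATE_COLS]
    design = np.column_stack([np.ones(len(v))] + [c - c.mean() for c in cols])
    for j, c in enumerate(_COVARIATE_COLS, start=1):
        if np.std(design[:, j]) == 0:
            raise ValueError(f"covariate column {c!r} is constant (rank-deficient design)")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ beta
    adjusted = resid + beta[0]
    model = AdjustmentModel(intercept=beta[0], coef=beta[1:].T, residuals=resid)
    return adjusted, model


def group_ttest(adjusted: np.ndarray, groups: np.ndarray, alpha: float = 0.05,
                m: int | None = None, welch: bool = False) -> TMap:
    """Per-region two-sample t-test, case (+1) minus control (-1).

    ``groups`` is per-subject: -1 control, +1 case, 0 excluded.  Bonferroni
    significance is flagged at alpha / m where m defaults to the number of
    regions tested.
    """
    x = np.asarray(adjusted, dtype=float)
    g = np.asarray(groups)
    case, ctrl = x[g == 1], x[g == -1]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 subjects per group")
    res = stats.ttest_ind(case, ctrl, axis=0, equal_var=not welch)
    t = np.atleast_1d(res.statistic)
    p = np.atleast_1d(res.pvalue)
    df = len(case) + len(ctrl) - 2
    m_eff = m if m is not None else t.size
    bad = ~np.isfinite(t)
    if np.any(bad):
        p = p.copy()
        p[bad] = np.nan
    sig = np.where(np.isfinite(p), p <= alpha / m_eff, False)
    return TMap(t=t, p=p, corrected_significant=sig, df=df,
                alpha=alpha, m=m_eff)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def two_sample_t_summary(m1, s1, n1, m2, s2, n2, welch: bool = False):
    """Two-sample t-test from group summary statistics.

    Pooled-variance Student t by default (df = n1 + n2 - 2); Welch by flag.
    Returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, n1 + n2 - 2, 1.0
        return float(np.inf) * np.sign(m1 - m2), n1 + n2 - 2, 0.0
    if welch:
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        return float(res.statistic), float(df), float(res.pvalue)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U (pairs with x > y, + half ties), tie-corrected z, p.

    The p-value is exact for small tie-free samples, otherwise from the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    u = float(res.statistic)
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (u - n1 * n2 / 2.0) / np.sqrt(var_u) if var_u > 0 else 0.0
    return u, float(z), float(res.pvalue)


def clinical_corr_map(strengths: np.ndarray, score: np.ndarray,
                      alpha: float = 0.05):
    """Per-region Pearson correlation with a clinical score, BH-FDR across regions.

    Subjects with a missing score are dropped pairwise.  Returns a DataFrame
    with r, p, p_fdr and an FDR-significance flag.
    """
    x = np.asarray(strengths, dtype=float)
    s = np.asarray(score, dtype=float)
    keep = np.isfinite(s)
    x, s = x[keep], s[keep]
    if s.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(s) == 0:
        raise ValueError("clinical score is constant")
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (sc ** 2).sum())
    r = np.where(denom > 0, xc.T @ sc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    dfree = s.size - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(dfree / np.clip(1 - r ** 2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), dfree)
    p_fdr = bh_fdr(p)
    return pd.DataFrame({"r": r, "p": p, "p_fdr": p_fdr,
                         "significant": p_fdr < alpha})


def quadratic_trajectory(strength, age) -> TrajectoryFit:
    """OLS fit of strength ~ 1 + age + age^2 (ageing trajectory)."""
    yv = np.asarray(strength, dtype=float)
    a = np.asarray(age, dtype=float)
    if yv.size < 4:
        raise ValueError("need at least 4 subjects")
    if np.unique(a).size <= 3:
        raise ValueError("need more than 3 distinct ages for a quadratic fit")
    import statsmodels.api as sm
    design = sm.add_constant(np.column_stack([a, a ** 2]))
    fit = sm.OLS(yv, design).fit()
    return TrajectoryFit(coef=np.asarray(fit.params), pvalues=np.asarray(fit.pvalues))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def demographics_report(covariates: pd.DataFrame, labels: np.ndarray) -> dict:
    """Pairwise group comparisons of the standard demographic/clinical columns.

    ``labels``: 0 = control, 1, 2 = subtypes.  Age and the clinical scores
    use pooled t-tests or Mann-Whitney (both reported); sex uses chi-square.
    """
    out = {}
    pairs = [(0, 1), (0, 2), (1, 2)]
    for a, b in pairs:
        key = f"{a}v{b}"
        ga = covariates[labels == a]
        gb = covariates[labels == b]
        entry = {}
        tab = np.array([
            [int((ga["sex"] == 1).sum()), int((ga["sex"] == 0).sum())],
            [int((gb["sex"] == 1).sum()), int((gb["sex"] == 0).sum())],
        ])
        if tab.sum(axis=0).min() > 0 and tab.sum(axis=1).min() > 0:
            chi2, p = chi_square_2x2(tab)
            entry["sex"] = {"chi2": chi2, "p": p}
        for col in ("age", "moca", "updrs_iii", "hy", "ledd", "duration"):
            if col not in covariates:
                continue
            xa = ga[col].dropna().to_numpy()
            xb = gb[col].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, df, p = two_sample_t_summary(xa.mean(), xa.std(ddof=1), len(xa),
                                            xb.mean(), xb.std(ddof=1), len(xb))
            u, z, pu = mann_whitney(xa, xb)
            entry[col] = {"t": t, "p_t": p, "u": u, "p_u": pu}
        out[key] = entry
    return out
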