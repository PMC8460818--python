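"""Nonparametric statistics, FDR control, effect sizes and survival.

Conventions used throughout:

* all tests are two-sided;
* mid-ranks handle ties; the Mann-Whitney U reported is the U of the
  first group, the Wilcoxon statistic is the smaller of the two
  signed-rank sums;
* exact p-values by enumeration for small samples (Mann-Whitney and
  Wilcoxon up to a combined/paired n of 12 when ties permit, Spearman up
  to n = 7 by full permutation), normal/chi-square approximations with
  tie corrections otherwise — the method actually used is recorded in
  the result;
* multiplicity is controlled per test family with the Benjamini-
  Hochberg step-up at q = 0.05, reporting both the reject/retain
  decision and the BH-adjusted p;
* Cox proportional-hazards models use Efron tie handling with Wald 95%
  confidence intervals, and Kaplan-Meier groups come from a median split
  of activity (values >= median go to the high group).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "HazardEstimate",
    "spearman_corr",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "cohens_d",
    "cohens_d_paired",
    "fdr_adjust",
    "zscore_vs_controls",
    "cox_ph",
    "km_median_split",
]


@dataclass
class TestResult:
    """A single hypothesis test: statistic, p, n, optional effect size."""

    test_name: str
    statistic: float
    p_value: float
    n: tuple                      # group sizes (or (n,) for one sample)
    effect_size: Optional[float] = None
    method: str = "asymptotic"    # 'exact' | 'asymptotic'
    adjusted_p: Optional[float] = None
    reject: Optional[bool] = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class HazardEstimate:
    """Cox model output for one covariate."""

    covariate: str
    hazard_ratio: float
    ci_95: tuple
    p_value: float
    n_events: int
    coef: float
    se: float

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        lo, hi = self.ci_95
        if not lo <= self.hazard_ratio <= hi:
            raise ValueError("CI must contain the point estimate")


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def spearman_corr(x, y, exact_n: int = 7) -> TestResult:
    """Spearman rank correlation with mid-rank ties, two-sided p.

    Pairs with non-finite entries are dropped pairwise.  For n <=
    ``exact_n`` the p-value is the exact permutation probability over
    all n! orderings of one variable's ranks.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n:
        rxc = rx - rx.mean()
        denom = math.sqrt((rxc ** 2).sum())
        count = 0
        total = 0
        ryc = ry - ry.mean()
        ry_norm = math.sqrt((ryc ** 2).sum())
        for perm in itertools.permutations(ryc):
            r = float(np.dot(rxc, perm)) / (denom * ry_norm)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        method = "asymptotic"
    return TestResult("spearman", rho, p, (n,), method=method)


def _has_ties(values) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(group_a, group_b, exact_n: int = 12) -> TestResult:
    """Mann-Whitney U (U of ``group_a``), two-sided.

    Exact p by enumeration when the combined sample is <= ``exact_n``
    and tie-free; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    use_exact = (len(pooled) <= exact_n) and not _has_ties(pooled)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return TestResult("mann_whitney_u", float(res.statistic),
                      float(res.pvalue), (len(a), len(b)),
                      method="exact" if use_exact else "asymptotic")


def wilcoxon_signed_rank(paired_a, paired_b, exact_n: int = 12,
                         min_pairs: int = 5) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped before ranking.  The reported W is the
    smaller of the positive- and negative-rank sums.  Exact p when the
    nonzero-pair count is <= ``exact_n`` with untied |differences|.
    """
    a, b = _clean_pairs(paired_a, paired_b)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < min_pairs:
        raise ValueError(
            f"only {n} nonzero pairs; need {min_pairs} for a p-value")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    use_exact = (n <= exact_n) and not _has_ties(np.abs(d))
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="exact" if use_exact else "approx")
    return TestResult("wilcoxon_signed_rank", w, float(res.pvalue), (n,),
                      method="exact" if use_exact else "asymptotic")


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical; H undefined")
    res = stats.kruskal(*groups)
    return TestResult("kruskal_wallis", float(res.statistic),
                      float(res.pvalue), tuple(len(g) for g in groups))


# ---------------------------------------------------------------------------
# Effect sizes, z-scores, FDR
# ---------------------------------------------------------------------------

def cohens_d(group_a, group_b) -> float:
    """Mean difference over the pooled (n-1) standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
        / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def cohens_d_paired(paired_a, paired_b) -> float:
    """Paired effect size: mean difference over the SD of differences."""
    a, b = _clean_pairs(paired_a, paired_b)
    d = a - b
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of differences")
    return float(d.mean() / sd)


def fdr_adjust(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up: per-test decisions + adjusted p."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([], dtype=bool), np.array([])
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def zscore_vs_controls(patient_values, control_values) -> np.ndarray:
    """Z-score patients against the control mean and (n-1) SD."""
    pv = np.asarray(patient_values, dtype=float)
    cv = np.asarray(control_values, dtype=float)
    if len(cv) < 2:
        raise ValueError("need at least 2 controls")
    sd = cv.std(ddof=1)
    if sd == 0:
        raise ValueError("zero control standard deviation")
    return (pv - cv.mean()) / sd


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def cox_ph(survival_inputs: pd.DataFrame, covariates: Sequence[str],
           duration_col: str = "time_weeks", event_col: str = "event"
           ) -> Dict[str, HazardEstimate]:
    """Multivariate Cox proportional hazards (Efron tie handling).

    Returns Wald 95% CIs and p-values per covariate.  Raises on zero
    events or non-convergence (with diagnostics from the fitter).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = survival_inputs[[duration_col, event_col, *covariates]].copy()
    df[event_col] = df[event_col].astype(bool)
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summary = cph.summary
    out: Dict[str, HazardEstimate] = {}
    for cov in covariates:
        row = summary.loc[cov]
        out[cov] = HazardEstimate(
            covariate=cov,
            hazard_ratio=float(row["exp(coef)"]),
            ci_95=(float(row["exp(coef) lower 95%"]),
                   float(row["exp(coef) upper 95%"])),
            p_value=float(row["p"]),
            n_events=n_events,
            coef=float(row["coef"]),
            se=float(row["se(coef)"]))
    return out


def km_median_split(survival_inputs: pd.DataFrame, activity,
                    duration_col: str = "time_weeks",
                    event_col: str = "event"):
    """Kaplan-Meier curves for high/low groups split at the median.

    Subjects with activity >= median form the high group.  Returns
    ``(curves, threshold)`` where ``curves`` maps 'high'/'low' to the
    product-limit survival function (a DataFrame indexed by time).
    Degenerate splits (a side with < 2 subjects) raise.
    """
    from lifelines import KaplanMeierFitter

    act = np.asarray(activity, dtype=float)
    if len(act) != len(survival_inputs):
        raise ValueError("one activity value per subject required")
    thr = float(np.median(act))
    high = act >= thr
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("degenerate median split (need >= 2 per side)")
    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(survival_inputs.loc[mask, duration_col],
               survival_inputs.loc[mask, event_col].astype(bool),
               label=label)
        curves[label] = km.survival_function_
    return curves, thr
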