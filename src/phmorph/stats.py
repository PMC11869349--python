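"""Statistical battery for morphometric cohort tables.

Implements the analysis set of a typical morphometry study: two-sample
comparisons from raw data (with a normality screen dispatching between the
pooled t-test and the Mann-Whitney U test), t-statistics recomputed from
published summary statistics alone (pooled and Welch forms), Pearson and
Spearman correlations, one-way ANOVA and Kruskal-Wallis across groups, and a
Kolmogorov-Smirnov normality check.  A :func:`study_report` driver turns a
cohort table into the standard report tables (overall summaries, per-sex
comparison, body-profile correlations, ethnicity ANOVA).

All p-values are two-tailed and unadjusted for multiple comparisons (a
warning is logged whenever a multi-test report is produced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import PARAMETER_COLUMNS

__all__ = [
    "SummaryStats",
    "TestResult",
    "t_from_summary",
    "two_sample_test",
    "normality",
    "correlation",
    "oneway",
    "kruskal",
    "study_report",
]

logger = logging.getLogger("phmorph.stats")

ALPHA = 0.05

_METHODS = {"pooled-t", "welch-t", "mann-whitney", "pearson", "spearman",
            "anova", "kruskal-wallis", "ks-normal"}


@dataclass(frozen=True)
class SummaryStats:
    """Per-group summary: mean, sample SD, group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method label {self.method!r}")


def _as_sample(x, name: str, min_n: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_n:
        raise ValueError(f"{name}: need at least {min_n} observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: non-finite values")
    return x


def t_from_summary(g1: SummaryStats, g2: SummaryStats,
                   method: str = "pooled") -> TestResult:
    """Two-sample t-test computed from group summaries alone.

    ``pooled``: t = (m1-m2) / (s_p sqrt(1/n1 + 1/n2)) with the df-weighted
    pooled variance and df = n1+n2-2.  ``welch``: per-group variance terms
    with Welch-Satterthwaite degrees of freedom.  The pooled form applied to
    raw-data summaries equals the raw-data pooled t exactly.
    """
    if method not in ("pooled", "welch"):
        raise ValueError("method must be 'pooled' or 'welch'")
    delta = g1.mean - g2.mean
    if g1.sd == 0.0 and g2.sd == 0.0:
        if delta == 0.0:
            df = g1.n + g2.n - 2 if method == "pooled" else float(g1.n + g2.n - 2)
            return TestResult(0.0, float(df), 1.0,
                              "pooled-t" if method == "pooled" else "welch-t")
        raise ValueError("zero variance in both groups with unequal means: "
                         "t-statistic is infinite")
    if method == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        label = "pooled-t"
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
        label = "welch-t"
    t = delta / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), label)


def normality(x, lilliefors: bool = False) -> TestResult:
    """Kolmogorov-Smirnov test against a normal with sample-estimated moments.

    The plain KS p-value (default) ignores that the moments were estimated;
    set ``lilliefors=True`` for the corrected variant.
    """
    x = _as_sample(x, "normality")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return TestResult(1.0, None, 0.0, "ks-normal")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        stat, p = _lf(x, dist="norm")
    else:
        stat, p = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return TestResult(float(stat), None, float(p), "ks-normal")


def two_sample_test(x, y, force: str = "auto",
                    lilliefors: bool = False) -> TestResult:
    """Two-sample location comparison with automatic test selection.

    ``auto`` screens each sample for normality (KS at alpha = 0.05) and runs
    the pooled t-test when both pass, otherwise the Mann-Whitney U test
    (normal approximation with tie and continuity corrections).  ``force``
    may be ``"t"`` or ``"mw"`` to bypass the screen.
    """
    x = _as_sample(x, "two_sample_test: x")
    y = _as_sample(y, "two_sample_test: y")
    if force not in ("auto", "t", "mw"):
        raise ValueError("force must be 'auto', 't' or 'mw'")
    use_t = force == "t"
    if force == "auto":
        use_t = (normality(x, lilliefors).p > ALPHA
                 and normality(y, lilliefors).p > ALPHA)
    if use_t:
        t, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(float(t), float(len(x) + len(y) - 2), float(p),
                          "pooled-t")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        # All observations tied: U equals its null expectation, no evidence.
        return TestResult(len(x) * len(y) / 2.0, None, 1.0, "mann-whitney")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                            method="asymptotic", use_continuity=True)
    return TestResult(float(u), None, float(p), "mann-whitney")


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a two-tailed p-value."""
    x = _as_sample(x, "correlation: x")
    y = _as_sample(y, "correlation: y")
    if len(x) != len(y):
        raise ValueError("correlation: samples must be paired")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation: zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(float(r), float(len(x) - 2), float(p), method)


def _check_groups(groups, name):
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) < 2:
        raise ValueError(f"{name}: need >= 2 groups with >= 2 members")
    return usable


def oneway(groups) -> TestResult:
    """One-way ANOVA across groups (groups with < 2 members are dropped)."""
    usable = _check_groups(groups, "oneway")
    f, p = sps.f_oneway(*usable)
    df = float(len(usable) - 1)
    return TestResult(float(f), df, float(p), "anova")


def kruskal(groups) -> TestResult:
    """Kruskal-Wallis H-test across groups (groups with < 2 members dropped)."""
    usable = _check_groups(groups, "kruskal")
    h, p = sps.kruskal(*usable)
    return TestResult(float(h), float(len(usable) - 1), float(p),
                      "kruskal-wallis")


# ---------------------------------------------------------------------------
# Report driver
# ---------------------------------------------------------------------------

def _require_columns(cohort: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing required columns: {missing}")


def study_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Produce the standard report tables from a cohort table.

    Returns a dict with keys ``overall`` (min/max/mean/sd per parameter),
    ``by_sex`` (per-sex summaries with pooled and Welch t), ``body_profile``
    (Pearson r and p of each parameter against height/weight/BMI) and
    ``ethnicity`` (one-way ANOVA F and p across ethnic groups with >= 2
    members).  P-values are deliberately left unadjusted.
    """
    _require_columns(cohort, ["sex", "height_cm", "weight_kg", "bmi",
                              "ethnicity", *PARAMETER_COLUMNS])
    logger.warning("study_report: p-values are unadjusted for multiple "
                   "comparisons")

    overall = pd.DataFrame({
        "parameter": PARAMETER_COLUMNS,
        "min": [cohort[c].min() for c in PARAMETER_COLUMNS],
        "max": [cohort[c].max() for c in PARAMETER_COLUMNS],
        "mean": [cohort[c].mean() for c in PARAMETER_COLUMNS],
        "sd": [cohort[c].std(ddof=1) for c in PARAMETER_COLUMNS],
    })

    rows = []
    sexes = sorted(cohort["sex"].unique())
    for param in PARAMETER_COLUMNS:
        row: dict = {"parameter": param}
        for sex in ("male", "female"):
            sub = cohort.loc[cohort["sex"] == sex, param]
            row[f"{sex}_n"] = int(len(sub))
            row[f"{sex}_mean"] = sub.mean() if len(sub) else np.nan
            row[f"{sex}_sd"] = sub.std(ddof=1) if len(sub) > 1 else np.nan
        if len(sexes) >= 2:
            male = cohort.loc[cohort["sex"] == "male", param].to_numpy()
            female = cohort.loc[cohort["sex"] == "female", param].to_numpy()
            g1 = SummaryStats(float(male.mean()), float(male.std(ddof=1)),
                              len(male))
            g2 = SummaryStats(float(female.mean()), float(female.std(ddof=1)),
                              len(female))
            pooled = t_from_summary(g1, g2, "pooled")
            welch = t_from_summary(g1, g2, "welch")
            row.update(t_pooled=pooled.statistic, p_pooled=pooled.p,
                       t_welch=welch.statistic, p_welch=welch.p)
        else:
            row.update(t_pooled=np.nan, p_pooled=np.nan,
                       t_welch=np.nan, p_welch=np.nan)
        rows.append(row)
    by_sex = pd.DataFrame(rows)

    rows = []
    for param in PARAMETER_COLUMNS:
        row = {"parameter": param}
        for covariate, label in (("height_cm", "height"),
                                 ("weight_kg", "weight"), ("bmi", "bmi")):
            res = correlation(cohort[covariate], cohort[param], "pearson")
            row[f"r_{label}"] = res.statistic
            row[f"p_{label}"] = res.p
        rows.append(row)
    body_profile = pd.DataFrame(rows)

    rows = []
    counts = cohort["ethnicity"].value_counts()
    usable_groups = counts[counts >= 2].index
    for param in PARAMETER_COLUMNS:
        row = {"parameter": param}
        if len(usable_groups) >= 2:
            groups = [cohort.loc[cohort["ethnicity"] == g, param].to_numpy()
                      for g in usable_groups]
            res = oneway(groups)
            row.update(F=res.statistic, p=res.p, n_groups=int(len(groups)))
        else:
            row.update(F=np.nan, p=np.nan, n_groups=int(len(usable_groups)))
        rows.append(row)
    ethnicity = pd.DataFrame(rows)

    return {"overall": overall, "by_sex": by_sex,
            "body_profile": body_profile, "ethnicity": ethnicity}
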