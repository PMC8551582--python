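"""Cohort-level statistics over per-eye metric tables.

Mirrors the study's SPSS workflow: Shapiro-Wilk normality and Levene
homogeneity gates choose one-way ANOVA (with Bonferroni-adjusted pooled-MSE
pairwise t-tests) or Kruskal-Wallis (with Bonferroni-adjusted Dunn pairwise
z-tests); Pearson correlation with t-based two-sided p-values; and
SPSS-style stepwise multiple linear regression (entry p < 0.05, removal
p > 0.10) for BCVA prediction.

Eyes are treated as independent observations, matching the study's sample
sizes; inter-eye correlation within patients is a documented caveat, not a
modeled effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EyeRecord",
    "CohortTable",
    "GroupComparison",
    "group_compare",
    "pearson_with_p",
    "pearson_p_from_r",
    "StepwiseResult",
    "stepwise_regression",
    "describe_groups",
    "chi_square_counts",
    "adjusted_r2",
]

GROUPS = ("HC", "acute", "convalescent")
ALPHA_NORMALITY = 0.05
ALPHA_ENTER = 0.05  # SPSS stepwise defaults
ALPHA_REMOVE = 0.10


@dataclass(frozen=True)
class EyeRecord:
    """One eye's metric vector with its study arm and visual acuity."""

    eye_id: str
    group: str
    bcva_logmar: Optional[float]
    metrics: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class CohortTable:
    """Per-eye records aggregated for statistics; convertible to a DataFrame."""

    records: List[EyeRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"eye_id": r.eye_id, "group": r.group, "bcva_logmar": r.bcva_logmar, **r.metrics}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @property
    def n_per_group(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.group] = out.get(r.group, 0) + 1
        return out


# ---------------------------------------------------------------- comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Three-group comparison report for one metric."""

    metric: str
    test_used: str  # "anova" | "kruskal"
    global_p: float
    pairwise_p: Dict[Tuple[str, str], float]  # Bonferroni-adjusted
    shapiro_p: Dict[str, float]
    levene_p: float


def _group_arrays(df: pd.DataFrame, metric: str, group_col: str) -> Dict[str, np.ndarray]:
    out = {}
    for g, sub in df.groupby(group_col, sort=False):
        vals = pd.to_numeric(sub[metric], errors="coerce").dropna().to_numpy(float)
        if vals.size:
            out[str(g)] = vals
    return out


def _anova_bonferroni(groups: Dict[str, np.ndarray]) -> Tuple[float, Dict]:
    names = list(groups)
    arrays = [groups[g] for g in names]
    _, p_global = stats.f_oneway(*arrays)
    # SPSS Bonferroni post hoc: pooled within-group MSE t-tests, p x m
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfe = n_total - k
    mse = sse / dfe
    m = k * (k - 1) // 2
    pairwise = {}
    for g1, g2 in combinations(names, 2):
        a, b = groups[g1], groups[g2]
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        tval = (a.mean() - b.mean()) / se
        p = 2.0 * stats.t.sf(abs(tval), dfe)
        pairwise[(g1, g2)] = min(1.0, p * m)
    return float(p_global), pairwise


def _dunn_bonferroni(groups: Dict[str, np.ndarray]) -> Dict:
    """Dunn's rank-based pairwise z-tests with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        pairwise[(g1, g2)] = min(1.0, p * m)
    return pairwise


def group_compare(df: pd.DataFrame, metric: str, group_col: str = "group") -> GroupComparison:
    """Compare one metric across study arms with the study's test gate.

    Shapiro-Wilk p > 0.05 in every arm *and* Levene homogeneity p > 0.05
    selects one-way ANOVA with Bonferroni pairwise t-tests on the pooled
    MSE; otherwise Kruskal-Wallis with Bonferroni-adjusted Dunn z-tests.
    """
    groups = _group_arrays(df, metric, group_col)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 3 for a in groups.values()):
        raise ValueError("each group needs >= 3 observations")
    shapiro_p = {
        g: (float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0)
        for g, a in groups.items()
    }
    all_constant = all(np.ptp(a) == 0 for a in groups.values())
    levene_p = 0.0 if all_constant else float(
        stats.levene(*groups.values(), center="mean").pvalue
    )
    normal = (
        not all_constant
        and all(p > ALPHA_NORMALITY for p in shapiro_p.values())
        and levene_p > ALPHA_NORMALITY
    )
    if normal:
        p_global, pairwise = _anova_bonferroni(groups)
        test = "anova"
    else:
        if all_constant and len({a[0] for a in groups.values()}) == 1:
            # all observations identical: no evidence of any difference
            p_global = 1.0
            m = len(groups) * (len(groups) - 1) // 2
            pairwise = {pair: 1.0 for pair in combinations(groups, 2)}
        else:
            _, p_global = stats.kruskal(*groups.values())
            pairwise = _dunn_bonferroni(groups)
            p_global = float(p_global)
        test = "kruskal"
    return GroupComparison(metric, test, p_global, pairwise, shapiro_p, levene_p)


# --------------------------------------------------------------- correlations


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a variable")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p of a Pearson r at sample size n: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if not -1.0 < r < 1.0:
        return 0.0
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


# ------------------------------------------------------------------ stepwise


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if n - k - 1 <= 0:
        raise ValueError("need n > k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class StepwiseResult:
    """Stepwise regression report in the layout of an SPSS model summary."""

    selected: Tuple[str, ...]
    coef: pd.DataFrame  # index: const + variables; columns: B, SE, beta, p
    r2: float
    adj_r2: float
    model_p: float  # overall F-test p (NaN for the empty model)
    n: int
    steps: Tuple[str, ...] = ()  # audit trail of entries/removals


def _fit(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y: Sequence[float],
    X: pd.DataFrame,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
    max_steps: int = 100,
) -> StepwiseResult:
    """SPSS-style stepwise multiple linear regression.

    At each step the candidate with the smallest t-test p-value when added
    to the current model enters if p < ``alpha_enter``; then any included
    variable whose p exceeds ``alpha_remove`` is removed (worst first).
    Iterates to a fixed point.  Collinear candidates (those that make the
    design singular) are skipped with a warning.  ``beta`` is the
    standardized coefficient B * sd(x)/sd(y).
    """
    y = np.asarray(y, dtype=float)
    X = X.astype(float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("y and X row counts differ")
    const_cols = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const_cols:
        warnings.warn(f"dropping zero-variance candidates: {const_cols}")
        X = X.drop(columns=const_cols)

    included: List[str] = []
    trail: List[str] = []
    for _ in range(max_steps):
        changed = False
        # entry
        candidates = [c for c in X.columns if c not in included]
        best_c, best_p = None, np.inf
        for c in candidates:
            trial = X[included + [c]]
            if np.linalg.matrix_rank(sm.add_constant(trial, has_constant="add")) < len(
                included
            ) + 2:
                warnings.warn(f"candidate {c!r} collinear with current model; skipped")
                continue
            res = _fit(y, trial)
            p = res.pvalues[c]
            if p < best_p:
                best_c, best_p = c, p
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            trail.append(f"+{best_c}")
            changed = True
        # removal
        while included:
            res = _fit(y, X[included])
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                trail.append(f"-{worst}")
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        coef = pd.DataFrame(
            {"B": [float(y.mean())], "SE": [float(y.std(ddof=1) / np.sqrt(n))],
             "beta": [np.nan], "p": [np.nan]},
            index=["const"],
        )
        return StepwiseResult((), coef, 0.0, 0.0, float("nan"), n, tuple(trail))

    res = _fit(y, X[included])
    sy = y.std(ddof=1)
    rows = {"B": [], "SE": [], "beta": [], "p": []}
    index = []
    for name in ["const"] + included:
        index.append(name)
        rows["B"].append(float(res.params[name]))
        rows["SE"].append(float(res.bse[name]))
        rows["p"].append(float(res.pvalues[name]))
        if name == "const":
            rows["beta"].append(np.nan)
        else:
            sx = X[name].to_numpy().std(ddof=1)
            rows["beta"].append(float(res.params[name] * sx / sy))
    coef = pd.DataFrame(rows, index=index)
    return StepwiseResult(
        selected=tuple(included),
        coef=coef,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        model_p=float(res.f_pvalue),
        n=n,
        steps=tuple(trail),
    )


# ---------------------------------------------------------------- descriptives


def describe_groups(df: pd.DataFrame, metric: str, group_col: str = "group") -> pd.DataFrame:
    """Per-group summary in the printed-table style.

    Groups passing Shapiro-Wilk (p > 0.05) are summarized as mean +/- SD,
    skewed groups as median (P25-P75); the ``normal`` flag records which
    style applies.
    """
    rows = []
    for g, vals in _group_arrays(df, metric, group_col).items():
        if vals.size >= 3 and np.ptp(vals) > 0:
            sw_p = float(stats.shapiro(vals).pvalue)
        else:
            sw_p = float("nan")
        normal = bool(sw_p > ALPHA_NORMALITY) if np.isfinite(sw_p) else True
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        p25, med, p75 = (float(q) for q in np.percentile(vals, [25, 50, 75]))
        summary = (
            f"{mean:.2f} ± {sd:.2f}" if normal else f"{med:.2f} ({p25:.2f}-{p75:.2f})"
        )
        rows.append(
            {
                "group": g,
                "n": vals.size,
                "mean": mean,
                "sd": sd,
                "median": med,
                "p25": p25,
                "p75": p75,
                "shapiro_p": sw_p,
                "normal": normal,
                "summary": summary,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def chi_square_counts(table: np.ndarray) -> Tuple[float, float]:
    """Pearson chi-square test of a contingency table (no Yates correction)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)
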