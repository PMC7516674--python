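"""Between-group comparisons and distribution-similarity machinery.

Continuous variables are gated through a Lilliefors normality test in
each group: a t-test is used when both groups look normal, otherwise the
Mann-Whitney U test.  Categorical variables get a chi-square test on the
contingency table.  Distribution similarity between an under-sampled
control subset and its parent group is quantified per variable with the
two-sample Kolmogorov-Smirnov statistic and the Jensen-Shannon
divergence (base-2 logs, so JSD is bounded in [0, 1]; 0 means identical
histograms, 1 disjoint ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from scipy.special import rel_entr

__all__ = [
    "GroupComparison",
    "lilliefors_test",
    "compare_groups",
    "comparison_report",
    "ks_two_sample",
    "jensen_shannon_divergence",
    "similarity_report",
    "CATEGORICAL_VARIABLES",
]

CATEGORICAL_VARIABLES = {"gender", "smoking_status", "diabetes", "hypertension"}

_LILLIEFORS_NULL_SEED = 20200220  # fixed: the null table must be reproducible
_null_cache: dict[tuple[int, int], np.ndarray] = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance of the standardised sample against N(0, 1)."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = st.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def _null_table(n: int, n_sims: int) -> np.ndarray:
    key = (n, n_sims)
    if key not in _null_cache:
        rng = np.random.default_rng(_LILLIEFORS_NULL_SEED)
        draws = rng.standard_normal((n_sims, n))
        z = np.sort((draws - draws.mean(axis=1, keepdims=True))
                    / draws.std(axis=1, ddof=1, keepdims=True), axis=1)
        cdf = st.norm.cdf(z)
        i = np.arange(1, n + 1)
        d = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        _null_cache[key] = np.sort(d)
    return _null_cache[key]


def lilliefors_test(x, n_sims: int = 10_000) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo null.

    The statistic is the KS distance between the sample (standardised by
    its own mean and SD) and the standard normal.  The p-value comes from
    ``n_sims`` simulated normal samples of the same size under a fixed
    internal seed: ``p = (1 + #{D_null >= D}) / (n_sims + 1)``.

    Returns ``(D, p)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError(f"Lilliefors test needs n >= 5, got {len(x)}")
    d = _lilliefors_statistic(x)
    null = _null_table(len(x), n_sims)
    exceed = len(null) - np.searchsorted(null, d, side="left")
    return d, float((1 + exceed) / (n_sims + 1))


@dataclass
class GroupComparison:
    """Result of one between-group comparison."""

    variable: str
    test: str              # "chi-square" | "t" | "mann-whitney"
    statistic: float
    p_value: float
    summary_case: str
    summary_control: str


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} [{q1:.1f}, {q3:.1f}]"


def _category_summary(x: np.ndarray) -> str:
    values, counts = np.unique(x, return_counts=True)
    pct = counts / counts.sum() * 100
    return "/".join(f"{v}:{p:.1f}%" for v, p in zip(values, pct))


def compare_groups(table: pd.DataFrame, variable: str, group_col: str = "cvd",
                   categorical: bool | None = None, alpha: float = 0.05,
                   lilliefors_sims: int = 10_000) -> GroupComparison:
    """Compare one variable between the two groups of a subject table.

    Categorical variables (or those in :data:`CATEGORICAL_VARIABLES` when
    ``categorical`` is None) get a chi-square test; continuous variables
    are tested with a t-test when both groups pass the Lilliefors gate at
    ``alpha``, otherwise with the Mann-Whitney U test.  Summaries follow
    the same gate: mean ± SD when both normal, else median [Q1, Q3].
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups in {group_col!r}, found {len(groups)}")
    a = table.loc[table[group_col] == groups[1], variable].to_numpy()  # cases
    b = table.loc[table[group_col] == groups[0], variable].to_numpy()  # controls
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if categorical is None:
        categorical = variable in CATEGORICAL_VARIABLES

    if categorical:
        contingency = pd.crosstab(table[group_col], table[variable]).to_numpy()
        stat, p, _, _ = st.chi2_contingency(contingency)
        return GroupComparison(variable, "chi-square", float(stat), float(p),
                               _category_summary(a), _category_summary(b))

    a = a.astype(float)
    b = b.astype(float)
    _, p_a = lilliefors_test(a, n_sims=lilliefors_sims)
    _, p_b = lilliefors_test(b, n_sims=lilliefors_sims)
    both_normal = (p_a > alpha) and (p_b > alpha)
    if both_normal:
        stat, p = st.ttest_ind(a, b)
        test = "t"
    else:
        stat, p = st.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparison(variable, test, float(stat), float(p),
                           _summary(a, both_normal), _summary(b, both_normal))


def comparison_report(table: pd.DataFrame, variables: list[str],
                      group_col: str = "cvd", **kwargs) -> pd.DataFrame:
    """Run :func:`compare_groups` over many variables; one row each."""
    rows = [compare_groups(table, v, group_col=group_col, **kwargs) for v in variables]
    return pd.DataFrame([r.__dict__ for r in rows])


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (max ECDF gap D, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = st.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def jensen_shannon_divergence(x, y, bins: int | None = None) -> float:
    """Jensen-Shannon divergence between two samples' histograms, in [0, 1].

    Histograms share bins over the pooled range; bin count follows the
    Freedman-Diaconis rule on the pooled data with a minimum of 10 bins
    (unless ``bins`` is given).  Zero-count cells receive machine-epsilon
    mass before normalisation.  Base-2 logs, so identical distributions
    give 0 and disjoint ones 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    lo, hi = pooled.min(), pooled.max()
    if bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        width = 2 * iqr / len(pooled) ** (1 / 3)
        bins = 10 if width <= 0 else max(10, int(np.ceil((hi - lo) / width)))
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(x, bins=edges)[0].astype(float)
    q = np.histogram(y, bins=edges)[0].astype(float)
    p = np.maximum(p, np.finfo(float).eps)
    q = np.maximum(q, np.finfo(float).eps)
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)
    jsd = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(jsd / np.log(2))


def similarity_report(subset: pd.DataFrame, parent: pd.DataFrame,
                      variables: list[str]) -> pd.DataFrame:
    """Per-variable KS D, KS p, and JSD between a subset and its parent."""
    rows = []
    for v in variables:
        d, p = ks_two_sample(subset[v], parent[v])
        jsd = jensen_shannon_divergence(subset[v], parent[v])
        rows.append({"variable": v, "ks_d": d, "ks_p": p, "jsd": jsd})
    return pd.DataFrame(rows)
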