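"""Population-level statistics over detected components and paths.

Covers the four summary analyses run across layers and injury
conditions: two-sample Kolmogorov-Smirnov comparisons of timing and
category distributions, ordinary least-squares regressions of
second-component time on first-component time (reported as intercept
± SE, flagged when the slope is not significant), category-proportion
tables over {0, 1, 2, 3+} components, and non-stationarity histograms
(0..4 and 5+ ms) of the primary component path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

CATEGORIES = ("0", "1", "2", "3plus")
NONSTATIONARITY_BINS = ("0", "1", "2", "3", "4", "5plus")


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    label: str = ""


@dataclass
class RegressionResult:
    n: int
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    p_value: float       # slope != 0
    r_squared: float
    significant: bool    # slope p < alpha
    computable: bool = True
    label: str = ""


def ks_two_sample(a, b, label: str = "", method: str = "asymp") -> KSResult:
    """Two-sided two-sample KS test (asymptotic p by default; pass
    ``method='exact'`` for small samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("KS test requires two non-empty samples")
    res = sps.ks_2samp(a, b, method=method)
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    n_a=len(a), n_b=len(b), label=label)


def timing_regression(first_times, second_times, label: str = "",
                      alpha: float = 0.05) -> RegressionResult:
    """OLS of second-component time on first-component time.

    Mirrors the inter-component timing analysis: for every
    multi-component unit the second component's time is regressed on the
    first's; the y-intercept ± SE is the headline number and fits whose
    slope is not significant at ``alpha`` are flagged (reported but
    marked, like the '#' marks in the original tables).
    """
    x = np.asarray(first_times, dtype=float)
    y = np.asarray(second_times, dtype=float)
    if len(x) != len(y):
        raise ValueError("first/second time vectors differ in length")
    if len(x) < 3:
        return RegressionResult(n=len(x), slope=math.nan, slope_se=math.nan,
                                intercept=math.nan, intercept_se=math.nan,
                                p_value=math.nan, r_squared=math.nan,
                                significant=False, computable=False, label=label)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p_slope = float(model.pvalues[1])
    return RegressionResult(
        n=len(x), slope=float(model.params[1]), slope_se=float(model.bse[1]),
        intercept=float(model.params[0]), intercept_se=float(model.bse[0]),
        p_value=p_slope, r_squared=float(model.rsquared),
        significant=bool(p_slope < alpha), label=label,
    )


def category_proportions(units: pd.DataFrame,
                         group_cols=("layer", "condition", "stimulus"),
                         category_col: str = "category") -> pd.DataFrame:
    """Per-group proportions of units with 0/1/2/3+ components.

    ``units`` needs one row per unit with a category column holding
    values from ``CATEGORIES`` (or integer counts, which are mapped).
    Returns a tidy frame with group columns, ``n_units`` and one
    proportion column per category, each group summing to 1.
    """
    df = units.copy()
    df[category_col] = df[category_col].map(_as_category)
    rows = []
    for keys, sub in df.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        counts = sub[category_col].value_counts()
        n = len(sub)
        row = dict(zip(group_cols, keys))
        row["n_units"] = n
        for cat in CATEGORIES:
            row[f"prop_{cat}"] = counts.get(cat, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def _as_category(v) -> str:
    if isinstance(v, str) and v in CATEGORIES:
        return v
    n = int(v)
    return str(n) if n < 3 else "3plus"


def _category_int(v) -> int:
    return 3 if _as_category(v) == "3plus" else int(_as_category(v))


def category_ks_matrix(units: pd.DataFrame,
                       group_cols=("layer", "condition", "stimulus"),
                       category_col: str = "category",
                       method: str = "asymp") -> pd.DataFrame:
    """Pairwise comparisons of per-unit component-count distributions.

    The proportion charts are compared with two-sample KS tests applied
    to the integer per-unit component counts {0, 1, 2, 3} of each group
    (the only reading under which a two-sample KS applies to
    proportions); a chi-square test on the 4-category contingency table
    is emitted alongside for reference.
    """
    df = units.copy()
    df["_count"] = df[category_col].map(_category_int)
    groups = {keys if isinstance(keys, tuple) else (keys,): sub["_count"].to_numpy()
              for keys, sub in df.groupby(list(group_cols), sort=True)}
    rows = []
    for (ka, a), (kb, b) in itertools.combinations(groups.items(), 2):
        ks = ks_two_sample(a, b, method=method)
        table = np.array([[np.sum(g == c) for c in range(4)] for g in (a, b)])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] > 1:
            chi2, chi2_p = sps.chi2_contingency(table)[:2]
        else:
            chi2, chi2_p = 0.0, 1.0
        rows.append({"group_a": "/".join(map(str, ka)),
                     "group_b": "/".join(map(str, kb)),
                     "ks_D": ks.statistic, "ks_p": ks.p_value,
                     "n_a": ks.n_a, "n_b": ks.n_b,
                     "chi2": float(chi2), "chi2_p": float(chi2_p)})
    return pd.DataFrame(rows)


def nonstationarity_distribution(paths: pd.DataFrame,
                                 group_cols=("layer", "condition"),
                                 value_col: str = "nonstationarity_ms",
                                 method: str = "asymp"
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histograms of primary-path non-stationarity plus pairwise KS tests.

    ``paths`` needs one row per unit (its rank-1 path).  Values are
    binned at 0, 1, 2, 3, 4 and 5+ ms; proportions per group sum to 1.
    Returns ``(histogram_frame, ks_frame)``.
    """
    rows = []
    groups = {}
    for keys, sub in paths.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = sub[value_col].to_numpy(dtype=float)
        groups[keys] = vals
        binned = np.clip(np.rint(vals).astype(int), 0, 5)
        row = dict(zip(group_cols, keys))
        row["n_units"] = len(vals)
        for i, name in enumerate(NONSTATIONARITY_BINS):
            row[f"prop_{name}"] = float(np.mean(binned == i)) if len(vals) else 0.0
        rows.append(row)
    hist = pd.DataFrame(rows)
    ks_rows = []
    for (ka, a), (kb, b) in itertools.combinations(groups.items(), 2):
        if len(a) and len(b):
            ks = ks_two_sample(a, b, method=method)
            ks_rows.append({"group_a": "/".join(map(str, ka)),
                            "group_b": "/".join(map(str, kb)),
                            "ks_D": ks.statistic, "ks_p": ks.p_value,
                            "n_a": ks.n_a, "n_b": ks.n_b})
    return hist, pd.DataFrame(ks_rows)
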