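"""Correlations at multiple aggregation levels, VIFs, subpopulation test.

Genetic correlations in half-sib trials are estimated as Pearson
correlations of family estimates (BLUPs) rather than by multivariate REML.
The informative contrast is between aggregation levels:

* ``within-focal`` — family estimates inside the single large focal
  population (clinal divergence removed by design);
* ``within-pooled`` — family estimates ``m + f_j`` pooled over the
  latitudinal populations after removing the fixed population effects;
* ``between-familywise`` — population-inclusive estimates
  ``m + f_j + p_k`` across latitudinal families, dominated by the clines;
* ``between-popmeans`` — the population means of the family estimates.

High between-population but low within-population correlations indicate
clines maintained by independent selection rather than by correlated
selection responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from clinesel.errors import DataError

log = logging.getLogger(__name__)

LEVELS = ("phenotypic", "within-focal", "within-pooled",
          "between-familywise", "between-popmeans")


@dataclass
class CorrelationEstimate:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    level: str = ""
    clamped: bool = False     # degenerate |r| = 1 interval


def pearson_with_ci(x, y, level: str = "", alpha: float = 0.05) -> CorrelationEstimate:
    """Product-moment correlation with Fisher-z confidence interval.

    The interval is ``tanh(atanh(r) +- z_{1-a/2} / sqrt(n - 3))`` and the
    p-value comes from ``t = r sqrt((n-2)/(1-r^2))`` on ``n - 2`` df.
    Pairs with a missing member are dropped (pairwise-complete).
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    n = len(x)
    if n < 4:
        raise DataError(f"need >= 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    clamped = False
    if abs(r) >= 1.0 - 1e-15:
        lo, hi = (r, r)
        clamped = True
        log.warning("pearson_with_ci: |r| = 1, CI clamped to a point")
        p = 0.0
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationEstimate(r=r, n=n, ci_low=float(lo), ci_high=float(hi),
                               p=float(p), level=level, clamped=clamped)


def correlation_levels(estimates: pd.DataFrame, mode: str,
                       traits: tuple[str, ...] | None = None,
                       focal: str | None = None) -> dict[tuple[str, str], CorrelationEstimate]:
    """Trait-pair correlations at a chosen aggregation level.

    Parameters
    ----------
    estimates : one row per family with a ``population`` column and one
        column per trait.  The caller supplies values on the scale the mode
        requires: within modes expect estimates with population effects
        removed (``m + f_j`` or focal-population BLUPs); between-familywise
        expects population-inclusive estimates ``m + f_j + p_k``.
    mode : one of ``within-focal``, ``within-pooled``,
        ``between-familywise``, ``between-popmeans``.
    focal : population label selecting the focal subset (within-focal only).
    """
    if mode not in ("within-focal", "within-pooled", "between-familywise",
                    "between-popmeans"):
        raise DataError(f"unknown correlation mode {mode!r}")
    if "population" not in estimates.columns:
        raise DataError("estimates must carry a population column")
    if traits is None:
        traits = tuple(c for c in estimates.columns if c != "population")
    df = estimates
    if mode == "within-focal":
        if focal is None:
            raise DataError("within-focal mode requires a focal population label")
        df = estimates.loc[estimates["population"] == focal]
    elif mode == "between-popmeans":
        if estimates["population"].nunique() < 2:
            raise DataError("between-popmeans needs >= 2 populations")
        df = estimates.groupby("population")[list(traits)].mean().reset_index()
    out = {}
    for a, b in combinations(traits, 2):
        out[(a, b)] = pearson_with_ci(df[a], df[b], level=mode)
    return out


def variance_inflation_factors(traits: pd.DataFrame) -> pd.Series:
    """VIF per trait: ``1 / (1 - R^2)`` of each trait on the others.

    Computed from the inverse of the trait correlation matrix, whose
    diagonal equals the VIFs; perfect collinearity is reported as ``inf``
    with a warning rather than raised.
    """
    cols = list(traits.columns)
    if len(cols) < 2:
        raise DataError("need >= 2 traits")
    X = traits.dropna().to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise DataError("need n > #traits + 1 complete rows")
    R = np.corrcoef(X, rowvar=False)
    try:
        vifs = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        log.warning("variance_inflation_factors: singular correlation matrix")
        return pd.Series(np.inf, index=cols)
    vifs = np.where(vifs < 0, np.inf, vifs)   # numerically singular
    if np.isinf(vifs).any():
        log.warning("variance_inflation_factors: perfect collinearity detected")
    return pd.Series(vifs, index=cols)


def subpop_mean_test(values, labels, equal_var: bool = True):
    """Two-sided two-sample t-test between exactly two subpopulations.

    Classical (equal-variance) Student's t by default, with a Welch option.
    Returns ``(t, df, p, group_means)``.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    labels = pd.Series(np.asarray(labels)).astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, got {len(groups)}")
    a = values[labels == groups[0]].dropna()
    b = values[labels == groups[1]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    means = {groups[0]: float(a.mean()), groups[1]: float(b.mean())}
    return float(res.statistic), float(df), float(res.pvalue), means
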