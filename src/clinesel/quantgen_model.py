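"""Half-sib mixed models: REML variance components, BLUPs, heritability.

The family model for a trait value :math:`Y_{ijq}` of seedling *q* of
family *j* in block *i* is

.. math:: Y_{ijq} = m + b_i + f_j + e_{ijq},

with fixed block effects :math:`b_i` (optionally also fixed population
effects for multi-population fits), a random family effect
:math:`f_j \\sim N(0, \\sigma^2_f)` and residual
:math:`e_{ijq} \\sim N(0, \\sigma^2_e)`.  Under the half-sib assumption the
additive genetic variance is :math:`V_A = 4\\sigma^2_f`, phenotypic variance
:math:`V_P = \\sigma^2_f + \\sigma^2_e` (blocks are fixed and excluded), and
narrow-sense heritability :math:`h^2 = V_A / V_P`.

Because the model has a single grouped random intercept, REML is fit by
profiling: for the variance ratio :math:`r = \\sigma^2_f/\\sigma^2_e` the
GLS fixed effects and the residual variance have closed forms from
per-family sufficient statistics, leaving a one-dimensional restricted
criterion that is maximized over :math:`r \\ge 0` (the boundary value is
accepted — no negative components).  The observed information matrix of the
restricted likelihood in :math:`(\\sigma^2_f, \\sigma^2_e)` provides
:math:`\\mathrm{Var}(\\hat\\sigma^2_f)` for the Dickerson standard error of
heritability, :math:`\\mathrm{SE}(h^2) = \\sqrt{16\\,\\mathrm{Var}(\\hat\\sigma^2_f)}/V_P`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from clinesel.errors import DataError
from clinesel.trial_data import TrialTable

log = logging.getLogger(__name__)

_REML_XTOL = 1e-12  # tolerance on log-variance-ratio in the profiled search


@dataclass
class VarianceComponents:
    sigma2_family: float
    sigma2_residual: float
    fixed_effects: pd.Series          # intercept + treatment-coded block/population
    n_families: int
    n_obs: int
    converged: bool
    loglik_restricted: float
    var_sigma2_family: float | None = None   # asymptotic Var of sigma2_family
    boundary: bool = False                   # sigma2_family hit the zero boundary
    trait: str = ""

    @property
    def VP(self) -> float:
        return self.sigma2_family + self.sigma2_residual


@dataclass
class FamilyEstimates:
    """Per-family BLUPs on three scales.

    ``deviation`` is the raw shrinkage estimate :math:`\\hat f_j` (mean ~0);
    ``centered`` adds the fixed-effect mean, matching estimates "centered
    around the intercept"; ``population_inclusive`` additionally carries the
    family's population effect (only for multi-population fits).
    """

    values: pd.DataFrame              # family_id index; columns per scale
    trait: str = ""

    def scale(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise DataError(f"scale {name!r} not available for this fit")
        return self.values[name]


@dataclass
class HeritabilityEstimate:
    VA: float
    VP: float
    h2: float
    se: float | None = None
    se_source: str = ""
    warning: str = ""


def _design(df: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies, first level as reference."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in fixed:
        levels = sorted(df[factor].astype(str).unique())
        for lev in levels[1:]:
            cols.append((df[factor].astype(str) == lev).to_numpy(float))
            names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names


class _RemlSufficientStats:
    """Per-family sufficient statistics for the one-random-factor model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, fam: np.ndarray):
        self.n, self.p = X.shape
        q = fam.max() + 1
        self.q = q
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.nj = np.bincount(fam, minlength=q).astype(float)
        self.Sj = np.zeros((q, self.p))
        np.add.at(self.Sj, fam, X)
        self.tj = np.bincount(fam, weights=y, minlength=q)

    def profile(self, r: float):
        """GLS pieces for variance ratio r = sigma2_f / sigma2_e."""
        c = r / (1.0 + r * self.nj)                       # per-family shrink factor
        A = self.XtX - (self.Sj * c[:, None]).T @ self.Sj  # X' H^-1 X
        b = self.Xty - self.Sj.T @ (c * self.tj)           # X' H^-1 y
        yHy = self.yty - float(c @ self.tj**2)
        beta = np.linalg.solve(A, b)
        qform = max(yHy - float(b @ beta), 0.0)            # y' P y
        sign, logdetA = np.linalg.slogdet(A)
        logdetH = float(np.sum(np.log1p(r * self.nj)))
        return beta, qform, logdetA, logdetH

    def criterion(self, r: float) -> float:
        """-2 restricted log-likelihood, profiled over beta and sigma2_e."""
        _, qform, logdetA, logdetH = self.profile(r)
        if qform <= 0:
            return np.inf
        npp = self.n - self.p
        return npp * np.log(qform / npp) + logdetH + logdetA

    def neg2_restricted_loglik(self, s2f: float, s2e: float) -> float:
        """-2 l_R at an arbitrary (sigma2_f, sigma2_e) point (for curvature)."""
        r = s2f / s2e
        _, qform, logdetA, logdetH = self.profile(r)
        npp = self.n - self.p
        return (npp * np.log(2 * np.pi * s2e) + logdetH + logdetA
                + self.p * 0.0 + qform / s2e)


def _fit_reml(y: np.ndarray, X: np.ndarray, fam: np.ndarray):
    stats = _RemlSufficientStats(y, X, fam)
    obj = lambda u: stats.criterion(np.exp(u))
    res = minimize_scalar(obj, bounds=(-25.0, 12.0), method="bounded",
                          options={"xatol": _REML_XTOL})
    r_hat, crit = float(np.exp(res.x)), float(res.fun)
    boundary = False
    crit0 = stats.criterion(0.0)
    if crit0 <= crit or r_hat < 1e-10:
        r_hat, crit, boundary = 0.0, crit0, True
    beta, qform, _, _ = stats.profile(r_hat)
    s2e = qform / (stats.n - stats.p)
    s2f = r_hat * s2e
    loglik = -0.5 * stats.neg2_restricted_loglik(max(s2f, 0.0), s2e) if s2e > 0 else np.nan

    var_s2f = None
    if not boundary and s2e > 0:
        # observed information of -2 l_R via central finite differences
        h = np.array([max(s2f, 1e-8) * 1e-4, s2e * 1e-4])
        theta = np.array([s2f, s2e])
        H = np.zeros((2, 2))
        f0 = stats.neg2_restricted_loglik(*theta)
        for a in range(2):
            for b in range(a, 2):
                ea = np.eye(2)[a] * h[a]
                eb = np.eye(2)[b] * h[b]
                fpp = stats.neg2_restricted_loglik(*(theta + ea + eb))
                fpm = stats.neg2_restricted_loglik(*(theta + ea - eb))
                fmp = stats.neg2_restricted_loglik(*(theta - ea + eb))
                fmm = stats.neg2_restricted_loglik(*(theta - ea - eb))
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
        info = H / 2.0   # information of l_R
        try:
            cov = np.linalg.inv(info)
            if cov[0, 0] > 0:
                var_s2f = float(cov[0, 0])
        except np.linalg.LinAlgError:
            pass

    # BLUPs: shrunken family-mean residuals
    resid_sum = stats.tj - stats.Sj @ beta
    denom = 1.0 + r_hat * stats.nj
    blup = r_hat * resid_sum / denom
    converged = bool(boundary or res.success)
    return s2f, s2e, beta, blup, loglik, var_s2f, boundary, converged


def fit_family_model(table: TrialTable, trait: str,
                     fixed: tuple[str, ...] = ("block",),
                     ) -> tuple[VarianceComponents, FamilyEstimates]:
    """REML fit of the block + family model for one trait.

    Parameters
    ----------
    table : trial table; excluded records and missing trait values dropped.
    trait : a numeric column of ``table.records`` (e.g. ``bst_days``,
        ``fyh_mm``, ``ffi_score`` — the ordinal score is analyzed on the
        linear scale since the underlying phenotype is continuous).
    fixed : fixed factors, ``("block",)`` for the single-population model or
        ``("block", "population")`` for the multi-population model.
    """
    rec = table.active()
    if trait not in rec.columns:
        raise DataError(f"trait {trait!r} not in records")
    df = rec.loc[rec[trait].notna(), ["family_id", *fixed, trait]].copy()
    if df.empty:
        raise DataError(f"trait {trait!r} has no non-missing observations")
    fam_counts = df["family_id"].value_counts()
    if (fam_counts >= 2).sum() < 2:
        raise DataError("need >= 2 families with >= 2 observations")

    y = df[trait].to_numpy(dtype=float)
    X, names = _design(df, fixed)
    fam_labels, fam = np.unique(df["family_id"].to_numpy(), return_inverse=True)

    if np.var(y) < 1e-12 * (1.0 + np.mean(y) ** 2):
        # degenerate: constant response
        fe = pd.Series(np.zeros(len(names)), index=names)
        fe["intercept"] = float(y.mean())
        vc = VarianceComponents(0.0, 0.0, fe, len(fam_labels), len(y), True,
                                np.nan, None, True, trait)
        est = pd.DataFrame({"deviation": np.zeros(len(fam_labels)),
                            "centered": np.full(len(fam_labels), y.mean())},
                           index=pd.Index(fam_labels, name="family_id"))
        return vc, FamilyEstimates(est, trait)

    s2f, s2e, beta, blup, loglik, var_s2f, boundary, converged = _fit_reml(y, X, fam)
    if not converged:
        log.warning("fit_family_model(%s): REML did not converge", trait)

    fe = pd.Series(beta, index=names)
    vc = VarianceComponents(
        sigma2_family=float(s2f), sigma2_residual=float(s2e),
        fixed_effects=fe, n_families=len(fam_labels), n_obs=len(y),
        converged=converged, loglik_restricted=float(loglik),
        var_sigma2_family=var_s2f, boundary=boundary, trait=trait,
    )
    # grand fixed-effect mean (block/population effects averaged over data)
    m = float(np.mean(X @ beta))
    est = pd.DataFrame({"deviation": blup, "centered": m + blup},
                       index=pd.Index(fam_labels, name="family_id"))
    if "population" in fixed:
        # intercept + mean block effect + own population effect
        blk_cols = [i for i, nm in enumerate(names) if nm.startswith("block[")]
        base = beta[0] + (X[:, blk_cols] @ beta[blk_cols]).mean()
        pop_of_fam = (df.drop_duplicates("family_id")
                        .set_index("family_id")["population"]
                        .reindex(fam_labels).astype(str))
        pop_eff = np.zeros(len(fam_labels))
        for i, nm in enumerate(names):
            if nm.startswith("population["):
                lev = nm[len("population["):-1]
                pop_eff[(pop_of_fam == lev).to_numpy()] = beta[i]
        est["population_inclusive"] = base + pop_eff + blup
    return vc, FamilyEstimates(est, trait)


def anova_oracle_balanced(table: TrialTable, trait: str) -> VarianceComponents:
    """Method-of-moments components for a perfectly balanced one-block design.

    Independent oracle for the REML fitter: with q families of k seedlings
    each, ``sigma2_f = (MS_between - MS_within) / k`` and
    ``sigma2_e = MS_within``.  Raises on unbalanced input.
    """
    rec = table.active()
    df = rec.loc[rec[trait].notna(), ["family_id", "block", trait]]
    if df["block"].nunique() != 1:
        raise DataError("balanced oracle requires a single block")
    counts = df["family_id"].value_counts()
    if counts.nunique() != 1:
        raise DataError("balanced oracle requires equal family sizes")
    k = int(counts.iloc[0])
    q = len(counts)
    if k < 2 or q < 2:
        raise DataError("need >= 2 families with >= 2 seedlings")
    y = df[trait].to_numpy(float)
    means = df.groupby("family_id")[trait].mean()
    grand = y.mean()
    ss_between = k * float(((means - grand) ** 2).sum())
    ss_within = float(((df[trait] - df["family_id"].map(means)) ** 2).sum())
    ms_b = ss_between / (q - 1)
    ms_w = ss_within / (q * (k - 1))
    s2f = max((ms_b - ms_w) / k, 0.0)
    fe = pd.Series({"intercept": grand})
    # sampling variance of the MoM family component (balanced one-way ANOVA)
    var_s2f = (2.0 / k**2) * (ms_b**2 / (q - 1) + ms_w**2 / (q * (k - 1)))
    return VarianceComponents(s2f, ms_w, fe, q, len(y), True, np.nan,
                              var_s2f, boundary=(ms_b <= ms_w), trait=trait)


def additive_variance(vc: VarianceComponents) -> float:
    """Half-sib additive variance: 4x the between-family component."""
    return 4.0 * vc.sigma2_family


def heritability(VA: float, VP: float) -> HeritabilityEstimate:
    """Narrow-sense heritability ``h2 = VA / VP``."""
    if VP <= 0:
        raise DataError("VP must be positive")
    h2 = VA / VP
    warning = "h2 > 1" if h2 > 1 else ""
    if warning:
        log.warning("heritability: %s (VA=%.4g, VP=%.4g)", warning, VA, VP)
    return HeritabilityEstimate(VA=VA, VP=VP, h2=h2, warning=warning)


def dickerson_se(vc: VarianceComponents) -> HeritabilityEstimate:
    """Heritability with its Dickerson-approximation standard error.

    Dickerson's approximation treats the denominator V_P as fixed, so
    ``Var(h2) ~= Var(V_A) / VP^2 = 16 Var(sigma2_f) / VP^2``.
    ``Var(sigma2_f)`` comes from the REML information matrix (or the ANOVA
    mean-square sampling variance when the fit came from the balanced
    oracle); when unavailable the SE is flagged missing rather than raised.
    """
    est = heritability(additive_variance(vc), vc.VP)
    if vc.var_sigma2_family is None:
        est.se = None
        est.se_source = "unavailable"
        log.warning("dickerson_se: Var(sigma2_family) unavailable; SE missing")
    else:
        est.se = float(np.sqrt(16.0 * vc.var_sigma2_family) / vc.VP)
        est.se_source = "reml-information" if not np.isnan(vc.loglik_restricted) else "anova-moments"
    return est
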