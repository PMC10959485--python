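"""Lande-Arnold selection gradients and canonical surface analysis.

Family-level selection analysis proceeds in two steps on SD-standardized
traits and relative fitness ``w = W / mean(W)``:

1. directional gradients from the linear-only regression
   ``w = a + sum_i beta_i f_i + e``;
2. quadratic/correlational gradients from the full second-order regression
   ``w = a + sum_i beta*_i f_i + sum_i (1/2) gamma_ii f_i^2
   + sum_{i<k} gamma_ik f_i f_k + e``
   (an OLS fit returns the squared-term coefficient as ``(1/2) gamma_ii``,
   so reported diagonal gradients are doubled).

The curvature of the surface is summarized by the symmetric matrix
``Gamma`` and its eigen-decomposition ``Gamma = M Lambda M'``: the rotated
index traits ``z = M'f`` have purely directional gradients
``theta = M' beta*`` and curvature gradients ``lambda_i``, with stationary
point ``z*_i = -theta_i / (2 lambda_i)``.  Significance of the canonical
gradients comes from re-fitting the full quadratic regression on the index
variables.

Two ``Gamma`` conventions are supported and always recorded:
``halved`` (diagonal ``gamma_ii / 2``, off-diagonal ``gamma_ik / 2`` — the
matrix of raw regression coefficients scaled so the quadratic form
reproduces the fitted surface) and ``full`` (diagonal ``gamma_ii``,
off-diagonal ``gamma_ik``; eigenvalues exactly double the halved ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from clinesel.errors import DataError

log = logging.getLogger(__name__)

CONVENTIONS = ("halved", "full")


@dataclass
class StandardizedTraitTable:
    values: pd.DataFrame          # unit-SD columns
    sds: pd.Series                # original SDs, for back-transformation
    centered: bool

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class FitnessVector:
    w: pd.Series                  # relative fitness, mean 1
    definition: str               # height-including-dead | survival-proportion
    mean_absolute: float


@dataclass
class LinearGradients:
    beta: pd.Series
    se: pd.Series
    p: pd.Series
    alpha: float


@dataclass
class QuadraticGradients:
    beta_star: pd.Series          # linear coefficients of the full model
    gamma_ii: pd.Series           # doubled squared-term coefficients
    gamma_off: pd.Series          # cross-term coefficients, index (i, k) pairs
    se: pd.Series                 # per reported coefficient (same doubling)
    p: pd.Series
    alpha: float
    doubling_applied: bool = True
    traits: tuple[str, ...] = ()


@dataclass
class GammaMatrix:
    matrix: pd.DataFrame
    convention: str

    def __post_init__(self):
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-15):
            raise DataError("Gamma must be symmetric")


@dataclass
class CanonicalDecomposition:
    M: pd.DataFrame               # columns m1.. ordered by descending lambda
    lam: pd.Series
    theta: pd.Series
    z_star: pd.Series | None = None
    index_ranges: pd.DataFrame | None = None
    theta_p: pd.Series | None = None
    lambda_p: pd.Series | None = None
    convention: str = "halved"
    degenerate: bool = False


@dataclass
class MardiaResult:
    skewness_stat: float
    skewness_p: float
    kurtosis_stat: float
    kurtosis_p: float
    multivariate_normal: bool


def standardize_traits(table: pd.DataFrame, center: bool = False) -> StandardizedTraitTable:
    """Divide each trait by its SD (optionally centering first).

    Standardization is by SD only by default, matching standard
    selection-gradient practice for family estimates that are already
    centered deviations.
    """
    sds = table.std(ddof=1)
    zero = sds[sds <= 0]
    if len(zero):
        raise DataError(f"zero SD for trait(s): {', '.join(zero.index)}")
    values = table - table.mean() if center else table.copy()
    values = values / sds
    return StandardizedTraitTable(values=values, sds=sds, centered=center)


def relative_fitness(W, definition: str) -> FitnessVector:
    """Relative fitness ``w = W / mean(W)``; mean(w) = 1 by construction."""
    W = pd.Series(W, dtype=float).dropna()
    mean_W = float(W.mean())
    if mean_W <= 0:
        raise DataError("mean absolute fitness must be positive")
    if (W < 0).any():
        raise DataError("absolute fitness must be non-negative")
    return FitnessVector(w=W / mean_W, definition=definition, mean_absolute=mean_W)


def _aligned(w: FitnessVector, traits: StandardizedTraitTable):
    # normalize index dtypes (string vs object ids) before intersecting
    X = traits.values.copy()
    X.index = X.index.astype(object)
    y = w.w.copy()
    y.index = y.index.astype(object)
    common = X.index.intersection(y.index)
    return X.loc[common], y.loc[common]


def linear_gradients(w: FitnessVector, traits: StandardizedTraitTable) -> LinearGradients:
    """Directional gradients beta from the linear-only OLS model."""
    X, y = _aligned(w, traits)
    if len(y) <= X.shape[1] + 1:
        raise DataError("too few families for the linear model")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise DataError("rank-deficient design; check variance_inflation_factors")
    fit = sm.OLS(y, Xc).fit()
    names = list(X.columns)
    return LinearGradients(beta=fit.params[names], se=fit.bse[names],
                           p=fit.pvalues[names], alpha=float(fit.params["const"]))


def _quadratic_design(X: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    names = list(X.columns)
    for t in names:
        cols[t] = X[t]
    for t in names:
        cols[f"{t}^2"] = X[t] ** 2
    for a, b in combinations(names, 2):
        cols[f"{a}:{b}"] = X[a] * X[b]
    return pd.DataFrame(cols, index=X.index)


def quadratic_gradients(w: FitnessVector, traits: StandardizedTraitTable) -> QuadraticGradients:
    """Full second-order OLS model; diagonal gradients reported doubled.

    The squared-term regressors enter as plain ``f_i^2``, so the raw OLS
    coefficient estimates ``(1/2) gamma_ii``; reported ``gamma_ii`` (and
    their SEs) are the raw values times 2.  Cross-term coefficients estimate
    ``gamma_ik`` directly.
    """
    X, y = _aligned(w, traits)
    names = list(X.columns)
    Z = _quadratic_design(X)
    if len(y) <= Z.shape[1] + 1:
        raise DataError("too few families for the quadratic model")
    Zc = sm.add_constant(Z, has_constant="add")
    if np.linalg.matrix_rank(Zc.to_numpy()) < Zc.shape[1]:
        raise DataError("rank-deficient design; check variance_inflation_factors")
    fit = sm.OLS(y, Zc).fit()
    sq = [f"{t}^2" for t in names]
    cross = [f"{a}:{b}" for a, b in combinations(names, 2)]
    gamma_ii = 2.0 * fit.params[sq]
    gamma_ii.index = names
    # SEs and p-values keyed by regressor label; squared-term SEs are doubled
    # with their coefficients (the t statistic and p are unaffected)
    se = pd.concat([fit.bse[names], 2.0 * fit.bse[sq], fit.bse[cross]])
    p = pd.concat([fit.pvalues[names], fit.pvalues[sq], fit.pvalues[cross]])
    return QuadraticGradients(
        beta_star=fit.params[names], gamma_ii=gamma_ii,
        gamma_off=fit.params[cross], se=se, p=p,
        alpha=float(fit.params["const"]), doubling_applied=True,
        traits=tuple(names),
    )


def mardia_test(traits: pd.DataFrame) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis test.

    Skewness ``b_{1,p} = n^{-2} sum_ij d_ij^3`` with ``n b_{1,p} / 6``
    referred to chi-square on ``p(p+1)(p+2)/6`` df; kurtosis
    ``b_{2,p} = n^{-1} sum_i d_ii^2`` referred to a normal with mean
    ``p(p+2)`` and variance ``8 p (p+2) / n``.  ``d_ij`` are Mahalanobis
    inner products with the ML (1/n) covariance.
    """
    X = traits.dropna().to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise DataError("need n > dimension + 1")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise DataError("singular covariance matrix") from None
    D = Xc @ Sinv @ Xc.T
    b1 = float((D**3).sum()) / n**2
    b2 = float((np.diag(D) ** 2).sum()) / n
    skew_stat = n * b1 / 6.0
    skew_df = p * (p + 1) * (p + 2) / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, skew_df))
    kurt_z = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2 * stats.norm.sf(abs(kurt_z)))
    return MardiaResult(skewness_stat=float(skew_stat), skewness_p=skew_p,
                        kurtosis_stat=float(b2), kurtosis_p=kurt_p,
                        multivariate_normal=(skew_p > 0.05 and kurt_p > 0.05))


def build_gamma_matrix(qg: QuadraticGradients, convention: str = "halved") -> GammaMatrix:
    """Assemble the symmetric surface matrix from quadratic gradients.

    ``halved``: diagonal ``gamma_ii / 2``, off-diagonal ``gamma_ik / 2`` —
    the quadratic form ``f' Gamma f`` then reproduces the fitted surface and
    its eigenvalues are the canonical curvature gradients on the same scale
    as the raw regression.  ``full`` doubles every entry.
    """
    if convention not in CONVENTIONS:
        raise DataError(f"unknown Gamma convention {convention!r}")
    names = list(qg.traits)
    k = len(names)
    m = np.zeros((k, k))
    for i, t in enumerate(names):
        m[i, i] = qg.gamma_ii[t]
    for (a, b) in combinations(range(k), 2):
        key = f"{names[a]}:{names[b]}"
        m[a, b] = m[b, a] = qg.gamma_off[key]
    if convention == "halved":
        m = m / 2.0
    return GammaMatrix(matrix=pd.DataFrame(m, index=names, columns=names),
                       convention=convention)


def canonical_analysis(gamma: GammaMatrix, beta_star: pd.Series) -> CanonicalDecomposition:
    """Eigen-decomposition of Gamma with theta = M' beta*.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed so
    its largest-magnitude loading is positive; exact ties are broken by the
    original axis index and flagged.
    """
    A = gamma.matrix.to_numpy()
    if not np.allclose(A, A.T, atol=1e-12):
        raise DataError("Gamma asymmetric beyond tolerance")
    lam, M = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam, M = lam[order], M[:, order]
    tol = 1e-12 * max(1.0, float(np.abs(lam).max()))
    degenerate = bool(np.any(np.abs(np.diff(lam)) < tol))
    if degenerate:
        log.warning("canonical_analysis: (near-)degenerate eigenvalues")
    for j in range(M.shape[1]):
        i_max = int(np.argmax(np.abs(M[:, j])))
        if M[i_max, j] < 0:
            M[:, j] = -M[:, j]
    names = list(gamma.matrix.columns)
    axes = [f"m{j+1}" for j in range(len(names))]
    Mdf = pd.DataFrame(M, index=names, columns=axes)
    beta = beta_star.reindex(names).to_numpy(dtype=float)
    theta = pd.Series(M.T @ beta, index=axes)
    return CanonicalDecomposition(M=Mdf, lam=pd.Series(lam, index=axes),
                                  theta=theta, convention=gamma.convention,
                                  degenerate=degenerate)


def canonical_significance(w: FitnessVector, traits: StandardizedTraitTable,
                           M: pd.DataFrame, convention: str = "halved",
                           ) -> tuple[pd.Series, pd.Series, QuadraticGradients]:
    """p-values for theta and lambda from the index-variable regression.

    Index values ``z = M'f`` are fed through the same full quadratic OLS;
    linear-term p-values test theta, squared-term p-values test lambda.  The
    squared-term coefficients estimate ``lambda`` directly under the
    ``halved`` convention (and half of it under ``full``), consistent with
    how the surface matrix was built.
    """
    X, y = _aligned(w, traits)
    Z = pd.DataFrame(X.to_numpy() @ M.to_numpy(), index=X.index,
                     columns=list(M.columns))
    zstt = StandardizedTraitTable(values=Z, sds=pd.Series(1.0, index=Z.columns),
                                  centered=traits.centered)
    qg = quadratic_gradients(w, zstt)
    axes = list(M.columns)
    theta_p = qg.p[axes]
    lambda_p = qg.p[[f"{ax}^2" for ax in axes]].set_axis(axes)
    return theta_p, lambda_p, qg


def stationary_point(theta: pd.Series, lam: pd.Series) -> pd.Series:
    """Stationary point ``z*_i = -theta_i / (2 lambda_i)`` per canonical axis.

    Axes with a zero eigenvalue have no stationary coordinate; they are
    returned as NaN with a warning.
    """
    theta = pd.Series(theta, dtype=float)
    lam = pd.Series(lam, dtype=float).reindex(theta.index)
    out = -theta / (2.0 * lam)
    undefined = lam == 0
    if undefined.any():
        log.warning("stationary_point: %d axes with lambda = 0 flagged NaN",
                    int(undefined.sum()))
        out[undefined] = np.nan
    return out


def observed_index_ranges(traits: StandardizedTraitTable, M: pd.DataFrame) -> pd.DataFrame:
    """Componentwise (min, max) of the observed index values z = M'f."""
    Z = traits.values.to_numpy() @ M.to_numpy()
    return pd.DataFrame({"min": Z.min(axis=0), "max": Z.max(axis=0)},
                        index=list(M.columns))


def full_canonical(w: FitnessVector, traits: StandardizedTraitTable,
                   convention: str = "halved") -> CanonicalDecomposition:
    """Convenience: quadratic fit, Gamma, decomposition, z*, ranges, p-values."""
    qg = quadratic_gradients(w, traits)
    gamma = build_gamma_matrix(qg, convention)
    dec = canonical_analysis(gamma, qg.beta_star)
    dec.z_star = stationary_point(dec.theta, dec.lam)
    dec.index_ranges = observed_index_ranges(traits, dec.M)
    dec.theta_p, dec.lambda_p, _ = canonical_significance(w, traits, dec.M,
                                                          convention)
    return dec


def significance_stars(p: float) -> str:
    """Star banding: '.' p<.10, '*' p<.05, '**' p<.01, '***' p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""
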