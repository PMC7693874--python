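"""Frequency-weighted kinship and REML variance components.

The polygenic model is y = X b + g + e with g ~ N(0, sigma_g^2 G) and
e ~ N(0, sigma_e^2 I), where G is the allele-frequency-weighted IBS
relationship matrix. Narrow-sense heritability is reported as the
intraclass correlation sigma_g^2 / (sigma_g^2 + sigma_e^2).

The random effect is realized directly through an eigendecomposition
G = U diag(s) U' (mathematically identical to the Cholesky-factor
formulation, and robust to near-singular G): rotating data into the
eigenbasis diagonalizes the covariance, so the restricted likelihood is a
cheap 1-D profile over the variance ratio delta = sigma_e^2/sigma_g^2,
maximized by bounded Brent search on log(delta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "KinshipEigen",
    "VarComp",
    "kinship_freq_weighted",
    "eigen_kinship",
    "fit_null_lmm",
    "reml_loglik",
]


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix with aligned row ids."""

    values: np.ndarray
    row_ids: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.values, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(g, g.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")
        g = 0.5 * (g + g.T)
        object.__setattr__(self, "values", g)
        object.__setattr__(self, "row_ids", np.asarray(self.row_ids, dtype=object))
        if len(self.row_ids) != g.shape[0]:
            raise ValueError("row id count does not match kinship dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class KinshipEigen:
    """Cached eigendecomposition G = U diag(s) U' (s ascending, floored)."""

    s: np.ndarray
    U: np.ndarray
    row_ids: np.ndarray


@dataclass(frozen=True)
class VarComp:
    """REML variance components and heritability for one phenotype."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 outside [0, 1]")


def kinship_freq_weighted(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Allele-frequency-weighted IBS relationship matrix.

    G_jk = (1/M) sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (4 p_m (1 - p_m)),
    with p_m the sample frequency of the allele coded 2. For haploid dosages
    (x/2 ~ Bernoulli(p)) each standardized marker has unit variance, so the
    diagonal has expectation 1 and unrelated pairs expectation 0.
    Monomorphic markers are rejected upstream by the genotype container.
    """
    x = genotypes.values.astype(float)
    p = genotypes.allele_freq()
    w = (x - 2.0 * p) / np.sqrt(4.0 * p * (1.0 - p))
    g = (w @ w.T) / genotypes.n_markers
    return KinshipMatrix(g, genotypes.row_ids)


_EIG_FLOOR = -1e-8


def eigen_kinship(kinship: KinshipMatrix | np.ndarray) -> KinshipEigen:
    """Eigendecompose a kinship matrix, flooring tiny negative eigenvalues."""
    if isinstance(kinship, KinshipEigen):
        return kinship
    if isinstance(kinship, KinshipMatrix):
        g, ids = kinship.values, kinship.row_ids
    else:
        g = np.asarray(kinship, dtype=float)
        ids = np.arange(g.shape[0]).astype(object)
    s, u = np.linalg.eigh(g)
    if s.min() < _EIG_FLOOR * max(1.0, abs(s.max())):
        raise ValueError(
            f"kinship matrix is not PSD: smallest eigenvalue {s.min():.3g}"
        )
    return KinshipEigen(np.clip(s, 0.0, None), u, np.asarray(ids, dtype=object))


def reml_loglik(
    y: np.ndarray, X: np.ndarray, eig: KinshipEigen, sigma_g2: float, sigma_e2: float
) -> float:
    """Restricted log-likelihood at (sigma_g2, sigma_e2).

    l_R = -1/2 [ (n-q) log 2pi + log|V| + log|X'V^-1 X| - log|X'X|
                 + (y - X b)' V^-1 (y - X b) ]
    with V = sigma_g2 G + sigma_e2 I and b the GLS estimate.
    """
    yr = eig.U.T @ y
    xr = eig.U.T @ X
    d = sigma_g2 * eig.s + sigma_e2
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    beta = np.linalg.solve(xtwx, xtwy)
    r = yr - xr @ beta
    quad = float(r @ (w * r))
    n, q = len(y), X.shape[1]
    _, ld_xtwx = np.linalg.slogdet(xtwx)
    _, ld_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - q) * np.log(2 * np.pi) + np.log(d).sum() + ld_xtwx - ld_xtx + quad
    )


def _profile_reml(
    yr: np.ndarray, xr: np.ndarray, s: np.ndarray, ld_xtx: float, log_delta: float
) -> tuple[float, float, float]:
    """Profiled REML at delta = sigma_e2/sigma_g2; returns (ll, sg2, se2)."""
    delta = np.exp(log_delta)
    d = s + delta
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    beta = np.linalg.solve(xtwx, xr.T @ (w * yr))
    r = yr - xr @ beta
    n, q = len(yr), xr.shape[1]
    sg2 = float(r @ (w * r)) / (n - q)
    _, ld_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi) + np.log(sg2) + 1.0)
        + np.log(d).sum()
        + ld_xtwx
        - ld_xtx
    )
    return ll, sg2, sg2 * delta


_LOG_DELTA_LO, _LOG_DELTA_HI = -14.0, 14.0


def fit_null_lmm(
    y: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    covariates: np.ndarray | None = None,
    tol: float = 1e-8,
) -> VarComp:
    """REML fit of the polygenic null model y = X b + g + e.

    ``covariates`` (n x c, without intercept — one is always added) enter the
    fixed part. The search runs over log(delta) in [-14, 14]; an optimum at
    either end is reported with ``at_boundary=True`` (delta at the high end
    means sigma_g2 ~ 0, i.e. h2 ~ 0).
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y contains missing values; drop them before fitting")
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for REML")
    eig = eigen_kinship(kinship)
    if len(eig.s) != n:
        raise ValueError("y length does not match kinship dimension")
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        X = np.column_stack([X, cov])
    yr = eig.U.T @ y
    xr = eig.U.T @ X
    _, ld_xtx = np.linalg.slogdet(X.T @ X)

    def neg(ld: float) -> float:
        return -_profile_reml(yr, xr, eig.s, ld_xtx, ld)[0]

    res = optimize.minimize_scalar(
        neg,
        bounds=(_LOG_DELTA_LO, _LOG_DELTA_HI),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [res.x, _LOG_DELTA_LO, _LOG_DELTA_HI]
    best = min(candidates, key=neg)
    ll, sg2, se2 = _profile_reml(yr, xr, eig.s, ld_xtx, best)
    at_boundary = best in (_LOG_DELTA_LO, _LOG_DELTA_HI) or abs(
        best - _LOG_DELTA_LO
    ) < 1e-3 or abs(best - _LOG_DELTA_HI) < 1e-3
    if sg2 <= 0 or not np.isfinite(ll):
        raise RuntimeError("REML optimizer failed to produce finite estimates")
    h2 = sg2 / (sg2 + se2)
    # delta at the high boundary encodes sigma_g2 -> 0: report h2 = 0 there
    return VarComp(sg2, se2, h2, float(ll), bool(at_boundary))
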