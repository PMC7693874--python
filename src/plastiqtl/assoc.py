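"""Genome-wide LMM association scans and multiple-testing machinery.

Scans fit the single-marker model y = mu + x beta + g + e with the polygenic
covariance sigma_g^2 G + sigma_e^2 I. A two-stage scheme is used: variance
components are estimated once from the null model (with any covariate
markers in the fixed part) and then held fixed while every marker is tested
by generalized least squares in the eigenbasis of G — O(n) per marker after
one rotation. This matches common mixed-model GWAS practice; it is an
approximation to full per-marker REML.

The genome-wide significance threshold divides the family-wise error target
by the effective number of independent markers Me, obtained per chromosome
from the eigenvalues of the marker correlation matrix via the Li–Ji
composition f(lambda) = 1(lambda >= 1) + frac(lambda), and summed over
chromosomes (cross-chromosome LD is ~0 in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, get_logger
from .varcomp import (
    KinshipEigen,
    KinshipMatrix,
    VarComp,
    eigen_kinship,
    fit_null_lmm,
)

__all__ = [
    "GwasScan",
    "QtlPeak",
    "Threshold",
    "ConditionalResult",
    "gwa_scan",
    "conditional_scan",
    "effective_markers",
    "significance_threshold",
    "detect_peaks",
    "genomic_inflation",
]

logger = get_logger(__name__)

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class GwasScan:
    """Per-marker association results for one phenotype.

    ``table`` columns: marker_id, chrom, pos, beta, se, stat, pvalue,
    collinear. ``stat`` is the Wald z statistic; pvalue its two-sided normal
    tail probability. Markers collinear with the covariates are recorded
    with pvalue 1 and the collinear flag set, never dropped.
    """

    table: pd.DataFrame
    phenotype: str = "y"
    covariate_markers: tuple[str, ...] = ()
    varcomp: VarComp | None = None

    def __post_init__(self) -> None:
        p = self.table["pvalue"].to_numpy()
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values outside (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class QtlPeak:
    """One association peak: lead marker plus the significant span."""

    lead_marker_id: str
    chromosome: str
    position_bp: int
    lead_pvalue: float
    span: tuple[int, int]
    n_significant: int = 1


@dataclass(frozen=True)
class Threshold:
    """Family-wise significance cutoff alpha / Me."""

    Me: float
    alpha: float = 0.05
    cutoff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Me < 1:
            raise ValueError("Me must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        object.__setattr__(self, "cutoff", self.alpha / self.Me)


def _rotated(eig: KinshipEigen, arr: np.ndarray) -> np.ndarray:
    return eig.U.T @ arr


def gwa_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    covariate_markers: tuple[str, ...] | list[str] = (),
    phenotype: str = "y",
    rotated_genotypes: np.ndarray | None = None,
) -> GwasScan:
    """LMM association scan of one phenotype across all markers.

    Segregants with missing y must be removed beforehand (the pipeline does
    this per phenotype). ``rotated_genotypes`` (U' X_geno) may be passed to
    amortize the big rotation across many scans sharing one kinship.
    """
    y = np.asarray(y, dtype=float)
    eig = eigen_kinship(kinship)
    n = genotypes.n
    if len(y) != n or len(eig.s) != n:
        raise ValueError("y, genotypes and kinship dimensions disagree")
    cov_ids = tuple(covariate_markers)
    cov_idx = [genotypes.map.index_of(m) for m in cov_ids]
    x_geno = genotypes.values.astype(float)
    cov = x_geno[:, cov_idx] if cov_idx else None

    vc = fit_null_lmm(y, eig, covariates=cov)

    d = vc.sigma_g2 * eig.s + vc.sigma_e2
    w = 1.0 / d
    x0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    x0r = _rotated(eig, x0)
    yr = _rotated(eig, y)
    gr = rotated_genotypes if rotated_genotypes is not None else _rotated(eig, x_geno)

    a = x0r.T @ (w[:, None] * x0r)               # q x q
    a_inv = np.linalg.inv(a)
    c = x0r.T @ (w[:, None] * gr)                # q x M
    b = np.einsum("ij,ij->j", gr, w[:, None] * gr)  # x' V^-1 x per marker
    d_y = gr.T @ (w * yr)                        # x' V^-1 y
    e0 = x0r.T @ (w * yr)                        # X0' V^-1 y
    ac = a_inv @ c
    denom = b - np.einsum("ij,ij->j", c, ac)     # Schur complement
    numer = d_y - ac.T @ e0

    collinear = denom <= _COLLINEAR_TOL * np.maximum(b, 1.0)
    safe = np.where(collinear, 1.0, denom)
    beta = numer / safe
    se = np.sqrt(1.0 / safe)
    stat = beta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    beta[collinear] = 0.0
    se[collinear] = np.nan
    stat[collinear] = 0.0
    pvalue[collinear] = 1.0
    if collinear.any():
        logger.info(
            "scan %s: %d markers collinear with covariates", phenotype,
            int(collinear.sum()),
        )

    table = pd.DataFrame(
        {
            "marker_id": genotypes.map.marker_id,
            "chrom": genotypes.map.chromosome,
            "pos": genotypes.map.position_bp,
            "beta": beta,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "collinear": collinear,
        }
    )
    return GwasScan(table, phenotype, cov_ids, vc)


@dataclass(frozen=True)
class ConditionalResult:
    """Outcome of the iterative conditional analysis."""

    scan: GwasScan                  # final scan, conditioned on all leads
    leads: tuple[str, ...]          # all lead marker ids, in discovery order
    rounds: int


def conditional_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    peak_leads: tuple[str, ...] | list[str] = (),
    threshold: Threshold | None = None,
    merge_kb: float = 100.0,
    max_rounds: int = 10,
    phenotype: str = "y",
    rotated_genotypes: np.ndarray | None = None,
) -> ConditionalResult:
    """Scan with lead markers as fixed covariates, iterated to convergence.

    Starting from ``peak_leads`` (typically the leads of an unconditional
    scan), each round re-scans with all current leads as covariates and adds
    the leads of any remaining significant peaks, stopping when a round
    yields no new signal or after ``max_rounds``. With ``threshold=None`` a
    single conditioned scan is returned without iteration.
    """
    eig = eigen_kinship(kinship)
    gr = (
        rotated_genotypes
        if rotated_genotypes is not None
        else _rotated(eig, genotypes.values.astype(float))
    )
    leads = list(peak_leads)
    rounds = 0
    while True:
        scan = gwa_scan(
            y, genotypes, eig, covariate_markers=leads, phenotype=phenotype,
            rotated_genotypes=gr,
        )
        rounds += 1
        if threshold is None or rounds >= max_rounds:
            break
        new_peaks = detect_peaks(scan, threshold, merge_kb=merge_kb)
        new = [p.lead_marker_id for p in new_peaks if p.lead_marker_id not in leads]
        if not new:
            break
        leads.extend(new)
    return ConditionalResult(scan, tuple(leads), rounds)


def _li_ji(eigvals: np.ndarray) -> float:
    lam = np.clip(eigvals, 0.0, None)
    # f(x) = 1(x >= 1) + frac(x) is discontinuous at integers; snap
    # eigenvalues within numerical noise of an integer before flooring
    near = np.abs(lam - np.round(lam)) < 1e-9 * max(1.0, lam.max(initial=1.0))
    lam = np.where(near, np.round(lam), lam)
    return float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))


def effective_markers(
    genotypes: GenotypeMatrix, method: str = "li-ji"
) -> float:
    """Effective number of independent markers from LD eigen-spectra.

    Computed chromosome by chromosome from the eigenvalues of the marker
    correlation matrix and summed (markers on different chromosomes are
    uncorrelated in expectation in an intercross).
    """
    if method != "li-ji":
        raise ValueError(f"unknown Me estimator {method!r}")
    if genotypes.n_markers < 2:
        raise ValueError("Me needs at least 2 markers")
    x = genotypes.values.astype(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance marker in Me computation")
    me = 0.0
    for c in pd.unique(genotypes.map.chromosome):
        cols = np.flatnonzero(genotypes.map.chromosome == c)
        if cols.size == 1:
            me += 1.0
            continue
        corr = np.corrcoef(x[:, cols], rowvar=False)
        me += _li_ji(np.linalg.eigvalsh(corr))
    return me


def significance_threshold(Me: float, alpha: float = 0.05) -> Threshold:
    """Family-wise threshold alpha / Me (Bonferroni over effective tests)."""
    return Threshold(Me=Me, alpha=alpha)


def detect_peaks(
    scan: GwasScan, threshold: Threshold | float, merge_kb: float = 100.0
) -> list[QtlPeak]:
    """Group significant markers into peaks per chromosome.

    Consecutive significant markers closer than ``merge_kb`` kb are joined
    into one peak; the lead is the minimum p (ties: smaller position).
    """
    cutoff = threshold.cutoff if isinstance(threshold, Threshold) else float(threshold)
    t = scan.table
    sig = t[t["pvalue"] <= cutoff]
    peaks: list[QtlPeak] = []
    merge_bp = merge_kb * 1000.0
    for _, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s0, e0 in zip(starts, ends):
            block = grp.iloc[s0 : e0 + 1]
            best = block.sort_values(["pvalue", "pos"]).iloc[0]
            peaks.append(
                QtlPeak(
                    lead_marker_id=str(best["marker_id"]),
                    chromosome=str(best["chrom"]),
                    position_bp=int(best["pos"]),
                    lead_pvalue=float(best["pvalue"]),
                    span=(int(block["pos"].min()), int(block["pos"].max())),
                    n_significant=len(block),
                )
            )
    return peaks


def genomic_inflation(scan: GwasScan) -> float:
    """Genomic inflation factor: median Wald chi2 over its null median."""
    chi2 = scan.table["stat"].to_numpy() ** 2
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
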