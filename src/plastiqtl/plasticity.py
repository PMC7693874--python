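"""Overall and environment-pair-specific growth-plasticity measures.

Five measures are computed from the n x E phenotype matrix:

overall (one score per segregant, summarizing all environments)
  PCA1/PCA2 — scores on the first two principal components of the
              column-centered phenotype matrix;
  VAR       — across-environment sample variance of a segregant's growth;
  FWR       — Finlay–Wilkinson regression slope: each segregant's growth is
              regressed on the environment index E_j (environment mean minus
              grand mean), partitioning growth into a constant component
              (intercept Pc) and a plastic one (slope b).

specific (one score per segregant per unordered environment pair)
  DIFF — raw growth difference between the two environments;
  DOT  — product of the two growth values after standardizing each column to
         mean 0 and unit sum of squares, so that the scores of a pair sum to
         the Pearson correlation of the two environments.

Missing data policy: PCA and FWR use complete rows only (scores are NaN for
dropped segregants); VAR, DIFF and DOT are pairwise/row-wise complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import PhenotypeMatrix, get_logger

__all__ = [
    "PcaResult",
    "FwrFit",
    "overall_pca",
    "overall_var",
    "overall_fwr",
    "specific_diff",
    "specific_dot",
    "all_plasticity",
    "OVERALL_MEASURES",
]

OVERALL_MEASURES = ("PCA1", "PCA2", "VAR", "FWR")

logger = get_logger(__name__)


@dataclass(frozen=True)
class PcaResult:
    """Scores/loadings for the first two principal components.

    ``scores`` has one row per phenotype row; segregants dropped for missing
    data carry NaN. Sign convention: the largest-magnitude element of each
    loading vector is positive.
    """

    scores: np.ndarray          # n x 2, NaN where incomplete
    loadings: np.ndarray        # E x 2
    variance_explained: np.ndarray  # length 2, fractions of total variance
    complete_rows: np.ndarray   # bool mask of retained rows


@dataclass(frozen=True)
class FwrFit:
    """Finlay–Wilkinson partition: y_ij ~ Pc_i + b_i * E_j.

    ``env_index`` sums to zero by construction; over segregants with complete
    data the slopes average exactly 1.
    """

    intercept: np.ndarray       # Pc_i, NaN where incomplete
    slope: np.ndarray           # b_i (the FWR plasticity score)
    env_index: np.ndarray       # E_j, length E
    complete_rows: np.ndarray


def _complete_rows(y: np.ndarray) -> np.ndarray:
    return ~np.isnan(y).any(axis=1)


def overall_pca(
    phenos: PhenotypeMatrix, scale: bool = False
) -> PcaResult:
    """PCA of the column-centered phenotype matrix via SVD.

    ``scale=True`` additionally divides columns by their s.d. (off by
    default: the growth phenotypes are assumed pre-normalized).
    """
    y = phenos.values
    if phenos.n_env < 2:
        raise ValueError("PCA needs at least 2 environments")
    keep = _complete_rows(y)
    if keep.sum() < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    if keep.sum() < phenos.n:
        logger.info("PCA: dropped %d incomplete rows", phenos.n - keep.sum())
    yc = y[keep] - y[keep].mean(axis=0)
    if scale:
        sd = yc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance environment column under scaling")
        yc = yc / sd
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    load = vt[:2].T.copy()            # E x 2
    score = u[:, :2] * s[:2]          # complete-rows x 2
    for k in range(2):
        if load[np.argmax(np.abs(load[:, k])), k] < 0:
            load[:, k] *= -1
            score[:, k] *= -1
    total = (s**2).sum()
    var_exp = s[:2] ** 2 / total if total > 0 else np.zeros(2)
    scores = np.full((phenos.n, 2), np.nan)
    scores[keep] = score
    return PcaResult(scores, load, var_exp, keep)


def overall_var(phenos: PhenotypeMatrix) -> np.ndarray:
    """Across-environment sample variance (denominator E-1) per segregant."""
    y = phenos.values
    n_obs = (~np.isnan(y)).sum(axis=1)
    if np.any(n_obs == 0):
        bad = phenos.row_ids[n_obs == 0]
        raise ValueError(f"all-missing phenotype rows: {list(bad[:5])}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(y, axis=1, ddof=1)
    v[n_obs < 2] = np.nan
    return v


def overall_fwr(phenos: PhenotypeMatrix) -> FwrFit:
    """Per-segregant regression of growth on the environment index."""
    y = phenos.values
    keep = _complete_rows(y)
    if keep.sum() < 2:
        raise ValueError("FWR needs at least 2 complete rows")
    yk = y[keep]
    col_means = yk.mean(axis=0)
    env_index = col_means - col_means.mean()
    sxx = float(env_index @ env_index)
    if sxx == 0:
        raise ValueError("zero environmental spread: all environment means equal")
    centered = yk - yk.mean(axis=1, keepdims=True)
    slope_k = centered @ env_index / sxx
    intercept_k = yk.mean(axis=1)  # E_j is centered, so Pc = row mean
    slope = np.full(phenos.n, np.nan)
    intercept = np.full(phenos.n, np.nan)
    slope[keep] = slope_k
    intercept[keep] = intercept_k
    return FwrFit(intercept, slope, env_index, keep)


def _pair_columns(
    phenos: PhenotypeMatrix, e1: str, e2: str
) -> tuple[np.ndarray, np.ndarray]:
    if e1 == e2:
        raise ValueError("environment pair must be two distinct environments")
    return phenos.column(e1), phenos.column(e2)


def specific_diff(phenos: PhenotypeMatrix, e1: str, e2: str) -> np.ndarray:
    """DIFF(e1, e2)_i = y_i,e1 - y_i,e2 (NaN where either value is missing)."""
    a, b = _pair_columns(phenos, e1, e2)
    return a - b


def specific_dot(phenos: PhenotypeMatrix, e1: str, e2: str) -> np.ndarray:
    """DOT scores whose sum over segregants is the Pearson correlation.

    Each column is restricted to the pairwise-complete segregants, centered,
    and scaled to unit sum of squares; the score is the elementwise product.
    """
    a, b = _pair_columns(phenos, e1, e2)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("DOT needs at least 3 pairwise-complete segregants")
    out = np.full(phenos.n, np.nan)
    x = a[ok] - a[ok].mean()
    y = b[ok] - b[ok].mean()
    ssx, ssy = float(x @ x), float(y @ y)
    if ssx == 0 or ssy == 0:
        raise ValueError(f"zero-variance column in DOT({e1},{e2})")
    out[ok] = (x / np.sqrt(ssx)) * (y / np.sqrt(ssy))
    return out


def pair_labels(environment_labels) -> list[tuple[str, str]]:
    """All unordered environment pairs in lexicographic label order."""
    return list(combinations(sorted(map(str, environment_labels)), 2))


def all_plasticity(
    phenos: PhenotypeMatrix,
    measures: str = "all",
    scale_pca: bool = False,
) -> pd.DataFrame:
    """Assemble the plasticity table: 4 overall + 2*C(E,2) specific columns.

    Column order: PCA1, PCA2, VAR, FWR, then DIFF(a,b) and DOT(a,b) for every
    unordered pair (a, b) in lexicographic label order. The index holds the
    segregant ids, aligned with the phenotype matrix.
    """
    if measures not in ("all", "overall", "specific"):
        raise ValueError(f"unknown measure selection {measures!r}")
    table: dict[str, np.ndarray] = {}
    if measures in ("all", "overall"):
        pca = overall_pca(phenos, scale=scale_pca)
        table["PCA1"] = pca.scores[:, 0]
        table["PCA2"] = pca.scores[:, 1]
        table["VAR"] = overall_var(phenos)
        table["FWR"] = overall_fwr(phenos).slope
    if measures in ("all", "specific"):
        for e1, e2 in pair_labels(phenos.environment_labels):
            table[f"DIFF({e1},{e2})"] = specific_diff(phenos, e1, e2)
        for e1, e2 in pair_labels(phenos.environment_labels):
            table[f"DOT({e1},{e2})"] = specific_dot(phenos, e1, e2)
    return pd.DataFrame(table, index=pd.Index(phenos.row_ids, name="id"))
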