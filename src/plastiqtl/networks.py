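"""Overlap of plasticity QTL with epistatic-network hub loci.

A mapped peak and a hub locus are declared overlapping when both criteria
hold: (i) physical distance between the lead marker and the hub position is
within 50 kb, and (ii) LD between the two markers exceeds r^2 = 0.5. Both
quantities are always computed and reported for same-chromosome pairs, never
short-circuited; pairs on different chromosomes are non-overlapping with r^2
left undefined.

The hub-profile analysis quantifies the G x G x E mechanism: a hub's
per-environment marginal additive effect is correlated with the number of
its epistatically interacting partner loci active in each environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import QtlPeak, gwa_scan
from .io import GenotypeMatrix, HubList, PhenotypeMatrix, get_logger
from .varcomp import KinshipEigen, KinshipMatrix, eigen_kinship

__all__ = [
    "OverlapReport",
    "HubProfile",
    "ld_r2",
    "overlap_qtl",
    "detection_frequency",
    "DetectionSummary",
    "hub_effect_profile",
]

logger = get_logger(__name__)

OVERLAP_COLUMNS = [
    "peak_marker_id",
    "peak_chrom",
    "peak_pos",
    "hub_label",
    "hub_chrom",
    "hub_pos",
    "hub_marker_id",
    "distance_bp",
    "r2",
    "overlaps",
    "resolved",
]


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise peak x hub evaluation of the 50 kb / r^2 > 0.5 rule."""

    table: pd.DataFrame
    max_dist_bp: int = 50_000
    min_r2: float = 0.5

    def overlapping(self) -> pd.DataFrame:
        return self.table[self.table["overlaps"]]


@dataclass(frozen=True)
class HubProfile:
    """Per-environment hub effect vs interactor count, with their correlation."""

    environments: np.ndarray
    beta: np.ndarray
    interactor_count: np.ndarray
    correlation: float
    pvalue: float
    undefined: bool = False


def _marker_index(genotypes: GenotypeMatrix, marker) -> int:
    if isinstance(marker, (int, np.integer)):
        return int(marker)
    return genotypes.map.index_of(str(marker))


def ld_r2(genotypes: GenotypeMatrix, marker_a, marker_b) -> float:
    """Squared Pearson correlation between two genotype columns."""
    ia, ib = (_marker_index(genotypes, m) for m in (marker_a, marker_b))
    a = genotypes.values[:, ia].astype(float)
    b = genotypes.values[:, ib].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic marker in LD computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def overlap_qtl(
    peaks: Sequence[QtlPeak],
    hubs: HubList,
    genotypes: GenotypeMatrix,
    max_dist_bp: int = 50_000,
    min_r2: float = 0.5,
    hub_resolve_bp: int = 10_000,
) -> OverlapReport:
    """Evaluate the overlap rule for every peak x hub pair.

    Distance is measured between the peak's lead-marker position and the hub
    position; LD between the lead marker and the hub's nearest genotyped
    marker. Hubs whose position cannot be resolved to a marker within
    ``hub_resolve_bp`` are kept in the report flagged unresolved.
    """
    rows = []
    for _, hub in hubs.entries.iterrows():
        try:
            res = HubList(pd.DataFrame([hub])).resolve_markers(
                genotypes, max_dist_bp=hub_resolve_bp
            )
            hub_marker = res["marker_id"].iloc[0]
            resolved = True
        except ValueError as err:
            logger.warning("hub not resolved: %s", err)
            hub_marker, resolved = None, False
        for peak in peaks:
            same_chrom = str(peak.chromosome) == str(hub["chrom"])
            if same_chrom:
                dist = abs(int(peak.position_bp) - int(hub["pos"]))
                r2 = (
                    ld_r2(genotypes, peak.lead_marker_id, hub_marker)
                    if resolved
                    else np.nan
                )
                overlaps = bool(
                    resolved and dist <= max_dist_bp and r2 > min_r2
                )
            else:
                dist, r2, overlaps = np.nan, np.nan, False
            rows.append(
                {
                    "peak_marker_id": peak.lead_marker_id,
                    "peak_chrom": peak.chromosome,
                    "peak_pos": peak.position_bp,
                    "hub_label": hub["label"],
                    "hub_chrom": hub["chrom"],
                    "hub_pos": int(hub["pos"]),
                    "hub_marker_id": hub_marker,
                    "distance_bp": dist,
                    "r2": r2,
                    "overlaps": overlaps,
                    "resolved": resolved,
                }
            )
    return OverlapReport(
        pd.DataFrame(rows, columns=OVERLAP_COLUMNS), max_dist_bp, min_r2
    )


@dataclass(frozen=True)
class DetectionSummary:
    """Per-locus detection counts across scans plus the unique-QTL union."""

    counts: pd.DataFrame          # index: locus label; columns: categories + total
    n_unique_qtl: int


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def detection_frequency(
    peak_sets: Mapping[str, Sequence[QtlPeak]],
    loci: HubList,
    genotypes: GenotypeMatrix,
    categories: Mapping[str, str] | None = None,
    max_dist_bp: int = 50_000,
    min_r2: float = 0.5,
) -> DetectionSummary:
    """Count, per locus, the scans in which an overlapping peak exists.

    ``categories`` maps scan name -> category label (e.g. overall / specific
    / trait-mean); per-category counts and the total are reported. The
    unique-QTL count merges all peaks across scans by single linkage under
    the same distance-and-LD rule.
    """
    categories = dict(categories or {})
    cats = sorted(set(categories.values())) or ["all"]
    labels = list(loci.entries["label"])
    counts = pd.DataFrame(0, index=pd.Index(labels, name="locus"), columns=cats)
    for scan_name, peaks in peak_sets.items():
        cat = categories.get(scan_name, cats[0])
        report = overlap_qtl(
            peaks, loci, genotypes, max_dist_bp=max_dist_bp, min_r2=min_r2
        )
        hit = report.table.groupby("hub_label")["overlaps"].any()
        for label in labels:
            if bool(hit.get(label, False)):
                counts.loc[label, cat] += 1
    counts["total"] = counts[cats].sum(axis=1)

    all_peaks = [p for peaks in peak_sets.values() for p in peaks]
    uf = _UnionFind(len(all_peaks))
    for i in range(len(all_peaks)):
        for j in range(i + 1, len(all_peaks)):
            a, b = all_peaks[i], all_peaks[j]
            if a.chromosome != b.chromosome:
                continue
            if abs(a.position_bp - b.position_bp) > max_dist_bp:
                continue
            if ld_r2(genotypes, a.lead_marker_id, b.lead_marker_id) > min_r2:
                uf.union(i, j)
    n_unique = len({uf.find(i) for i in range(len(all_peaks))})
    return DetectionSummary(counts, n_unique)


def hub_effect_profile(
    phenos: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    hub_marker,
    interactor_counts: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray | None = None,
) -> HubProfile:
    """Correlate a hub's per-environment additive effect with its number of
    active epistatic interactors.

    The per-environment effect is the hub marker's LMM estimate from a scan
    of that environment's growth phenotype (kinship defaults to the
    frequency-weighted matrix of the supplied genotypes). Requires E >= 3;
    constant interactor counts leave the correlation undefined (flagged).
    """
    counts = np.asarray(interactor_counts, dtype=float)
    e = phenos.n_env
    if e < 3:
        raise ValueError("need at least 3 environments for a correlation")
    if len(counts) != e:
        raise ValueError("interactor count vector length != E")
    if kinship is None:
        from .varcomp import kinship_freq_weighted

        kinship = kinship_freq_weighted(genotypes)
    eig = eigen_kinship(kinship)
    idx = _marker_index(genotypes, hub_marker)
    # restrict the scan to the hub marker; the kinship stays genome-wide
    mp = genotypes.map
    sub = GenotypeMatrix(
        genotypes.values[:, [idx]],
        genotypes.row_ids,
        type(mp)(mp.marker_id[[idx]], mp.chromosome[[idx]], mp.position_bp[[idx]]),
    )
    betas = np.empty(e)
    for j, label in enumerate(phenos.environment_labels):
        y = phenos.values[:, j]
        if np.isnan(y).any():
            raise ValueError(f"missing growth values in environment {label!r}")
        scan = gwa_scan(y, sub, eig, phenotype=str(label))
        betas[j] = scan.table["beta"].iloc[0]
    if np.ptp(counts) == 0:
        logger.warning("interactor counts constant: correlation undefined")
        return HubProfile(
            phenos.environment_labels.copy(), betas, counts, np.nan, np.nan, True
        )
    r, p = stats.pearsonr(betas, counts)
    return HubProfile(
        phenos.environment_labels.copy(), betas, counts, float(r), float(p), False
    )
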