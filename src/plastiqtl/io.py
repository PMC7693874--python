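"""Readers, writers and validated containers for genotype/phenotype data.

On-disk formats are plain tab-delimited text so that every artifact is
portable and diff-able:

* genotypes  — individuals in rows, markers in columns, header row of marker
  ids, first column ``id``; values are haploid dosages in ``{0, 2}`` (minor /
  major parental allele).
* marker map — columns ``marker_id``, ``chrom``, ``pos`` (1-based bp).
* phenotypes — first column ``id``, one column per environment; ``NA`` marks
  a missing value.
* hub lists  — columns ``label``, ``chrom``, ``pos``.
* scans      — columns ``marker_id``, ``chrom``, ``pos``, ``beta``, ``se``,
  ``stat``, ``pvalue``.

PLINK .bed/.bim/.fam is supported read-only as a convenience; diploid 0/1/2
dosages are accepted only when no heterozygous calls occur, as expected for a
haploid cross, and are kept on the 0/2 scale.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "HubList",
    "get_logger",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_hubs",
    "write_hubs",
    "read_scan",
    "write_scan",
]


def get_logger(name: str = "plastiqtl") -> logging.Logger:
    """Package logger; structured single-line records to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


class CodingError(ValueError):
    """Genotype value outside the haploid {0, 2} coding."""


class AlignmentError(ValueError):
    """Row ids of two containers do not match."""


@dataclass(frozen=True)
class MarkerMap:
    """Genomic coordinates of the genotyped markers.

    Positions are 1-based physical bp; within each chromosome they must be
    strictly increasing so that physical-distance rules (e.g. the 50 kb
    overlap window) are well defined.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(mid) == len(chrom) == len(pos)):
            raise ValueError("marker map columns have unequal lengths")
        if len(np.unique(mid)) != len(mid):
            raise ValueError("marker ids are not unique")
        if np.any(pos < 0):
            raise ValueError("negative bp position in marker map")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    def __len__(self) -> int:
        return len(self.marker_id)

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker_id)
        if hits.size == 0:
            raise KeyError(f"unknown marker id {marker_id!r}")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chromosome,
                "pos": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """n segregants x M markers of haploid dosages coded 0/2.

    Markers must be polymorphic (minor allele count > 0) — monomorphic
    columns break the frequency-weighted kinship and LD computations and are
    rejected up front.
    """

    values: np.ndarray
    row_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        ids = np.asarray(self.row_ids, dtype=object)
        if vals.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n, m = vals.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 and M >= 1, got {n} x {m}")
        bad = ~np.isin(vals, (0, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CodingError(
                f"non-{{0,2}} genotype value {vals[i, j]!r} at row "
                f"{ids[i]!r}, marker {self.map.marker_id[j]!r}"
            )
        if len(ids) != n:
            raise ValueError("row_ids length does not match genotype rows")
        if len(np.unique(ids)) != n:
            raise ValueError("duplicate segregant ids")
        if len(self.map) != m:
            raise ValueError(
                f"marker map length {len(self.map)} != marker count {m}"
            )
        mono = np.flatnonzero(vals.min(axis=0) == vals.max(axis=0))
        if mono.size:
            raise ValueError(
                "monomorphic markers after QC: "
                + ", ".join(map(str, self.map.marker_id[mono[:5]]))
            )
        object.__setattr__(self, "values", vals.astype(np.int8))
        object.__setattr__(self, "row_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the allele coded 2 (haploid dosage x/2)."""
        return self.values.mean(axis=0) / 2.0


@dataclass(frozen=True)
class PhenotypeMatrix:
    """n segregants x E environments of normalized growth.

    Missing values are NaN — explicit, never silent zeros. ``row_ids`` must
    align with the genotype container they are analyzed against.
    """

    values: np.ndarray
    row_ids: np.ndarray
    environment_labels: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.row_ids, dtype=object)
        labels = np.asarray(self.environment_labels, dtype=object)
        if vals.ndim != 2:
            raise ValueError("phenotype values must be 2-D")
        if vals.shape[0] != len(ids):
            raise ValueError("row_ids length does not match phenotype rows")
        if vals.shape[1] != len(labels):
            raise ValueError("environment label count does not match columns")
        if len(labels) == 0:
            raise ValueError("zero environments")
        if len(np.unique(labels)) != len(labels):
            raise ValueError("duplicate environment labels")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate segregant ids")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_ids", ids)
        object.__setattr__(self, "environment_labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_env(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        hits = np.flatnonzero(self.environment_labels == label)
        if hits.size == 0:
            raise KeyError(f"unknown environment label {label!r}")
        return self.values[:, int(hits[0])]

    def check_aligned(self, genotypes: GenotypeMatrix) -> None:
        if self.values.shape[0] != genotypes.n or np.any(
            self.row_ids != genotypes.row_ids
        ):
            missing = sorted(set(self.row_ids) ^ set(genotypes.row_ids))
            raise AlignmentError(
                "phenotype/genotype row ids differ"
                + (f"; unmatched ids: {missing[:10]}" if missing else " in order")
            )


@dataclass(frozen=True)
class HubList:
    """Named epistatic-network hub loci given by genomic position."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "chrom", "pos"])
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        for col in ("label", "chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"hub list missing column {col!r}")
        df = df.reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        object.__setattr__(self, "entries", df)

    def __len__(self) -> int:
        return len(self.entries)

    def resolve_markers(
        self, genotypes: GenotypeMatrix, max_dist_bp: int = 10_000
    ) -> pd.DataFrame:
        """Resolve each hub to its nearest genotyped marker.

        Fails loudly (ValueError) when the nearest marker on the hub's
        chromosome is farther than ``max_dist_bp``.
        """
        mp = genotypes.map
        rows = []
        for _, hub in self.entries.iterrows():
            on_chrom = np.flatnonzero(mp.chromosome == hub["chrom"])
            if on_chrom.size == 0:
                raise ValueError(
                    f"hub {hub['label']!r}: no markers on chromosome {hub['chrom']!r}"
                )
            d = np.abs(mp.position_bp[on_chrom] - hub["pos"])
            k = on_chrom[np.argmin(d)]
            if d.min() > max_dist_bp:
                raise ValueError(
                    f"hub {hub['label']!r} at {hub['chrom']}:{hub['pos']} is "
                    f"{d.min()} bp from the nearest marker (cap {max_dist_bp})"
                )
            rows.append(
                {
                    "label": hub["label"],
                    "chrom": hub["chrom"],
                    "pos": int(hub["pos"]),
                    "marker_id": mp.marker_id[k],
                    "marker_index": int(k),
                    "marker_pos": int(mp.position_bp[k]),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["label", "chrom", "pos", "marker_id", "marker_index", "marker_pos"],
        )


# ---------------------------------------------------------------------------
# tab-delimited readers / writers


def _map_path(path: str | Path) -> Path:
    return Path(str(path) + ".map")


def read_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    return MarkerMap(
        df["marker_id"].to_numpy(object),
        df["chrom"].to_numpy(object),
        df["pos"].to_numpy(np.int64),
    )


def write_map(mp: MarkerMap, path: str | Path) -> None:
    mp.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, format_flag: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``format_flag='tsv'`` expects the tab-delimited matrix at ``path`` with a
    companion map file at ``path + '.map'``. ``format_flag='plink'`` expects
    ``path`` to be the PLINK prefix of a .bed/.bim/.fam triple.
    """
    if format_flag == "plink":
        return _read_plink(path)
    if format_flag != "tsv":
        raise ValueError(f"unknown genotype format {format_flag!r}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("genotype file must have a leading 'id' column")
    ids = df["id"].to_numpy(object)
    vals = df.drop(columns="id").to_numpy()
    mp = read_map(_map_path(path))
    if not np.array_equal(np.asarray(df.columns[1:], dtype=object), mp.marker_id):
        raise ValueError("genotype header marker ids do not match the map file")
    return GenotypeMatrix(vals, ids, mp)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.values, columns=g.map.marker_id)
    df.insert(0, "id", g.row_ids)
    df.to_csv(path, sep="\t", index=False)
    write_map(g.map, _map_path(path))


def _read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Minimal PLINK1 .bed/.bim/.fam reader (SNP-major .bed only).

    Heterozygous calls or missing genotypes are rejected: the expected input
    is a haploid cross exported with homozygous diploid coding, which maps
    0/2 dosage -> 0/2 haploid dosage unchanged.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str
    )
    ids = fam[1].to_numpy(object)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError("not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # 2-bit codes per individual: 00=hom a1, 01=missing, 10=het, 11=hom a2
    shifts = (2 * (np.arange(n) % 4)).astype(np.uint8)
    codes = (body[:, np.arange(n) // 4] >> shifts) & 0b11
    if np.any(codes == 1):
        raise ValueError("missing genotypes in .bed are not supported")
    if np.any(codes == 2):
        raise CodingError(
            "heterozygous calls found; expected a haploid cross coded 0/2"
        )
    vals = np.where(codes == 3, 2, 0).T  # hom a2 -> dosage 2
    mp = MarkerMap(
        bim["marker_id"].to_numpy(object),
        bim["chrom"].to_numpy(object),
        bim["pos"].to_numpy(np.int64),
    )
    return GenotypeMatrix(vals, ids, mp)


def read_phenotypes(
    path: str | Path, genotypes: GenotypeMatrix | None = None
) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    if "id" not in df.columns:
        raise ValueError("phenotype file must have a leading 'id' column")
    if df.shape[1] < 2:
        raise ValueError("phenotype file has zero environment columns")
    phenos = PhenotypeMatrix(
        df.drop(columns="id").to_numpy(float),
        df["id"].to_numpy(object),
        np.asarray(df.columns[1:], dtype=object),
    )
    if genotypes is not None:
        extra = sorted(set(phenos.row_ids) - set(genotypes.row_ids))
        if extra:
            raise AlignmentError(f"phenotype ids absent from genotypes: {extra[:10]}")
        order = {sid: k for k, sid in enumerate(phenos.row_ids)}
        idx = np.array([order[sid] for sid in genotypes.row_ids])
        phenos = PhenotypeMatrix(
            phenos.values[idx], genotypes.row_ids, phenos.environment_labels
        )
    return phenos


def write_phenotypes(p: PhenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(p.values, columns=p.environment_labels)
    df.insert(0, "id", p.row_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.15g")


SCAN_COLUMNS = ["marker_id", "chrom", "pos", "beta", "se", "stat", "pvalue"]


def write_scan(scan, path: str | Path) -> None:
    """Write a GwasScan's per-marker table (fixed 7-column header)."""
    df = scan.table if hasattr(scan, "table") else pd.DataFrame(scan)
    df[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan file missing columns {missing}")
    return df


def read_hubs(path: str | Path) -> HubList:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "chrom": str})
    hubs = HubList(df)
    if len(hubs) == 0:
        get_logger().warning("hub file %s is empty", path)
    return hubs


def write_hubs(hubs: HubList, path: str | Path) -> None:
    hubs.entries[["label", "chrom", "pos"]].to_csv(path, sep="\t", index=False)
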