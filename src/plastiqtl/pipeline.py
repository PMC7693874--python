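"""One-command orchestration of the plasticity-QTL workflow.

Stages: obtain data (simulate or read) -> plasticity measures -> kinship ->
heritability per phenotype -> association scans (trait means, overall
measures, specific measures) with the Me-based threshold and conditional
analysis -> peak detection -> hub overlap and detection frequency -> summary
tables. Every stage writes its artifact under the output directory and the
manifest lists them all; the run is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import assoc, networks, plasticity, simulate, varcomp
from . import io as pio

__all__ = ["RunConfig", "RunSummary", "run"]

logger = pio.get_logger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source must be set: ``sim`` (a SimConfig) or
    ``genotypes_path``/``phenotypes_path``. ``threshold_mode`` is "me"
    (alpha over the effective marker number), "bonferroni" (alpha over M) or
    a numeric cutoff.
    """

    outdir: Path
    seed: int = 1
    sim: simulate.SimConfig | None = None
    genotypes_path: Path | None = None
    phenotypes_path: Path | None = None
    hubs_path: Path | None = None
    measures: str = "all"
    scan_trait_means: bool = True
    conditional: bool = True
    threshold_mode: str | float = "me"
    alpha: float = 0.05
    merge_kb: float = 100.0
    write_scans: str = "overall"  # "all" | "overall" | "none"

    def __post_init__(self) -> None:
        simulated = self.sim is not None
        real = self.genotypes_path is not None or self.phenotypes_path is not None
        if simulated == real:
            raise ValueError(
                "exactly one of a simulation config or real input paths is required"
            )
        if real and (self.genotypes_path is None or self.phenotypes_path is None):
            raise ValueError("real input needs both genotype and phenotype paths")
        object.__setattr__(self, "outdir", Path(self.outdir))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "sim" in raw:
            s = dict(raw.pop("sim"))
            preset = s.pop("preset", None)
            hub = s.pop("hub", None)
            if preset == "desk":
                if hub:  # hub: true, or a mapping of hub_architecture kwargs
                    n_env = s.get("n_environments", 18)
                    kwargs = hub if isinstance(hub, dict) else {}
                    s["architecture"] = simulate.hub_architecture(n_env, **kwargs)
                sim = simulate.desk_preset(seed=raw.get("seed", 1), **s)
            else:
                if hub:
                    raise ValueError("hub shorthand requires the desk preset")
                s["chromosomes"] = tuple(
                    simulate.ChromosomeSpec(*c) for c in s["chromosomes"]
                )
                sim = simulate.SimConfig(**s)
        for key in ("outdir", "genotypes_path", "phenotypes_path", "hubs_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(sim=sim, **raw)


@dataclass(frozen=True)
class RunSummary:
    """Headline numbers of a run; every value is recomputable from the
    per-stage files listed in the manifest."""

    n_qtl: Mapping[str, int]            # unique QTL per scan category
    n_scans: Mapping[str, int]
    heritability: pd.DataFrame          # index phenotype; columns h2, sigma_g2, ...
    Me: float
    cutoff: float
    hub_overlap: pd.DataFrame | None    # per-hub detection counts
    hub_profile: networks.HubProfile | None
    manifest: Mapping[str, str] = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# Run summary", ""]
        lines.append(f"- effective markers Me = {self.Me:.1f}")
        lines.append(f"- significance cutoff = {self.cutoff:.3g}")
        for cat in sorted(self.n_scans):
            lines.append(
                f"- {cat}: {self.n_scans[cat]} scans, "
                f"{self.n_qtl.get(cat, 0)} unique significant QTL"
            )
        if self.hub_profile is not None and not self.hub_profile.undefined:
            lines.append(
                f"- hub effect-vs-interactors correlation R = "
                f"{self.hub_profile.correlation:.2f} (p = {self.hub_profile.pvalue:.2g})"
            )
        lines.append("")
        lines.append("## Heritability (overall measures and trait means)")
        lines.append("```\n" + self.heritability.round(3).to_string() + "\n```")
        if self.hub_overlap is not None:
            lines.append("")
            lines.append("## Hub detection frequency")
            lines.append("```\n" + self.hub_overlap.to_string() + "\n```")
        return "\n".join(lines) + "\n"


def _categorize(name: str) -> str:
    if name in plasticity.OVERALL_MEASURES:
        return "overall"
    if name.startswith(("DIFF(", "DOT(")):
        return "specific"
    return "trait_mean"


def run(config: RunConfig) -> RunSummary:
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save(key: str, name: str) -> Path:
        path = out / name
        manifest[key] = name
        return path

    # --- stage 1: data -----------------------------------------------------
    truth: simulate.SimTruth | None = None
    hubs: pio.HubList | None = None
    if config.sim is not None:
        genotypes = simulate.simulate_cross(config.sim)
        phenos, truth = simulate.simulate_phenotypes(genotypes, config.sim)
        pio.write_genotypes(genotypes, save("genotypes", "genotypes.tsv"))
        pio.write_phenotypes(phenos, save("phenotypes", "phenotypes.tsv"))
        if truth.architecture.hubs:
            mp = genotypes.map
            hubs = pio.HubList(
                pd.DataFrame(
                    {
                        "label": [
                            f"hub_{mp.marker_id[h.marker_index]}"
                            for h in truth.architecture.hubs
                        ],
                        "chrom": [
                            mp.chromosome[h.marker_index]
                            for h in truth.architecture.hubs
                        ],
                        "pos": [
                            int(mp.position_bp[h.marker_index])
                            for h in truth.architecture.hubs
                        ],
                    }
                )
            )
            pio.write_hubs(hubs, save("hubs", "hubs.tsv"))
    else:
        genotypes = pio.read_genotypes(config.genotypes_path)
        phenos = pio.read_phenotypes(config.phenotypes_path, genotypes)
        if config.hubs_path is not None:
            hubs = pio.read_hubs(config.hubs_path)

    # --- stage 2: plasticity measures -------------------------------------
    table = plasticity.all_plasticity(phenos, measures=config.measures)
    table.to_csv(save("plasticity", "plasticity.tsv"), sep="\t", float_format="%.10g")

    # --- stage 3: kinship + threshold --------------------------------------
    kin = varcomp.kinship_freq_weighted(genotypes)
    eig = varcomp.eigen_kinship(kin)
    me = assoc.effective_markers(genotypes)
    if config.threshold_mode == "me":
        threshold = assoc.significance_threshold(me, config.alpha)
    elif config.threshold_mode == "bonferroni":
        threshold = assoc.significance_threshold(genotypes.n_markers, config.alpha)
    else:
        threshold = assoc.Threshold(
            Me=config.alpha / float(config.threshold_mode), alpha=config.alpha
        )
    (save("threshold", "threshold.json")).write_text(
        json.dumps(
            {"Me": me, "alpha": threshold.alpha, "cutoff": threshold.cutoff}, indent=2
        )
    )

    # --- stage 4: phenotype book -------------------------------------------
    phenotypes: dict[str, np.ndarray] = {}
    if config.scan_trait_means:
        for j, label in enumerate(phenos.environment_labels):
            phenotypes[str(label)] = phenos.values[:, j]
    for col in table.columns:
        phenotypes[col] = table[col].to_numpy()

    # --- stage 5: heritability + scans -------------------------------------
    rot = eig.U.T @ genotypes.values.astype(float)
    h2_rows = []
    peaks_by_scan: dict[str, list[assoc.QtlPeak]] = {}
    categories: dict[str, str] = {}
    peak_rows = []
    for name, y in phenotypes.items():
        cat = _categorize(name)
        categories[name] = cat
        ok = ~np.isnan(y)
        if not ok.all():
            # per-analysis complete-case subset needs its own eigensystem
            sub_kin = varcomp.KinshipMatrix(
                kin.values[np.ix_(ok, ok)], kin.row_ids[ok]
            )
            sub_eig = varcomp.eigen_kinship(sub_kin)
            sub_geno = pio.GenotypeMatrix(
                genotypes.values[ok], genotypes.row_ids[ok], genotypes.map
            )
            sub_rot = sub_eig.U.T @ sub_geno.values.astype(float)
        else:
            sub_eig, sub_geno, sub_rot = eig, genotypes, rot
        yv = y[ok]
        scan = assoc.gwa_scan(
            yv, sub_geno, sub_eig, phenotype=name, rotated_genotypes=sub_rot
        )
        vc = scan.varcomp
        scan_peaks = assoc.detect_peaks(scan, threshold, config.merge_kb)
        if config.conditional and scan_peaks:
            result = assoc.conditional_scan(
                yv, sub_geno, sub_eig,
                peak_leads=[p.lead_marker_id for p in scan_peaks],
                threshold=threshold, merge_kb=config.merge_kb, phenotype=name,
                rotated_genotypes=sub_rot,
            )
            # conditional leads not already among first-pass peaks become
            # their own single-marker peaks
            known = {p.lead_marker_id for p in scan_peaks}
            for lead in set(result.leads) - known:
                k = sub_geno.map.index_of(lead)
                scan_peaks.append(
                    assoc.QtlPeak(
                        lead,
                        str(sub_geno.map.chromosome[k]),
                        int(sub_geno.map.position_bp[k]),
                        float(scan.table["pvalue"].iloc[k]),
                        (
                            int(sub_geno.map.position_bp[k]),
                            int(sub_geno.map.position_bp[k]),
                        ),
                    )
                )
        peaks_by_scan[name] = scan_peaks
        h2_rows.append(
            {
                "phenotype": name,
                "category": cat,
                "h2": vc.h2,
                "sigma_g2": vc.sigma_g2,
                "sigma_e2": vc.sigma_e2,
                "at_boundary": vc.at_boundary,
            }
        )
        for p in scan_peaks:
            peak_rows.append(
                {
                    "scan": name,
                    "category": cat,
                    "marker_id": p.lead_marker_id,
                    "chrom": p.chromosome,
                    "pos": p.position_bp,
                    "pvalue": p.lead_pvalue,
                    "span_start": p.span[0],
                    "span_end": p.span[1],
                }
            )
        if config.write_scans == "all" or (
            config.write_scans == "overall" and cat in ("overall", "trait_mean")
        ):
            pio.write_scan(scan, save(f"scan:{name}", f"scan_{name}.tsv"))

    h2_table = pd.DataFrame(h2_rows).set_index("phenotype")
    h2_table.to_csv(save("heritability", "heritability.tsv"), sep="\t",
                    float_format="%.6g")
    pd.DataFrame(
        peak_rows,
        columns=["scan", "category", "marker_id", "chrom", "pos", "pvalue",
                 "span_start", "span_end"],
    ).to_csv(save("peaks", "peaks.tsv"), sep="\t", index=False)

    # --- stage 6: unique QTL per category ----------------------------------
    n_qtl: dict[str, int] = {}
    n_scans: dict[str, int] = {}
    for cat in sorted(set(categories.values())):
        sets = {k: v for k, v in peaks_by_scan.items() if categories[k] == cat}
        n_scans[cat] = len(sets)
        if hubs is not None and len(hubs):
            summary = networks.detection_frequency(sets, hubs, genotypes)
            n_qtl[cat] = summary.n_unique_qtl
        else:
            all_p = [p for ps in sets.values() for p in ps]
            n_qtl[cat] = networks.detection_frequency(
                {"_": all_p}, pio.HubList(), genotypes
            ).n_unique_qtl

    # --- stage 7: hub overlap + profile ------------------------------------
    hub_counts = None
    profile = None
    if hubs is not None and len(hubs):
        summary = networks.detection_frequency(
            peaks_by_scan, hubs, genotypes, categories=categories
        )
        hub_counts = summary.counts
        hub_counts.to_csv(save("hub_detection", "hub_detection.tsv"), sep="\t")
        overall_peaks = [
            p
            for name, ps in peaks_by_scan.items()
            if categories[name] == "overall"
            for p in ps
        ]
        report = networks.overlap_qtl(overall_peaks, hubs, genotypes)
        report.table.to_csv(
            save("overlap_overall", "overlap_overall.tsv"), sep="\t", index=False
        )
    if truth is not None and truth.architecture.hubs and config.scan_trait_means:
        hub = truth.architecture.hubs[0]
        profile = networks.hub_effect_profile(
            phenos,
            genotypes,
            hub.marker_index,
            truth.hub_interactor_counts[0],
            kinship=eig,
        )
        pd.DataFrame(
            {
                "environment": profile.environments,
                "beta": profile.beta,
                "interactors": profile.interactor_count,
            }
        ).to_csv(save("hub_profile", "hub_profile.tsv"), sep="\t", index=False)

    summary = RunSummary(
        n_qtl=n_qtl,
        n_scans=n_scans,
        heritability=h2_table,
        Me=me,
        cutoff=threshold.cutoff,
        hub_overlap=hub_counts,
        hub_profile=profile,
        manifest=manifest,
    )
    (out / "summary.md").write_text(summary.to_markdown())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return summary
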