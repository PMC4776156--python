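"""Run configuration, report rendering, and the end-to-end pipeline driver.

``run_pipeline`` executes the narrative order of the analysis: simulate a
dataset, process each replicate's reads into site profiles, quantify
replicate concordance, call significant interaction domains on the
reproducible sites, and run the association statistics — writing tabular
outputs plus a machine-readable JSON report.  Reruns under the same config
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import enrichment_analysis, snp_proximity
from .domains import DomainParams, call_domains
from .processing import (
    FragmentEndIndex,
    SiteProfile,
    cis_trans_summary,
    process_fastq,
    reproducible_sites,
)
from .qc import bin_densities, overlap_rate, pearson_correlation, random_overlap_simulation
from .simulate import (
    PlantedDomain,
    SimConfig,
    simulate_chip_tags,
    simulate_contact_profile,
    simulate_genome,
    simulate_reads,
    simulate_snps,
)


@dataclass
class ProcessParams:
    max_mismatches: int = 0
    min_payload: int = 16
    exclusion_fragments: int = 2


@dataclass
class QCParams:
    cis_bin: int = 1_000_000
    trans_bin: int = 2_000_000
    n_random_sets: int = 10
    log1p: bool = False


@dataclass
class AssociationParams:
    flank: int = 500_000
    norm_total: float = 10_000_000.0
    n_random_draws: int = 1


@dataclass
class RunConfig:
    """All stage parameters with the published defaults (primer architecture,
    windows 500/200/5,000, α=0.05, ±500 kb flank, 1/2 Mb bins, 10 random sets)."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    process: ProcessParams = field(default_factory=ProcessParams)
    qc: QCParams = field(default_factory=QCParams)
    domains: DomainParams = field(default_factory=DomainParams)
    association: AssociationParams = field(default_factory=AssociationParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, section: dict):
            allowed = {f.name for f in fields(klass)}
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**section)

        data = dict(data)
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_section = dict(data.get("sim", {}))
        domains_spec = sim_section.get("planted_domains")
        if domains_spec is not None:
            sim_section["planted_domains"] = [
                PlantedDomain(d["chrom"], int(d["start_index"]), int(d["end_index"]), float(d["fold"]))
                for d in domains_spec
            ]
        return cls(
            seed=int(data.get("seed", 0)),
            sim=build(SimConfig, sim_section),
            process=build(ProcessParams, dict(data.get("process", {}))),
            qc=build(QCParams, dict(data.get("qc", {}))),
            domains=build(DomainParams, dict(data.get("domains", {}))),
            association=build(AssociationParams, dict(data.get("association", {}))),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def resolved_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))


def _plain(obj: Any) -> Any:
    """Convert to pure-Python JSON/YAML-serializable values."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed indentation, plain types."""
    with open(path, "w") as handle:
        json.dump(_plain(obj), handle, sort_keys=True, indent=2)
        handle.write("\n")


def count_pct(part: int, total: int) -> str:
    """Render "n (p%)" with the percentage recomputed from the counts."""
    pct = 0.0 if total == 0 else 100 * part / total
    return f"{part:,} ({pct:.1f}%)"


def render_table1(rows: list[dict]) -> pd.DataFrame:
    """Summary table in the published layout; every percentage is derived
    from the integer counts at render time.

    Each row dict carries: label, reads, sites, cis_sites and optionally
    overlapping_sites, overlapping_cis_sites.
    """
    out = []
    for row in rows:
        sites = int(row["sites"])
        cis = int(row["cis_sites"])
        rec = {
            "replicate": row["label"],
            "reads": f"{int(row['reads']):,}",
            "non_random_sites": f"{sites:,}",
            "cis_sites": count_pct(cis, sites),
            "trans_sites": count_pct(sites - cis, sites),
        }
        if row.get("overlapping_sites") is not None:
            ov = int(row["overlapping_sites"])
            ov_cis = int(row["overlapping_cis_sites"])
            rec["overlapping_sites"] = f"{ov:,}"
            rec["overlapping_cis_sites"] = count_pct(ov_cis, ov)
            rec["overlapping_trans_sites"] = count_pct(ov - ov_cis, ov)
        else:
            rec["overlapping_sites"] = ""
            rec["overlapping_cis_sites"] = ""
            rec["overlapping_trans_sites"] = ""
        out.append(rec)
    return pd.DataFrame(out)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """simulate → process (×2 replicates) → qc → call-domains → associate → report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_r1, rng_r2, rng_tags, rng_snps, rng_qc, rng_assoc = (
        np.random.default_rng(child) for child in ss.spawn(7)
    )

    # --- simulate ---------------------------------------------------------
    sim = config.sim
    genome, library = simulate_genome(sim, rng_genome)
    genome.to_fasta(outdir / "genome.fa")
    library.to_bed(outdir / "sites.bed")
    truth = simulate_contact_profile(library, sim)
    truth.to_tsv(outdir / "truth.tsv")
    fastqs = {}
    for replicate, rng in (("rep1", rng_r1), ("rep2", rng_r2)):
        path = outdir / f"reads_{replicate}.fastq"
        simulate_reads(truth, genome, library, sim, replicate, rng, fastq_path=path)
        fastqs[replicate] = path
    tags = simulate_chip_tags(library, truth, sim, rng_tags)
    tags.to_csv(outdir / "tags.bed", sep="\t", header=False, index=False)
    snps = simulate_snps(library, truth, sim, rng_snps)
    snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)

    # --- process ----------------------------------------------------------
    index = FragmentEndIndex(genome, library)
    profiles: dict[str, SiteProfile] = {}
    for replicate, path in fastqs.items():
        profile = process_fastq(
            path,
            index,
            library,
            replicate,
            truth.bait_chrom,
            truth.bait_pos,
            primer=sim.primer_readthrough,
            max_mismatches=config.process.max_mismatches,
            min_payload=config.process.min_payload,
            exclusion_fragments=config.process.exclusion_fragments,
        )
        profile.to_table(outdir / f"sites_{replicate}.tsv")
        profiles[replicate] = profile

    shared = reproducible_sites(profiles["rep1"], profiles["rep2"])
    shared_summary = cis_trans_summary(shared, truth.bait_chrom) if shared else None
    table_rows = []
    for replicate, profile in profiles.items():
        summary = cis_trans_summary(profile.sites, truth.bait_chrom)
        row = {
            "label": replicate,
            "reads": profile.stats.reads_in,
            "sites": summary["total"],
            "cis_sites": summary["cis_n"],
        }
        if replicate == "rep1" and shared_summary:
            row["overlapping_sites"] = shared_summary["total"]
            row["overlapping_cis_sites"] = shared_summary["cis_n"]
        table_rows.append(row)
    table1 = render_table1(table_rows)
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

    # --- qc ---------------------------------------------------------------
    densities = {
        replicate: bin_densities(
            profile.sites,
            truth.bait_chrom,
            library.chrom_lengths,
            config.qc.cis_bin,
            config.qc.trans_bin,
        )
        for replicate, profile in profiles.items()
    }
    r = pearson_correlation(densities["rep1"], densities["rep2"], log1p=config.qc.log1p)
    ov = overlap_rate(profiles["rep1"].sites, profiles["rep2"].sites)
    rand = random_overlap_simulation(
        library, ov.n_a, ov.n_b, n_sets=config.qc.n_random_sets, rng=rng_qc
    )
    ov.random_rates = rand.random_rates
    ov.random_median = rand.random_median
    qc_report = {
        "pearson_r": r,
        "overlap": ov.as_dict(),
        "cis_read_fraction": {
            replicate: _cis_read_fraction(profile) for replicate, profile in profiles.items()
        },
    }
    write_json(qc_report, outdir / "qc.json")

    # --- domains ----------------------------------------------------------
    call = call_domains(shared, library, truth.bait_chrom, config.domains)
    call.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    call.domains.to_csv(outdir / "domains.tsv", sep="\t", index=False, float_format="%.6g")
    call.domains_bed().to_csv(outdir / "domains.bed", sep="\t", header=False, index=False)

    # --- association ------------------------------------------------------
    enrich = enrichment_analysis(
        shared,
        {"planted_tags": tags},
        library,
        flank=config.association.flank,
        norm_total=config.association.norm_total,
        rng=rng_assoc,
        n_random_draws=config.association.n_random_draws,
    )
    prox = snp_proximity(shared, snps, library, rng=rng_assoc)
    association_report = {
        "enrichment": {name: res.as_dict() for name, res in enrich.items()},
        "snp_proximity": prox.as_dict(),
    }
    write_json(association_report, outdir / "association.json")

    # --- report -----------------------------------------------------------
    resolved = config.resolved_dict()
    with open(outdir / "config.resolved.yaml", "w") as handle:
        yaml.safe_dump(resolved, handle, sort_keys=True)
    config_hash = hashlib.sha256(
        yaml.safe_dump(resolved, sort_keys=True).encode()
    ).hexdigest()
    report = {
        "version": __version__,
        "config_sha256": config_hash,
        "stages": {replicate: p.stats.as_dict() for replicate, p in profiles.items()},
        "reproducible_sites": len(shared),
        "reproducible_summary": shared_summary,
        "qc": qc_report,
        "n_domains": int(len(call.domains)),
        "association": association_report,
    }
    write_json(report, outdir / "report.json")
    return report


def _cis_read_fraction(profile: SiteProfile) -> float:
    """cis/overall ratio of mapped reads (library QC; >40% marks a good run)."""
    if profile.stats.mapped == 0:
        return float("nan")
    return profile.stats.cis_reads_raw / profile.stats.mapped
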