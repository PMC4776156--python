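#!/usr/bin/env python
"""Process each replicate's reads into a site profile.

Primer-gate the reads at the 5' end, trim through the BglII junction, map the
captured payloads to the fragment-end library, merge reads per site, drop
single-read sites, intersect the replicates, and print the summary table
(reads, non-random sites, reproducible sites, cis/trans split).
"""

import argparse
import json
from pathlib import Path

from fourc.pipeline import RunConfig, render_table1, write_json
from fourc.processing import (
    FragmentEndIndex,
    cis_trans_summary,
    process_fastq,
    reproducible_sites,
)
from fourc.restriction import Genome, build_site_library

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=ROOT / "configs" / "demo.yaml")
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    config = RunConfig.from_yaml(args.config)
    manifest = json.loads((args.data / "manifest.json").read_text())
    genome = Genome.from_fasta(args.data / "genome.fa")
    library = build_site_library(genome)
    index = FragmentEndIndex(genome, library)

    profiles = {}
    for replicate in ("rep1", "rep2"):
        profile = process_fastq(
            args.data / f"reads_{replicate}.fastq",
            index,
            library,
            replicate,
            manifest["bait_chrom"],
            manifest["bait_pos"],
            primer=manifest["primer"],
            max_mismatches=config.process.max_mismatches,
            min_payload=config.process.min_payload,
            exclusion_fragments=config.process.exclusion_fragments,
        )
        profile.to_table(args.out / f"sites_{replicate}.tsv")
        profiles[replicate] = profile
        stats = profile.stats
        print(
            f"{replicate}: {stats.reads_in:,} reads in, "
            f"{stats.primer_passed:,} primer-passed, {stats.mapped:,} mapped "
            f"({100 * stats.mapped / max(1, stats.primer_passed):.1f}%), "
            f"{stats.sites_filtered:,} sites with coverage > 1, "
            f"cis read ratio {stats.cis_reads_raw / max(1, stats.mapped):.2f}"
        )

    shared = reproducible_sites(profiles["rep1"], profiles["rep2"])
    summary = cis_trans_summary(shared, manifest["bait_chrom"])
    print(
        f"reproducible sites: {summary['total']:,} "
        f"(cis {summary['cis_n']} = {summary['cis_pct']}%, "
        f"trans {summary['trans_n']} = {summary['trans_pct']}%)"
    )

    rows = []
    for replicate, profile in profiles.items():
        rep_summary = cis_trans_summary(profile.sites, manifest["bait_chrom"])
        row = {
            "label": replicate,
            "reads": profile.stats.reads_in,
            "sites": rep_summary["total"],
            "cis_sites": rep_summary["cis_n"],
        }
        if replicate == "rep1":
            row["overlapping_sites"] = summary["total"]
            row["overlapping_cis_sites"] = summary["cis_n"]
        rows.append(row)
    table = render_table1(rows)
    table.to_csv(args.out / "table1.tsv", sep="\t", index=False)
    write_json(
        {r: p.stats.as_dict() for r, p in profiles.items()}, args.out / "processing.json"
    )
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
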