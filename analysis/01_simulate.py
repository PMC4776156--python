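#!/usr/bin/env python
"""Generate the demonstration 4C-seq dataset.

Emits a miniature genome with planted BglII sites, the ground-truth contact
profile (power-law cis decay, uniform trans background, two fold-10 planted
domains), two replicates of inverse-PCR FASTQ reads, a ChIP-style tag track
enriched over the planted domains, and an index-SNP table — all seeded, under
results/data/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from fourc.pipeline import RunConfig, write_json
from fourc.simulate import (
    simulate_chip_tags,
    simulate_contact_profile,
    simulate_genome,
    simulate_reads,
    simulate_snps,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=ROOT / "configs" / "demo.yaml")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    config = RunConfig.from_yaml(args.config)
    sim = config.sim
    args.out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_r1, rng_r2, rng_tags, rng_snps = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    genome, library = simulate_genome(sim, rng_genome)
    genome.to_fasta(args.out / "genome.fa")
    library.to_bed(args.out / "sites.bed")
    library.to_site_table(args.out / "sites.tsv")
    truth = simulate_contact_profile(library, sim)
    truth.to_tsv(args.out / "truth.tsv")

    n_reads = {}
    for replicate, rng in (("rep1", rng_r1), ("rep2", rng_r2)):
        records, _counts = simulate_reads(
            truth, genome, library, sim, replicate, rng,
            fastq_path=args.out / f"reads_{replicate}.fastq",
        )
        n_reads[replicate] = len(records)

    tags = simulate_chip_tags(library, truth, sim, rng_tags)
    tags.to_csv(args.out / "tags.bed", sep="\t", header=False, index=False)
    snps = simulate_snps(library, truth, sim, rng_snps)
    snps.to_csv(args.out / "snps.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": str(args.config),
        "bait_chrom": truth.bait_chrom,
        "bait_pos": truth.bait_pos,
        "primer": sim.primer_readthrough,
        "n_sites": library.total_sites,
        "n_reads": n_reads,
        "n_tags": int(len(tags)),
        "n_snps": int(len(snps)),
        "planted_domains_bp": truth.domain_intervals_bp(library),
    }
    write_json(manifest, args.out / "manifest.json")

    print(f"genome: {len(genome.chromosomes)} chromosomes, "
          f"{sum(genome.lengths.values()):,} bp, {library.total_sites:,} BglII sites")
    print(f"bait at {truth.bait_chrom}:{truth.bait_pos:,}")
    for chrom, start, end in manifest["planted_domains_bp"]:
        print(f"planted domain {chrom}:{start:,}-{end:,}")
    for replicate, n in n_reads.items():
        print(f"{replicate}: {n:,} reads")
    print(f"{len(tags):,} tags, {len(snps)} SNPs -> {args.out}")


if __name__ == "__main__":
    main()
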