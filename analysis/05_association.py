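#!/usr/bin/env python
"""Association statistics around the reproducible sites.

Count tag-track tags within the flank around each reproducible site,
compare against size-matched random restriction sites (one-sided rank-sum,
'greater'), and test whether index SNPs lie closer to the reproducible sites
than to random sites (one-sided, 'less').
"""

import argparse
import json
from pathlib import Path

import numpy as np

from fourc.association import enrichment_analysis, snp_proximity
from fourc.formats import read_bed, read_snp_table
from fourc.pipeline import RunConfig, write_json
from fourc.processing import SiteProfile, reproducible_sites
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
    library = build_site_library(Genome.from_fasta(args.data / "genome.fa"))
    profiles = [
        SiteProfile.from_table(
            args.out / f"sites_{rep}.tsv", rep, manifest["bait_chrom"], manifest["bait_pos"]
        )
        for rep in ("rep1", "rep2")
    ]
    shared = reproducible_sites(*profiles)
    tags = read_bed(args.data / "tags.bed")
    snps = read_snp_table(args.data / "snps.tsv")

    rng = np.random.default_rng([config.seed, 50])
    enrich = enrichment_analysis(
        shared,
        {"planted_tags": tags},
        library,
        flank=config.association.flank,
        norm_total=config.association.norm_total,
        rng=rng,
        n_random_draws=config.association.n_random_draws,
        edge_exclusion=config.association.flank,
    )
    for name, res in enrich.items():
        print(
            f"{name}: query median {np.median(res.query_counts):,.0f} vs random "
            f"{np.median(res.random_counts):,.0f} normalized tags "
            f"(n = {len(res.query_counts)}), one-sided rank-sum p = {res.pvalue:.3e}"
        )

    prox = snp_proximity(shared, snps, library, rng=rng)
    print(
        f"SNP proximity: {prox.n_within_1mb}/{prox.n_snps} SNPs within 1 Mb of a "
        f"site, {prox.n_within_10kb} within 10 kb; rank-sum ('less') p = "
        f"{prox.pvalue:.3e}"
    )
    report = {
        "enrichment": {name: res.as_dict() for name, res in enrich.items()},
        "snp_proximity": prox.as_dict(),
    }
    write_json(report, args.out / "association.json")


if __name__ == "__main__":
    main()
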