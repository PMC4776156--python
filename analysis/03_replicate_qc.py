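#!/usr/bin/env python
"""Replicate-concordance QC.

Bin each replicate's interacting sites (1 Mb cis / 2 Mb trans), compute the
Pearson correlation between replicates, cluster the binned profiles
(complete linkage, Euclidean), and contrast the observed replicate overlap
rate with 10 random site sets of matched sizes.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from fourc.pipeline import RunConfig, write_json
from fourc.processing import SiteProfile
from fourc.qc import (
    bin_densities,
    cluster_samples,
    overlap_rate,
    pearson_correlation,
    random_overlap_simulation,
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
    library = build_site_library(Genome.from_fasta(args.data / "genome.fa"))

    profiles = {
        rep: SiteProfile.from_table(
            args.out / f"sites_{rep}.tsv", rep, manifest["bait_chrom"], manifest["bait_pos"]
        )
        for rep in ("rep1", "rep2")
    }
    densities = {
        rep: bin_densities(
            profile.sites,
            manifest["bait_chrom"],
            library.chrom_lengths,
            config.qc.cis_bin,
            config.qc.trans_bin,
        )
        for rep, profile in profiles.items()
    }
    r = pearson_correlation(densities["rep1"], densities["rep2"], log1p=config.qc.log1p)
    labels, linkage_matrix = cluster_samples(densities)

    observed = overlap_rate(profiles["rep1"].sites, profiles["rep2"].sites)
    rng = np.random.default_rng([config.seed, 30])
    random = random_overlap_simulation(
        library, observed.n_a, observed.n_b, n_sets=config.qc.n_random_sets, rng=rng
    )
    observed.random_rates = random.random_rates
    observed.random_median = random.random_median

    report = {
        "pearson_r": r,
        "cluster_labels": labels,
        "linkage": linkage_matrix.tolist(),
        "overlap": observed.as_dict(),
    }
    write_json(report, args.out / "qc.json")
    for rep, density in densities.items():
        density.to_csv(args.out / f"bins_{rep}.tsv", sep="\t", index=False)

    print(f"Pearson r between replicate bin profiles: {r:.3f}")
    print(
        f"replicate overlap: {observed.n_shared:,} shared of "
        f"{observed.n_a:,}/{observed.n_b:,} -> {observed.rate:.1f}%"
    )
    print(
        f"random site sets ({config.qc.n_random_sets}): median overlap "
        f"{observed.random_median:.2f}% "
        f"(range {min(observed.random_rates):.2f}-{max(observed.random_rates):.2f}%)"
    )


if __name__ == "__main__":
    main()
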