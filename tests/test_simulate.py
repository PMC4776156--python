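import numpy as np
import pytest

from fourc.restriction import end_sequence
from fourc.simulate import (
    PlantedDomain,
    SimConfig,
    simulate_chip_tags,
    simulate_contact_profile,
    simulate_genome,
    simulate_reads,
    simulate_site_counts,
    simulate_snps,
    synthetic_site_library,
)


def tiny_config(**kwargs) -> SimConfig:
    defaults = dict(
        n_chromosomes=3,
        chromosome_length=200_000,
        inter_site_spacing=2_000,
        reads_per_replicate=5_000,
        error_rate=0.0,
        seed=11,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def test_genome_deterministic_under_seed():
    a, _ = simulate_genome(tiny_config())
    b, _ = simulate_genome(tiny_config())
    assert a.chromosomes == b.chromosomes


def test_genome_record_count_and_site_density():
    config = tiny_config(n_chromosomes=3, chromosome_length=100_000)
    genome, library = simulate_genome(config)
    assert len(genome.chromosomes) == 3
    # spacing 2 kb over 100 kb -> about 50 sites
    for chrom in library.chroms:
        assert 40 <= library.n_sites(chrom) <= 55


def test_too_tight_spacing_rejected():
    with pytest.raises(ValueError):
        tiny_config(inter_site_spacing=10)


def test_truth_weights_normalized_and_bait_zone_zero(small_sim):
    config, _genome, library, truth = small_sim
    assert np.isclose(truth.ends["weight"].sum(), 1.0)
    zone = truth.ends[
        (truth.ends["chrom"] == truth.bait_chrom)
        & (abs(truth.ends["site_index"] - truth.bait_index) <= config.bait_exclusion_fragments)
    ]
    assert (zone["weight"] == 0).all()


def test_cis_decay_is_power_law():
    library = synthetic_site_library(2, 200)
    config = tiny_config(planted_domains=[], cis_read_fraction=None, trans_background=1e-4)
    truth = simulate_contact_profile(library, config)
    cis = truth.ends[(truth.ends["chrom"] == "chr1") & (truth.ends["side"] == "R")]
    w = cis.set_index("site_index")["weight"]
    bait = truth.bait_index
    # alpha = 1: doubling the distance halves the weight
    assert np.isclose(w[bait + 8] / w[bait + 4], 0.5)
    assert np.isclose(w[bait + 20] / w[bait + 10], 0.5)


def test_zero_trans_background():
    library = synthetic_site_library(2, 100)
    config = tiny_config(planted_domains=[], cis_read_fraction=None, trans_background=0.0)
    truth = simulate_contact_profile(library, config)
    trans = truth.ends[truth.ends["chrom"] != "chr1"]
    assert (trans["weight"] == 0).all()


def test_planted_trans_domain_fold_is_exact():
    library = synthetic_site_library(2, 500)
    dom = PlantedDomain("chr2", 100, 150, 5.0)
    config = tiny_config(planted_domains=[dom])
    truth = simulate_contact_profile(library, config)
    trans = truth.ends[truth.ends["chrom"] == "chr2"]
    inside = trans[(trans["site_index"] >= 100) & (trans["site_index"] < 150)]["weight"]
    outside = trans[(trans["site_index"] >= 150) | (trans["site_index"] < 100)]["weight"]
    assert np.isclose(inside.mean() / outside.mean(), 5.0)


def test_all_zero_weights_rejected():
    library = synthetic_site_library(1, 20)
    config = tiny_config(
        n_chromosomes=1,
        planted_domains=[],
        cis_read_fraction=None,
        trans_background=0.0,
        bait_exclusion_fragments=30,  # swallows the whole chromosome
    )
    with pytest.raises(ValueError):
        simulate_contact_profile(library, config)


def test_reads_error_free_payload_matches_fragment_end(small_sim, small_reads):
    config, genome, library, truth = small_sim
    records, counts = small_reads
    assert len(records) == counts.sum()  # conservation
    primer = config.primer_readthrough
    payload_len = config.read_length - len(primer)
    # reconstruct which end emitted the first block of reads
    first_end = truth.ends.iloc[np.flatnonzero(counts)[0]]
    name, seq = records[0]
    assert seq.startswith(primer)
    expected = end_sequence(
        genome, len(library.primary_motif), first_end["chrom"], int(first_end["pos"]),
        first_end["side"], payload_len,
    )
    assert seq[len(primer):] == expected


def test_reads_deterministic_and_replicates_distinct(small_sim):
    config, genome, library, truth = small_sim
    rec_a, _ = simulate_reads(truth, genome, library, config, "r", np.random.default_rng(5))
    rec_b, _ = simulate_reads(truth, genome, library, config, "r", np.random.default_rng(5))
    rec_c, _ = simulate_reads(truth, genome, library, config, "r", np.random.default_rng(6))
    assert rec_a == rec_b
    assert rec_a != rec_c


def test_replicate_counts_correlated(small_sim):
    config, _genome, _library, truth = small_sim
    rng = np.random.default_rng(0)
    a = simulate_site_counts(truth, config, rng)
    b = simulate_site_counts(truth, config, rng)
    nz = (a + b) > 0
    r = np.corrcoef(a[nz], b[nz])[0, 1]
    assert r > 0.5


def test_poisson_count_model_switch(small_sim):
    config, _genome, _library, truth = small_sim
    from dataclasses import replace

    poisson_cfg = replace(config, count_model="poisson")
    counts = simulate_site_counts(truth, poisson_cfg, np.random.default_rng(1))
    assert counts.sum() > 0
    # standardized residuals have unit variance under Poisson noise; NB with
    # k=10 would inflate them by 1 + mean/k
    mean = poisson_cfg.reads_per_replicate * truth.ends["weight"].to_numpy()
    hot = mean > 5
    z = (counts[hot] - mean[hot]) / np.sqrt(mean[hot])
    assert 0.5 < np.var(z) < 2.0


def test_chip_tags_fold_one_is_uniform(small_sim):
    _config, _genome, library, truth = small_sim
    config = tiny_config(n_tags=20_000)
    tags = simulate_chip_tags(library, truth, config, np.random.default_rng(3), fold=1.0)
    assert len(tags) == 20_000
    intervals = truth.domain_intervals_bp(library)
    domain_bp = sum(end - start for _c, start, end in intervals)
    genome_bp = sum(library.chrom_lengths.values())
    in_domains = sum(
        ((tags["chrom"] == c) & (tags["start"] >= s) & (tags["start"] < e)).sum()
        for c, s, e in intervals
    )
    expect = 20_000 * domain_bp / genome_bp
    sd = np.sqrt(expect * (1 - domain_bp / genome_bp))
    assert abs(in_domains - expect) < 4 * sd


def test_chip_tags_zero_requested(small_sim):
    _config, _genome, library, truth = small_sim
    tags = simulate_chip_tags(library, truth, tiny_config(), np.random.default_rng(0), n_tags=0)
    assert len(tags) == 0
    from fourc.association import count_tags_near_sites

    with pytest.raises(ValueError, match="no tags"):
        count_tags_near_sites({("chr1", 1000)}, tags)


def test_snps_placed_near_domains(small_sim):
    _config, _genome, library, truth = small_sim
    config = tiny_config(n_snps=200, snp_near_domain_frac=0.5, snp_domain_window=20_000)
    snps = simulate_snps(library, truth, config, np.random.default_rng(9))
    assert len(snps) == 200
    assert snps["id"].is_unique
    intervals = truth.domain_intervals_bp(library)
    near = 0
    for rec in snps.itertuples():
        for c, s, e in intervals:
            if rec.chrom == c and s - 20_000 <= rec.pos <= e + 20_000:
                near += 1
                break
    assert near >= 100  # at least the planted fraction
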