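from collections import Counter

import numpy as np
import pytest

from fourc.processing import (
    FragmentEndIndex,
    ProcessingStats,
    cis_trans_summary,
    count_sites,
    filter_primer_reads,
    filter_singletons,
    map_captures,
    process_fastq,
    reproducible_sites,
)
from fourc.restriction import Genome, build_site_library
from fourc.simulate import simulate_reads

PRIMER = "ATGGAAATCAAGCAGCAGATCT"


def test_primer_gate_keeps_and_trims():
    payload = "ACGTACGTACGTACGTACGT"
    kept, stats = filter_primer_reads([("r1", PRIMER + payload)], PRIMER)
    assert kept == [payload]
    assert (stats.reads_in, stats.primer_passed, stats.primer_failed) == (1, 1, 0)


def test_primer_gate_mismatch_handling():
    mutated = "C" + PRIMER[1:] + "ACGTACGT"
    kept0, stats0 = filter_primer_reads([("r", mutated)], PRIMER, max_mismatches=0)
    assert kept0 == [] and stats0.primer_failed == 1
    kept1, _ = filter_primer_reads([("r", mutated)], PRIMER, max_mismatches=1)
    assert kept1 == ["ACGTACGT"]


def test_primer_longer_than_read_tallied_separately():
    _kept, stats = filter_primer_reads([("r", "ACGT")], PRIMER)
    assert stats.primer_too_short == 1
    assert stats.reads_in == stats.primer_passed + stats.primer_failed + stats.primer_too_short


def _two_site_genome():
    """chrZ carries two recognition sites; the two right ends are distinct,
    but both left flanks are the identical sequence, so left-end payloads are
    ambiguous."""
    shared = "TTGACCAGTTGACCAGTTGACCAG"  # 24 bp identical left flank
    middle = "ACGGTCATCAAGGTCCAATCCGTA"
    right2 = "CCATTGAACGGTTCAAGCCTTGCA"
    seq = shared + "AGATCT" + middle + shared + "AGATCT" + right2
    return Genome([("chrZ", seq)])


def test_mapping_unique_and_ambiguous_hits():
    genome = _two_site_genome()
    library = build_site_library(genome, "AGATCT")
    assert library.n_sites("chrZ") == 2
    index = FragmentEndIndex(genome, library, key_length=16)
    p1, p2 = library.positions["chrZ"]
    # unique right-end payload maps to the first site
    middle_prefix = genome.sequence("chrZ")[p1 + 6 : p1 + 26]
    hits, stats = map_captures([middle_prefix], index)
    assert hits == [("chrZ", int(p1), "R")]
    # both left ends share their sequence -> ambiguous, discarded
    from fourc.restriction import revcomp

    left_payload = revcomp(genome.sequence("chrZ")[p1 - 20 : p1])
    hits, stats = map_captures([left_payload], index, stats=ProcessingStats())
    assert hits == [] and stats.ambiguous == 1
    # too-short payloads are tallied
    _hits, stats2 = map_captures(["ACGT"], index)
    assert stats2.payload_too_short == 1


def test_count_sites_multiset():
    s1, s2 = ("chr1", 10, "R"), ("chr2", 99, "L")
    profile = count_sites([s1, s1, s2], "rep", "chr1", 10)
    assert profile.counts == {s1: 2, s2: 1}
    empty = count_sites([], "rep", "chr1", 10)
    assert empty.counts == {}


def test_singleton_filter_rule():
    profile = count_sites([], "rep", "chr1", 0)
    profile.counts = {"s1": 1, "s2": 5, "s3": 2}
    assert filter_singletons(profile).counts == {"s2": 5, "s3": 2}
    profile.counts = {"a": 1, "b": 1}
    assert filter_singletons(profile).counts == {}


def test_reproducible_sites_is_intersection():
    a = count_sites([], "a", "chr1", 0)
    b = count_sites([], "b", "chr1", 0)
    a.counts = {"s1": 3, "s2": 2}
    b.counts = {"s2": 4, "s4": 2}
    assert reproducible_sites(a, b) == {"s2"}
    b.counts = dict(a.counts)
    assert reproducible_sites(a, b) == {"s1", "s2"}


@pytest.mark.parametrize(
    "total,cis,cis_pct,trans_pct",
    [
        (4_529, 403, 8.9, 91.1),
        (2_096, 208, 9.9, 90.1),
        (10, 0, 0.0, 100.0),
    ],
)
def test_cis_trans_summary_percentages(total, cis, cis_pct, trans_pct):
    sites = [("chrBait", i, "R") for i in range(cis)] + [
        ("chrOther", i, "R") for i in range(total - cis)
    ]
    summary = cis_trans_summary(sites, "chrBait")
    assert summary["cis_pct"] == cis_pct
    assert summary["trans_pct"] == trans_pct
    assert summary["cis_n"] + summary["trans_n"] == total


def test_cis_trans_summary_empty_errors():
    with pytest.raises(ValueError, match="no sites"):
        cis_trans_summary([], "chr1")


def test_end_to_end_mapping_rate_and_conservation(small_sim, tmp_path):
    config, genome, library, truth = small_sim
    rng = np.random.default_rng(13)
    fastq = tmp_path / "r1.fastq"
    _records, counts = simulate_reads(truth, genome, library, config, "r1", rng, fastq_path=fastq)
    index = FragmentEndIndex(genome, library)
    profile = process_fastq(
        fastq, index, library, "r1", truth.bait_chrom, truth.bait_pos,
        primer=config.primer_readthrough,
    )
    stats = profile.stats
    stats.check()
    assert stats.primer_passed == stats.reads_in  # error-free reads all pass
    assert stats.mapped >= 0.99 * stats.primer_passed
    # per-site counts match the simulator's draws for every retained site
    ends = truth.ends
    expected = {
        (ends.at[i, "chrom"], int(ends.at[i, "pos"]), ends.at[i, "side"]): int(counts[i])
        for i in np.flatnonzero(counts >= 2)
    }
    # exclusion zone carries zero weight, so the profiles should agree exactly
    assert profile.counts == expected


def test_pipeline_is_deterministic(small_sim, tmp_path):
    config, genome, library, truth = small_sim
    fastq = tmp_path / "det.fastq"
    rng = np.random.default_rng(21)
    simulate_reads(truth, genome, library, config, "d", rng, fastq_path=fastq)
    index = FragmentEndIndex(genome, library)
    run = lambda: process_fastq(
        fastq, index, library, "d", truth.bait_chrom, truth.bait_pos,
        primer=config.primer_readthrough,
    )
    assert run().counts == run().counts
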