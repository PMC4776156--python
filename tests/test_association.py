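import itertools

import numpy as np
import pandas as pd
import pytest

from fourc.association import (
    count_tags_near_sites,
    enrichment_analysis,
    nearest_site_distances,
    rank_sum_test,
    sample_random_sites,
    snp_proximity,
)
from fourc.simulate import synthetic_site_library


def _track(positions_by_chrom):
    rows = [(c, p, p + 1) for c, ps in positions_by_chrom.items() for p in ps]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_tag_count_worked_example():
    track = _track({"chr1": [600_000, 1_400_000], "chr2": [1, 2, 3]})  # 5 tags total
    counts = count_tags_near_sites({("chr1", 1_000_000)}, track, flank=500_000)
    # raw 2 tags in the window, normalized by 10^7 / 5
    assert counts[0] == pytest.approx(4_000_000.0)


def test_tag_count_closed_interval_boundaries():
    track = _track({"chr1": [500, 1_500, 1_501, 2, 499]})
    counts = count_tags_near_sites({("chr1", 1_000)}, track, flank=500)
    # tags exactly at s-flank and s+flank are counted; 499 and 1501 are not
    assert counts[0] == pytest.approx(2 * (1e7 / 5))


def test_tag_count_matches_quadratic_oracle():
    rng = np.random.default_rng(2)
    tags = _track({f"chr{c}": rng.integers(0, 1_000_000, size=300) for c in (1, 2)})
    sites = {(f"chr{rng.integers(1, 3)}", int(rng.integers(0, 1_000_000))) for _ in range(40)}
    flank = 50_000
    counts = count_tags_near_sites(sites, tags, flank=flank)
    ordered = sorted(sites)
    total = len(tags)
    for got, (chrom, pos) in zip(counts, ordered):
        raw = sum(
            1
            for rec in tags.itertuples()
            if rec.chrom == chrom and abs(rec.start - pos) <= flank
        )
        assert got == pytest.approx(raw * 1e7 / total)


def test_tag_normalization_invariant_under_duplication():
    track = _track({"chr1": [100, 200, 300_000]})
    doubled = pd.concat([track, track], ignore_index=True)
    sites = {("chr1", 150), ("chr1", 290_000)}
    a = count_tags_near_sites(sites, track, flank=1_000)
    b = count_tags_near_sites(sites, doubled, flank=1_000)
    assert np.allclose(a, b)


def test_sample_random_sites_edges_and_determinism():
    library = synthetic_site_library(2, 25)
    everything = sample_random_sites(library, 50, rng=0)
    assert set(everything) == set(library.iter_sites())
    assert sample_random_sites(library, 0, rng=0) == []
    assert sample_random_sites(library, 10, rng=5) == sample_random_sites(library, 10, rng=5)
    exclude = {("chr1", int(library.positions["chr1"][0]))}
    drawn = sample_random_sites(library, 49, rng=1, exclude=exclude)
    assert exclude.isdisjoint(drawn)
    with pytest.raises(ValueError):
        sample_random_sites(library, 51, rng=0)


def _enumeration_pvalue(x, y, alternative):
    """Exhaustive rank-sum null: every assignment of the pooled values."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2  # observed U for x
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[pooled[i]] for i in combo) - n1 * (n1 + 1) / 2
        stats.append(u)
    stats = np.array(stats)
    if alternative == "greater":
        return np.mean(stats >= obs)
    if alternative == "less":
        return np.mean(stats <= obs)
    lo = min(np.mean(stats <= obs), np.mean(stats >= obs))
    return min(1.0, 2 * lo)


def test_rank_sum_exact_worked_example():
    _u, p = rank_sum_test([1, 2, 3], [4, 5, 6], alternative="less")
    assert p == pytest.approx(1 / 20)


def test_rank_sum_exact_matches_enumeration_for_all_splits():
    values = np.array([3.0, 1.5, 9.0, 4.2, 7.7, 0.3, 5.5, 8.1])
    for n1 in (3, 4):
        for combo in itertools.combinations(range(len(values)), n1):
            x = values[list(combo)]
            y = np.delete(values, list(combo))
            for alternative in ("greater", "less"):
                _u, p = rank_sum_test(x, y, alternative=alternative)
                assert p == pytest.approx(_enumeration_pvalue(x, y, alternative))


def test_rank_sum_identical_multisets_two_sided():
    x = list(range(10))
    _u, p = rank_sum_test(x, x, alternative="two-sided")
    assert p >= 0.99


def test_rank_sum_all_identical_warns():
    with pytest.warns(UserWarning):
        _u, p = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0


def test_rank_sum_agrees_with_permutation_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(1.0, 1.0, size=30)
    y = rng.normal(0.0, 1.0, size=30)
    _u, p = rank_sum_test(x, y, alternative="greater")
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:30].sum()
    perm = np.empty(10_000)
    for i in range(10_000):
        rng.shuffle(ranks)
        perm[i] = ranks[:30].sum()
    p_perm = (np.sum(perm >= obs) + 1) / (len(perm) + 1)
    assert p / 2 <= max(p_perm, 1e-4) and p_perm <= max(2 * p, 1e-3)


def test_enrichment_detects_planted_track():
    from fourc.experiments import enrichment_experiment

    pvals = enrichment_experiment(n_seeds=2, fold=10.0, base_seed=0)
    assert (pvals < 0.01).all()


def test_snp_proximity_window_counts():
    library = synthetic_site_library(1, 2_000)
    sites = {("chr1", 100_000)}
    snps = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [150_000, 2_000_000], "id": ["rs1", "rs2"]}
    )
    res = snp_proximity(sites, snps, library, rng=0)
    assert res.n_within_1mb == 1
    assert res.n_within_10kb == 0


def test_snp_exactly_at_site_distance_zero():
    sites = {("chr1", 5_000)}
    snps = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000], "id": ["rs1"]})
    assert nearest_site_distances(snps, sites)[0] == 0


def test_snp_on_sitefree_chromosome_excluded():
    library = synthetic_site_library(2, 100)
    sites = {("chr1", int(p)) for p in library.positions["chr1"][:10]}
    snps = pd.DataFrame(
        {"chrom": ["chrX", "chr1"], "pos": [1_000, 2_000], "id": ["rs1", "rs2"]}
    )
    res = snp_proximity(sites, snps, library, rng=0)
    assert res.n_unreachable == 1


def test_snp_empty_table_rejected():
    library = synthetic_site_library(1, 10)
    with pytest.raises(ValueError):
        snp_proximity({("chr1", 2_000)}, pd.DataFrame(columns=["chrom", "pos", "id"]), library)


def test_snp_proximity_rejects_for_planted_snps():
    from fourc.experiments import snp_proximity_experiment

    pvals = snp_proximity_experiment(n_seeds=2, base_seed=0)
    assert (pvals < 0.05).all()
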