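import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fourc.domains import (
    ChromosomeModel,
    DomainParams,
    call_domains,
    expected_cis,
    expected_trans,
    merge_significant_windows,
    scan_chromosome,
    sliding_windows,
    window_scan,
)
from fourc.simulate import synthetic_site_library


def test_window_scan_example():
    starts, ends, n = window_scan(np.array([2, 3, 7]), 10, 5, 5)
    assert list(n) == [2, 1]
    assert list(starts) == [0, 5]


def test_window_scan_empty_profile():
    _s, _e, n = window_scan(np.array([], dtype=int), 20, 5, 5)
    assert (n == 0).all()


def test_window_scan_matches_naive_recount():
    rng = np.random.default_rng(4)
    m = 137
    idx = np.sort(rng.choice(m, size=40, replace=False))
    for window, step in [(10, 5), (25, 25), (140, 7)]:
        starts, ends, n = window_scan(idx, m, window, step)
        for s, e, cnt in zip(starts, ends, n):
            assert cnt == sum(1 for i in idx if s <= i < e)
        # every candidate site is covered by at least one window
        covered = np.zeros(m, dtype=bool)
        for s, e in zip(starts, ends):
            covered[s:e] = True
        assert covered.all()


def test_truncated_window_flagged():
    starts, ends, truncated = sliding_windows(7, 10, 5)
    assert truncated and list(starts) == [0] and list(ends) == [7]


def test_expected_trans_binomial_arithmetic():
    model = ChromosomeModel("chrW", 10_000_000, 1_000, 100)
    mu, sigma = expected_trans(model, 200)
    assert mu == pytest.approx(20.0)
    assert sigma == pytest.approx(np.sqrt(18.0))


def test_degenerate_rates_flagged():
    assert ChromosomeModel("c", 1, 100, 0).degenerate
    assert ChromosomeModel("c", 1, 100, 100).degenerate
    assert not ChromosomeModel("c", 1, 100, 10).degenerate


def test_expected_cis_whole_chromosome_equals_trans():
    idx = np.array([1, 5, 9, 14, 22, 37, 41])
    m = 50
    starts, ends, _n = window_scan(idx, m, 10, 10)
    p_local, bg_m, _bg_s = expected_cis(idx, m, starts, ends, background_sites=m)
    model = ChromosomeModel("c", 1, m, len(idx))
    assert np.allclose(p_local, model.p)
    assert (bg_m == m).all()


def test_expected_cis_local_background_tracks_uniform_rate():
    rng = np.random.default_rng(8)
    m = 5_000
    idx = np.flatnonzero(rng.random(m) < 0.2)
    starts, ends, _n = window_scan(idx, m, 200, 100)
    p_local, _bg_m, _bg_s = expected_cis(idx, m, starts, ends, background_sites=1_000)
    assert abs(p_local.mean() - len(idx) / m) < 0.02


def test_scan_statistics_match_bruteforce_enumeration():
    """30-site toy chromosome: every window statistic recomputed from scratch."""
    library = synthetic_site_library(1, 30)
    idx = np.array([0, 1, 2, 3, 11, 17, 23, 24])
    params = DomainParams(window_trans=10, step_trans=5, alpha=0.05)
    table = scan_chromosome("chr1", idx, library, params, is_bait_chrom=False)
    m, s = 30, len(idx)
    p = s / m
    for rec in table.itertuples():
        lo, hi = rec.first_index, rec.last_index + 1
        n_expect = sum(1 for i in idx if lo <= i < hi)
        l = hi - lo
        mu = l * p
        sigma = np.sqrt(l * p * (1 - p) * (1 - l / m))  # estimated-rate variance
        z = (n_expect - mu) / sigma
        assert rec.n == n_expect
        assert rec.mu == pytest.approx(mu)
        assert rec.sigma == pytest.approx(sigma)
        assert rec.z == pytest.approx(z)
        if mu >= params.exact_tail_threshold:
            assert rec.pvalue == pytest.approx(sps.norm.sf(z))
        else:
            assert rec.pvalue == pytest.approx(sps.binom.sf(n_expect - 1, l, p))


def test_z_increases_with_observed_count():
    library = synthetic_site_library(1, 1_000)
    params = DomainParams(window_trans=100, step_trans=100)
    rng = np.random.default_rng(0)
    base = np.sort(rng.choice(np.arange(100, 1_000), size=100, replace=False))
    dense = np.unique(np.concatenate([base, np.arange(0, 40)]))
    t_base = scan_chromosome("chr1", base, library, params, is_bait_chrom=False)
    t_dense = scan_chromosome("chr1", dense, library, params, is_bait_chrom=False)
    # the window holding the added sites gains z despite a higher global rate
    assert t_dense.iloc[0]["z"] > t_base.iloc[0]["z"]


def test_significance_threshold_is_strict():
    params = DomainParams()
    alpha = params.alpha
    windows = pd.DataFrame(
        {
            "chrom": ["c"] * 3,
            "first_index": [0, 10, 20],
            "last_index": [9, 19, 29],
            "start": [0, 100, 200],
            "end": [99, 199, 299],
            "n": [5, 5, 5],
            "mu": [1.0, 1.0, 1.0],
            "sigma": [1.0, 1.0, 1.0],
            "z": [0.0, 0.0, 0.0],
            "pvalue": [alpha + 1e-9, alpha, alpha - 1e-9],
            "degenerate": [False, False, False],
        }
    )
    from fourc.domains import _mark_significant

    marked = _mark_significant(windows, params)
    assert list(marked["significant"]) == [False, True, True]


def test_domain_merging_adjacent_and_idempotent():
    windows = pd.DataFrame(
        {
            "chrom": ["c1", "c1", "c1", "c2"],
            "first_index": [0, 5, 40, 3],
            "last_index": [9, 14, 49, 12],
            "start": [0, 500, 4000, 300],
            "end": [999, 1499, 4999, 1299],
            "n": [4, 4, 4, 4],
            "mu": [1.0] * 4,
            "sigma": [1.0] * 4,
            "z": [3.0, 4.0, 2.5, 5.0],
            "pvalue": [1e-3, 1e-4, 1e-2, 1e-5],
            "degenerate": [False] * 4,
            "significant": [True] * 4,
        }
    )
    domains = merge_significant_windows(windows, 6)
    assert len(domains) == 3  # overlapping pair merged, distant window separate
    merged = domains[domains["chrom"] == "c1"].iloc[0]
    assert merged["first_index"] == 0 and merged["last_index"] == 14
    assert merged["max_z"] == 4.0
    # domains on one chromosome are disjoint
    c1 = domains[domains["chrom"] == "c1"].sort_values("start")
    assert (c1["start"].to_numpy()[1:] >= c1["end"].to_numpy()[:-1]).all()


def test_call_on_subset_equals_restriction():
    library = synthetic_site_library(3, 400)
    rng = np.random.default_rng(5)
    sites = {
        chrom: np.sort(rng.choice(400, size=60, replace=False))
        for chrom in ("chr2", "chr3")
    }
    params = DomainParams(window_trans=50, step_trans=25)
    full = call_domains({**sites, "chr1": np.array([], dtype=int)}, library, "chr1", params)
    only2 = scan_chromosome("chr2", sites["chr2"], library, params, is_bait_chrom=False)
    sub = full.windows[full.windows["chrom"] == "chr2"].reset_index(drop=True)
    pd.testing.assert_frame_equal(sub, only2)


def test_empty_profile_rejected():
    library = synthetic_site_library(1, 100)
    with pytest.raises(ValueError):
        call_domains({"chr1": np.array([], dtype=int)}, library, "chr1")
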