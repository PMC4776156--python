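"""Integrative association statistics around interacting sites.

Two analyses: (1) chromatin-mark / transcription-factor tag enrichment —
ChIP tags within ±500 kb of each interacting site are counted, normalized to
a 10-million-tag track, and compared against size-matched random restriction
sites with a one-sided Wilcoxon rank-sum test; (2) risk-SNP proximity — the
nearest-site distance of each index SNP to the interacting sites, counted
within ±10 kb and ±1 Mb, and compared against random sites with a one-sided
("less") rank-sum test.

Random sites are drawn from the restriction-site universe so the null shares
the query sites' fragment-density support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .restriction import SiteLibrary, collapse_sides

DEFAULT_FLANK = 500_000
DEFAULT_NORM_TOTAL = 10_000_000


def _tags_by_chrom(tags: pd.DataFrame) -> dict[str, np.ndarray]:
    if not len(tags):
        raise ValueError("no tags")
    col = "start" if "start" in tags.columns else "pos"
    return {
        chrom: np.sort(group[col].to_numpy(dtype=np.int64))
        for chrom, group in tags.groupby("chrom", sort=False)
    }


def count_tags_near_sites(
    sites: Iterable[tuple],
    tags: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    norm_total: float = DEFAULT_NORM_TOTAL,
) -> np.ndarray:
    """Normalized tag count within ±flank (closed interval) of each site.

    Raw counts are scaled by ``norm_total / total tags in track`` so tracks of
    different depth are comparable.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    by_chrom = _tags_by_chrom(tags)
    total = sum(len(v) for v in by_chrom.values())
    positions = sorted(collapse_sides(sites))
    counts = np.empty(len(positions), dtype=float)
    for i, (chrom, pos) in enumerate(positions):
        arr = by_chrom.get(chrom)
        if arr is None:
            counts[i] = 0.0
            continue
        lo = np.searchsorted(arr, pos - flank, side="left")
        hi = np.searchsorted(arr, pos + flank, side="right")  # closed at pos+flank
        counts[i] = hi - lo
    return counts * (norm_total / total)


def interior_sites(
    positions: Iterable[tuple[str, int]], library: SiteLibrary, margin: int
) -> set[tuple[str, int]]:
    """Sites at least ``margin`` bp from both chromosome ends.

    Miniature genomes make edge-truncated flank windows a material bias;
    restricting both query and random sites to the interior restores the
    exchangeability the rank-sum null assumes.  At genome scale the excluded
    fraction is negligible.
    """
    return {
        (c, p)
        for c, p in positions
        if margin <= p <= library.chrom_lengths[c] - margin
    }


def sample_random_sites(
    library: SiteLibrary,
    n: int,
    rng: np.random.Generator | int = 0,
    exclude: set[tuple[str, int]] | None = None,
    interior_margin: int = 0,
) -> list[tuple[str, int]]:
    """Uniform draw without replacement from the recognition-site universe."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    universe = [site for site in library.iter_sites() if not exclude or site not in exclude]
    if interior_margin:
        universe = sorted(interior_sites(universe, library, interior_margin))
    if n > len(universe):
        raise ValueError("requested more random sites than the universe holds")
    picks = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in picks]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) with midranks for ties.

    Exact enumeration when the pooled sample is small (<= 12) and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U statistic for x, one- or two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Per-site normalized tag counts for query vs random sites, with the
    one-sided ('greater') rank-sum comparison."""

    track: str
    query_counts: np.ndarray
    random_counts: np.ndarray
    u_statistic: float
    pvalue: float
    flank: int = DEFAULT_FLANK
    norm_total: float = DEFAULT_NORM_TOTAL

    def as_dict(self) -> dict:
        return {
            "track": self.track,
            "n_query": int(len(self.query_counts)),
            "n_random": int(len(self.random_counts)),
            "query_median": float(np.median(self.query_counts)),
            "random_median": float(np.median(self.random_counts)),
            "u_statistic": self.u_statistic,
            "pvalue": self.pvalue,
            "flank": self.flank,
        }


def enrichment_analysis(
    query_sites: Iterable[tuple],
    tracks: Mapping[str, pd.DataFrame],
    library: SiteLibrary,
    flank: int = DEFAULT_FLANK,
    norm_total: float = DEFAULT_NORM_TOTAL,
    rng: np.random.Generator | int = 0,
    n_random_draws: int = 1,
    edge_exclusion: int = 0,
    exclude_query_from_random: bool = False,
) -> dict[str, EnrichmentResult]:
    """Tag enrichment around query sites versus size-matched random sites.

    Random sites are drawn from the full restriction-site universe (set
    ``exclude_query_from_random`` to forbid overlap with the query set).
    ``edge_exclusion`` (bp) drops query sites — and random candidates — whose
    flank window would be truncated by a chromosome end; see
    :func:`interior_sites`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    query_positions = collapse_sides(query_sites)
    if edge_exclusion:
        query_positions = interior_sites(query_positions, library, edge_exclusion)
    if not query_positions:
        raise ValueError("no query sites (after edge exclusion)")
    results = {}
    for name, tags in tracks.items():
        query_counts = count_tags_near_sites(query_positions, tags, flank, norm_total)
        random_counts = []
        for _ in range(n_random_draws):
            random_sites = sample_random_sites(
                library,
                len(query_positions),
                rng,
                exclude=query_positions if exclude_query_from_random else None,
                interior_margin=edge_exclusion,
            )
            random_counts.append(count_tags_near_sites(random_sites, tags, flank, norm_total))
        random_counts = np.concatenate(random_counts)
        u, p = rank_sum_test(query_counts, random_counts, alternative="greater")
        results[name] = EnrichmentResult(
            track=name,
            query_counts=query_counts,
            random_counts=random_counts,
            u_statistic=u,
            pvalue=p,
            flank=flank,
            norm_total=norm_total,
        )
    return results


def nearest_site_distances(
    snps: pd.DataFrame, sites: Iterable[tuple]
) -> np.ndarray:
    """Per-SNP distance to the nearest same-chromosome site (inf if none)."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in collapse_sides(sites):
        by_chrom.setdefault(chrom, []).append(pos)
    sorted_sites = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}
    out = np.empty(len(snps), dtype=float)
    for i, rec in enumerate(snps.itertuples()):
        arr = sorted_sites.get(rec.chrom)
        if arr is None or len(arr) == 0:
            out[i] = np.inf
            continue
        j = np.searchsorted(arr, rec.pos)
        best = np.inf
        if j < len(arr):
            best = min(best, abs(int(arr[j]) - int(rec.pos)))
        if j > 0:
            best = min(best, abs(int(arr[j - 1]) - int(rec.pos)))
        out[i] = best
    return out


@dataclass
class SNPProximityResult:
    distances: np.ndarray
    random_distances: np.ndarray
    n_snps: int
    n_within_10kb: int
    n_within_1mb: int
    n_unreachable: int  # SNPs on site-free chromosomes, excluded from the test
    u_statistic: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "n_within_10kb": self.n_within_10kb,
            "n_within_1mb": self.n_within_1mb,
            "n_unreachable": self.n_unreachable,
            "u_statistic": self.u_statistic,
            "pvalue": self.pvalue,
        }


def snp_proximity(
    query_sites: Iterable[tuple],
    snps: pd.DataFrame,
    library: SiteLibrary,
    rng: np.random.Generator | int = 0,
    random_sites: Sequence[tuple[str, int]] | None = None,
    near_window: int = 10_000,
    far_window: int = 1_000_000,
) -> SNPProximityResult:
    """Nearest-site distances from index SNPs to query sites, window counts,
    and a one-sided ('less') rank-sum comparison against random sites."""
    if not len(snps):
        raise ValueError("empty SNP table")
    query_positions = collapse_sides(query_sites)
    dist = nearest_site_distances(snps, query_positions)
    if random_sites is None:
        random_sites = sample_random_sites(
            library, len(query_positions), rng, exclude=query_positions
        )
    rand_dist = nearest_site_distances(snps, random_sites)
    finite = np.isfinite(dist) & np.isfinite(rand_dist)
    u, p = rank_sum_test(dist[finite], rand_dist[finite], alternative="less")
    return SNPProximityResult(
        distances=dist,
        random_distances=rand_dist,
        n_snps=int(len(snps)),
        n_within_10kb=int(np.sum(dist <= near_window)),
        n_within_1mb=int(np.sum(dist <= far_window)),
        n_unreachable=int(np.sum(~np.isfinite(dist))),
        u_statistic=u,
        pvalue=p,
    )
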