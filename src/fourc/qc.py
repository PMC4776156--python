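"""Replicate-concordance QC and overlap significance.

Interacting sites are binned genome-wide (1 Mb bins on the bait chromosome,
2 Mb elsewhere), replicate bin vectors are compared by Pearson correlation and
complete-linkage hierarchical clustering, and the replicate overlap rate —
shared sites divided by the larger set, in percent — is contrasted with the
rates of randomly resampled site sets of matched sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .restriction import SiteLibrary, collapse_sides

CIS_BIN = 1_000_000
TRANS_BIN = 2_000_000


def bin_densities(
    sites: Iterable[tuple],
    bait_chrom: str,
    chrom_lengths: dict[str, int],
    cis_bin: int = CIS_BIN,
    trans_bin: int = TRANS_BIN,
) -> pd.DataFrame:
    """Site counts per genomic bin: ``cis_bin`` on the bait chromosome,
    ``trans_bin`` elsewhere.  Bins tile each chromosome from 0; the last bin
    is truncated at the chromosome end; counts conserve sites."""
    positions = collapse_sides(sites)
    rows = []
    for chrom, length in chrom_lengths.items():
        width = cis_bin if chrom == bait_chrom else trans_bin
        edges = np.arange(0, length + width, width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] <= edges[-2]:
            edges = edges[:-1]
        pos = np.array(sorted(p for c, p in positions if c == chrom), dtype=np.int64)
        counts, _ = np.histogram(pos, bins=edges)
        for i in range(len(edges) - 1):
            rows.append((chrom, int(edges[i]), int(edges[i + 1]), int(counts[i])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def _check_same_bins(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if not (
        a[["chrom", "start", "end"]].reset_index(drop=True).equals(
            b[["chrom", "start", "end"]].reset_index(drop=True)
        )
    ):
        raise ValueError("bin schemes differ between samples")


def pearson_correlation(
    density_a: pd.DataFrame, density_b: pd.DataFrame, log1p: bool = False
) -> float:
    """Product-moment correlation of the concatenated bin vectors."""
    _check_same_bins(density_a, density_b)
    x = density_a["count"].to_numpy(dtype=float)
    y = density_b["count"].to_numpy(dtype=float)
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: fewer than 2 bins or zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def cluster_samples(
    densities: dict[str, pd.DataFrame], log1p: bool = False
) -> tuple[list[str], np.ndarray]:
    """Complete-linkage agglomerative clustering on Euclidean distances
    between bin vectors.  Returns (sample labels, scipy linkage matrix);
    scipy's deterministic index-ordered tie-breaking applies."""
    labels = list(densities)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples to cluster")
    first = densities[labels[0]]
    for name in labels[1:]:
        _check_same_bins(first, densities[name])
    matrix = np.stack([densities[name]["count"].to_numpy(dtype=float) for name in labels])
    if log1p:
        matrix = np.log1p(matrix)
    return labels, linkage(matrix, method="complete", metric="euclidean")


@dataclass
class OverlapReport:
    """Replicate overlap with optional random-resampling comparison."""

    n_a: int
    n_b: int
    n_shared: int
    rate: float  # percent, |A∩B| / max(|A|,|B|)
    random_rates: list[float] = field(default_factory=list)
    random_median: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "rate_pct": round(self.rate, 1),
            "random_rates_pct": [round(r, 4) for r in self.random_rates],
            "random_median_pct": None
            if self.random_median is None
            else round(self.random_median, 4),
        }


def overlap_rate_from_counts(n_a: int, n_b: int, n_shared: int) -> float:
    """Overlap rate in percent: shared sites over the larger set."""
    if n_shared > min(n_a, n_b):
        raise ValueError("shared count exceeds a set size")
    if max(n_a, n_b) == 0:
        raise ValueError("both sets empty")
    return 100.0 * n_shared / max(n_a, n_b)


def overlap_rate(site_set_a: set, site_set_b: set) -> OverlapReport:
    shared = len(site_set_a & site_set_b)
    return OverlapReport(
        n_a=len(site_set_a),
        n_b=len(site_set_b),
        n_shared=shared,
        rate=overlap_rate_from_counts(len(site_set_a), len(site_set_b), shared),
    )


def random_overlap_simulation(
    library: SiteLibrary,
    size_a: int,
    size_b: int,
    n_sets: int = 10,
    rng: np.random.Generator | int = 0,
) -> OverlapReport:
    """Overlap rates of ``n_sets`` pairs of random site sets drawn uniformly
    without replacement from the fragment-end universe, plus their median
    (mean of the central pair when ``n_sets`` is even)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    universe = 2 * library.total_sites  # both fragment ends of every site
    if size_a > universe or size_b > universe:
        raise ValueError("requested set size exceeds the site universe")
    rates = []
    for _ in range(n_sets):
        a = rng.choice(universe, size=size_a, replace=False)
        b = rng.choice(universe, size=size_b, replace=False)
        shared = len(np.intersect1d(a, b, assume_unique=True))
        rates.append(overlap_rate_from_counts(size_a, size_b, shared))
    return OverlapReport(
        n_a=size_a,
        n_b=size_b,
        n_shared=-1,
        rate=float("nan"),
        random_rates=rates,
        random_median=float(np.median(rates)),
    )
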