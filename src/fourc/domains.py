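"""Binomial-model screen for significant interaction domains.

Candidate restriction sites on each chromosome are scanned with sliding
windows measured in site units (windows of 500 candidate sites for trans
chromosomes, 200 for the bait chromosome).  Under the null, the number of
interacting sites in a window of l candidates is Binomial(l, p) with p the
interacting-site rate — chromosome-wide (p_W = S_W / M_W) for trans windows,
or estimated from a 5,000-site background window centred on the test window
for cis, where the strong distance decay makes a local background essential.
Each window receives z = (n − μ) / σ with μ = l·p, and windows with one-sided
upper-tail significance at the type-I error rate α = 0.05 are merged into
domains.

Because p is estimated from the same chromosome, the exact null variance of
n − l·p̂ is l·p̂(1−p̂)·(1 − l/M) (sampling-without-replacement form); the
finite-population factor is applied by default and is negligible when l ≪ M,
as at genome scale.  For sparse windows (μ below ``exact_tail_threshold``)
the normal approximation is replaced by an exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .restriction import SiteLibrary, collapse_sides


@dataclass
class ChromosomeModel:
    """Null model for one chromosome: M candidate sites, S interacting."""

    chrom: str
    length: int
    m_sites: int
    s_sites: int

    def __post_init__(self) -> None:
        if not 0 <= self.s_sites <= self.m_sites:
            raise ValueError("need 0 <= S <= M")

    @property
    def p(self) -> float:
        return self.s_sites / self.m_sites if self.m_sites else 0.0

    @property
    def degenerate(self) -> bool:
        return self.p <= 0.0 or self.p >= 1.0


@dataclass
class DomainParams:
    """Screen parameters; defaults are the published analysis settings
    (trans window 500 sites, cis window 200, cis background 5,000, α=0.05).
    The sliding step defaults to half the window (overlapping windows)."""

    window_trans: int = 500
    window_cis: int = 200
    background_cis: int = 5_000
    alpha: float = 0.05
    step_trans: int | None = None
    step_cis: int | None = None
    finite_population_correction: bool = True
    exact_tail_threshold: float = 5.0
    bh_correction: bool = False

    @property
    def z_crit(self) -> float:
        return float(sps.norm.isf(self.alpha))


def sliding_windows(m_sites: int, window: int, step: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Start/end site-index pairs covering all ``m_sites`` candidates.

    Returns (starts, ends, truncated); a chromosome with fewer candidates than
    the window yields a single truncated window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if m_sites <= 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64), False
    if m_sites <= window:
        return np.array([0]), np.array([m_sites]), m_sites < window
    starts = list(range(0, m_sites - window + 1, step))
    if starts[-1] != m_sites - window:
        starts.append(m_sites - window)  # final window flush with the chromosome end
    starts = np.array(starts, dtype=np.int64)
    return starts, starts + window, False


def window_scan(
    interacting_idx: np.ndarray, m_sites: int, window: int, step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed interacting-site count per sliding window.

    ``interacting_idx`` are sorted site indices on one chromosome; returns
    (starts, ends, n) arrays.
    """
    idx = np.asarray(interacting_idx, dtype=np.int64)
    if np.any(idx < 0) or (len(idx) and idx.max() >= m_sites):
        raise ValueError("interacting index outside the candidate universe")
    starts, ends, _ = sliding_windows(m_sites, window, step)
    n = np.searchsorted(idx, ends, side="left") - np.searchsorted(idx, starts, side="left")
    return starts, ends, n


def expected_trans(model: ChromosomeModel, window_sites: int) -> tuple[float, float]:
    """Binomial expectation for a trans window: μ = l·p_W, σ = sqrt(l·p_W·(1−p_W))."""
    p = model.p
    mu = window_sites * p
    sigma = float(np.sqrt(window_sites * p * (1 - p)))
    return float(mu), sigma


def expected_cis(
    interacting_idx: np.ndarray,
    m_sites: int,
    starts: np.ndarray,
    ends: np.ndarray,
    background_sites: int = 5_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local binomial expectation for cis windows.

    The background window of ``background_sites`` candidates is centred on
    each test window and truncated at chromosome ends; p_local is the
    interacting fraction inside it.  Returns (p_local, bg_m, bg_s) per window.
    """
    idx = np.asarray(interacting_idx, dtype=np.int64)
    centres = (np.asarray(starts) + np.asarray(ends)) // 2
    half = background_sites // 2
    lo = np.maximum(0, centres - half)
    hi = np.minimum(m_sites, lo + background_sites)
    lo = np.maximum(0, hi - background_sites)
    bg_s = np.searchsorted(idx, hi, side="left") - np.searchsorted(idx, lo, side="left")
    bg_m = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        p_local = np.where(bg_m > 0, bg_s / bg_m, 0.0)
    return p_local, bg_m, bg_s


def _window_table(
    chrom: str,
    positions: np.ndarray,
    motif_len: int,
    starts: np.ndarray,
    ends: np.ndarray,
    n: np.ndarray,
    p: np.ndarray,
    bg_m: np.ndarray,
    params: DomainParams,
) -> pd.DataFrame:
    """Assemble per-window statistics: μ, σ, z, p-value, significance."""
    l = ends - starts
    mu = l * p
    var = l * p * (1 - p)
    if params.finite_population_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            fpc = np.where(bg_m > l, 1.0 - l / bg_m, np.nan)
        var = var * fpc
    sigma = np.sqrt(var)
    degenerate = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(sigma) | (sigma <= 0)
    z = np.full(len(l), np.nan)
    ok = ~degenerate
    z[ok] = (n[ok] - mu[ok]) / sigma[ok]
    pval = np.full(len(l), np.nan)
    exact = ok & (mu < params.exact_tail_threshold)
    normal = ok & ~exact
    pval[normal] = sps.norm.sf(z[normal])
    if np.any(exact):
        pval[exact] = sps.binom.sf(n[exact] - 1, l[exact], p[exact])
    return pd.DataFrame(
        {
            "chrom": chrom,
            "first_index": starts,
            "last_index": ends - 1,
            "start": positions[starts],
            "end": positions[ends - 1] + motif_len,
            "n": n,
            "mu": mu,
            "sigma": sigma,
            "z": z,
            "pvalue": pval,
            "degenerate": degenerate,
        }
    )


def _mark_significant(windows: pd.DataFrame, params: DomainParams) -> pd.DataFrame:
    tested = ~windows["degenerate"]
    pvals = windows.loc[tested, "pvalue"].to_numpy()
    if params.bh_correction and len(pvals):
        order = np.argsort(pvals, kind="mergesort")
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pvals)
        out[order] = np.minimum(adj, 1.0)
        pvals = out
    sig = np.zeros(len(windows), dtype=bool)
    sig[np.flatnonzero(tested)] = pvals <= params.alpha
    windows = windows.copy()
    windows["significant"] = sig
    return windows


def scan_chromosome(
    chrom: str,
    interacting_idx: np.ndarray,
    library: SiteLibrary,
    params: DomainParams,
    is_bait_chrom: bool,
) -> pd.DataFrame:
    """Window statistics for one chromosome (cis or trans parameterization)."""
    m = library.n_sites(chrom)
    positions = library.positions[chrom]
    motif_len = len(library.primary_motif)
    if is_bait_chrom:
        window = params.window_cis
        step = params.step_cis or max(1, window // 2)
        starts, ends, _ = sliding_windows(m, window, step)
        n = np.searchsorted(interacting_idx, ends) - np.searchsorted(interacting_idx, starts)
        p, bg_m, _bg_s = expected_cis(interacting_idx, m, starts, ends, params.background_cis)
    else:
        window = params.window_trans
        step = params.step_trans or max(1, window // 2)
        starts, ends, n = window_scan(interacting_idx, m, window, step)
        model = ChromosomeModel(chrom, int(library.chrom_lengths[chrom]), m, len(interacting_idx))
        p = np.full(len(starts), model.p)
        bg_m = np.full(len(starts), m)
    if len(starts) == 0:
        return pd.DataFrame()
    table = _window_table(chrom, positions, motif_len, starts, ends, n, p, bg_m, params)
    return _mark_significant(table, params)


def merge_significant_windows(windows: pd.DataFrame, motif_len: int) -> pd.DataFrame:
    """Merge overlapping or index-adjacent significant windows into domains."""
    cols = ["chrom", "start", "end", "first_index", "last_index", "n_sites", "max_z", "min_pvalue"]
    sig = windows[windows.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    if sig.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, group in sig.groupby("chrom", sort=False):
        group = group.sort_values("first_index", kind="mergesort")
        cur = None
        for rec in group.itertuples():
            if cur is not None and rec.first_index <= cur["last_index"] + 1:
                cur["last_index"] = max(cur["last_index"], rec.last_index)
                cur["end"] = max(cur["end"], rec.end)
                cur["n_windows"] += 1
                cur["max_z"] = np.nanmax([cur["max_z"], rec.z])
                cur["min_pvalue"] = np.nanmin([cur["min_pvalue"], rec.pvalue])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(rec.start),
                    "end": int(rec.end),
                    "first_index": int(rec.first_index),
                    "last_index": int(rec.last_index),
                    "n_windows": 1,
                    "max_z": rec.z,
                    "min_pvalue": rec.pvalue,
                }
        rows.append(cur)
    domains = pd.DataFrame(rows)
    return domains


def sites_to_index_arrays(
    sites: Iterable[tuple] | Mapping[str, np.ndarray], library: SiteLibrary
) -> dict[str, np.ndarray]:
    """Normalize an interacting-site collection to sorted per-chromosome
    site-index arrays.  Accepts side-level ids, (chrom, pos) pairs, or an
    already-built mapping of index arrays."""
    if isinstance(sites, Mapping):
        return {c: np.asarray(sorted(set(map(int, v))), dtype=np.int64) for c, v in sites.items()}
    by_chrom: dict[str, set[int]] = {}
    for chrom, pos in collapse_sides(sites):
        by_chrom.setdefault(chrom, set()).add(library.site_index(chrom, pos))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}


@dataclass
class DomainCallResult:
    windows: pd.DataFrame
    domains: pd.DataFrame

    def domains_bed(self) -> pd.DataFrame:
        return self.domains[["chrom", "start", "end"]]


def call_domains(
    sites: Iterable[tuple] | Mapping[str, np.ndarray],
    library: SiteLibrary,
    bait_chrom: str,
    params: DomainParams | None = None,
) -> DomainCallResult:
    """Genome-wide binomial screen: cis windows on the bait chromosome, trans
    windows elsewhere; significant windows merged into domains."""
    params = params or DomainParams()
    by_chrom = sites_to_index_arrays(sites, library)
    if not any(len(v) for v in by_chrom.values()):
        raise ValueError("profile is empty")
    tables = []
    for chrom in library.chroms:
        idx = by_chrom.get(chrom, np.array([], dtype=np.int64))
        table = scan_chromosome(chrom, idx, library, params, chrom == bait_chrom)
        if len(table):
            tables.append(table)
    windows = pd.concat(tables, ignore_index=True)
    domains = merge_significant_windows(windows, len(library.primary_motif))
    return DomainCallResult(windows=windows, domains=domains)
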