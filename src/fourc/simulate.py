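"""Seeded miniature 4C-seq datasets with the statistical structure the
analysis assumes.

The generator emulates a viewpoint-anchored inverse-PCR experiment: a bait
fragment on one chromosome, cis contact frequency decaying as a power law of
genomic distance, a uniform trans background, planted high-contact domains,
negative-binomially overdispersed read counts per captured fragment end (8
parallel PCRs imply duplicate clusters), two replicates sharing one true
contact profile, ChIP-style tag tracks enriched over the planted domains, and
index-SNP tables placed preferentially near the domains.  Everything is
byte-deterministic under a fixed seed.

The read architecture follows the inverse-PCR design: each 50 bp single-end
read starts with the constant bait-side primer read-through whose 3' end is
the reconstituted BglII motif (``...AGATCT``), followed by the captured
fragment-end sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .restriction import (
    BGLII_MOTIF,
    Genome,
    SiteLibrary,
    build_site_library,
    end_sequence,
)

# 3'-terminal genomic segment of the universal inverse-PCR primer; it ends in
# the BglII motif, so trimming it leaves the captured fragment-end sequence.
PRIMER_READTHROUGH = "ATGGAAATCAAGCAGCAGATCT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedDomain:
    """High-contact interval: site indices [start_index, end_index) on one chromosome."""

    chrom: str
    start_index: int
    end_index: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("domain fold-enrichment must be >= 1")
        if self.end_index <= self.start_index:
            raise ValueError("empty domain interval")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference condition used throughout: five 4 Mb
    chromosomes digested every ~2 kb (≈2,000 candidate sites each), the bait
    mid-chromosome-1, 1/d cis decay carrying ~55% of reads in cis (inside the
    47–66% range a well-behaved viewpoint shows), two fold-10 planted domains
    (one cis, one trans), and 200,000 reads per replicate with negative-
    binomial overdispersion k=10.
    """

    n_chromosomes: int = 5
    chromosome_length: int = 4_000_000
    inter_site_spacing: int = 2_000
    bait_chrom: str = "chr1"
    bait_index: int | None = None  # None -> middle site of the bait chromosome
    cis_decay_exponent: float = 1.0
    trans_background: float | None = None  # per-end weight; None -> derived
    cis_read_fraction: float | None = 0.55  # overrides trans_background if set
    planted_domains: list[PlantedDomain] | None = None  # None -> defaults
    bait_exclusion_fragments: int = 2
    reads_per_replicate: int = 200_000
    duplicate_dispersion: float = 10.0  # NB size k; variance = m + m^2/k
    count_model: str = "nb"  # "nb" | "poisson"
    read_length: int = 50
    primer_readthrough: str = PRIMER_READTHROUGH
    error_rate: float = 0.0
    n_tags: int = 50_000
    tag_domain_fold: float = 10.0
    n_snps: int = 112
    snp_near_domain_frac: float = 0.6
    snp_domain_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_decay_exponent < 0:
            raise ValueError("cis_decay_exponent must be >= 0")
        if self.inter_site_spacing < 2 * len(BGLII_MOTIF):
            raise ValueError("inter_site_spacing must be at least twice the motif length")
        if self.read_length <= len(self.primer_readthrough):
            raise ValueError("read_length must exceed the primer read-through length")
        if self.count_model not in ("nb", "poisson"):
            raise ValueError("count_model must be 'nb' or 'poisson'")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def default_domains(self, n_sites_per_chrom: int) -> list[PlantedDomain]:
        """Two fold-10 domains: one cis (bait chromosome) and one trans."""
        width = max(10, n_sites_per_chrom // 35)
        cis_start = min(n_sites_per_chrom - width, int(n_sites_per_chrom * 0.7))
        trans_chrom = "chr3" if self.n_chromosomes >= 3 else self.chrom_names[-1]
        trans_start = int(n_sites_per_chrom * 0.45)
        return [
            PlantedDomain(self.bait_chrom, cis_start, cis_start + width, 10.0),
            PlantedDomain(trans_chrom, trans_start, trans_start + width, 10.0),
        ]


@dataclass
class ContactTruth:
    """Ground-truth contact profile over fragment ends.

    ``ends`` has one row per fragment end: chrom, site_index, pos, side,
    weight; weights are non-negative, zero at the bait and inside its
    exclusion zone, and sum to 1.
    """

    ends: pd.DataFrame
    domains: list[PlantedDomain]
    bait_chrom: str
    bait_index: int
    bait_pos: int

    def __post_init__(self) -> None:
        total = float(self.ends["weight"].sum())
        if not np.isclose(total, 1.0):
            raise ValueError(f"truth weights must sum to 1 (got {total})")

    def domain_intervals_bp(self, library: SiteLibrary) -> list[tuple[str, int, int]]:
        """Planted domains as genomic (chrom, start, end) intervals."""
        motif_len = len(library.primary_motif)
        out = []
        for dom in self.domains:
            pos = library.positions[dom.chrom]
            start = int(pos[dom.start_index])
            end = int(pos[min(dom.end_index, len(pos)) - 1]) + motif_len
            out.append((dom.chrom, start, end))
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.ends.to_csv(path, sep="\t", index=False)


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(rng.choice(_BASES, size=n).tobytes())


def _scrub_motif(seq: bytearray, motif: bytes, planted: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate accidental motif occurrences so only planted ones remain.

    A mutated base is always chosen outside every planted motif interval, so
    planted occurrences are never corrupted.  Re-scans until clean.
    """
    m = len(motif)
    planted = np.asarray(planted, dtype=np.int64)
    for _ in range(50):
        dirty = False
        start = bytes(seq).find(motif)
        while start != -1:
            i = np.searchsorted(planted, start)
            if i >= len(planted) or planted[i] != start:
                dirty = True
                for j in range(m):
                    p = start + j
                    k = np.searchsorted(planted, p, side="right") - 1
                    inside = k >= 0 and planted[k] <= p < planted[k] + m
                    if not inside:
                        choices = [b for b in _BASES if b != seq[p]]
                        seq[p] = int(rng.choice(choices))
                        break
            start = bytes(seq).find(motif, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif occurrences")


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[Genome, SiteLibrary]:
    """Random genome with BglII motifs planted at ~inter_site_spacing.

    Flanks are scrubbed of accidental motif occurrences, so the library built
    from the emitted sequence matches the planted positions exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    motif = BGLII_MOTIF.encode()
    m = len(motif)
    chromosomes = []
    planted_positions: dict[str, np.ndarray] = {}
    for name in config.chrom_names:
        length = config.chromosome_length
        spacing = config.inter_site_spacing
        n_sites = max(0, (length - spacing) // spacing)
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=n_sites)
        positions = spacing * (1 + np.arange(n_sites, dtype=np.int64)) + jitter
        positions = np.clip(positions, m, length - 2 * m)
        positions = np.unique(positions)
        # enforce a minimum gap so fragment ends are distinct sequences
        keep = np.concatenate(([True], np.diff(positions) >= 2 * m))
        positions = positions[keep]
        seq = _random_bases(rng, length)
        for pos in positions:
            seq[pos : pos + m] = motif
        _scrub_motif(seq, motif, positions, rng)
        chromosomes.append((name, seq.decode()))
        planted_positions[name] = positions
    genome = Genome(chromosomes)
    library = build_site_library(genome, BGLII_MOTIF)
    for name, positions in planted_positions.items():
        if not np.array_equal(library.positions[name], positions):
            raise AssertionError(f"library on {name} does not match planted sites")
    return genome, library


def synthetic_site_library(
    n_chromosomes: int,
    n_sites_per_chrom: int,
    spacing: int = 2_000,
) -> SiteLibrary:
    """Sequence-free site library on an even grid, for count-level experiments.

    Statistical experiments that never touch read sequences (window-scan
    calibration, large recovery sweeps) only need site coordinates; this
    avoids generating megabases of sequence.
    """
    positions = {
        f"chr{i + 1}": spacing * (1 + np.arange(n_sites_per_chrom, dtype=np.int64))
        for i in range(n_chromosomes)
    }
    lengths = {c: int(spacing * (n_sites_per_chrom + 1)) for c in positions}
    return SiteLibrary(primary_motif=BGLII_MOTIF, positions=positions, chrom_lengths=lengths)


def simulate_contact_profile(library: SiteLibrary, config: SimConfig) -> ContactTruth:
    """True per-fragment-end contact weights.

    Cis weight at site-index distance d from the bait is d^(-alpha) times the
    planted-domain fold; trans weight is a constant background times the fold;
    the bait and its exclusion zone get weight 0; weights are normalized.  If
    ``cis_read_fraction`` is set, the trans background is solved so cis ends
    carry exactly that share of the total weight.
    """
    bait_chrom = config.bait_chrom
    if bait_chrom not in library.positions:
        raise ValueError(f"bait chromosome {bait_chrom!r} not in library")
    n_bait_sites = library.n_sites(bait_chrom)
    bait_index = config.bait_index if config.bait_index is not None else n_bait_sites // 2
    if not 0 <= bait_index < n_bait_sites:
        raise ValueError("bait site index out of range")
    bait_pos = int(library.positions[bait_chrom][bait_index])

    frames = []
    for chrom, positions in library.positions.items():
        n = len(positions)
        idx = np.arange(n, dtype=np.int64)
        if chrom == bait_chrom:
            d = np.abs(idx - bait_index).astype(float)
            with np.errstate(divide="ignore"):
                base = np.where(d > 0, d ** (-config.cis_decay_exponent), 0.0)
            base[np.abs(idx - bait_index) <= config.bait_exclusion_fragments] = 0.0
        else:
            base = np.ones(n)  # scaled by the trans background below
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "site_index": np.repeat(idx, 2),
                    "pos": np.repeat(positions, 2),
                    "side": np.tile(np.array(["L", "R"]), n),
                    "base": np.repeat(base, 2),
                }
            )
        )
    ends = pd.concat(frames, ignore_index=True)

    is_cis = (ends["chrom"] == bait_chrom).to_numpy()
    cis_sum = float(ends.loc[is_cis, "base"].sum())
    n_trans_ends = int((~is_cis).sum())
    if config.cis_read_fraction is not None:
        f = config.cis_read_fraction
        if not 0 < f < 1:
            raise ValueError("cis_read_fraction must be in (0, 1)")
        if n_trans_ends == 0 or cis_sum == 0:
            raise ValueError("cannot balance cis/trans weight on this geometry")
        beta = cis_sum * (1 - f) / f / n_trans_ends
    else:
        beta = config.trans_background if config.trans_background is not None else 0.0
    weight = ends["base"].to_numpy(copy=True)
    weight[~is_cis] *= beta

    domains = config.planted_domains
    if domains is None:
        domains = config.default_domains(n_bait_sites)
    for dom in domains:
        if dom.chrom not in library.positions:
            raise ValueError(f"domain chromosome {dom.chrom!r} not in library")
        mask = (
            (ends["chrom"] == dom.chrom)
            & (ends["site_index"] >= dom.start_index)
            & (ends["site_index"] < dom.end_index)
        ).to_numpy()
        weight[mask] *= dom.fold

    total = weight.sum()
    if total <= 0:
        raise ValueError("contact profile has all-zero weights")
    ends = ends.drop(columns="base")
    ends["weight"] = weight / total
    return ContactTruth(
        ends=ends,
        domains=list(domains),
        bait_chrom=bait_chrom,
        bait_index=bait_index,
        bait_pos=bait_pos,
    )


def simulate_site_counts(
    truth: ContactTruth, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-fragment-end read counts for one replicate.

    Mean ``reads_per_replicate * weight`` with negative-binomial
    overdispersion (variance m + m^2/k), or Poisson when
    ``count_model == "poisson"``.
    """
    mean = config.reads_per_replicate * truth.ends["weight"].to_numpy()
    if config.count_model == "poisson":
        return rng.poisson(mean)
    k = config.duplicate_dispersion
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def _apply_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0 or not reads:
        return reads
    out = []
    for read in reads:
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        mask = rng.random(len(arr)) < error_rate
        n_err = int(mask.sum())
        if n_err:
            # substitute with one of the three other bases
            current = arr[mask]
            subs = _BASES[rng.integers(0, 3, size=n_err)]
            bump = subs == current
            while np.any(bump):
                subs[bump] = _BASES[rng.integers(0, 4, size=int(bump.sum()))]
                bump = subs == current
            arr[mask] = subs
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(
    truth: ContactTruth,
    genome: Genome,
    library: SiteLibrary,
    config: SimConfig,
    replicate_id: str,
    rng: np.random.Generator,
    fastq_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """FASTQ reads for one replicate.

    Each read is the bait-side primer read-through (ending at the BglII
    junction) followed by the captured fragment-end sequence, truncated to
    ``read_length``, with substitution errors at ``error_rate``.  Returns
    ``(records, counts)`` where records are ``(name, sequence)`` pairs in
    emission order and counts align with ``truth.ends`` rows; optionally
    writes a 4-line-record FASTQ.
    """
    counts = simulate_site_counts(truth, config, rng)
    primer = config.primer_readthrough
    payload_len = config.read_length - len(primer)
    motif_len = len(library.primary_motif)
    records: list[tuple[str, str]] = []
    ends = truth.ends
    chrom_arr = ends["chrom"].to_numpy()
    pos_arr = ends["pos"].to_numpy()
    side_arr = ends["side"].to_numpy()
    nonzero = np.flatnonzero(counts)
    read_no = 0
    for i in nonzero:
        payload = end_sequence(genome, motif_len, chrom_arr[i], int(pos_arr[i]), side_arr[i], payload_len)
        base_read = primer + payload
        copies = _apply_errors([base_read] * int(counts[i]), config.error_rate, rng)
        for seq in copies:
            records.append((f"{replicate_id}:{read_no}", seq))
            read_no += 1
    if fastq_path is not None:
        with open(fastq_path, "w") as handle:
            for name, seq in records:
                handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return records, counts


def simulate_chip_tags(
    library: SiteLibrary,
    truth: ContactTruth,
    config: SimConfig,
    rng: np.random.Generator,
    n_tags: int | None = None,
    fold: float | None = None,
) -> pd.DataFrame:
    """ChIP-style tag positions: uniform genome-wide plus a component enriched
    over the planted domains at ``fold`` times the background density.

    Returns a BED-style frame (chrom, start, end) sorted by coordinate.
    """
    n = config.n_tags if n_tags is None else n_tags
    f = config.tag_domain_fold if fold is None else fold
    if f < 1:
        raise ValueError("tag fold-enrichment must be >= 1")
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    genome_bp = int(sum(library.chrom_lengths.values()))
    intervals = truth.domain_intervals_bp(library)
    domain_bp = sum(end - start for _, start, end in intervals)
    p_extra = (f - 1) * domain_bp / (genome_bp + (f - 1) * domain_bp)
    n_extra = rng.binomial(n, p_extra) if p_extra > 0 else 0

    chroms = list(library.chrom_lengths)
    lengths = np.array([library.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_pick = rng.choice(len(chroms), size=n - n_extra, p=lengths / lengths.sum())
    rows = [
        (chroms[c], int(rng.integers(0, library.chrom_lengths[chroms[c]])))
        for c in chrom_pick
    ]
    if n_extra:
        widths = np.array([end - start for _, start, end in intervals], dtype=float)
        dom_pick = rng.choice(len(intervals), size=n_extra, p=widths / widths.sum())
        for d in dom_pick:
            chrom, start, end = intervals[d]
            rows.append((chrom, int(rng.integers(start, end))))
    tags = pd.DataFrame(rows, columns=["chrom", "start"])
    tags["end"] = tags["start"] + 1
    return tags.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def simulate_snps(
    library: SiteLibrary,
    truth: ContactTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Index-SNP table (chrom, pos, id): a configured fraction placed within
    ``snp_domain_window`` of a planted domain, the remainder uniform."""
    n = config.n_snps
    n_near = int(round(config.snp_near_domain_frac * n))
    intervals = truth.domain_intervals_bp(library)
    if not intervals:
        n_near = 0
    rows = []
    for i in range(n):
        if i < n_near:
            chrom, start, end = intervals[int(rng.integers(0, len(intervals)))]
            lo = max(0, start - config.snp_domain_window)
            hi = min(library.chrom_lengths[chrom], end + config.snp_domain_window)
            pos = int(rng.integers(lo, hi))
        else:
            chroms = list(library.chrom_lengths)
            lengths = np.array([library.chrom_lengths[c] for c in chroms], dtype=float)
            chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
            pos = int(rng.integers(0, library.chrom_lengths[chrom]))
        rows.append((chrom, pos, f"rs{i + 1:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])
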