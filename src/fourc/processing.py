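"""Viewpoint-anchored read processing: FASTQ to per-replicate site profiles.

The stages mirror the analysis the assay prescribes: gate reads on the
forward inverse-PCR primer at the 5' end, trim through the reconstituted
BglII junction, map the captured payload to the genome-wide fragment-end
library in two rounds (exact sequence match, then acceptance only at library
fragment-end starts), merge reads per site, eliminate single-read sites as
random-ligation noise, and intersect replicates to obtain reproducible sites
(coverage > 1 in both).

Mapping is exact prefix matching against fragment-end sequences; reads hitting
two or more ends equally are discarded as ambiguous and tallied.  Read
conservation (input = kept + discarded by reason) is tracked at every stage.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .restriction import Genome, SiteLibrary, end_sequence

SiteKey = tuple[str, int, str]  # (chrom, recognition-site position, side)


@dataclass
class ProcessingStats:
    """Per-stage read tallies; conservation is asserted by :meth:`check`."""

    reads_in: int = 0
    primer_passed: int = 0
    primer_failed: int = 0
    primer_too_short: int = 0
    payload_too_short: int = 0
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    sites_raw: int = 0
    sites_filtered: int = 0
    excluded_bait_zone_reads: int = 0
    cis_reads_raw: int = 0  # mapped reads on the bait chromosome, pre-filter

    def check(self) -> None:
        if self.reads_in != self.primer_passed + self.primer_failed + self.primer_too_short:
            raise AssertionError("primer-stage read conservation violated")
        if self.primer_passed != (
            self.mapped + self.ambiguous + self.unmapped + self.payload_too_short
        ):
            raise AssertionError("mapping-stage read conservation violated")

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


@dataclass
class SiteProfile:
    """One replicate's map from 4C site to read count, with the bait location."""

    replicate: str
    bait_chrom: str
    bait_pos: int
    counts: dict[SiteKey, int]
    stats: ProcessingStats = field(default_factory=ProcessingStats)

    @property
    def sites(self) -> set[SiteKey]:
        return set(self.counts)

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))

    def cis_sites(self) -> set[SiteKey]:
        return {s for s in self.counts if s[0] == self.bait_chrom}

    def to_table(self, path: str | Path) -> None:
        rows = [
            (c, p, side, n, "cis" if c == self.bait_chrom else "trans")
            for (c, p, side), n in sorted(self.counts.items())
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "side", "count", "kind"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_table(
        cls, path: str | Path, replicate: str, bait_chrom: str, bait_pos: int
    ) -> "SiteProfile":
        df = pd.read_csv(path, sep="\t")
        counts = {
            (str(r.chrom), int(r.pos), str(r.side)): int(r.count) for r in df.itertuples()
        }
        return cls(replicate=replicate, bait_chrom=bait_chrom, bait_pos=bait_pos, counts=counts)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file, gzip-transparent."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for name, seq, _qual in FastqGeneralIterator(handle):
            yield name, seq.upper()


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def filter_primer_reads(
    reads: Iterable[tuple[str, str]],
    primer: str,
    max_mismatches: int = 0,
    stats: ProcessingStats | None = None,
) -> tuple[list[str], ProcessingStats]:
    """Keep reads whose 5' end matches the forward primer; trim through the junction.

    The primer read-through ends in the BglII motif, so trimming its full
    length removes everything up to and including the junction; what remains
    is the captured-fragment payload.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    stats = stats or ProcessingStats()
    payloads: list[str] = []
    n = len(primer)
    for _name, seq in reads:
        stats.reads_in += 1
        if len(seq) < n:
            stats.primer_too_short += 1
            continue
        prefix = seq[:n]
        ok = prefix == primer if max_mismatches == 0 else _hamming_leq(prefix, primer, max_mismatches)
        if ok:
            stats.primer_passed += 1
            payloads.append(seq[n:])
        else:
            stats.primer_failed += 1
    return payloads, stats


class FragmentEndIndex:
    """Exact-match index of fragment-end sequences at library sites.

    Round 1 of mapping is the sequence lookup; round 2 — acceptance only when
    the hit coincides with a library fragment-end start — is implicit because
    only library ends are indexed.  Hits matching >= 2 ends equally are
    ambiguous.
    """

    def __init__(
        self,
        genome: Genome,
        library: SiteLibrary,
        key_length: int = 16,
        max_end_length: int = 64,
    ) -> None:
        self.key_length = key_length
        self.max_end_length = max_end_length
        motif_len = len(library.primary_motif)
        self._index: dict[str, list[tuple[SiteKey, str]]] = {}
        for chrom, pos, side in library.iter_fragment_ends():
            seq = end_sequence(genome, motif_len, chrom, pos, side, max_end_length)
            if len(seq) < key_length:
                continue  # truncated end at a chromosome boundary
            self._index.setdefault(seq[:key_length], []).append(((chrom, pos, side), seq))

    def lookup(self, payload: str) -> list[SiteKey]:
        """All fragment ends whose sequence starts with ``payload``."""
        query = payload[: self.max_end_length]
        candidates = self._index.get(query[: self.key_length], ())
        return [site for site, seq in candidates if seq.startswith(query)]


def map_captures(
    payloads: Iterable[str],
    index: FragmentEndIndex,
    min_payload: int = 16,
    stats: ProcessingStats | None = None,
) -> tuple[list[SiteKey], ProcessingStats]:
    """Assign each trimmed payload to a unique library fragment end."""
    stats = stats or ProcessingStats()
    hits: list[SiteKey] = []
    for payload in payloads:
        if len(payload) < min_payload:
            stats.payload_too_short += 1
            continue
        matches = index.lookup(payload)
        if len(matches) == 1:
            stats.mapped += 1
            hits.append(matches[0])
        elif len(matches) == 0:
            stats.unmapped += 1
        else:
            stats.ambiguous += 1
    return hits, stats


def count_sites(
    hits: Iterable[SiteKey],
    replicate: str,
    bait_chrom: str,
    bait_pos: int,
    stats: ProcessingStats | None = None,
) -> SiteProfile:
    """Merge reads aligned to the same site into per-site counts."""
    counts = Counter(hits)
    profile = SiteProfile(
        replicate=replicate,
        bait_chrom=bait_chrom,
        bait_pos=bait_pos,
        counts=dict(counts),
        stats=stats or ProcessingStats(),
    )
    profile.stats.sites_raw = len(profile.counts)
    return profile


def exclude_bait_zone(
    profile: SiteProfile, library: SiteLibrary, n_fragments: int = 2
) -> SiteProfile:
    """Drop sites within ±n_fragments of the bait (self-ligation / undigested)."""
    bait_index = library.site_index(profile.bait_chrom, profile.bait_pos)
    positions = library.positions[profile.bait_chrom]
    lo = max(0, bait_index - n_fragments)
    hi = min(len(positions), bait_index + n_fragments + 1)
    zone = {int(p) for p in positions[lo:hi]}
    kept, dropped = {}, 0
    for site, n in profile.counts.items():
        if site[0] == profile.bait_chrom and site[1] in zone:
            dropped += n
        else:
            kept[site] = n
    profile.counts = kept
    profile.stats.excluded_bait_zone_reads += dropped
    return profile


def filter_singletons(profile: SiteProfile) -> SiteProfile:
    """Eliminate sites with only one read (random-ligation noise)."""
    profile.counts = {s: n for s, n in profile.counts.items() if n >= 2}
    profile.stats.sites_filtered = len(profile.counts)
    return profile


def reproducible_sites(profile_a: SiteProfile, profile_b: SiteProfile) -> set[SiteKey]:
    """Sites with coverage > 1 in both biological replicates (exact id match)."""
    return set(profile_a.counts) & set(profile_b.counts)


def cis_trans_summary(sites: Iterable[SiteKey], bait_chrom: str) -> dict:
    """Counts and 1-decimal percentages of cis (bait-chromosome) vs trans sites."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    cis = sum(1 for s in sites if s[0] == bait_chrom)
    total = len(sites)
    trans = total - cis
    return {
        "total": total,
        "cis_n": cis,
        "trans_n": trans,
        "cis_pct": round(100 * cis / total, 1),
        "trans_pct": round(100 * trans / total, 1),
    }


def process_fastq(
    fastq_path: str | Path,
    index: FragmentEndIndex,
    library: SiteLibrary,
    replicate: str,
    bait_chrom: str,
    bait_pos: int,
    primer: str,
    max_mismatches: int = 0,
    min_payload: int = 16,
    exclusion_fragments: int = 2,
) -> SiteProfile:
    """Full per-replicate pipeline: gate, trim, map, count, exclude bait zone,
    drop singletons.  Asserts read conservation."""
    stats = ProcessingStats()
    payloads, stats = filter_primer_reads(read_fastq(fastq_path), primer, max_mismatches, stats)
    hits, stats = map_captures(payloads, index, min_payload, stats)
    profile = count_sites(hits, replicate, bait_chrom, bait_pos, stats)
    # cis/overall read ratio is a library-quality metric, taken before any
    # site-level filtering
    profile.stats.cis_reads_raw = sum(
        n for (chrom, _p, _s), n in profile.counts.items() if chrom == bait_chrom
    )
    profile = exclude_bait_zone(profile, library, exclusion_fragments)
    profile = filter_singletons(profile)
    profile.stats.check()
    return profile
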