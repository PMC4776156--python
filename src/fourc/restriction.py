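"""In-silico restriction digestion and fragment-end site libraries.

4C-seq counts ligation partners of a fixed viewpoint ("bait") at the
recognition sites of the primary restriction enzyme (BglII, ``AGATCT`` by
default).  Every downstream stage — read mapping, window scanning, random-site
resampling — operates on the genome-wide catalogue of those sites, so this
module owns the two foundational containers:

* :class:`Genome` — an ordered set of named chromosome sequences.
* :class:`SiteLibrary` — per chromosome, the sorted 0-based start positions of
  every primary-motif occurrence, with optional secondary-enzyme (CviQI,
  ``GTAC``) positions.

Each recognition site has two flanking fragment ends (sides ``"L"`` and
``"R"``); a 4C site is identified by ``(chrom, position, side)``.  Coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

BGLII_MOTIF = "AGATCT"
CVIQI_MOTIF = "GTAC"
SIDES = ("L", "R")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_BASES = frozenset("ACGT")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def find_recognition_sites(sequence: str, motif: str) -> list[int]:
    """All 0-based start positions of ``motif`` in ``sequence``.

    Overlapping occurrences are reported (the scanner is generic even though
    AGATCT cannot self-overlap).  Positions are sorted ascending.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    positions: list[int] = []
    start = sequence.find(motif)
    while start != -1:
        positions.append(start)
        start = sequence.find(motif, start + 1)
    return positions


@dataclass
class Genome:
    """Ordered list of ``(name, sequence)`` chromosomes over the A/C/G/T alphabet."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def sequence(self, name: str) -> str:
        for chrom, seq in self.chromosomes:
            if chrom == name:
                return seq
        raise KeyError(name)

    def validate_alphabet(self) -> None:
        for name, seq in self.chromosomes:
            if not _VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters: {bad}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as handle:
            for name, seq in self.chromosomes:
                handle.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    handle.write(seq[i : i + width] + "\n")


@dataclass
class SiteLibrary:
    """Genome-wide catalogue of primary recognition-site positions.

    ``positions[chrom]`` is a strictly increasing int64 array of 0-based motif
    start positions.  The candidate-site universe for window scans and random
    resampling is the collapsed position level; fragment ends are derived as
    ``(chrom, pos, side)``.
    """

    primary_motif: str
    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    secondary_motif: str | None = None
    secondary_positions: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"positions on {chrom} are not strictly increasing")
            self.positions[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str) -> int:
        return int(len(self.positions[chrom]))

    @property
    def total_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def site_index(self, chrom: str, pos: int) -> int:
        """Index of a recognition site within its chromosome; KeyError if absent."""
        arr = self.positions[chrom]
        i = int(np.searchsorted(arr, pos))
        if i >= len(arr) or arr[i] != pos:
            raise KeyError(f"no {self.primary_motif} site at {chrom}:{pos}")
        return i

    def iter_sites(self) -> Iterator[tuple[str, int]]:
        for chrom, arr in self.positions.items():
            for pos in arr:
                yield chrom, int(pos)

    def iter_fragment_ends(self) -> Iterator[tuple[str, int, str]]:
        for chrom, pos in self.iter_sites():
            for side in SIDES:
                yield chrom, pos, side

    def to_bed(self, path: str | Path) -> None:
        """One BED record per recognition site (0-based half-open)."""
        rows = []
        motif_len = len(self.primary_motif)
        for chrom, arr in self.positions.items():
            for i, pos in enumerate(arr):
                rows.append((chrom, int(pos), int(pos) + motif_len, f"{chrom}_site{i}"))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def to_site_table(self, path: str | Path, end_length: int = 30) -> None:
        """Tab-separated site table: chrom, pos, left_end_start, right_end_end."""
        motif_len = len(self.primary_motif)
        rows = []
        for chrom, arr in self.positions.items():
            length = self.chrom_lengths[chrom]
            for pos in arr:
                pos = int(pos)
                rows.append(
                    (chrom, pos, max(0, pos - end_length), min(length, pos + motif_len + end_length))
                )
        pd.DataFrame(rows, columns=["chrom", "pos", "left_end_start", "right_end_end"]).to_csv(
            path, sep="\t", index=False
        )


def build_site_library(
    genome: Genome,
    primary_motif: str = BGLII_MOTIF,
    secondary_motif: str | None = None,
) -> SiteLibrary:
    """Scan every chromosome for the primary (and optional secondary) motif."""
    genome.validate_alphabet()
    positions = {
        name: np.asarray(find_recognition_sites(seq, primary_motif), dtype=np.int64)
        for name, seq in genome.chromosomes
    }
    secondary = None
    if secondary_motif:
        secondary = {
            name: np.asarray(find_recognition_sites(seq, secondary_motif), dtype=np.int64)
            for name, seq in genome.chromosomes
        }
    return SiteLibrary(
        primary_motif=primary_motif,
        positions=positions,
        chrom_lengths=genome.lengths,
        secondary_motif=secondary_motif,
        secondary_positions=secondary,
    )


def end_sequence(
    genome: Genome,
    motif_len: int,
    chrom: str,
    pos: int,
    side: str,
    length: int,
) -> str:
    """Captured-fragment sequence read outward from a ligation junction.

    The inverse-PCR read crosses the reconstituted recognition site and then
    continues into the captured fragment, so side ``"R"`` is the sequence
    immediately 3' of the motif on the forward strand and side ``"L"`` is the
    reverse complement of the sequence immediately 5' of the motif.
    """
    seq = genome.sequence(chrom)
    if side == "R":
        return seq[pos + motif_len : pos + motif_len + length]
    if side == "L":
        return revcomp(seq[max(0, pos - length) : pos])
    raise ValueError(f"side must be 'L' or 'R', got {side!r}")


def collapse_sides(sites: Iterable[tuple]) -> set[tuple[str, int]]:
    """Collapse side-level 4C site ids ``(chrom, pos, side)`` to positions."""
    out = set()
    for site in sites:
        if len(site) == 3:
            out.add((site[0], int(site[1])))
        elif len(site) == 2:
            out.add((site[0], int(site[1])))
        else:
            raise ValueError(f"not a site id: {site!r}")
    return out
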