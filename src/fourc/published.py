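"""Published summary counts from the two-cell-line 8q24-enhancer 4C study
this pipeline re-implements.

The raw sequencing libraries were never deposited, so the printed summary
table is the only exact worked example available: per-replicate totals of
non-random interacting sites, their cis/trans split, and the replicate
overlaps.  These integers are inputs to arithmetic checks — every percentage
and overlap rate is recomputed from them at run time, never stored.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class SummaryRow:
    cell_line: str
    replicate: int
    read_pairs: int
    sites: int  # non-random (coverage > 1) sites
    cis_sites: int
    overlapping_sites: int | None = None  # reproducible across both replicates
    overlapping_cis_sites: int | None = None

    @property
    def trans_sites(self) -> int:
        return self.sites - self.cis_sites


SUMMARY_ROWS = [
    SummaryRow("LNCaP", 1, 27_518_509, 4_529, 403, 2_096, 208),
    SummaryRow("LNCaP", 2, 38_637_799, 3_840, 322),
    SummaryRow("C4-2B", 1, 25_060_263, 2_536, 208, 897, 102),
    SummaryRow("C4-2B", 2, 39_250_858, 2_041, 181),
]

# Replicate site-set sizes and their intersection, per cell line.
OVERLAP_COUNTS = {
    "LNCaP": {"n_a": 4_529, "n_b": 3_840, "n_shared": 2_096},
    "C4-2B": {"n_a": 2_536, "n_b": 2_041, "n_shared": 897},
}
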