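"""Light-weight validated readers/writers for the tabular formats the
pipeline exchanges: BED (0-based half-open) tag tracks and SNP tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file; malformed records raise with a line number."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated SNP table with columns chrom, pos, id."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SNP table missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP ids")
    return df
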