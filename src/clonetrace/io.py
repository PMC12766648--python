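"""Readers and writers for the pipeline's tables.

Everything travels as long-format TSV (the formats emitted by the synthetic
generator and accepted by each analysis stage), plus YAML for simulation
configs and FASTA window extraction (via pyfaidx) for the artifact filter.
Every writer has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from .simulate import SimConfig

__all__ = [
    "write_table",
    "read_variants",
    "read_amplicons",
    "read_cells",
    "read_tally",
    "read_panel_reads",
    "write_config",
    "read_config",
    "windows_from_fasta",
]

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_variants(path: str | Path) -> pd.DataFrame:
    """Long variant table: variant, region, aaf (fraction), depth."""
    return _read(path, ["variant", "region", "aaf", "depth"])


def read_amplicons(path: str | Path) -> pd.DataFrame:
    return _read(path, ["variant", "region", "primer", "depth", "alt_reads"])


def read_cells(path: str | Path) -> pd.DataFrame:
    return _read(path, ["cell_id", "region", "cell_type"])


def read_tally(path: str | Path) -> pd.DataFrame:
    return _read(path, ["cell", "variant", "total_umis", "mut_umis"])


def read_panel_reads(path: str | Path) -> pd.DataFrame:
    return _read(path, ["cell", "site", "total_reads", "alt_reads"])


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimConfig(**data)


def windows_from_fasta(
    fasta_path: str | Path, sites: pd.DataFrame, half_width: int = 20
) -> pd.DataFrame:
    """Attach reference windows (2*half_width+1 bases, centered) to sites.

    ``sites`` needs columns chrom, pos (1-based), ref, alt.  Positions too
    close to a contig edge are padded with ``N`` (masked downstream).
    """
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    windows = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        seq = str(fa[str(chrom)][:])
        i = int(pos) - 1
        lo, hi = i - half_width, i + half_width + 1
        win = seq[max(lo, 0) : min(hi, len(seq))]
        win = "N" * max(0, -lo) + win + "N" * max(0, hi - len(seq))
        windows.append(win)
    out = sites.copy()
    out["window"] = windows
    return out
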