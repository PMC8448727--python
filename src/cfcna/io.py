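"""Readers and writers for the flat-text formats used by the pipeline.

Formats: fixed-step WIG (per-bin tracks), TSV bin tracks, SEG-like segment
tables (1-based inclusive coordinates, as is conventional for SEG), 3-column
BED (0-based half-open) and gene coordinate tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinTrack, GenomeGrid, make_genome_grid

TRACK_COLUMNS = ["chrom", "start", "end", "value", "gc", "mappability", "masked"]


# ---------------------------------------------------------------------------
# fixed-step WIG


def write_fixedstep_wig(path: str | Path, grid: GenomeGrid, values: np.ndarray) -> None:
    """Write one fixed-step WIG block per chromosome (step = span = bin size)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for chrom, sl in grid.chrom_slices():
            fh.write(
                f"fixedStep chrom={chrom} start={int(grid.bin_start[sl.start]) + 1} "
                f"step={grid.bin_size} span={grid.bin_size}\n"
            )
            for v in values[sl]:
                fh.write(f"{v:.6g}\n")


def read_fixedstep_wig(path: str | Path, grid: GenomeGrid) -> np.ndarray:
    """Read a fixed-step WIG into an array aligned to ``grid``."""
    out = np.full(grid.n_bins, np.nan)
    slices = dict(grid.chrom_slices())
    chrom, cursor = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                if chrom not in slices:
                    raise ValueError(f"chromosome {chrom!r} not in grid")
                start = int(fields["start"]) - 1
                if int(fields["step"]) != grid.bin_size:
                    raise ValueError("WIG step does not match grid bin size")
                sl = slices[chrom]
                offset = (start - int(grid.bin_start[sl.start])) // grid.bin_size
                cursor = sl.start + offset
            else:
                if chrom is None:
                    raise ValueError("WIG data line before fixedStep header")
                out[cursor] = float(line)
                cursor += 1
    return out


def read_fixedstep_wig_with_grid(path: str | Path) -> tuple[GenomeGrid, np.ndarray]:
    """Read a fixed-step WIG and reconstruct its grid from the headers."""
    chroms: dict[str, list[float]] = {}
    bin_size = None
    current: list[float] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                step = int(fields["step"])
                if bin_size is None:
                    bin_size = step
                elif step != bin_size:
                    raise ValueError("inconsistent WIG step sizes")
                current = chroms.setdefault(fields["chrom"], [])
            else:
                if current is None:
                    raise ValueError("WIG data line before fixedStep header")
                current.append(float(line))
    if bin_size is None:
        raise ValueError("empty WIG file")
    lengths = {c: len(v) * bin_size for c, v in chroms.items()}
    grid = make_genome_grid(lengths, bin_size)
    values = np.concatenate([np.asarray(chroms[c]) for c in grid.chrom_names])
    return grid, values


# ---------------------------------------------------------------------------
# TSV bin tracks


def write_track_tsv(path: str | Path, track: BinTrack) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track_tsv(path: str | Path, grid: GenomeGrid | None = None) -> BinTrack:
    df = pd.read_csv(path, sep="\t")
    if grid is None:
        grid = grid_from_frame(df)
    return BinTrack(
        grid=grid,
        values=df["value"].to_numpy(),
        gc=df["gc"].to_numpy() if df["gc"].notna().any() else None,
        mappability=(
            df["mappability"].to_numpy() if df["mappability"].notna().any() else None
        ),
        mask=df["masked"].to_numpy(dtype=bool),
    )


def grid_from_frame(df: pd.DataFrame) -> GenomeGrid:
    """Reconstruct a grid from a (chrom, start, end) bin table."""
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    lengths: dict[str, int] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        lengths[str(chrom)] = int(sub["end"].max())
    return make_genome_grid(lengths, bin_size)


# ---------------------------------------------------------------------------
# SEG-like segment tables


def write_seg(path: str | Path, segments: pd.DataFrame) -> None:
    """Write a segment table with 1-based inclusive coordinates."""
    out = segments.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like table back to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# BED and gene tables


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return df


_ENSEMBL_COLUMNS = {
    "Gene stable ID": "gene_id",
    "Chromosome/scaffold name": "chrom",
    "Gene start (bp)": "start",
    "Gene end (bp)": "end",
    "Strand": "strand",
    "HGNC symbol": "symbol",
    "Gene name": "symbol",
}

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "symbol"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene coordinate table.

    Accepts either a TSV with Ensembl-style attribute columns (gene stable
    id, chromosome, start, end, strand, HGNC symbol), a TSV already using
    the canonical column names, or a 6-column BED (name column = symbol).
    """
    df = pd.read_csv(path, sep="\t")
    if set(GENE_COLUMNS) <= set(df.columns):
        out = df[GENE_COLUMNS].copy()
    elif any(c in df.columns for c in _ENSEMBL_COLUMNS):
        out = df.rename(columns=_ENSEMBL_COLUMNS)
        if "symbol" not in out.columns or "gene_id" not in out.columns:
            raise ValueError("gene table missing id or symbol column")
        out = out.loc[:, ~out.columns.duplicated()][GENE_COLUMNS]
    else:
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "symbol", "score", "strand"],
        )
        out = pd.DataFrame(
            {
                "gene_id": bed["symbol"],
                "chrom": bed["chrom"],
                "start": bed["start"],
                "end": bed["end"],
                "strand": bed["strand"],
                "symbol": bed["symbol"],
            }
        )
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    strand = out["strand"].astype(str).map({"1": "+", "-1": "-", "+": "+", "-": "-"})
    out["strand"] = strand.fillna("+")
    if (out["start"] >= out["end"]).any():
        raise ValueError("gene table has start >= end")
    return out.reset_index(drop=True)
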