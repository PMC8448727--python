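"""Genomic bin grids and per-bin value tracks.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only in SEG output (see :mod:`cfcna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000

#: Small genome used throughout the test-suite: 4 chromosomes x 125 Mb
#: gives 500 bins at the default 1 Mb bin size.
TOY_CHROM_LENGTHS: dict[str, int] = {f"chr{i}": 125_000_000 for i in range(1, 5)}

#: GRCh37/hg19 autosome lengths (bp).
HG19_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
}


@dataclass(frozen=True, eq=False)
class GenomeGrid:
    """Ordered, non-overlapping, fixed-width bins over a chromosome set.

    Bins are emitted in input chromosome order, then by position.  Trailing
    partial bins (shorter than ``bin_size``) are dropped so that every bin
    has exactly the same width.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    bin_chrom: np.ndarray  #: integer chromosome code per bin
    bin_start: np.ndarray
    bin_end: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.bin_start.size)

    @property
    def bin_chrom_names(self) -> np.ndarray:
        """Chromosome name (object array) for every bin."""
        return np.asarray(self.chrom_names, dtype=object)[self.bin_chrom]

    def chrom_slices(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom_name, slice_into_bin_arrays)`` per chromosome."""
        for code, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.bin_chrom == code)
            if idx.size:
                yield name, slice(int(idx[0]), int(idx[-1]) + 1)

    def equals(self, other: "GenomeGrid") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bin_chrom_names,
                "start": self.bin_start,
                "end": self.bin_end,
            }
        )


def make_genome_grid(
    chrom_lengths: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> GenomeGrid:
    """Build a :class:`GenomeGrid` from chromosome lengths.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping of chromosome name to length in bp.
    bin_size
        Bin width in bp; trailing partial bins are dropped.
    """
    if not chrom_lengths:
        raise ValueError("no chromosomes")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    names = tuple(chrom_lengths)
    lengths = tuple(int(chrom_lengths[n]) for n in names)
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")

    chrom_codes, starts = [], []
    for code, length in enumerate(lengths):
        n = length // bin_size
        chrom_codes.append(np.full(n, code, dtype=np.int64))
        starts.append(np.arange(n, dtype=np.int64) * bin_size)
    bin_chrom = np.concatenate(chrom_codes) if chrom_codes else np.empty(0, np.int64)
    bin_start = np.concatenate(starts) if starts else np.empty(0, np.int64)
    return GenomeGrid(
        chrom_names=names,
        chrom_lengths=lengths,
        bin_size=int(bin_size),
        bin_chrom=bin_chrom,
        bin_start=bin_start,
        bin_end=bin_start + int(bin_size),
    )


@dataclass
class BinTrack:
    """Per-bin values aligned to a :class:`GenomeGrid`.

    ``values`` holds raw counts or log2 ratios; masked bins always carry
    NaN, never zero.  ``gc`` and ``mappability`` are optional per-bin
    annotations used by the normalization stage.
    """

    grid: GenomeGrid
    values: np.ndarray
    gc: np.ndarray | None = None
    mappability: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.size != n:
            raise ValueError("value vector length does not match grid bin count")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            if self.mask.size != n:
                raise ValueError("mask length does not match grid bin count")
        for name in ("gc", "mappability"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"{name} length does not match grid bin count")
                setattr(self, name, arr)
        self.values[self.mask] = np.nan

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    @property
    def n_unmasked(self) -> int:
        return int(np.count_nonzero(~self.mask))

    def with_values(
        self, values: np.ndarray, mask: np.ndarray | None = None
    ) -> "BinTrack":
        """New track sharing grid/annotations but with different values."""
        return BinTrack(
            grid=self.grid,
            values=values,
            gc=self.gc,
            mappability=self.mappability,
            mask=self.mask if mask is None else mask,
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["value"] = self.values
        df["gc"] = self.gc if self.gc is not None else np.nan
        df["mappability"] = self.mappability if self.mappability is not None else np.nan
        df["masked"] = self.mask
        return df


def _runs(keys: np.ndarray, chrom: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``keys`` and ``chrom`` are both constant."""
    n = keys.size
    if n == 0:
        return []
    change = np.flatnonzero((keys[1:] != keys[:-1]) | (chrom[1:] != chrom[:-1])) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class TruthProfile:
    """Ground-truth copy-number profile for one simulated patient.

    Per-bin representation: ``copy_number`` is the clonal tumor copy number
    and ``prevalence`` the cellular prevalence of the event (1.0 for clonal
    bins and unaltered background).  Tumor ploidy is the bin-weighted mean
    copy number; with fixed-width bins that is the plain mean.
    """

    patient_id: str
    grid: GenomeGrid
    copy_number: np.ndarray
    prevalence: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=np.int64)
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if self.copy_number.size != self.grid.n_bins:
            raise ValueError("copy_number length does not match grid")
        if self.prevalence.size != self.grid.n_bins:
            raise ValueError("prevalence length does not match grid")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if np.any((self.prevalence <= 0) | (self.prevalence > 1)):
            raise ValueError("prevalence must be in (0, 1]")

    @property
    def tumor_ploidy(self) -> float:
        return float(self.copy_number.mean())

    def effective_copy(self, normal_ploidy: float = 2.0) -> np.ndarray:
        """Prevalence-weighted copy number seen by a bulk sample."""
        s = self.prevalence
        return s * self.copy_number + (1.0 - s) * normal_ploidy

    def segments(self) -> pd.DataFrame:
        """Merge per-bin state into genomic segments (partition of the grid)."""
        key = np.stack([self.copy_number, (self.prevalence * 1e9).astype(np.int64)])
        combined = key[0] * 2_000_000_000 + key[1]
        rows = []
        for a, b in _runs(combined, self.grid.bin_chrom):
            rows.append(
                {
                    "sample": self.patient_id,
                    "chrom": self.grid.chrom_names[self.grid.bin_chrom[a]],
                    "start": int(self.grid.bin_start[a]),
                    "end": int(self.grid.bin_end[b - 1]),
                    "n_bins": b - a,
                    "copy_number": int(self.copy_number[a]),
                    "prevalence": float(self.prevalence[a]),
                }
            )
        return pd.DataFrame(rows)
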