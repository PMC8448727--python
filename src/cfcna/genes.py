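"""Gene-level annotation of copy-number segments and cohort frequencies."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeGrid

CATEGORIES = ("loss", "neutral", "gain", "amplification")
NO_CALL = "no-call"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    symbol: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene start must be < end")


def categorize_cn(copy_number: int) -> str:
    """Copy-number category: <2 loss, 2 neutral, 3-4 gain, >4 amplification."""
    cn = int(copy_number)
    if cn < 0:
        raise ValueError("negative copy number")
    if cn < 2:
        return "loss"
    if cn == 2:
        return "neutral"
    if cn <= 4:
        return "gain"
    return "amplification"


def packaged_gene_panel() -> pd.DataFrame:
    """The 15-gene breast-cancer panel (hg19 coordinates) shipped with the
    package so tests and demos run offline."""
    from . import io as cio

    with resources.as_file(
        resources.files("cfcna").joinpath("data/gene_panel_hg19.tsv")
    ) as path:
        return cio.read_gene_table(path)


def synthetic_gene_table(
    grid: GenomeGrid, n_genes: int = 15, gene_length: int | None = None
) -> pd.DataFrame:
    """Deterministic gene table spread evenly over a grid (for toy genomes)."""
    if gene_length is None:
        gene_length = max(grid.bin_size // 2, 1)
    step = max(grid.n_bins // n_genes, 1)
    rows = []
    for g in range(n_genes):
        b = min(g * step, grid.n_bins - 1)
        start = int(grid.bin_start[b]) + grid.bin_size // 4
        rows.append(
            {
                "gene_id": f"SYNG{g + 1:04d}",
                "chrom": grid.chrom_names[grid.bin_chrom[b]],
                "start": start,
                "end": start + gene_length,
                "strand": "+" if g % 2 == 0 else "-",
                "symbol": f"GENE{g + 1}",
            }
        )
    return pd.DataFrame(rows)


def assign_gene_cn(
    genes: pd.DataFrame, segments: pd.DataFrame, patient_id: str = "sample"
) -> pd.DataFrame:
    """Assign each gene the copy number of its largest-overlap segment.

    Ties break toward the copy number farthest from 2, then toward the
    lower genomic coordinate.  Genes with no overlapping segment get a
    ``no-call`` (excluded from frequency denominators).
    """
    rows = []
    for gene in genes.itertuples(index=False):
        seg = segments[segments["chrom"] == gene.chrom]
        best = None  # (overlap, |cn-2|, -start, cn)
        for srow in seg.itertuples(index=False):
            ov = min(gene.end, srow.end) - max(gene.start, srow.start)
            if ov <= 0:
                continue
            key = (ov, abs(srow.copy_number - 2), -srow.start)
            if best is None or key > best[0]:
                best = (key, int(srow.copy_number))
        if best is None:
            rows.append(
                {
                    "patient": patient_id,
                    "symbol": gene.symbol,
                    "copy_number": pd.NA,
                    "category": NO_CALL,
                    "overlap_fraction": 0.0,
                }
            )
        else:
            cn = best[1]
            rows.append(
                {
                    "patient": patient_id,
                    "symbol": gene.symbol,
                    "copy_number": cn,
                    "category": categorize_cn(cn),
                    "overlap_fraction": best[0][0] / (gene.end - gene.start),
                }
            )
    out = pd.DataFrame(rows)
    out["copy_number"] = out["copy_number"].astype("Int64")
    return out


def cohort_matrix(calls: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Genes x patients category matrix from per-patient call tables."""
    long = pd.concat(list(calls), ignore_index=True)
    return long.pivot(index="symbol", columns="patient", values="category")


def cohort_frequency(
    table: pd.DataFrame, gene: str, categories: Sequence[str] | set[str]
) -> tuple[int, float]:
    """Count and percentage (one decimal) of patients whose category at
    ``gene`` falls in ``categories``, over patients with a call."""
    if gene not in table.index:
        raise KeyError("gene not in cohort table")
    row = table.loc[gene]
    called = row[row != NO_CALL].dropna()
    if called.empty:
        raise ValueError("no patients with a call for gene")
    count = int(called.isin(set(categories)).sum())
    return count, round(100.0 * count / len(called), 1)
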