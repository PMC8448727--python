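"""Raw bin counts -> masked, bias-corrected, panel-normalized log2 ratios.

Order of operations for a sample: mask low-mappability and centromeric
bins, fit-and-divide a local regression of counts against GC then against
mappability, center by the median to obtain a ratio track, log2-transform
(zero-coverage bins are masked), and subtract the per-bin median of a
panel of normals processed the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinTrack


@dataclass
class NormalizationConfig:
    mappability_threshold: float = 0.75
    centromeres: pd.DataFrame | None = None  # columns chrom, start, end
    loess_span: float = 0.3
    robustness_iters: int = 2
    min_unmasked: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.mappability_threshold <= 1.0:
            raise ValueError("mappability threshold must be in [0, 1]")


def apply_masks(track: BinTrack, config: NormalizationConfig) -> BinTrack:
    """Mask bins overlapping centromere intervals or with low mappability."""
    mask = track.mask.copy()
    if track.mappability is not None:
        mask |= track.mappability < config.mappability_threshold
    if config.centromeres is not None and len(config.centromeres):
        grid = track.grid
        names = grid.bin_chrom_names
        for row in config.centromeres.itertuples(index=False):
            hit = (
                (names == row.chrom)
                & (grid.bin_start < int(row.end))
                & (grid.bin_end > int(row.start))
            )
            mask |= hit
    return track.with_values(track.values, mask=mask)


def _local_fit(
    x: np.ndarray, y: np.ndarray, span: float, iters: int
) -> np.ndarray:
    """Robust tricube-weighted local linear fit of y on x, evaluated at x."""
    if np.ptp(x) < 1e-12:  # degenerate covariate: nothing to correct
        return np.full_like(y, float(np.median(y)))
    fitted = lowess(y, x, frac=span, it=iters, return_sorted=False)
    floor = 1e-8 * max(float(np.median(np.abs(y))), 1.0)
    return np.maximum(fitted, floor)


def correct_gc_mappability(
    track: BinTrack, config: NormalizationConfig | None = None
) -> BinTrack:
    """Two-pass local-regression bias correction, then median centering.

    Returns a ratio track whose unmasked median is 1.  Masked bins stay
    missing.
    """
    config = config or NormalizationConfig()
    ok = track.unmasked
    if int(ok.sum()) < config.min_unmasked:
        raise ValueError("insufficient bins for bias fit")
    y = track.values[ok].astype(float)
    for covariate in (track.gc, track.mappability):
        if covariate is None:
            continue
        fitted = _local_fit(
            covariate[ok], y, config.loess_span, config.robustness_iters
        )
        y = y / fitted
    y = y / np.median(y)
    values = np.full(track.grid.n_bins, np.nan)
    values[ok] = y
    return track.with_values(values)


def log2_ratio(track: BinTrack) -> BinTrack:
    """log2-transform a ratio track; non-positive bins are masked
    ("zero coverage")."""
    ok = track.unmasked & (np.nan_to_num(track.values, nan=-1.0) > 0)
    values = np.full(track.grid.n_bins, np.nan)
    values[ok] = np.log2(track.values[ok])
    return track.with_values(values, mask=~ok)


def subtract_panel(log2_track: BinTrack, panel: list[BinTrack]) -> BinTrack:
    """Subtract the per-bin median of panel log2 ratios.

    Bins masked in the sample, or masked in more than half the panel, are
    masked in the output.  The panel median uses unmasked donor values only.
    """
    for donor in panel:
        if not donor.grid.equals(log2_track.grid):
            raise ValueError("panel grid mismatch")
    stack = np.vstack([d.values for d in panel])  # masked donors are NaN
    n_masked = np.vstack([d.mask for d in panel]).sum(axis=0)
    with warnings.catch_warnings():
        # bins masked in every donor yield an all-NaN median; they are
        # masked below, so the warning is expected noise
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    mask = log2_track.mask | (n_masked > len(panel) / 2) | ~np.isfinite(med)
    values = log2_track.values - med
    return log2_track.with_values(values, mask=mask)


def build_panel_log2(
    panel_counts: list[BinTrack], config: NormalizationConfig | None = None
) -> list[BinTrack]:
    """Run mask/correct/log2 on every panel donor count track."""
    config = config or NormalizationConfig()
    out = []
    for donor in panel_counts:
        t = apply_masks(donor, config)
        t = correct_gc_mappability(t, config)
        out.append(log2_ratio(t))
    return out


def normalize_sample(
    counts: BinTrack,
    panel_log2: list[BinTrack] | None = None,
    config: NormalizationConfig | None = None,
) -> BinTrack:
    """Full normalization chain for one sample count track."""
    config = config or NormalizationConfig()
    t = apply_masks(counts, config)
    t = correct_gc_mappability(t, config)
    t = log2_ratio(t)
    if panel_log2:
        t = subtract_panel(t, panel_log2)
    return t
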