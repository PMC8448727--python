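"""Seeded synthetic cfDNA cohort generation.

Produces ground-truth copy-number profiles, negative-binomially distributed
per-bin read counts at two sequencing depths (an ultra-low-pass and a deep
profile that differ only in count scale and dispersion), a healthy-donor
panel for normalization, injected GC bias, and cohort metadata.

Randomness is split into documented sub-streams of a single seed (GC track,
event placement, patient counts, panel donors) so that, e.g., changing the
number of panel donors never perturbs patient counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .genome import BinTrack, GenomeGrid, TruthProfile

# Sub-stream tags combined with the user seed to build independent
# generators (np.random.default_rng accepts a sequence of integers).
_STREAM_GC = 11
_STREAM_PROFILE = 12
_STREAM_COUNTS = 13
_STREAM_PANEL = 14
_STREAM_META = 15

DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.005, 0.01, 0.02, 0.04, 0.08, 0.15, 0.30, 0.40)

NORMAL_PLOIDY = 2.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


@dataclass(frozen=True)
class SimulationConfig:
    """Count model for one sequencing depth.

    The negative-binomial dispersion ``r`` gives per-bin variance
    ``m + m**2 / r`` at mean ``m``; larger ``r`` means tighter counts.
    """

    depth: str = "30x"
    mean_reads_per_bin: float = 20_000.0
    dispersion: float = 1_000.0
    n_normal_donors: int = 27
    gc_bias_linear: float = 0.8
    gc_bias_quad: float = -2.0

    def __post_init__(self) -> None:
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean reads per bin must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


#: Default count models for the two depth labels.  The deep profile has
#: both a larger count scale and a much smaller relative overdispersion,
#: matching the observation that deep WGS log-ratio tracks are far tighter
#: than ultra-low-pass ones.
DEPTH_PRESETS: dict[str, SimulationConfig] = {
    "0.1x": SimulationConfig(depth="0.1x", mean_reads_per_bin=600.0, dispersion=60.0),
    "30x": SimulationConfig(depth="30x", mean_reads_per_bin=20_000.0, dispersion=1_000.0),
}


def simulate_gc_track(grid: GenomeGrid, seed: int) -> np.ndarray:
    """Per-bin GC fraction, uniform in [0.3, 0.6] (genome property, shared
    by all samples of a cohort)."""
    return _rng(seed, _STREAM_GC).uniform(0.3, 0.6, size=grid.n_bins)


def gc_bias(gc: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Smooth unimodal multiplicative coverage bias as a function of GC."""
    d = np.asarray(gc, dtype=float) - 0.45
    return np.clip(1.0 + config.gc_bias_linear * d + config.gc_bias_quad * d * d, 0.1, None)


def simulate_truth_profile(
    grid: GenomeGrid,
    n_events: int,
    event_size_range: tuple[int, int],
    cn_values: Sequence[int] = (0, 1, 3, 4, 5),
    subclonal_rate: float = 0.0,
    alpha: float = 0.1,
    seed: int = 0,
    patient_id: str = "P01",
    patient_index: int = 0,
) -> TruthProfile:
    """Place non-overlapping copy-number events on a diploid background.

    Events are rejection-sampled: a start bin and size are drawn, and the
    placement is rejected if it crosses a chromosome boundary or overlaps
    an existing event.  Subclonal events (copy number 1 or 3) receive a
    cellular prevalence drawn uniformly from [0.3, 0.8].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    lo, hi = int(event_size_range[0]), int(event_size_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("event sizes must be >= 1 bin")
    rng = _rng(seed, _STREAM_PROFILE, patient_index)
    cn_choices = [c for c in cn_values if c != 2]
    if n_events > 0 and not cn_choices:
        raise ValueError("cn_values must contain a non-neutral copy number")

    cn = np.full(grid.n_bins, 2, dtype=np.int64)
    prevalence = np.ones(grid.n_bins)
    occupied = np.zeros(grid.n_bins, dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = max(1000, 500 * n_events)
    while placed < n_events:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("genome too small for events")
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, grid.n_bins))
        end = start + size
        if end > grid.n_bins:
            continue
        if grid.bin_chrom[start] != grid.bin_chrom[end - 1]:
            continue
        if occupied[start:end].any():
            continue
        c = int(rng.choice(cn_choices))
        s = 1.0
        if c in (1, 3) and rng.random() < subclonal_rate:
            s = float(rng.uniform(0.3, 0.8))
        cn[start:end] = c
        prevalence[start:end] = s
        occupied[start:end] = True
        placed += 1
    return TruthProfile(
        patient_id=patient_id, grid=grid, copy_number=cn,
        prevalence=prevalence, alpha=float(alpha),
    )


def expected_bin_means(
    truth: TruthProfile, config: SimulationConfig, gc: np.ndarray
) -> np.ndarray:
    """Expected read count per bin under the mixture model.

    mean = depth_mean * g(gc) * (a*c_eff + (1-a)*2) / (a*phi_t + (1-a)*2)
    where ``c_eff`` is the prevalence-weighted copy number.
    """
    a = truth.alpha
    c_eff = truth.effective_copy(NORMAL_PLOIDY)
    num = a * c_eff + (1.0 - a) * NORMAL_PLOIDY
    den = a * truth.tumor_ploidy + (1.0 - a) * NORMAL_PLOIDY
    return config.mean_reads_per_bin * gc_bias(gc, config) * num / den


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_bin_counts(
    truth: TruthProfile,
    grid: GenomeGrid,
    config: SimulationConfig,
    gc: np.ndarray | None = None,
    seed: int = 0,
    stream: tuple[int, ...] = (),
) -> BinTrack:
    """Draw negative-binomial counts for one sample at one depth.

    ``stream`` selects a documented sub-stream (e.g. the patient index and
    depth code) so cohort draws are independent and reproducible.
    """
    if truth.grid is not grid and not truth.grid.equals(grid):
        raise ValueError("truth not defined on grid")
    if gc is None:
        gc = simulate_gc_track(grid, seed)
    rng = _rng(seed, _STREAM_COUNTS, *stream)
    mean = expected_bin_means(truth, config, gc)
    counts = _draw_nb(rng, mean, config.dispersion)
    return BinTrack(
        grid=grid, values=counts, gc=gc, mappability=np.ones(grid.n_bins)
    )


def simulate_panel_of_normals(
    grid: GenomeGrid,
    n_donors: int,
    config: SimulationConfig,
    gc: np.ndarray | None = None,
    seed: int = 0,
) -> list[BinTrack]:
    """Simulate healthy donors (alpha = 0) under the same GC-bias model."""
    if n_donors < 2:
        raise ValueError("panel too small")
    if gc is None:
        gc = simulate_gc_track(grid, seed)
    flat = TruthProfile(
        patient_id="NORMAL", grid=grid,
        copy_number=np.full(grid.n_bins, 2), prevalence=np.ones(grid.n_bins),
        alpha=0.0,
    )
    mean = expected_bin_means(flat, config, gc)
    donors = []
    depth_code = 0 if config.depth == "0.1x" else 1
    for d in range(n_donors):
        rng = _rng(seed, _STREAM_PANEL, depth_code, d)
        counts = _draw_nb(rng, mean, config.dispersion)
        donors.append(
            BinTrack(grid=grid, values=counts, gc=gc, mappability=np.ones(grid.n_bins))
        )
    return donors


# ---------------------------------------------------------------------------
# cohort-level generation


@dataclass
class CohortSim:
    """In-memory result of a cohort simulation."""

    grid: GenomeGrid
    gc: np.ndarray
    truths: list[TruthProfile]
    counts: dict[str, list[BinTrack]]  # depth label -> per-patient tracks
    panels: dict[str, list[BinTrack]]
    metadata: pd.DataFrame


def simulate_cohort(
    grid: GenomeGrid,
    alphas: Sequence[float] | None = None,
    configs: Mapping[str, SimulationConfig] | None = None,
    seed: int = 0,
    n_patients: int = 15,
    n_events: int = 8,
    event_size_range: tuple[int, int] = (10, 30),
    cn_values: Sequence[int] = (0, 1, 3, 4, 5),
    subclonal_rate: float = 0.0,
) -> CohortSim:
    """Simulate a full two-depth cohort with a panel of normals.

    Patient tumor fractions default to cycling through
    :data:`DEFAULT_ALPHA_GRID`; each patient gets an independent truth
    profile shared by both depths.
    """
    if configs is None:
        configs = DEPTH_PRESETS
    if alphas is None:
        alphas = [DEFAULT_ALPHA_GRID[i % len(DEFAULT_ALPHA_GRID)] for i in range(n_patients)]
    else:
        alphas = list(alphas)
        n_patients = len(alphas)

    gc = simulate_gc_track(grid, seed)
    truths = [
        simulate_truth_profile(
            grid,
            n_events=n_events,
            event_size_range=event_size_range,
            cn_values=cn_values,
            subclonal_rate=subclonal_rate,
            alpha=alphas[i],
            seed=seed,
            patient_id=f"P{i + 1:02d}",
            patient_index=i,
        )
        for i in range(n_patients)
    ]
    counts: dict[str, list[BinTrack]] = {}
    panels: dict[str, list[BinTrack]] = {}
    for depth_code, (label, config) in enumerate(sorted(configs.items())):
        counts[label] = [
            simulate_bin_counts(t, grid, config, gc=gc, seed=seed, stream=(i, depth_code))
            for i, t in enumerate(truths)
        ]
        panels[label] = simulate_panel_of_normals(
            grid, config.n_normal_donors, config, gc=gc, seed=seed
        )

    meta_rng = _rng(seed, _STREAM_META)
    order = np.argsort(-np.asarray(alphas, dtype=float), kind="stable")
    subtype = np.array(["non-TNBC"] * n_patients, dtype=object)
    subtype[order[: max(1, n_patients // 3)]] = "TNBC"  # high-burden patients
    metadata = pd.DataFrame(
        {
            "patient": [t.patient_id for t in truths],
            "true_alpha": alphas,
            "subtype": subtype,
            "age_group": meta_rng.choice(["<50", ">=50"], size=n_patients),
            "grade": meta_rng.choice(["G2", "G3", "GU"], size=n_patients),
            "stage": meta_rng.choice(["2B", "3A", "3B", "NA"], size=n_patients),
            "size_class": meta_rng.choice(["2-5cm", ">5cm"], size=n_patients),
        }
    )
    return CohortSim(grid=grid, gc=gc, truths=truths, counts=counts, panels=panels, metadata=metadata)


def write_cohort(outdir: str | Path, sim: CohortSim) -> list[Path]:
    """Write a simulated cohort as flat text (TSV tracks, WIG GC, SEG truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save_track(path: Path, track: BinTrack) -> None:
        cio.write_track_tsv(path, track)
        written.append(path)

    gc_path = outdir / "gc.wig"
    cio.write_fixedstep_wig(gc_path, sim.grid, sim.gc)
    written.append(gc_path)

    truth_segments = pd.concat([t.segments() for t in sim.truths], ignore_index=True)
    truth_path = outdir / "truth_segments.seg"
    cio.write_seg(truth_path, truth_segments)
    written.append(truth_path)

    for label, tracks in sim.counts.items():
        tag = label.replace(".", "_")
        for truth, track in zip(sim.truths, tracks):
            _save_track(outdir / f"counts_{tag}_{truth.patient_id}.tsv", track)
            wig_path = outdir / f"counts_{tag}_{truth.patient_id}.wig"
            cio.write_fixedstep_wig(wig_path, sim.grid, track.values)
            written.append(wig_path)
    for label, donors in sim.panels.items():
        tag = label.replace(".", "_")
        for d, track in enumerate(donors):
            _save_track(outdir / f"panel_{tag}_N{d + 1:02d}.tsv", track)

    meta_path = outdir / "metadata.tsv"
    sim.metadata.to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)
    return written
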