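"""End-to-end orchestration: simulate -> normalize -> estimate (both depth
profiles) -> annotate -> concordance -> cohort stats.

Everything flows from one YAML config and one seed; every stage writes
flat TSV/WIG/SEG artifacts into its own subdirectory and the run ends with
a checksum manifest, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import genes as genes_mod
from . import io as cio
from . import normalize as norm
from . import simulate as sim
from . import stats as cstats
from .genome import TOY_CHROM_LENGTHS, HG19_AUTOSOME_LENGTHS, make_genome_grid
from .hmm import HMMConfig, fit_tumor_fraction, solution_summary

log = logging.getLogger("cfcna.pipeline")

STAGES = ("simulate", "normalize", "estimate", "annotate", "concordance", "cohort_stats")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cfcna_out"
    genome: str = "toy"  # "toy", "hg19", or a custom mapping
    chrom_lengths: dict[str, int] | None = None
    bin_size: int = 1_000_000
    n_patients: int = 15
    alphas: list[float] | None = None
    n_events: int = 8
    event_size_range: tuple[int, int] = (10, 30)
    subclonal_rate: float = 0.0
    depth_configs: dict[str, sim.SimulationConfig] = field(
        default_factory=lambda: dict(sim.DEPTH_PRESETS)
    )
    hmm_overrides: dict[str, Any] = field(default_factory=dict)
    gene_table: str | None = None
    thresholds: cstats.DetectionThresholds = field(default_factory=cstats.DetectionThresholds)
    min_concordance_tf: float = 0.03
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in (
            "seed", "outdir", "genome", "bin_size", "n_patients", "alphas",
            "n_events", "subclonal_rate", "gene_table", "min_concordance_tf",
            "log_level", "chrom_lengths", "hmm_overrides",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "event_size_range" in raw:
            cfg.event_size_range = tuple(raw["event_size_range"])
        if "depths" in raw:
            cfg.depth_configs = {}
            for label, dd in raw["depths"].items():
                cfg.depth_configs[label] = sim.SimulationConfig(depth=label, **dd)
        if "thresholds" in raw:
            cfg.thresholds = cstats.DetectionThresholds(**raw["thresholds"])
        return cfg

    def build_grid(self):
        if self.chrom_lengths:
            lengths = self.chrom_lengths
        elif self.genome == "toy":
            lengths = TOY_CHROM_LENGTHS
        elif self.genome == "hg19":
            lengths = HG19_AUTOSOME_LENGTHS
        else:
            raise ValueError(f"unknown genome: {self.genome!r}")
        return make_genome_grid(lengths, self.bin_size)

    def hmm_config(self, profile: str) -> HMMConfig:
        base = HMMConfig.deep_profile if profile == "deep" else HMMConfig.ulp_profile
        return base(**self.hmm_overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _depth_role(label: str, config: sim.SimulationConfig) -> str:
    """'deep' for the higher-coverage depth, 'ulp' for the other."""
    return label


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict[str, Any]:
    """Execute all six stages; returns (and writes) the artifact manifest."""
    outdir = Path(config.outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"output directory already has a manifest: {manifest_path}")
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    depth_labels = sorted(config.depth_configs)
    by_scale = sorted(
        depth_labels, key=lambda l: config.depth_configs[l].mean_reads_per_bin
    )
    ulp_label, deep_label = by_scale[0], by_scale[-1]

    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": [
                    {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                    for p in sorted(files)
                ],
            }
        )

    def stage_dir(stage: str) -> Path:
        d = outdir / stage
        d.mkdir(exist_ok=True)
        return d

    grid = config.build_grid()

    # -- stage 1: simulate ------------------------------------------------
    t0 = time.perf_counter()
    try:
        cohort = sim.simulate_cohort(
            grid,
            alphas=config.alphas,
            configs=config.depth_configs,
            seed=config.seed,
            n_patients=config.n_patients,
            n_events=config.n_events,
            event_size_range=config.event_size_range,
            subclonal_rate=config.subclonal_rate,
        )
        files = sim.write_cohort(stage_dir("simulate"), cohort)
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    record("simulate", files)
    log.info("simulate: %d patients, %.1fs", len(cohort.truths), time.perf_counter() - t0)

    # -- stage 2: normalize -----------------------------------------------
    t0 = time.perf_counter()
    ncfg = norm.NormalizationConfig()
    log2_tracks: dict[str, list] = {}
    files = []
    d = stage_dir("normalize")
    try:
        for label in depth_labels:
            panel_log2 = norm.build_panel_log2(cohort.panels[label], ncfg)
            log2_tracks[label] = []
            tag = label.replace(".", "_")
            for truth, counts in zip(cohort.truths, cohort.counts[label]):
                track = norm.normalize_sample(counts, panel_log2, ncfg)
                log2_tracks[label].append(track)
                path = d / f"log2_{tag}_{truth.patient_id}.tsv"
                cio.write_track_tsv(path, track)
                files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    record("normalize", files)
    log.info("normalize: %.1fs", time.perf_counter() - t0)

    # -- stage 3: estimate ------------------------------------------------
    t0 = time.perf_counter()
    files = []
    d = stage_dir("estimate")
    summaries: dict[str, pd.DataFrame] = {}
    seg_tables: dict[str, dict[str, pd.DataFrame]] = {}
    try:
        for label in depth_labels:
            profile = "deep" if label == deep_label else "ulp"
            hcfg = config.hmm_config(profile)
            rows, segs = [], {}
            tag = label.replace(".", "_")
            for truth, track in zip(cohort.truths, log2_tracks[label]):
                solution, _ = fit_tumor_fraction(track, hcfg)
                rows.append(solution_summary(solution, truth.patient_id))
                seg = solution.segments.copy()
                seg.insert(0, "sample", truth.patient_id)
                segs[truth.patient_id] = seg
                seg_path = d / f"segments_{tag}_{truth.patient_id}.seg"
                cio.write_seg(seg_path, seg)
                files.append(seg_path)
            summary = pd.DataFrame(rows)
            summaries[label] = summary
            seg_tables[label] = segs
            path = d / f"solutions_{tag}.tsv"
            summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
            files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'estimate' failed: {exc}") from exc
    record("estimate", files)
    log.info("estimate: %.1fs", time.perf_counter() - t0)

    # -- stage 4: annotate ------------------------------------------------
    t0 = time.perf_counter()
    files = []
    d = stage_dir("annotate")
    matrices: dict[str, pd.DataFrame] = {}
    try:
        if config.gene_table:
            gene_table = cio.read_gene_table(config.gene_table)
        elif config.genome == "hg19":
            gene_table = genes_mod.packaged_gene_panel()
        else:
            gene_table = genes_mod.synthetic_gene_table(grid)
        gt_path = d / "gene_table.tsv"
        gene_table.to_csv(gt_path, sep="\t", index=False)
        files.append(gt_path)
        for label in depth_labels:
            calls = [
                genes_mod.assign_gene_cn(gene_table, seg, patient_id=pid)
                for pid, seg in seg_tables[label].items()
            ]
            matrix = genes_mod.cohort_matrix(calls)
            matrices[label] = matrix
            tag = label.replace(".", "_")
            path = d / f"cohort_matrix_{tag}.tsv"
            matrix.to_csv(path, sep="\t")
            files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc
    record("annotate", files)
    log.info("annotate: %.1fs", time.perf_counter() - t0)

    # -- stage 5: concordance ---------------------------------------------
    t0 = time.perf_counter()
    files = []
    d = stage_dir("concordance")
    try:
        tf_deep = summaries[deep_label].set_index("sample")["tumor_fraction"]
        inp = conc.ConcordanceInput(
            table_a=matrices[ulp_label],
            table_b=matrices[deep_label],
            tumor_fraction=tf_deep,
            min_tumor_fraction=config.min_concordance_tf,
        )
        if inp.eligible_patients():
            report = conc.concordance_report(inp)
        else:
            report = {
                "per_gene": pd.DataFrame(columns=["gene", "concordance_pct"]),
                "per_patient": pd.DataFrame(
                    columns=["patient", "tumor_fraction", "tf_band", "concordance_pct"]
                ),
            }
        for name, df in report.items():
            path = d / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'concordance' failed: {exc}") from exc
    record("concordance", files)
    log.info("concordance: %.1fs", time.perf_counter() - t0)

    # -- stage 6: cohort stats --------------------------------------------
    t0 = time.perf_counter()
    files = []
    d = stage_dir("cohort_stats")
    try:
        cohort_table = cohort.metadata.copy()
        cohort_table["tumor_fraction_deep"] = (
            summaries[deep_label].set_index("sample")["tumor_fraction"]
            .reindex(cohort_table["patient"]).to_numpy()
        )
        cohort_table["tumor_fraction_ulp"] = (
            summaries[ulp_label].set_index("sample")["tumor_fraction"]
            .reindex(cohort_table["patient"]).to_numpy()
        )
        table_path = d / "cohort_table.tsv"
        cohort_table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
        files.append(table_path)

        rows = []
        for depth in ("deep", "ulp"):
            s = cstats.detection_summary(cohort_table, depth, config.thresholds)
            rows.append(
                {
                    "metric": f"detected_{depth}",
                    "value": f"{s.count}/{s.trials}",
                    "percent": s.percent,
                    "ci_low": s.ci_percent[0],
                    "ci_high": s.ci_percent[1],
                }
            )
        med, (q1, q3) = cstats.summarize_tf(cohort_table["tumor_fraction_deep"])
        rows.append({"metric": "median_tf_deep", "value": med, "percent": "", "ci_low": q1, "ci_high": q3})
        try:
            r, p = cstats.correlate_depths(
                cohort_table["tumor_fraction_deep"], cohort_table["tumor_fraction_ulp"]
            )
            rows.append({"metric": "pearson_r_depths", "value": r, "percent": "", "ci_low": p, "ci_high": ""})
        except ValueError:
            pass
        tnbc = cohort_table[cohort_table["subtype"] == "TNBC"]["tumor_fraction_deep"]
        rest = cohort_table[cohort_table["subtype"] != "TNBC"]["tumor_fraction_deep"]
        if len(tnbc) and len(rest):
            p = cstats.compare_groups(tnbc, rest)
            rows.append({"metric": "mannwhitney_p_tnbc", "value": p, "percent": "", "ci_low": "", "ci_high": ""})
        path = d / "summary.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'cohort_stats' failed: {exc}") from exc
    record("cohort_stats", files)
    log.info("cohort_stats: %.1fs", time.perf_counter() - t0)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
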