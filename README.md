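# cfcna

Tumor-fraction and somatic copy-number estimation from binned cell-free DNA
(cfDNA) whole-genome coverage, together with a fully synthetic cohort
generator so the entire analysis chain can be exercised offline.

The pipeline mirrors the standard ultra-low-pass WGS ctDNA workflow:

1. **simulate** (`cfcna.simulate`) — seeded synthetic cohorts: ground-truth
   segmental copy-number profiles on a 1 Mb bin grid, negative-binomial
   read counts at two sequencing depths (an ultra-low-pass "0.1x" profile
   and a deep "30x" profile differing in count scale and dispersion),
   injected quadratic GC bias, and a 27-donor panel of normals.
2. **normalize** (`cfcna.normalize`) — centromere/mappability masking
   (mappability threshold 0.75), two-pass robust local-regression
   correction of GC and mappability bias, median centering, log2
   transform, and subtraction of the per-bin panel-of-normals median.
3. **estimate** (`cfcna.hmm`) — the core estimator: a Student's-t-emission
   hidden Markov model over log2 ratios whose states are clonal copy
   numbers 0..5 plus subclonal CN 1 and 3 at a shared cellular prevalence.
   EM (forward–backward + coordinate-ascent M-step) is run over a grid of
   normal-fraction restarts {0.5..0.95} and ploidy restarts {2, 3} with
   sticky transitions (txnE = 0.99, transition pseudo-count strength 100).
   Solutions are filtered by subclonal-genome-fraction rules (< 0.5
   genome subclonal, < 0.7 per subclone), ranked by log-likelihood, and
   passed through a detection gate (minimum altered genome fraction and
   minimum altered segment length; 0.05/50 bins for the ULP profile,
   0.01/20 bins for the deep profile).
4. **annotate** (`cfcna.genes`) — largest-overlap assignment of segment
   copy number to genes; categories loss (<2), neutral (2), gain (3–4),
   amplification (>4); cohort-level category frequencies.
5. **concordance** (`cfcna.concordance`) — cross-depth agreement of
   3-level gene categories (amplification collapsed into gain): per gene
   across eligible patients (ctDNA fraction >= 3%) and per patient across
   a gene panel.
6. **cohort stats** (`cfcna.stats`) — detection proportions with exact
   Clopper–Pearson confidence intervals, median/IQR tumor-fraction
   summaries, Pearson correlation between depths, Mann–Whitney /
   Wilcoxon group comparisons.

## CLI

Everything is driven from one YAML config and one seed:

```bash
cfdna-pipeline run --config pipeline.yaml
```

Example `pipeline.yaml`:

```yaml
seed: 1
outdir: demo_out
genome: toy           # "toy" (500 bins), "hg19" (2875 bins), or chrom_lengths
n_patients: 15
n_events: 8
event_size_range: [10, 30]
depths:
  0.1x: {mean_reads_per_bin: 600, dispersion: 60}
  30x: {mean_reads_per_bin: 20000, dispersion: 1000}
thresholds: {deep: 0.01, ulp: 0.03}
```

The run writes flat TSV/WIG/SEG artifacts per stage plus a
`manifest.json` with SHA-256 checksums; rerunning with the same config and
seed reproduces identical checksums.

Individual stages are exposed as subcommands
(`simulate-cohort`, `normalize`, `estimate`, `annotate`, `concordance`,
`cohort-stats`); see `cfdna-pipeline <cmd> --help`.

## Notes on the estimator

- Emissions are Student's-t (df 2.1) with one shared variance across
  states; the variance update uses the standard latent-scale weights.
- Tumor ploidy is a continuous parameter softly anchored to its restart
  value, and solutions whose fitted ploidy disagrees with the
  genome-average called copy number are rejected as relabeled
  (ploidy-shifted) degenerate fits.
- Chains restart at chromosome boundaries; masked bins are skipped
  without transition decay. Fitting starts chains from the neutral state
  (weight 50) so uninformative chromosomes stay neutral at near-zero
  tumor fraction.
- Among solutions within a small log-likelihood window the least-altered
  one is selected — a reproducible stand-in for manual review of ranked
  solutions.
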