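# vstscan

Population-divergence scanning of copy number variation (CNV) from
SNP-array intensity signal.

Array-based CNV studies in livestock and other species call per-sample CNVs
(e.g. with PennCNV from Log R Ratio, LRR, and B Allele Frequency), merge the
calls across samples into CNV regions (CNVRs), and then ask which regions are
unusually differentiated between groups — a signature of divergent selection.
`vstscan` implements that analysis as a tested, reusable pipeline for anyone
working with PennCNV-style calls and a probe-level LRR matrix: population
geneticists scanning for selection on CNVs, and breeders characterising
structural variation across populations.

## The statistics

For a CNVR, each sample's signal is the mean LRR over all probes inside the
region span. Differentiation between groups *i* and *j* is

```
V_ST = (V_T − V_S) / V_T
```

where *V_T* is the sample variance (denominator *n*−1) of the pooled values of
the two groups and *V_S* = (*n_i v_i* + *n_j v_j*)/(*n_i* + *n_j*) is the
size-weighted mean of the within-group variances — the quantitative analogue
of F_ST for copy-number intensity. *V_ST* ≤ 1, may be negative, and is defined
as 0 when *V_T* = 0.

The group-specific divergence of one region for group *i* is

```
V_i = Σ_{j≠i} ( V_ST^ij − E[V_ST^ij] ) / sd[V_ST^ij]
```

with *E* and *sd* taken over the whole analysis region set, so each term is a
genome-wide standardized deviation. Large positive *V_i* flags regions far
more differentiated between group *i* and the rest than the genome at large.
Candidates are the top empirical 1% and 5% of *V_i* per group
(round-half-up of quantile × *n*); candidate sets are then partitioned into
shared vs. group-specific regions, and annotated against gene/CDS/exon
intervals.

The pipeline also covers the surrounding steps: sample QC (call rate > 0.95,
pairwise PI-HAT < 0.25 relatedness pruning, PennCNV signal-quality thresholds
LRR SD ≤ 0.35, BAF drift ≤ 0.01, |waviness| ≤ 0.05), CNVR compilation by
≥ 1 bp overlap with gain/loss/both typing, removal of single-event regions
before the scan, and Table-style cohort summaries.

Because raw SNP-array cohorts are rarely redistributable, the package ships a
synthetic-cohort generator (`vstscan.simulate`) whose defaults emulate a
157-sample cohort in four groups (35/17/63/42) over 29 autosomes: Bernoulli
group-specific carrier frequencies, copy-number-dependent LRR means
(cn1 ≈ −0.45, cn3 ≈ +0.3) and Gaussian probe noise, plus a truth table and a
closed-form expected *V_ST* for validation.

## Worked example

```bash
cat > sim.yaml <<'YAML'
seed: 42
groups: [[North, 35], [Northwest, 17], [Southwest, 63], [South, 42]]
n_chrom: 4
chrom_length_bp: 2000000
probe_spacing_bp: 10000
lrr_noise_sd: 0.2
YAML
vstscan --config sim.yaml simulate --out-dir cohort
vstscan merge --calls cohort/calls.rawcnv --out cnvr.tsv
vstscan scan --calls cohort/calls.rawcnv --lrr cohort/lrr.tsv \
        --groups cohort/groups.tsv --quantiles 0.05 --out-dir scan
```

prints

```
simulated 157 samples, 800 probes, 1158 CNV calls -> cohort
1158 calls -> 36 CNVRs -> cnvr.tsv
36 CNVRs (34 after singleton filtering); results in scan
```

The default truth set contains one strongly differentiated region per group
(carrier frequency 0.8 there, 0.05 elsewhere). The scan recovers it:
`scan/candidates_North_0.05.tsv` begins

```
group   rank  cnvr_id  vi           quantile  threshold_vi
North   1     CNVR1    13.00355805  0.05      3.247210596
```

CNVR1 is exactly the span of the North-specific simulated deletion; its
*V_i* of 13.0 means its three pairwise *V_ST* values against the other groups
sit a combined thirteen standard deviations above their genome-wide means.
`scan/` also holds the pairwise `vst.tsv`, the full `vi.tsv`, a
Manhattan-ready table, the shared/specific Venn partition and per-group LRR
box-plot summaries for the candidates. The same objects are available from
Python via `vstscan.simulate_cohort`, `vstscan.run_scan`, etc.

`vstscan summarize` reports cohort statistics (event counts, mean CNV/CNVR
lengths, per-sample rate, percent of genome covered), and
`vstscan annotate` intersects a CNVR table with a 5-column gene BED.

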