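# Methods

## Signal model and statistics

A CNVR's quantitative signal for sample *s* is the arithmetic mean of that
sample's LRR over every probe whose position lies inside the region's closed
span `[start, end]`. Missing probe values are excluded from the mean and a
sample with no observed in-region probe is missing for that region; missing
samples are dropped pairwise in each V_ST computation (never imputed). A
region with zero probes in its span is an error; the pipeline drops such
regions with a warning.

Pairwise differentiation between groups *i* and *j* is
`V_ST = (V_T − V_S)/V_T`. All variances use denominator *n*−1. Design
choices where the definition is genuinely open:

* **V_T is the pooled variance of the two groups of the pair**, not of the
  whole cohort. V_ST is inherently pairwise; computing V_T per pair makes
  every pair's statistic self-contained and keeps `vst()` a pure function of
  the two groups' values.
* **V_S weights are raw group sizes** `(n_i v_i + n_j v_j)/(n_i + n_j)`,
  the simplest reading of "weighted for sample size".
* **V_T = 0 maps to V_ST = 0**: no variance anywhere means no
  differentiation. Negative V_ST values (within-group variance exceeding
  pooled) are retained, not clipped.

The group-divergence statistic is
`V_i = Σ_{j≠i} (V_ST^ij − E[V_ST^ij]) / sd[V_ST^ij]`, the sum over the other
groups of genome-wide standardized pairwise V_ST. E and sd are the mean and
(*n*−1) standard deviation of that pair's V_ST across the **analysis set**:
the singleton-filtered region list (regions with ≥ 2 supporting CNV events).
Per-pair standardized terms therefore have mean 0 and sd 1 over that set by
construction (asserted to 1e−9 in tests). A pair whose V_ST is constant
across all regions has sd 0 and is reported as an error rather than silently
producing infinities. With four groups each V_i is a sum of three terms; with
two groups both groups share the single term.

Candidate selection takes the top `k = round-half-up(q·n)` regions per group
by descending V_i (q ∈ {0.01, 0.05} by default; 1,232 regions give k = 12
and 62). Ties at the cut are broken by ascending region id so selection is
deterministic; `threshold_vi` is the V_i of the k-th region. k = 0 is an
error, steering the caller to a larger set instead of returning nothing.

## CNVR compilation

Calls merge per chromosome by single-linkage transitive closure of ≥ 1 bp
overlap between closed intervals (`a.start ≤ b.end and b.start ≤ a.end`);
abutting calls (end + 1 = start) do not merge, matching BEDTools-merge
defaults. The region span is the union of member spans; type is `gain` iff
all members are gains, `loss` iff all losses, otherwise `both`. `is_unique`
flags regions whose events all come from one individual; singleton filtering
(the pre-scan step) removes regions with fewer than 2 events. The two notions
coincide when no individual carries two calls merged into one region. Ids are
`CNVR<k>` in genome order (numeric chromosomes first, then others
lexicographically). All lengths are `end − start + 1`.

Summary percentages divide total CNVR length by configurable genome sizes;
the defaults (2,545.9 Mb autosomal, 2,918.0 Mb whole) are the standard
bovine UMD3.1 figures, supplied as constants rather than computed from an
assembly.

## Sample QC

Call rate passes on strict `>` (threshold 0.95); the PennCNV signal metrics
pass on `≤` at the boundary (LRR SD ≤ 0.35, BAF drift ≤ 0.01,
|waviness| ≤ 0.05), PennCNV's conventional usage. Both conventions are
configurable. Relatedness pruning removes, repeatedly, the sample in the
most PI-HAT ≥ 0.25 pairs (ties: lexicographically smallest id) until no
related pair survives — a deterministic greedy vertex cover; the suite
checks the no-surviving-pair postcondition by brute force. All filters are
idempotent.

## Synthetic cohorts

`SimConfig` defaults encode the cohort design the pipeline targets: four
groups of 35/17/63/42 samples (157 total), 29 autosomes of 10 Mb at desk
scale with probes every 2 kb, LRR noise sd 0.2, and LRR state means
cn0 −3.5, cn1 −0.45, cn2 0.0, cn3 +0.3, cn4 +0.75 — the canonical
Illumina-array signal model of the PennCNV HMM family. Each sample carries
each truth region independently with its group's Bernoulli frequency;
carriers get in-region probe LRR drawn at the carried copy number's mean and
also emit a CNV call directly (the HMM calling step is out of scope; an
optional `miscall_rate` drops calls to probe robustness). The default truth
set mixes one strongly differentiated region per group (0.8 vs 0.05 carrier
frequency), 24 undifferentiated common regions (0.25) and 8 rare regions
(0.02) that produce singleton fodder.

What the generator does **not** emulate: BAF, GC waviness and long-range LRR
artifacts, probe-density variation, linkage disequilibrium between probes,
boundary uncertainty of HMM calls, and reference-bias differences between
subspecies. Passing tests therefore demonstrate correctness of the
statistics and plumbing under the assumed signal model, not robustness to
every artifact of real arrays.

`expected_vst` gives the closed-form V_ST of this generative model: with
carrier frequency *f_g*, LRR shift Δ and effective noise σ²/m for a region
mean over *m* probes, the within-group variance is
`v_g = σ²/m + f_g(1−f_g)Δ²`, the pooled variance adds the between-group mean
spread under sample-size weights, and `V_ST = (V_T − V_S)/V_T`. It is the
analytic oracle for the simulation tests and is itself cross-checked against
direct Monte-Carlo draws (10⁵ per group) in the suite.

## Validation choices and problem sizes

* **Merge oracle**: the sweep merge is compared with connected components of
  the brute-force pairwise overlap graph on random call sets (≤ 200 calls).
* **V_ST oracle**: hand-computed closed forms (0.25, 0, 1) to 1e−12 and a
  two-pass variance routine on random inputs; inputs are drawn on a
  3-decimal grid to keep the comparison away from catastrophic cancellation.
* **Null calibration**: with no group differentiation (100 pure-noise
  regions, 157 samples in the four study groups), a fixed region lands in a
  group's top 1% in ≈ 1% of 200 replicates (two-sided binomial test).
* **Power**: a deletion at 0.8 carrier frequency in one group and 0.05
  elsewhere among 99 undifferentiated regions, simulated on a 4-chromosome,
  1,000-probe grid, is recovered in that group's top 1% in ≥ 95 of 100
  end-to-end replicates (simulate → merge → singleton filter → scan).
* **Analytic convergence**: at 1,000 samples per group, simulated V_ST
  agrees with `expected_vst` to 0.02. One cohort's estimate has sampling sd
  ≈ 0.017 — the same order as the tolerance — so the check compares the mean
  of 10 independent cohorts, making the Monte-Carlo error of the check
  itself negligible while leaving the tolerance untouched.
* **Determinism**: identical seed and config give byte-identical output
  files.

Problem sizes above (100-region nulls, 4-chromosome power grids, 10-cohort
averages) are chosen so the full suite runs in well under a minute of
simulation time while leaving the binomial/frequency checks adequately
powered.

## Known limitations

* The relatedness pruner is greedy, not an exact minimum vertex cover; on
  adversarial graphs it may drop one sample more than necessary (it agrees
  with brute force on small random graphs).
* V_i assumes the standardized pairwise V_ST are comparable across pairs;
  strongly unbalanced group sizes make some pairs noisier than others, which
  standardization only partially absorbs.
* Candidate counts use round-half-up of q·n, so tiny analysis sets with
  q = 0.01 legitimately select zero regions and raise.
* CNVR tables store carrier counts, not carrier identities; rehydrating a
  table cannot restore per-sample membership.
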