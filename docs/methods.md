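# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED convention). narrowPeak summits
are stored as absolute coordinates; a summit offset of −1 in column 10 maps
to the interval midpoint. Chromosome-name dialects are never auto-translated:
a strict-match check warns and lists unmatched chromosomes, because a silent
"chr1" vs "1" mismatch produces all-zero counts rather than an error.

Fragment–region counting uses "any overlap ≥ 1 bp" by default (the default
behavior of standard feature-counting tools); a fragment spanning two regions
increments both. Each fragment interval is counted once — paired-end
bookkeeping is assumed to have been resolved upstream into fragments.

## Unified tissue peak set

Peaks are standardized to 501 bp (`summit ± 250`, clipped at chromosome
bounds), blacklist overlappers dropped, and the union built by iterative
overlap merging: retain the most significant peak (by −log10 p), delete all
peaks overlapping it by ≥ 1 bp, repeat. Ties break by smaller start
coordinate, then chromosome, then name, making the result deterministic.
The output is non-overlapping, idempotent under re-merging, and greedy-
dominant: every deleted peak overlaps a retained peak of at least its
significance. All samples' standardized peaks are pooled before merging, and
provenance records the contributing samples.

Two sharing notions are deliberately kept distinct: `partition_common_specific`
labels a peak *common* when **any** other sample has an overlapping peak,
while `shared_in_all` returns unified-set regions overlapped by a peak from
**every** sample. Window CV uses the sample (n−1) standard deviation over
per-sample peak counts (peaks assigned to the window containing their
summit), undefined when the window holds no peaks; with four samples the
population SD would understate dispersion. Annotation assigns one feature per
region at its midpoint with priority Promoter (TSS ± 3000 bp) > Exon >
Intron > Downstream (≤ 3000 bp past the strand-aware gene end) > Distal
intergenic; midpoint assignment gives 501-bp regions a unique label even when
they straddle a boundary.

## cfDNA open-region calling

Candidates are flanked by the immediately adjacent 500-bp windows (Peak-F
upstream, Peak-B downstream). A flank clipped by a chromosome edge excludes
the region from testing rather than testing unequal widths, since raw counts
scale with window width. Three layers of evidence are computed:

- **Strict dominance**: in-region count > both flank counts in *every*
  sample. This deterministic rule is the gatekeeper for a call.
- **Per-region pooled signed-rank**: one-sided exact Wilcoxon signed-rank
  over the paired differences {(peak − flank-F), (peak − flank-B)} pooled
  across samples, BH-adjusted across regions. With S samples the design has
  2S pairs; the minimal attainable one-sided exact p is 2^−2S, so the BH
  gate (q ≤ α) is applied only when 2^−2S ≤ α (i.e. S ≥ 3 at α = 0.05) and
  the dominance rule alone decides otherwise.
- **Global pooled signed-rank**: one pooled one-sided test over all
  (peak, mean-flank) pairs across regions and samples, summarizing the
  cohort-level protection signal in a single p-value.

Counts enter the tests raw, not depth-normalized: the peak/flank comparison
is paired within a sample, so per-sample depth cancels. Zero differences are
dropped before ranking (the classical treatment), which keeps the exact
enumeration well defined. Enrichment of cfDNA support among tissue-derived
candidates is tested with a one-sided (greater) Fisher exact test of
called/not-called against 500-bp background tiles that do not overlap any
tissue peak; the odds ratio uses the Haldane–Anscombe 0.5 correction when a
cell is zero.

### Power of the dominance rule

With background coverage λ fragments per 500-bp window and in-region density
e·λ, a call requires X > max(Y_F, Y_B) independently in every sample
(X ≈ Poisson(eλ'), Y ≈ Poisson(λ'), widths and mono-nucleosome spillover
folded into λ'). At the default cohort conditions (50,000 fragments per
sample on a 10-Mb genome, ≈ 0.8× coverage; e = 3) λ' ≈ 4, the per-sample
dominance probability is ≈ 0.8, and the all-of-four requirement brings
per-region sensitivity to ≈ 0.4 — the measured end-to-end value (0.44 at
seed 7). The rule buys a near-zero false-call rate (measured 0 over 20 null
cohorts; every call in the worked example overlaps planted truth) at the
price of sensitivity; sensitivity rises steeply with depth (λ' ≈ 10 per
window already gives > 0.95). The package reports all three evidence layers
so downstream users can trade the strict rule against the pooled tests.

## Exact test machinery

The signed-rank and rank-sum null distributions are computed exactly by
dynamic programming over doubled ranks (so midranks from ties stay integral):
the signed-rank convolves per-pair factors (½ + ½·x^{2r_i}); the rank-sum
tracks (subset size, rank sum) over all equally likely group assignments.
Exact mode is used up to 200 pairs (signed-rank) and 30 total observations
(rank-sum); beyond that a normal approximation with tie and continuity
correction takes over. Two-sided p-values are twice the smaller tail, capped
at 1. The test suite checks both statistics against full 2^n sign and
C(n+m, n) subset enumerations to 1e−12, and the Fisher p against exact
rational hypergeometric enumeration.

AUC is the rank statistic P(score⁺ > score⁻) with half-credit ties,
verified against the all-pairs concordance count; confidence intervals are
2.5/97.5 percentiles of a stratified bootstrap (resampling positives and
negatives separately, default 2000 replicates).

## Subtype-differential screen

Counts are CPM-normalized per sample (count / column total × 1e6); the effect
size is the difference of group means of log2(CPM+1) and the p-value the
exact two-sided rank-sum (group sizes ≤ 10) on the same transformed values.
The `significant` flag applies the display thresholds p < 0.05 and
|log2FC| > 2; BH q-values are reported alongside, and FDR-controlled
selection should use q ≤ 0.1 with the fold-change gate — with 16 true
effects among 200 regions the raw-p flag admits too many of the 184 nulls to
control FDR (measured FDP ≈ 0.23 vs ≈ 0.07 for the BH screen at equal
sensitivity). A moderated linear-model test is a common alternative for this
screen; the exact rank-sum was chosen because it is assumption-light at
n ≈ 5 per group and consistent with the package's other comparisons, at some
cost in power for very small groups.

Mutation-flank regions default to one ±90-bp region per position (181 bp,
about one mono-nucleosomal fragment); a `split` flag yields the alternative
reading of two separate 90-bp regions. Mutation positions are user input —
no gene-panel coordinates are bundled.

## Grade classifier

Grades II/III map to low, IV to high. The split is stratified per class
(rounded to the nearest sample, 7:3 by default) and seeded. Hyperparameters
(tree depth 2–3, learning rate 0.1/0.3, 50/150 rounds) are chosen by mean
validation AUC over stratified 10-fold CV on the training split only; the
chosen setting is refit on the full training split and both train and test
AUC are reported from that single refit model, with stratified-bootstrap
CIs. No feature selection is applied by default — the marker regions are an
input — and feature importances (gain) are reported for inspection.

## Synthetic cohorts

The generator lays out non-overlapping 501-bp regions on a 2.5-kb grid with
≥ 1 kb clearance, so every planted region's 500-bp flanks are free of other
planted signal, then assigns them to roles: shared tissue peaks (planted in
all samples with ±25 bp summit jitter; raw widths 150–400 bp per side before
standardization; −log10 p drawn log-uniform in [3.16, 100]), sample-specific
peaks (one sample each), and analysis regions for the subtype/grade cohorts.

Fragment midpoints follow a mixture of a uniform genomic background and
extra mass on enriched regions such that the total in-region midpoint
density equals `fold × background` (protection fold 3 for protected regions
in CSF samples; effect fold 8 for differential regions in the GBM subtype
group and in grade-IV samples). Lengths are truncated-normal
(mean 167, SD 20, minimum 50 bp); exactly `depth` fragments are drawn per
sample and clipped inside chromosome bounds. Identical config and seed give
byte-identical output files.

Default conditions: one 10-Mb chromosome; 4 tissue/CSF samples; 100 shared
(50 protected) and 20 per-sample specific peaks; 200 analysis regions with
16 differential; 5 samples per subtype group; graded cohort of 32 + 15 + 64
(WHO II/III/IV); 50,000 fragments per sample. The single synthetic
chromosome and ~0.8× coverage keep every analysis and the full test suite at
desk scale (the complete acceptance run takes under a minute).

What the generator does **not** emulate: GC and mappability bias,
nucleosome-phased periodic fragment placement (an optional concern the
statistics are insensitive to, since all tests compare region vs flank
density), copy-number structure, sequence content, and 5hmC chemistry.
Passing recovery tests therefore demonstrate the pipeline's statistical
behavior under its own model assumptions, not performance on real cfDNA.

## Numerical and degenerate-input choices

- Empty intervals, inverted coordinates, negative positions, and coordinates
  beyond chromosome bounds raise validation errors naming the offender.
- CV is NaN (undefined) for windows with zero mean count; top-k TF fractions
  are NaN for regions with zero sites; both propagate rather than defaulting.
- All-zero sample columns abort CPM normalization with the sample named.
- The signed-rank test with no nonzero differences is vacuous (p = 1).
- Odds ratios use Haldane 0.5 only when a cell is zero.
- All randomness flows through numpy Generators seeded from explicit integer
  seeds; per-sample streams derive from (seed, stage, stable string hash) so
  adding samples never perturbs existing ones.
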