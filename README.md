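# cfaccess

Chromatin-accessibility inference from cell-free DNA (cfDNA) fragment counts,
for liquid-biopsy analysis of glioma.

Tumor tissue assayed with transposase-based accessibility sequencing yields
per-sample peak calls; cfDNA from cerebrospinal fluid (CSF) or plasma yields
fragment intervals. Protein-bound open chromatin protects cfDNA from nuclease
digestion, so an accessible, protected region keeps **more** fragments than
its immediate neighborhood. This package implements the full analysis chain
that turns those two inputs into liquid-biopsy features:

1. **Unified tissue peak set** — peak summits are extended ±250 bp to a fixed
   501-bp width, blacklist overlappers are removed, and an iterative-overlap
   merge greedily retains the most significant peak while deleting everything
   it overlaps, producing a non-overlapping union set. Cross-sample diversity
   is quantified by a common/specific partition, regions shared by all
   samples, per-window coefficient of variation of peak counts
   (CV = s/&#x0078;&#x0304;, sample SD over mean), and genomic-feature
   annotation (Promoter > Exon > Intron > Downstream > Distal intergenic,
   assigned at the region midpoint).
2. **cfDNA open-region calling** — for each candidate region ("Peak") the
   500-bp windows immediately upstream ("Peak-F") and downstream ("Peak-B")
   serve as local background. A region is called open when its fragment count
   strictly exceeds both flank counts in every sample and the pooled one-sided
   exact Wilcoxon signed-rank over the paired (peak, flank) counts survives
   Benjamini–Hochberg adjustment at α = 0.05. A one-sided Fisher exact test
   against non-peak 500-bp genome tiles quantifies how strongly cfDNA support
   concentrates in tissue-derived regions.
3. **Subtype-differential regions** — per-region two-sided exact rank-sum on
   log2(CPM+1) between sample groups (e.g. lower-grade glioma vs
   glioblastoma), BH-adjusted; a region is flagged significant at p < 0.05
   and |log2FC| > 2. Mutation-flank region sets (±90 bp, i.e. 181 bp ≈ one
   mono-nucleosomal fragment) and TF-binding-site summaries (top-50 TF site
   fraction per region) support the companion comparisons.
4. **Grade classifier** — WHO grades II/III are labeled low-grade, IV
   high-grade; CPM features over marker regions feed an XGBoost classifier
   with a stratified 7:3 split, 10-fold cross-validated hyperparameter
   choice, and AUC = P(score⁺ > score⁻) with stratified-bootstrap 95% CIs.
5. **Synthetic cohorts** — a seeded generator plants shared/sample-specific
   tissue peaks, protected regions at a chosen fragment-density enrichment,
   subtype-differential regions, and a graded cohort, so every stage has a
   ground-truth recovery test without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort and write their tables under `results/`. For example:

```sh
python analysis/03_cfdna_open_regions.py
```

prints

```
candidates (shared tissue regions): 100
called open by cfDNA: 22
sensitivity vs planted protected regions: 0.44 (dominance in all 4 samples is a strict rule at ~0.8x coverage; see docs/methods.md)
false discovery proportion: 0.000
pooled signed-rank global p: 1.147e-27
Fisher enrichment vs background windows: odds ratio 1146.8, p = 7.501e-31
null false-call rate (uniform fragments, 20 seeds): 0.0000
```

Of the 100 regions shared by all four tissue samples, 22 are called open from
CSF cfDNA; every call overlaps a planted protected region (false discovery
proportion 0), the pooled peak-vs-flank signed-rank is globally significant,
and calls are ~1000-fold enriched among tissue peaks relative to background
genome tiles. Sensitivity is limited by the strict per-sample dominance rule
at the cohort's sequencing depth — `docs/methods.md` discusses the power of
this rule. Likewise:

```sh
python analysis/05_grade_classifier.py
```

```
cohort: 111 samples (47 low, 64 high)
train AUC 1.000 [1.000, 1.000]
test  AUC 1.000 [1.000, 1.000]
best hyperparameters: {'max_depth': 2, 'learning_rate': 0.1, 'n_estimators': 50} (10-fold CV)
planted markers in importance top-20: 16/16
permuted-label test AUC (mean of 5): 0.541
```

The classifier separates the planted 16-marker effect essentially perfectly,
ranks all 16 planted regions in its importance top-20, and collapses to
chance when grade labels are permuted.

## Layout

- `src/cfaccess/` — the library: `genomic_io`, `tissue_peaks`,
  `cfdna_access`, `subtype_differential`, `grade_classifier`,
  `synthetic_data`, `stats`, `pipeline`.
- `analysis/01…05_*.py` — narrative drivers, one per stage.
- `tests/` — unit, property (hypothesis), and acceptance tests.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
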