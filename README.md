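# rnaedit

Analysis of adenosine-to-inosine (A-to-I) RNA editing in treatment
time-course RNA-seq designs — built around the kind of experiment in which
animals receive an inflammatory stimulus (e.g. LPS) and tissues are sampled
at a control point and several times post-treatment, with a few replicates
per time point.

Inosine pairs like guanosine, so A-to-I editing appears in RNA-seq as A>G
mismatches on the transcribed strand (T>C for minus-strand genes). Starting
from per-site, per-sample allele counts (pre-counted tables or
samtools-mpileup text), the package:

* **calls candidate sites** under the standard screen — base quality ≥ 25,
  sequencing depth ≥ 10, alternative allele depth ≥ 2, mismatch frequency
  ≥ 1% — and resolves A-to-I identity from the strand of the overlapping
  gene;
* **retains high-confidence events**: editing level ≥ 1% in at least two
  samples, or membership in a known-editing-site list (REDIportal-style),
  which rescues singly observed sites;
* **annotates** each event from transcript models (3′UTR, 5′UTR, missense /
  synonymous / stop-related via codon recoding with HGVS c./p. output,
  intronic, lincRNA, intergenic);
* **tests differential editing (DRE)** with a dual criterion: a binomial
  GLM likelihood-ratio test of per-sample (edited, unedited) counts on the
  group factor, plus an exact R×2 Fisher test on group-pooled counts for
  GLM-significant sites; a site is differentially edited iff
  GLM *p* < 0.05 **and** (GLM FDR < 0.05 **or** Fisher FDR < 0.05), with
  Benjamini–Hochberg adjustment and Tukey HSD as a descriptive post-hoc;
* **finds time-dependent and cis-regulated editing** by Spearman
  correlation of editing levels with minutes post-treatment, with host-gene
  expression (TPM), and with editing-enzyme (ADAR-family) expression;
* **reports** PCA of DRE editing-level matrices, per-group activity
  summaries, presence/Venn overlaps, and functional-category distributions,
  with a JSON run manifest (checksums, seeds, stage counts).

A first-class synthetic-data generator (`rnaedit.simulate`) emulates the
study design — 4 time-point groups × 3 replicates, beta-distributed
baseline editing levels, negative-binomial depth, designated
differential / time-trend / cis-correlated site blocks, ADAR-like enzyme
trajectories, and non-A>G decoy mismatches — and emits a ground-truth table
so every stage is testable by recovery.

## The statistics in brief

For site *i* with per-sample alternative (edited) counts *y* and reference
counts *n − y*, the GLM stage fits `y ~ Binomial(n, p)` with
`logit(p) = group` against an intercept-only null; the likelihood-ratio
statistic is referred to χ² with (k − 1) df (a permutation mode is also
provided). For GLM-significant sites an exact two-sided Fisher test is run
on the k×2 table of group-pooled (ref, alt) counts: the p-value is the total
probability, under fixed margins, of tables whose point probability does not
exceed the observed one — enumerated exactly up to a table-count budget,
seeded Monte-Carlo beyond it. Time-dependence uses tie-corrected Spearman
correlation with the control encoded at time 0 and p from the
t-approximation on n − 2 df.

## Worked example

Run the whole pipeline on a simulated 300-site dataset:

```bash
cat > config.yaml <<'YAML'
seed: 1
simulate:
  n_sites: 300
  seed: 1
YAML
rnaedit run config.yaml --out-dir run1
```

Stage counts printed at the end of the run:

```json
{
  "allele_rows": 3600,
  "calls": 2803,
  "calls_a_to_i": 3240,
  "events": 264,
  "dre_sites_tested": 264,
  "dre_significant": 52,
  "time_dependent": 41,
  "cis_records": 264
}
```

3,600 allele-count rows (300 sites × 12 samples) yield 2,803 records passing
the calling thresholds; 264 sites survive the high-confidence retention
rule; 52 are called differentially edited under the dual GLM/Fisher rule and
41 correlate with time post-treatment at Spearman *p* < 0.05. The head of
`run1/dre.tsv` restricted to DRE sites:

```
chrom   pos strand        glm_p      glm_fdr  fisher_fdr  max_intergroup_diff category hgvs_p
 chr1   637      + 1.705202e-09 7.502890e-08     0.00055             0.253120 missense p.K46R
 chr1  5016      + 1.391495e-07 3.673546e-06     0.00055             0.183495     5UTR
 chr1 10938      + 1.098770e-09 5.801504e-08     0.00055             0.201233     3UTR
```

`max_intergroup_diff` is the spread of per-group mean editing levels (e.g.
0.25 = 25 percentage points); missense DRE events with spread > 5% carry a
dedicated flag. `run1/pca_variance.tsv` shows PC1 of the DRE editing-level
matrix explaining ~40% of the variance, and `run1/venn_groups.tsv` reports
the fraction of events observed in all four groups (0.87 here at deep
simulated coverage).

Each stage is also available separately (`rnaedit simulate / call / filter /
annotate / dre / timecorr / report`), and everything is importable as a
library — see `rnaedit.dre.run_differential_editing`,
`rnaedit.timecorr.time_dependent_sites`, `rnaedit.report.pca_on_dre`.

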