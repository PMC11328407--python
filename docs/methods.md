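# Methods

This note documents the models and procedures implemented in `rnaedit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Site calling

Input is either samtools-mpileup 6-column text or a pre-counted allele
table. The pileup parser counts only bases whose Phred quality is at or
above `min_base_quality` (default 25); `.`/`,` count as reference, explicit
base symbols as substitutions, `^`+mapq / `$` read-boundary markers and
`+n`/`-n` indel runs are consumed without contributing counts, and `*`,
`<`, `>`, `N` fall into an "other" bucket. Every symbol is conserved:
ref + alt + other + below-quality equals the pileup depth column, which the
parser enforces per line. At multi-allelic sites only the majority
non-reference base is kept as the alternative allele, ties broken in base
order A < C < G < T — a deterministic rule chosen because nothing in the
data distinguishes the tied alleles.

A record passes the screen iff depth ≥ 10, alternative depth ≥ 2 and
frequency ≥ 1%. The editing level is alt/(ref+alt) — "other" bases are
treated as noise and excluded from the denominator, the convention of
REDIportal-style pipelines; the same quantity serves as the calling
frequency and the retention level. A site is A-to-I iff the mismatch is A>G
on a plus-strand gene or T>C on a minus-strand gene; the strand comes from
the transcript model overlapping the site. Sites overlapped by genes on
both strands are strand-ambiguous: they are withheld from A-to-I typing and
reported separately rather than guessed. Positions are 1-based throughout.

## Retention (high-confidence events)

An A-to-I site becomes a high-confidence event when its editing level is
≥ 1% in at least two samples, or when it appears in the known-site list.
The rescue clause still requires a passing call in at least one sample;
without that, a known site with no read evidence in this dataset would
enter the analysis carrying no information.

Per-sample mean editing uses only sites called in that sample (no zero
imputation of undetected sites); per-group activity is reported both as the
mean of sample means (default) and as the pooled mean over all site×sample
values, since either convention is defensible and they differ when
detection rates differ between samples.

## Annotation and recoding

One canonical transcript represents each gene: longest CDS, then longest
exonic span, then transcript id — multi-isoform consequence ranking is out
of scope and a single c./p. call per gene is the reporting convention.
Category precedence across overlapping same-strand genes is CDS > UTR >
intron > lincRNA > intergenic, mirroring "most severe consequence"
behaviour. 5′ vs 3′ UTR is decided by the transcript-space position
relative to the CDS, so it is correct on both strands.

For CDS sites the genomic position is mapped to a 1-based CDS coordinate by
walking exons in transcript orientation; the codon index is ⌈cds_pos/3⌉ and
the offset within the codon ((cds_pos−1) mod 3)+1. The edited base must be
A in transcript orientation (a model/sequence mismatch raises an error
rather than silently recoding). Both codons are translated with the
standard genetic code only — mitochondrial codes and selenocysteine
recoding are not handled. Output is HGVS-style `c.<pos>A>G` /
`p.<ref><index><alt>`; substitutions touching a stop codon are classed
`stop_related`.

## Differential editing

The decision is the dual rule: empirical GLM *p* < 0.05 AND (GLM FDR < 0.05
OR Fisher FDR < 0.05), all thresholds configurable.

**GLM stage.** Per-sample (alt, ref) count pairs — counts, not level
proportions, so read depth weights each sample's information — are modelled
as binomial with a logit-linear group effect and tested against an
intercept-only null by likelihood ratio, χ² with k−1 df. With a single
categorical predictor the maximum-likelihood fits are the group-pooled
proportions, so the deviance difference is computed in closed form; a test
verifies equality with iteratively fitted GLMs. "Empirical p" defaults to
this χ² tail (`empirical_p_mode="lrt"`); a permutation mode (group-label
shuffles of the per-sample pairs, +1-smoothed tail proportion) is provided
because at 3 replicates/group the χ² approximation is a modelling choice
one may wish to check. Note the permutation null is granular: its smallest
attainable p is set by the number of distinguishable group relabellings.
Complete separation (a group with zero edited or zero unedited reads) is
guarded by adding 0.5 to every group's pooled ref and alt count
(Haldane–Anscombe), flagged in the output.

**Fisher stage.** For GLM-significant sites, an exact two-sided Fisher test
on the k×2 group-pooled table: p is the fixed-margin probability mass of
tables whose point probability is ≤ the observed (relative tolerance 1e−7).
Tables are enumerated by recursive descent while the candidate-table bound
stays under `fisher_enum_budget` (default 2×10⁵); beyond that a seeded
Monte-Carlo sample of multivariate-hypergeometric tables is used and the
result is labelled `monte_carlo`.

**Multiplicity.** GLM p-values are BH-adjusted across all tested sites of a
run (one tissue). Fisher p-values are computed only in the GLM-significant
subset, but adjusted with multiplicity over *all* GLM-tested sites
(untested sites count as p = 1). The subset-only family is available
(`fisher_bh_family="subset"`) but is not the default for a structural
reason: on pooled counts the Fisher and GLM tests are nearly the same test,
so within a subset selected by GLM p < 0.05 essentially every Fisher p is
small and subset-BH passes the whole subset — the "dual" criterion then
degenerates to the single GLM gate and the realized false-discovery rate
inflates to roughly the GLM type-I rate divided by the discovery fraction
(≈0.3 in our recovery simulations, versus ≈0.03 with the all-tested
family at equal sensitivity).

Tukey HSD on per-sample levels (studentized-range distribution, N−k df) is
emitted for every group pair as a descriptive post-hoc; it never gates the
DRE decision. When every group has zero within-group variance the
studentized range is undefined and the limit convention (p = 0 for unequal
means, 1 for equal) is applied and flagged. Missense DRE events whose
per-group mean levels spread by more than 5 percentage points carry
`missense_flag`.

## Time-course and cis correlations

Spearman correlation (tie-corrected, two-sided p from the t-approximation
on n−2 df; an exact-permutation option exists for small n) is used for
three analyses: editing level vs minutes post-treatment (control encoded as
time 0; vessels-like design 0/15/30/240 min, endothelial/microglia-like
0/30/60/120 min — the time axis is minutes because the analysis treats time
as an ordered continuous covariate and the original labels mix units);
editing level vs host-gene TPM per (site, gene) pair; and per-sample mean
editing vs ADAR-family enzyme TPM. Correlations default to per-sample
values (n = groups × replicates) rather than group means — with 4 groups a
group-mean Spearman cannot reach p < 0.05 at all — and a group-means mode
exists for sensitivity analysis. Records with fewer than 6 pairs are
flagged low-n. Constant vectors give missing results rather than r = 0.

## Expression support

TPM is computed as count/length rescaled to 10⁶ per sample. Differential
expression across groups is a one-way Gaussian test on log2(TPM+1) —
equivalent to the ANOVA F test — BH-adjusted across genes. This is
deliberately lightweight: its role here is to support editing↔expression
correlation analyses, not to replace count-based differential-expression
frameworks (no TMM normalisation, no dispersion shrinkage); analyses whose
endpoint is differential expression itself should use a dedicated tool.
The pseudo-count of 1 bounds the influence of zeros at typical TPM scales.

## Synthetic-data generator

The generator emulates the study design so recovery against known truth is
possible: k time-point groups (default 4: 0/15/30/240 min) × r replicates
(default 3); per-site baseline editing levels Beta(2, 18) (mean 10%, the
scale of typical bulk editing screens); per-site per-sample depth
negative-binomial (mean 50, dispersion 5 — RNA-seq-like overdispersion;
recovery experiments in the tests use mean 100); edited reads
Binomial(depth, level).

Site blocks: a `frac_dre` block shifts one random group by `effect_size`
(default 0.15) additively on the proportion scale with clipping to [0,1] —
configurations whose shifted levels leave [0,1] beyond a small tolerance
are rejected. A `frac_time_trend` block follows
baseline + sign·amplitude·log1p(t)/log1p(t_max), a saturating early
response chosen because an LPS response rises quickly and because a
strictly linear-in-minutes shape makes the first three time points (0–30
min) statistically indistinguishable at realistic depth; `trend_positive_frac`
(default 0.7) biases trend signs upward, matching enzyme upregulation under
acute stimulation and giving the global mean editing level a real
trajectory for the enzyme gene to track. Cis sites are drawn from the trend
block (a cis site needs a non-constant trajectory for its expression link
to be observable); their gene's expected expression is proportional to
0.2 + 8·(true group editing level). An ADAR2-like gene ("Adarb1") tracks
the per-sample mean true editing level; an ADAR1-like gene ("Adar") stays
flat; both are modelled as deeply covered, lower-dispersion genes. Decoy
sites (default 10%) carry non-A>G mismatches; a T>C decoy is always hosted
on a plus-strand gene so no decoy can masquerade as A-to-I.

Each site gets its own small two-exon gene (one-exon for lincRNA) with CDS
sequences built from random non-stop codons and the designed codon at the
edited position, so the recoding path can be exercised end-to-end. Known
sites are a random 30% of true editing sites, mimicking partial database
coverage.

What the generator does **not** emulate: read-level artefacts (alignment
error, strand bias, position-in-read effects), library-prep and batch
effects, overdispersion of editing levels beyond binomial within a group,
linkage between nearby sites, and realistic genome structure (one gene per
site, uniform gene models). Passing recovery tests therefore demonstrates
the statistical machinery under its stated assumptions, not robustness to
alignment artefacts — on real data the calling thresholds and the
known-site rescue carry that burden.

## Numerical conventions and edge cases

* Editing level at zero informative reads is missing (NaN), never 0.
* BH adjustment passes missing p-values through untouched and errors on
  values outside [0,1].
* PCA of DRE levels imputes missing values by the site mean, drops
  constant sites (fp tolerance 1e−12), centers each site, and takes sample
  scores from the SVD; variance fractions are squared singular values over
  their total and sum to 1 by construction.
* Venn/presence regions are exclusive region counts and always sum to the
  union size.
* All randomness flows from explicit seeds (numpy `default_rng`); a fixed
  seed fixes every emitted byte, which the manifest checksums make
  checkable. Monte-Carlo Fisher results are labelled as such.

## Problem sizes used in the test suite

Calibration and recovery experiments in the tests use 500–2,000 sites at
depth mean 80–100 with 4×3 designs: large enough for stable rate estimates
(binomial SE on a 5% rate at n = 2,000 is ≈0.5%) while keeping the full
suite fast on a single core.
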