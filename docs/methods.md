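# Methods

## Scope and data model

`lncloc` analyzes transcript-level count matrices from fractionation RNA-seq:
samples are annotated with (condition, fraction, replicate), fractions are
nuclear and cytoplasmic, and the pipeline starts downstream of alignment and
counting. Inputs are plain text throughout: TSV matrices and designs, FASTA
sequences, and pileup-style TSV base-call summaries with 0-based coordinates.

## Expression filtering

RPKM is computed as `counts × 10⁹ / (length_bp × library_size)` with the
library size taken as the column sum of the count matrix. A transcript is
*expressed in a condition* when its mean RPKM over all of that condition's
samples — both fractions pooled — exceeds 0.5 (strict inequality), and
*expressed in a fraction* when the mean over that fraction's replicates does.
The pooled-mean reading of "average across all samples in a condition" is a
design choice: it yields a single condition-level expressed set on which the
localization test runs, while the per-fraction sets are reported
independently alongside. The threshold (0.5) and the comparison direction are
configurable but deliberately default to the convention above.

## Differential localization

The test is a two-group negative-binomial Wald test, reimplemented and
documented here rather than delegated, because every classification downstream
hinges on its exact behavior:

* **Size factors** — median-of-ratios: for each sample, the median over
  transcripts (with positive counts in every sample) of the ratio to the
  per-transcript geometric mean.
* **Dispersion** — method of moments on normalized counts. Per group g with
  sample mean m_g and variance v_g, `α_g = (v_g − m_g·mean(1/s)) / m_g²`;
  the per-transcript estimate is the replicate-weighted average of the two
  groups, floored at 10⁻⁸. A trend `α(μ) = a₀ + a₁/μ` is fitted by least
  squares to the positive per-transcript estimates, and the dispersion used
  is the **maximum** of the per-transcript estimate and the trend value.
  Taking the maximum is deliberately conservative: with five replicates the
  moment estimator frequently underestimates α (sample variance below the
  Poisson floor), and an underestimated dispersion inflates the Wald
  statistic. The maximum rule trades a little power for robust type-I error
  control, which the null-simulation test verifies directly.
* **Effect and test** — fold change is reported as
  `log₂((μ̂_cyt + ½)/(μ̂_nuc + ½))` with pseudocount 0.5 on the normalized
  fraction means (cytoplasm:nuclear orientation; positive = cytoplasmic).
  The Wald statistic divides the natural-log ratio by a delta-method
  standard error with `Var(μ̂_g) = μ_g·mean(1/s)/n_g + α·μ_g²/n_g`; p-values
  are two-sided normal, adjusted by Benjamini–Hochberg over all tested
  transcripts in the condition. All-zero rows are excluded and logged.

### Classification

* cytoplasmic: ratio ≥ 2 and padj < 0.01
* nuclear: ratio ≤ ½ and padj < 0.01
* mixed: max(ratio, 1/ratio) < 1.9, regardless of significance
* unassigned: everything else — i.e. ratio in [1.9, 2.0) in either direction,
  or ≥ 2-fold but non-significant.

The 1.9/2.0 gap is intentional and surfaced as its own category rather than
folded into mixed: condition-to-condition gains in localized transcripts
typically come out of this unassigned pool, and hiding it would misstate the
rule. The mixed criterion is directionless ("between fractions"), hence the
max of ratio and reciprocal. Cross-condition behavior is summarized by a 4×4
transition table over transcripts expressed in both conditions, and by
fold-increase statistics (treated/control per category, rounded half-up to
one decimal).

## Retention motifs

Motifs are IUPAC patterns scanned on the sense strand (transcript sequences
are already stranded); overlapping occurrences are counted, and `N` in a
sequence matches nothing. The scanner is regex-based (lookahead for overlaps)
and is property-tested against a position-by-position oracle.

The shipped defaults — 5'SS `AGGTAAGT`, BORG `AGCCC`, SIRLOIN `CCCTCCC` — are
transcribed from the motif literature and marked "verify against source" in
`src/lncloc/data/motifs.yaml`; they are configuration, not code, because the
motif set is an empirical input that a user may need to revise against the
primary references (e.g. scanning the BORG core with its reported flanking
context `WNNNNSNNAGCCC` instead).

Random-motif nulls preserve each parent position's structure: a fixed purine
is redrawn within {A, G}, a fixed pyrimidine within {C, T}, and a degenerate
position keeps its cardinality (R/Y are the only two-base codes of their
class and stay fixed; mixed two-base codes redraw within {S, W, K, M};
three-base within {B, D, H, V}; N stays N). Draws are uniform over that space
with the parent itself rejected; independent draws may repeat. A motif whose
structure space contains only itself raises an error.

Enrichment is reported two ways: stratified category distributions
(percentages over classified transcripts, computed separately for the
with-motif and without-motif strata, which partition the tested set) and an
unweighted OLS fit of log₂FC on per-transcript hit count over all tested
transcripts with finite fold change, zero-count transcripts included. With
the cytoplasm:nuclear orientation, nuclear association appears as a negative
slope. Zero variance in hit count yields a not-available trend rather than an
error. Transcripts carrying both a real motif and its random variant are not
excluded from either stratum; the strata are defined per scanned pattern.

## A-to-I editing

Editing analysis works from pileup evidence rather than raw reads. Because
inosine is read as guanosine, candidates are A→G sites: reference base A,
G reads ≥ 3, G fraction ≥ 0.1, coverage ≥ 10 (defaults; all configurable;
calls are monotone in each threshold). Other mismatch classes are tabulated
for bookkeeping but can never become candidates. Verdicts then use the
matched genomic sequence: genomic A → *edit*; genomic base differing from the
reference → *snp*; genomic base missing or N → *no_evidence* (logged). The
three verdicts partition the candidates. Coordinates are sense-strand
transcript positions; any genome-strand conversion (T→C on minus strand) is
the responsibility of whatever produced the pileup.

A transcript is "edited in a fraction" when it has ≥ 1 edit verdict from that
fraction's evidence (default); a strict mode instead requires strictly more
edit sites in that fraction than in the other. The overlap summary intersects
per-fraction edited transcripts with the transcripts localized to that
fraction.

## Synthetic data generator

The generator emulates the fractionation study design the pipeline targets:
2 conditions × 2 fractions × 5 replicates, ~2000 transcripts of 400–3000 bp.
What it models, and how:

* **Counts** — NB with variance μ + αμ², shared dispersion α = 0.05 by
  default. Each transcript gets a base abundance in RPKM units (log-normal,
  median ≈ 15, floored at 2 for expressed transcripts; uniform 0.02–0.3 for
  planted-unexpressed ones, safely below the 0.5 filter). Expressed levels
  are rescaled so expected per-sample totals match the drawn library size
  (log-normal around 2×10⁶, σ = 0.15, drawn per sample to exercise
  normalization).
* **Localization** — per condition, transcripts are nuclear-planted (10%),
  cytoplasmic-planted (5%), mixed (65%) or unexpressed (20%) by default. A
  planted asymmetry of `planted_log2fc` (default 2, i.e. 4-fold) is split
  symmetrically in log space around the base abundance, so total abundance is
  independent of category. The defaults are conventions chosen to resemble a
  fractionation experiment in which most transcripts are mixed and localized
  ones are a strongly nuclear-skewed minority; no claim is made that real
  localized transcripts share one effect size.
* **Second condition** — categories are redrawn from the control truth via a
  configurable transition matrix (mostly retained; the mixed pool feeds the
  localized classes), which exercises the transition-table machinery without
  modeling stress biology.
* **Sequences** — uniform A/C/G/T backgrounds; each motif is inserted (one
  concrete realization of its IUPAC pattern, random offset, overlaps
  re-drawn with bounded retries) with a category-dependent probability,
  default 0.6 for nuclear-planted vs 0.1–0.15 elsewhere, producing the
  motif–localization coupling the enrichment stage should detect.
* **Editing evidence** — per-transcript Bernoulli selection (edit rate 0.05,
  SNP rate 0.02 by default; one site each at distinct reference-A positions;
  unexpressed-everywhere transcripts skipped). Coverage is Poisson(30);
  sequencing errors hit at rate 0.001 spread over the non-reference bases.
  Edit sites show G at alt fraction 0.5 in the edited fraction(s) only, with
  the genomic base left at A; SNP sites are homozygous variants — genomic G
  and essentially all-G transcript calls in both fractions. Configurations
  where the alt fraction does not exceed the error rate are rejected as
  undetectable by construction. Pileups cover transcripts bearing planted
  sites plus 50 background transcripts; event-free full-transcriptome
  pileups add cost without adding information to any recovery metric.

Everything derives from one seed (independent per-stage substreams), so a
full pipeline run is byte-reproducible; the manifest records the seed,
thresholds and version needed to regenerate a bundle.

What the generator does **not** model — and therefore what passing recovery
tests do not establish about real data: read-level artifacts (mapping bias,
duplicates), GC/length bias, batch effects, correlated dispersions,
non-uniform background sequence composition (real motif background rates are
composition-dependent), allele-specific expression, heterozygous SNPs, and
hyper-edited clusters.

## Problem sizes and numerical choices

The shipped experiments use 1000–2000 transcripts with 5 replicates per
fraction and 1000-transcript sequence/editing simulations — sizes at which
every recovery metric is stable across seeds while a full test-and-acceptance
cycle completes in well under a minute. Ties and degenerate inputs are
handled explicitly: dispersion floor 10⁻⁸; pseudocount 0.5 in the fold
change; p-values clipped to [0, 1]; fold-increase rounding is half-up (so
1.25 → 1.3, not banker's rounding); zero-variance hit counts and
zero-control-count fold increases return not-available rather than raising;
all-zero count rows are excluded from testing and logged.

## Known limitations

* The Wald test is asymptotic; with 2–3 replicates per fraction its p-values
  are approximate and the conservative dispersion rule is what keeps the
  realized false-positive rate at the nominal level. It is not a numerical
  clone of any specific differential-expression package.
* The expression filter's pooled-mean convention is one defensible reading of
  condition-level expression; requiring expression in either fraction
  separately would give different condition-level counts.
* Editing calls are only as good as the pileup: the module does not remap
  reads, detect hyper-editing, or handle strand conversion.
* Motif defaults must be verified against the primary literature before use
  on real data (see `data/motifs.yaml`).
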