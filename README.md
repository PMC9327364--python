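# lncloc

Nuclear vs cytoplasmic localization analysis of long noncoding RNAs (lncRNAs)
from fraction-resolved RNA-seq.

Where a lncRNA sits in the cell — retained in the nucleus or exported to the
cytoplasm — constrains how it can act, and fractionation RNA-seq (sequencing
nuclear and cytoplasmic RNA separately, with replicates, under one or more
conditions) is the standard way to map this transcriptome-wide. `lncloc`
implements the full analysis chain for such an experiment, for
bioinformaticians who start from transcript-level count matrices and
sequences:

1. **Expression filtering** — RPKM normalization and an expressed-transcript
   filter (mean RPKM > 0.5 per condition, and per fraction).
2. **Differential localization** — a two-group negative-binomial Wald test of
   cytoplasmic vs nuclear replicates, followed by a three-way classification:
   *cytoplasmic* (fold change ≥ 2, adjusted p < 0.01), *nuclear* (the same on
   the reciprocal), *mixed* (fold change < 1.9 either way, regardless of
   significance), with the deliberate gap between the two thresholds left
   *unassigned*. Cross-condition shifts are summarized in a category
   transition table and fold-increase statistics.
3. **Retention-motif analysis** — IUPAC scanning of transcript sequences for
   nuclear-retention motifs (5'SS, BORG, SIRLOIN by default), stratified
   category distributions (with vs without each motif), random
   structure-matched motif variants as a null, and an OLS trend of
   localization fold change on per-transcript motif count.
4. **A-to-I editing** — candidate editing sites called as A→G mismatches from
   pileup-style base-call evidence, discriminated into bona fide edits vs
   SNPs using matched genomic sequence, and intersected with localization.
5. **Synthetic data** — a ground-truth generator emulating the full study
   design (2 conditions × 2 fractions × 5 replicates, NB counts, planted
   asymmetric transcripts, motif-bearing sequences, planted edits/SNPs), so
   every stage is testable end-to-end without external downloads.

## The model in brief

Counts are modeled as NB(μ, variance μ + αμ²). For each condition the test
compares cytoplasmic and nuclear replicates: median-of-ratios size factors,
per-transcript method-of-moments dispersion (floored at 10⁻⁸, shrunk
conservatively toward a fitted α(μ) = a₀ + a₁/μ trend by taking the maximum),
and a Wald statistic on

log₂FC = log₂((μ̂_cyt + ½) / (μ̂_nuc + ½)),

with Benjamini–Hochberg adjustment over all tested transcripts. Positive
log₂FC means cytoplasmic enrichment.

## Worked example

```bash
python examples/01_simulate_and_localize.py
```

```
control: {'nuclear': 98, 'cytoplasmic': 49, 'mixed': 644, 'unassigned': 0}  localized total = 147
  sensitivity for planted localized transcripts: 1.000 (n=147)
H2O2: {'nuclear': 141, 'cytoplasmic': 68, 'mixed': 579, 'unassigned': 0}  localized total = 209
  sensitivity for planted localized transcripts: 1.000 (n=209)
```

Most transcripts are mixed; of the asymmetric ones, more are nuclear than
cytoplasmic, and the stress condition has more localized transcripts — the
pattern the generator plants and the pipeline recovers with sensitivity 1.0
here. `examples/02_motif_enrichment.py` shows the motif stratification (the
with-motif stratum is more nuclear than the without-motif stratum for real
motifs but not for their randomized variants, with a negative count-vs-fold
trend), `examples/03_editing_calls.py` the editing verdicts and their overlap
with localization, and `examples/04_reference_count_checks.py` the arithmetic
checks below.

There is also a thin CLI mirroring the library:

```bash
lncloc run-all --outdir demo_run --seed 42     # full synthetic demonstration
lncloc check-reference                         # reference-count arithmetic
lncloc simulate/expression/localize/motifs/editing --help
```

## Documentation

See `docs/methods.md` for the statistical model, default parameters, the
synthetic generator's assumptions, and known limitations.
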