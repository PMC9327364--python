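"""Retention-motif stratification and the motif-count vs localization trend.

Simulates sequences in which nuclear-planted transcripts preferentially carry
the configured retention motifs (5'SS, BORG, SIRLOIN), then compares the
localization category distribution of transcripts with vs without each motif
and against a randomized structure-matched variant. A higher nuclear
percentage in the with-motif stratum, absent for the random variant, mirrors
what motif-driven nuclear retention looks like in real fractionation data;
the negative OLS slope says more motif copies track with more nuclear
enrichment (log2 cytoplasm:nuclear orientation).
"""

import pandas as pd

from lncloc import (
    SyntheticConfig,
    classify_results,
    compute_rpkm,
    differential_localization,
    expression_filter,
    load_motif_config,
    motif_count_trend,
    random_motif_variants,
    scan_transcripts,
    simulate_counts,
    simulate_sequences,
    stratified_distribution,
)

motifs = load_motif_config()
cfg = SyntheticConfig(n_transcripts=800, transcript_length_range=(300, 1000), seed=2)
counts, design, truth = simulate_counts(cfg)
sequences = simulate_sequences(cfg, truth, motifs)
expr = expression_filter(compute_rpkm(counts, truth.lengths), design, truth.lengths)
tested = differential_localization(counts, design, "control", expr.expressed_set("control"))
results = classify_results(tested, "control")

scanned = list(motifs)
for m in motifs:
    scanned.extend(random_motif_variants(m, 1, seed=cfg.seed))
hits = pd.concat([scan_transcripts(sequences, m) for m in scanned], ignore_index=True)

for m in scanned:
    with_s, without_s = stratified_distribution(results, hits, m.name, "control")
    trend = motif_count_trend(results, hits, m.name, "control")
    slope = f"{trend.slope:+.3f}" if trend.slope is not None else "NA"
    print(
        f"{m.name:<14s} ({m.provenance:<10s}) nuclear% with={with_s.percentages['nuclear']:5.1f} "
        f"without={without_s.percentages['nuclear']:5.1f}  trend slope={slope}"
    )
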