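"""End-to-end orchestration: simulate (or load) inputs, run every stage, and
write a reproducible report bundle.

The bundle contains, per condition: expression tables, localization results
and category summaries, the cross-condition transition table, per-motif
stratified summaries and count trends (real motifs plus randomized
structure-matched variants), editing site calls with verdicts, and
editing x localization overlap tables — plus a machine-readable manifest
(thresholds, seed, version) and a plain-text report. All randomness flows
from the single seed in the configuration, so two runs with the same
configuration produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .editing import (
    call_sites,
    discriminate_snps,
    editing_localization_overlap,
    sites_to_frame,
)
from .expression import SampleDesign, compute_rpkm, expression_filter
from .localization import (
    classify_results,
    differential_localization,
    summarize_categories,
    transition_table,
)
from .motifs import (
    load_motif_config,
    motif_count_trend,
    random_motif_variants,
    scan_transcripts,
    stratified_distribution,
)
from .simulate import (
    SyntheticConfig,
    plant_variant_sites,
    simulate_counts,
    simulate_editing_evidence,
    simulate_sequences,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and inputs for a full run.

    With no input paths the pipeline simulates its own data from
    ``synthetic`` (the demonstration mode); with paths it loads the
    user-supplied matrices/sequences instead.
    """

    outdir: Path = Path("lncloc_run")
    expression_threshold: float = 0.5
    fc_threshold: float = 2.0
    mixed_threshold: float = 1.9
    alpha: float = 0.01
    min_coverage: int = 10
    min_alt_fraction: float = 0.1
    min_alt_reads: int = 3
    n_random_variants: int = 2
    overlap_mode: str = "any"
    motif_config_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    lengths_path: str | None = None
    fasta_path: str | None = None
    genome_fasta_path: str | None = None
    pileup_paths: dict[str, str] = field(default_factory=dict)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("expression_threshold", "fc_threshold", "mixed_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def seed(self) -> int:
        return self.synthetic.seed


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format="%.6g")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns key results.

    Stage failures raise with the failing stage named; files written before
    the failure are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict = {}
    try:
        stage = "inputs"
        motifs = load_motif_config(config.motif_config_path)
        synthetic = config.counts_path is None
        if synthetic:
            counts, design, truth = simulate_counts(config.synthetic)
            sequences = simulate_sequences(config.synthetic, truth, motifs)
            plant_variant_sites(config.synthetic, truth, sequences)
            pileups, genomic = simulate_editing_evidence(config.synthetic, truth, sequences)
            lengths = truth.lengths
            io.write_counts(counts, out / "counts.tsv")
            io.write_design(design.table, out / "design.tsv")
            io.write_lengths(lengths, out / "lengths.tsv")
            io.sequences_to_fasta(sequences, out / "transcripts.fasta")
            io.sequences_to_fasta(genomic, out / "genome.fasta")
            for frac, pu in pileups.items():
                io.write_pileup(pu, out / f"pileup_{frac}.tsv")
            _write_tsv(
                truth.category.reset_index().rename(columns={"index": "transcript_id"}),
                out / "truth_categories.tsv",
            )
            _write_tsv(truth.placements_frame(), out / "truth_motif_placements.tsv")
            _write_tsv(truth.edit_sites_frame(), out / "truth_edit_sites.tsv")
            _write_tsv(truth.snp_sites_frame(), out / "truth_snp_sites.tsv")
            results["truth"] = truth
        else:
            counts = io.read_counts(config.counts_path)
            design = SampleDesign(io.read_design(config.design_path))
            lengths = io.read_lengths(config.lengths_path)
            sequences = io.fasta_to_sequences(Path(config.fasta_path)) if config.fasta_path else {}
            genomic = (
                io.fasta_to_sequences(Path(config.genome_fasta_path))
                if config.genome_fasta_path
                else {}
            )
            pileups = {
                frac: io.read_pileup(path) for frac, path in config.pileup_paths.items()
            }

        stage = "expression"
        rpkm = compute_rpkm(counts, lengths)
        expr = expression_filter(rpkm, design, lengths, config.expression_threshold)
        _write_tsv(expr.counts_summary(), out / "expressed_counts.tsv")
        results["expression"] = expr

        stage = "localization"
        loc_results = {}
        summaries = {}
        for cond in design.conditions:
            tested = differential_localization(
                counts, design, cond, expressed=expr.expressed_set(cond)
            )
            res = classify_results(
                tested, cond, config.fc_threshold, config.mixed_threshold, config.alpha
            )
            loc_results[cond] = res
            summaries[cond] = summarize_categories(res, cond)
            frame = tested.copy()
            frame["category"] = [r.category for r in res]
            _write_tsv(
                frame.reset_index().rename(columns={"index": "transcript_id"}),
                out / f"localization_{cond}.tsv",
            )
            _write_tsv(summaries[cond].to_frame(), out / f"summary_{cond}.tsv")
            volcano = frame[["log2fc", "padj"]].copy()
            _write_tsv(
                volcano.reset_index().rename(columns={"index": "transcript_id"}),
                out / f"volcano_{cond}.tsv",
            )
        results["localization"] = loc_results
        results["summaries"] = summaries

        if len(design.conditions) >= 2:
            c0, c1 = design.conditions[:2]
            trans = transition_table(
                loc_results[c0],
                loc_results[c1],
                expr.expressed_set(c0),
                expr.expressed_set(c1),
            )
            _write_tsv(trans, out / "transition_table.tsv", index=True, index_label="control")
            results["transitions"] = trans

        stage = "motifs"
        motif_rows = []
        trend_rows = []
        if sequences:
            all_motifs = []
            for m in motifs:
                all_motifs.append(m)
                all_motifs.extend(
                    random_motif_variants(m, config.n_random_variants, seed=config.seed)
                )
            hits_frames = [scan_transcripts(sequences, m) for m in all_motifs]
            hits = pd.concat(hits_frames, ignore_index=True)
            _write_tsv(hits, out / "motif_hits.tsv")
            for cond in design.conditions:
                for m in all_motifs:
                    with_s, without_s = stratified_distribution(
                        loc_results[cond], hits, m.name, cond
                    )
                    for label, s in (("with", with_s), ("without", without_s)):
                        pct = s.percentages
                        motif_rows.append(
                            {
                                "condition": cond,
                                "motif": m.name,
                                "provenance": m.provenance,
                                "stratum": label,
                                "n_classified": s.n_classified,
                                "nuclear_pct": pct["nuclear"],
                                "cytoplasmic_pct": pct["cytoplasmic"],
                                "mixed_pct": pct["mixed"],
                            }
                        )
                    trend = motif_count_trend(loc_results[cond], hits, m.name, cond)
                    trend_rows.append(
                        {
                            "condition": cond,
                            "motif": m.name,
                            "provenance": m.provenance,
                            "slope": trend.slope if trend.slope is not None else "NA",
                            "intercept": trend.intercept if trend.intercept is not None else "NA",
                            "r": trend.r if trend.r is not None else "NA",
                            "n": trend.n,
                        }
                    )
            _write_tsv(pd.DataFrame(motif_rows), out / "motif_stratified.tsv")
            _write_tsv(pd.DataFrame(trend_rows), out / "motif_trends.tsv")
            results["motif_stratified"] = pd.DataFrame(motif_rows)
            results["motif_trends"] = pd.DataFrame(trend_rows)

        stage = "editing"
        if pileups and sequences and genomic:
            sites_by_fraction = {}
            for frac, pu in pileups.items():
                cands = call_sites(
                    pu,
                    sequences,
                    fraction=frac,
                    min_coverage=config.min_coverage,
                    min_alt_fraction=config.min_alt_fraction,
                    min_alt_reads=config.min_alt_reads,
                )
                sites_by_fraction[frac] = discriminate_snps(cands, genomic)
                _write_tsv(sites_to_frame(sites_by_fraction[frac]), out / f"editing_sites_{frac}.tsv")
            overlap_frames = []
            overlaps = {}
            for cond in design.conditions:
                summ = editing_localization_overlap(
                    sites_by_fraction, loc_results[cond], cond, mode=config.overlap_mode
                )
                overlaps[cond] = summ
                overlap_frames.append(summ.to_frame())
            _write_tsv(pd.concat(overlap_frames, ignore_index=True), out / "editing_overlap.tsv")
            results["editing_sites"] = sites_by_fraction
            results["editing_overlap"] = overlaps

        stage = "report"
        manifest = {
            "lncloc_version": __version__,
            "seed": config.seed,
            "synthetic": synthetic,
            "thresholds": {
                "expression_rpkm": config.expression_threshold,
                "fold_change": config.fc_threshold,
                "mixed": config.mixed_threshold,
                "alpha": config.alpha,
                "editing_min_coverage": config.min_coverage,
                "editing_min_alt_fraction": config.min_alt_fraction,
                "editing_min_alt_reads": config.min_alt_reads,
            },
            "n_random_variants": config.n_random_variants,
            "overlap_mode": config.overlap_mode,
            "synthetic_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config.synthetic).items()
            }
            if synthetic
            else None,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        (out / "report.txt").write_text(_render_report(design, expr, summaries, results))
        results["manifest"] = manifest
        return results
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _render_report(design, expr, summaries, results) -> str:
    lines = ["lncloc run report", "=" * 40, ""]
    lines.append("Expressed transcripts (mean RPKM > threshold):")
    for _, row in expr.counts_summary().iterrows():
        lines.append(f"  {row['condition']:>10s} / {row['fraction']:<12s}: {row['n_expressed']}")
    lines.append("")
    for cond, s in summaries.items():
        pct = s.percentages
        lines.append(f"Localization in {cond}:")
        for cat in ("nuclear", "cytoplasmic", "mixed"):
            lines.append(f"  {cat:<12s}: {s.counts.get(cat, 0):6d}  ({pct[cat]:.1f}% of classified)")
        lines.append(f"  unassigned  : {s.counts.get('unassigned', 0):6d}")
        lines.append(f"  localized total (nuclear + cytoplasmic): {s.localized_total}")
        lines.append("")
    if "transitions" in results:
        lines.append("Category transitions (control rows -> treated columns):")
        lines.append(results["transitions"].to_string())
        lines.append("")
    if "editing_overlap" in results:
        for cond, summ in results["editing_overlap"].items():
            lines.append(f"Editing x localization in {cond}:")
            lines.append(summ.to_frame().to_string(index=False))
            lines.append("")
    return "\n".join(lines) + "\n"
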