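import numpy as np
import pandas as pd
import pytest

from lncloc.editing import call_sites, discriminate_snps
from lncloc.motifs import MotifDefinition, scan_motif
from lncloc.simulate import (
    SyntheticConfig,
    plant_variant_sites,
    simulate_counts,
    simulate_editing_evidence,
    simulate_sequences,
)

MOTIF = MotifDefinition(name="probe", pattern="AGCCC")


class TestConfigValidation:
    def test_proportions_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(frac_nuclear_planted=0.6, frac_cytoplasmic_planted=0.3, frac_mixed_planted=0.3)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="n_replicates"):
            SyntheticConfig(n_replicates=1)

    def test_undetectable_edits_rejected(self):
        with pytest.raises(ValueError, match="alt_fraction"):
            SyntheticConfig(alt_fraction=0.001, error_rate=0.01)


class TestSimulateCounts:
    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_transcripts=100, seed=1)
        c1, d1, t1 = simulate_counts(cfg)
        c2, d2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.category, t2.category)
        m1 = simulate_sequences(cfg, t1, [MOTIF])
        m2 = simulate_sequences(cfg, t2, [MOTIF])
        assert m1 == m2

    def test_shape_and_design(self):
        cfg = SyntheticConfig(n_transcripts=50, n_replicates=3, seed=2)
        counts, design, truth = simulate_counts(cfg)
        assert counts.shape == (50, 2 * 2 * 3)
        assert set(design.table["condition"]) == {"control", "H2O2"}
        assert len(truth.category) == 50

    def test_null_config_has_symmetric_means(self):
        # planted_log2fc=0 makes both fraction means equal for every transcript
        cfg = SyntheticConfig(n_transcripts=400, planted_log2fc=0.0, seed=3)
        counts, design, _ = simulate_counts(cfg)
        nuc = counts[design.samples("control", "nuclear")].to_numpy().mean()
        cyt = counts[design.samples("control", "cytoplasmic")].to_numpy().mean()
        assert abs(np.log2(cyt / nuc)) < 0.15

    def test_planted_ratio_recovered(self):
        # Monte-Carlo: nuclear-planted transcripts at log2fc=2 have a
        # cytoplasmic/nuclear mean ratio near 2**-2 = 0.25
        cfg = SyntheticConfig(
            n_transcripts=1000,
            frac_nuclear_planted=0.2,
            frac_cytoplasmic_planted=0.0,
            frac_mixed_planted=0.6,
            planted_log2fc=2.0,
            seed=4,
        )
        counts, design, truth = simulate_counts(cfg)
        nuc_planted = truth.transcripts_in("control", "nuclear")
        nuc_mean = counts.loc[nuc_planted, design.samples("control", "nuclear")].mean(axis=1)
        cyt_mean = counts.loc[nuc_planted, design.samples("control", "cytoplasmic")].mean(axis=1)
        ratio = (cyt_mean / nuc_mean).median()
        assert ratio == pytest.approx(0.25, rel=0.15)

    def test_column_sums_near_library_size(self):
        cfg = SyntheticConfig(n_transcripts=2000, library_size_sigma=0.05, seed=5)
        counts, _, _ = simulate_counts(cfg)
        rel_dev = (counts.sum() - cfg.library_size_mean).abs() / cfg.library_size_mean
        assert rel_dev.median() < 0.15

    def test_transition_probabilities_recovered(self):
        cfg = SyntheticConfig(n_transcripts=4000, seed=6)
        _, _, truth = simulate_counts(cfg)
        ctrl = truth.category["control"]
        trt = truth.category["H2O2"]
        mixed = ctrl[ctrl == "mixed"].index
        observed = (trt.loc[mixed] == "nuclear").mean()
        expected = cfg.transition_probs["mixed"]["nuclear"]
        se = np.sqrt(expected * (1 - expected) / len(mixed))
        assert abs(observed - expected) < 4 * se


class TestSimulateSequences:
    def test_no_insertion_when_rates_zero(self):
        cfg = SyntheticConfig(
            n_transcripts=50,
            transcript_length_range=(200, 400),
            motif_insertion_rate_by_category={},
            seed=7,
        )
        _, _, truth = simulate_counts(cfg)
        simulate_sequences(cfg, truth, [MOTIF])
        assert truth.motif_placements == []

    def test_planted_motif_found_at_offset(self):
        cfg = SyntheticConfig(
            n_transcripts=30,
            transcript_length_range=(200, 400),
            motif_insertion_rate_by_category={c: 1.0 for c in ("nuclear", "cytoplasmic", "mixed", "unexpressed")},
            seed=8,
        )
        _, _, truth = simulate_counts(cfg)
        seqs = simulate_sequences(cfg, truth, [MOTIF])
        assert truth.motif_placements
        for tx, motif, off in truth.motif_placements:
            assert off in scan_motif(seqs[tx], MOTIF)

    def test_insertion_rate_difference_recovered(self):
        # nuclear rate 0.8 vs cytoplasmic 0.1 -> presence-frequency gap ~0.7;
        # an 8-nt probe keeps background-chance hits negligible (<1%)
        probe = MotifDefinition(name="probe8", pattern="AGGTAAGT")
        rates = {"nuclear": 0.8, "cytoplasmic": 0.1, "mixed": 0.0, "unexpressed": 0.0}
        cfg = SyntheticConfig(
            n_transcripts=500,
            transcript_length_range=(200, 400),
            frac_nuclear_planted=0.4,
            frac_cytoplasmic_planted=0.4,
            frac_mixed_planted=0.2,
            motif_insertion_rate_by_category=rates,
            seed=9,
        )
        _, _, truth = simulate_counts(cfg)
        seqs = simulate_sequences(cfg, truth, [probe])
        def presence(category):
            txs = truth.transcripts_in("control", category)
            return np.mean([len(scan_motif(seqs[t], probe)) > 0 for t in txs])
        gap = presence("nuclear") - presence("cytoplasmic")
        # ~200 transcripts per class: binomial error ~ 3*sqrt(0.8*0.2/200)
        assert gap == pytest.approx(0.7, abs=0.1)

    def test_oversized_motif_rejected(self):
        cfg = SyntheticConfig(n_transcripts=10, transcript_length_range=(50, 60), seed=10)
        _, _, truth = simulate_counts(cfg)
        big = MotifDefinition(name="big", pattern="A" * 100)
        with pytest.raises(ValueError, match="longer"):
            simulate_sequences(cfg, truth, [big])


class TestSimulateEditingEvidence:
    def test_zero_rates_yield_zero_edits(self):
        cfg = SyntheticConfig(
            n_transcripts=30,
            transcript_length_range=(200, 300),
            edit_rate=0.0,
            snp_rate=0.0,
            error_rate=1e-9,
            n_background_pileup_transcripts=10,
            seed=11,
        )
        _, _, truth = simulate_counts(cfg)
        seqs = simulate_sequences(cfg, truth, [])
        plant_variant_sites(cfg, truth, seqs)
        pileups, genomic = simulate_editing_evidence(cfg, truth, seqs)
        for frac, pu in pileups.items():
            sites = discriminate_snps(call_sites(pu, seqs, fraction=frac), genomic)
            assert [s for s in sites if s.verdict == "edit"] == []

    def test_single_planted_edit_recovered_exactly(self):
        cfg = SyntheticConfig(
            n_transcripts=20,
            transcript_length_range=(200, 300),
            coverage_mean=50,
            alt_fraction=0.5,
            error_rate=1e-9,
            n_background_pileup_transcripts=5,
            seed=12,
        )
        _, _, truth = simulate_counts(cfg)
        seqs = simulate_sequences(cfg, truth, [])
        tx = truth.transcripts_in("control", "mixed")[0]
        pos = seqs[tx].index("A")
        truth.edit_sites = [(tx, pos, ("nuclear",))]
        truth.snp_sites = []
        pileups, genomic = simulate_editing_evidence(cfg, truth, seqs)
        sites = discriminate_snps(call_sites(pileups["nuclear"], seqs, fraction="nuclear"), genomic)
        edits = [(s.transcript_id, s.pos0) for s in sites if s.verdict == "edit"]
        assert edits == [(tx, pos)]

    def test_snp_alters_genome_not_truth_overlap(self):
        cfg = SyntheticConfig(
            n_transcripts=40,
            transcript_length_range=(200, 300),
            edit_rate=0.3,
            snp_rate=0.3,
            seed=13,
        )
        _, _, truth = simulate_counts(cfg)
        seqs = simulate_sequences(cfg, truth, [])
        plant_variant_sites(cfg, truth, seqs)
        edit_keys = {(t, p) for t, p, _ in truth.edit_sites}
        snp_keys = set(truth.snp_sites)
        assert edit_keys.isdisjoint(snp_keys)
        _, genomic = simulate_editing_evidence(cfg, truth, seqs)
        for tx, pos in truth.snp_sites:
            assert seqs[tx][pos] == "A"
            assert genomic[tx][pos] == "G"
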