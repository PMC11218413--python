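"""The generator's determinism, error model and editing experiment."""

import numpy as np
import pytest

from isohap.alignment import INSERTION, DELETION, MATCH, MISMATCH
from isohap.annotation_io import transcript_sequences
from isohap.inosine_editing import EditSite, pileup_counts
from isohap.synthetic_reads import (
    SimConfig,
    make_transcriptome,
    plant_variants,
    simulate_editing_experiment,
    simulate_reads,
)


def test_same_seed_is_byte_identical():
    cfg = SimConfig(seed=42, n_genes=3, isoforms_per_gene=2)
    g1, m1, t1 = make_transcriptome(cfg)
    g2, m2, t2 = make_transcriptome(cfg)
    assert g1 == g2 and m1 == m2 and t1 == t2
    r1 = simulate_reads(cfg, m1, g1)
    r2 = simulate_reads(cfg, m2, g2)
    assert [(r.read_id, r.sequence) for r in r1] == [
        (r.read_id, r.sequence) for r in r2
    ]


def test_isoforms_share_exons_and_chains_differ():
    cfg = SimConfig(seed=1, n_genes=1, isoforms_per_gene=2)
    _, models, truth = make_transcriptome(cfg)
    a, b = models
    assert set(a.exons) & set(b.exons)
    assert a.junctions != b.junctions


def test_single_isoform_gene_has_one_chain():
    cfg = SimConfig(seed=1, n_genes=1, isoforms_per_gene=1)
    _, models, truth = make_transcriptome(cfg)
    assert len(models) == 1


def test_perfect_accuracy_reproduces_transcript():
    cfg = SimConfig(seed=2, per_base_accuracy=1.0, coverage_per_haplotype=2)
    genome, models, _ = make_transcriptome(cfg)
    seqs = transcript_sequences(models, genome)
    for read in simulate_reads(cfg, models, genome):
        assert read.sequence == seqs[read.isoform_id]
        assert read.tx_alignment.ops == ((MATCH, len(read.sequence)),)


def test_coverage_per_haplotype_arithmetic():
    cfg = SimConfig(seed=2, n_genes=1, isoforms_per_gene=1, coverage_per_haplotype=20)
    genome, models, _ = make_transcriptome(cfg)
    variants = plant_variants(models, genome, 3, np.random.default_rng(0))
    haps = [("ref",) * 3, ("alt",) * 3, ("ref", "alt", "ref")]
    reads = simulate_reads(cfg, models, genome, variants, haps)
    assert len(reads) == 60  # 3 haplotypes x 20x for the single isoform


def test_realized_error_rate_matches_target():
    cfg = SimConfig(
        seed=9, per_base_accuracy=0.99, coverage_per_haplotype=10,
        exon_len_range=(200, 400),
    )
    genome, models, _ = make_transcriptome(cfg)
    reads = simulate_reads(cfg, models, genome)
    errors = total = 0
    for r in reads:
        for kind, length in r.tx_alignment.ops:
            if kind in (MISMATCH, INSERTION, DELETION):
                errors += length
            total += length if kind != INSERTION else 0
    assert total > 10_000
    rate = errors / total
    sd = np.sqrt(0.01 * 0.99 / total)
    # substitutions may coincide with the reference base, so the observed
    # op-level rate sits slightly below the planted 1%
    assert 0.01 - 0.2 * 0.01 - 4 * sd < rate < 0.01 + 4 * sd


def test_truncation_keeps_three_prime_end():
    cfg = SimConfig(
        seed=4, per_base_accuracy=1.0, coverage_per_haplotype=20,
        truncation_model=("3prime_geometric", 0.01),
    )
    genome, models, _ = make_transcriptome(cfg)
    seqs = transcript_sequences(models, genome)
    reads = simulate_reads(cfg, models, genome)
    assert any(len(r.sequence) < len(seqs[r.isoform_id]) for r in reads)
    for r in reads:
        assert seqs[r.isoform_id].endswith(r.sequence)


def test_truth_table_complete():
    cfg = SimConfig(seed=5, n_genes=2, coverage_per_haplotype=4)
    genome, models, _ = make_transcriptome(cfg)
    reads = simulate_reads(cfg, models, genome)
    ids = [r.read_id for r in reads]
    assert len(ids) == len(set(ids))
    assert all(r.isoform_id in {m.transcript_id for m in models} for r in reads)


def test_editing_zero_control_fraction_means_no_edits():
    cfg = SimConfig(seed=6, n_genes=1, isoforms_per_gene=1, coverage_per_haplotype=10,
                    n_replicates=1)
    exp = simulate_editing_experiment(cfg, n_sites=5, fraction_ctrl=0.0, fraction_kd=0.0)
    assert all(not r.edited_positions for r in exp.reads["ctrl"])


def test_editing_fraction_is_binomial_across_sites():
    cfg = SimConfig(
        seed=7, n_genes=1, isoforms_per_gene=1, coverage_per_haplotype=30,
        n_replicates=1, exon_len_range=(400, 500), fixed_strand="+",
    )
    exp = simulate_editing_experiment(cfg, n_sites=40, fraction_ctrl=0.6, fraction_kd=0.2)
    per_site = {pos: 0 for _, pos, _, _, _ in exp.sites}
    for r in exp.reads["ctrl"]:
        for pos in r.edited_positions:
            per_site[pos] += 1
    mean = np.mean(list(per_site.values()))
    # Binomial(30, 0.6): mean 18, sd 2.68; 40 sites
    assert abs(mean - 18.0) < 4 * 2.68 / np.sqrt(40)


def test_intronic_sites_are_spliced_out_and_edited():
    cfg = SimConfig(
        seed=8, n_genes=1, isoforms_per_gene=1, coverage_per_haplotype=40,
        n_replicates=1, intron_retention_rate=0.5, fixed_strand="+",
    )
    exp = simulate_editing_experiment(
        cfg, n_sites=3, fraction_ctrl=0.9, fraction_kd=0.0, site_region="intronic"
    )
    sites = [EditSite(c, p, s) for c, p, s, _, _ in exp.sites]
    counts = pileup_counts(exp.alignments, sites)
    assert all(c.spliced_out > 0 for c in counts)
    assert any(c.edited_ctrl > 0 for c in counts)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(per_base_accuracy=0.4)
    with pytest.raises(ValueError):
        SimConfig(coverage_per_haplotype=0)
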