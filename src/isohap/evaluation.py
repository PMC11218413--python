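"""End-to-end desk-scale experiments used to validate the pipeline.

These workflows wire the synthetic generator through the assignment,
haplotype and editing modules at small, fixed study designs: a
multi-haplotype variant-recovery benchmark, a null calibration of the
differential-editing test, and a knockdown-recovery experiment.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import align_to_transcript
from .annotation_io import GenomeInterval, TranscriptModel, Variant, transcript_sequences
from .haplotype_integration import ALT, REF, profile_reads, tabulate_haplotypes
from .inosine_editing import EditSite, differential_editing, pileup_counts
from .synthetic_reads import (
    SimConfig,
    _ALT_OF,
    _BASES,
    simulate_editing_experiment,
    simulate_reads,
)
from .transcript_assignment import assign_all, supported_annotated_isoforms

__all__ = [
    "haplotype_recovery",
    "editing_null_calibration",
    "knockdown_recovery",
]


def _hst_benchmark_gene(rng: np.random.Generator):
    """A hand-built two-isoform gene carrying 15 planted variants.

    The exon layout is fixed; only the genome sequence (and hence the read
    errors downstream) varies with the seed.  Isoform iso0 keeps all four
    exons; iso1 skips exon 3.  Five variants sit in each of exons 1, 3 and
    4, pairwise >= 5 bp apart, giving three haplotypes on iso0 (alt at
    v1-v5 / alt at v6-v10 / all-reference) and two on iso1 (alt at
    v11-v15 / all-reference) -- five consistent allele combinations in one
    gene, which a diploid phaser could not represent.
    """
    chrom = "chrB"
    exons = [(1000, 1300), (1500, 1800), (2100, 2400), (2700, 3100)]
    genome = {chrom: "".join(_BASES[rng.integers(0, 4, size=4300)])}
    iso0 = TranscriptModel(
        "geneH.iso0",
        "geneH",
        "+",
        tuple(GenomeInterval(chrom, s, e, "+") for s, e in exons),
    )
    iso1 = TranscriptModel(
        "geneH.iso1",
        "geneH",
        "+",
        tuple(
            GenomeInterval(chrom, s, e, "+")
            for s, e in (exons[0], exons[1], exons[3])
        ),
    )
    positions = (
        [1010, 1060, 1110, 1160, 1210]  # exon 1 (both isoforms)
        + [2110, 2160, 2210, 2260, 2310]  # exon 3 (iso0 only)
        + [2710, 2760, 2810, 2860, 2910]  # exon 4 (both isoforms)
    )
    variants = [
        Variant(chrom, p, genome[chrom][p], _ALT_OF[genome[chrom][p]])
        for p in positions
    ]

    def vector(alt_idx: Sequence[int]) -> Tuple[str, ...]:
        return tuple(ALT if i in alt_idx else REF for i in range(len(variants)))

    haplotypes = {
        "geneH.iso0": [vector(range(0, 5)), vector(range(5, 10)), vector(())],
        "geneH.iso1": [vector(range(10, 15)), vector(())],
    }
    return genome, [iso0, iso1], variants, haplotypes


def haplotype_recovery(
    seed: int,
    coverage: int = 20,
    accuracy: float = 0.99,
    min_support: int = 3,
    min_fraction: float = 0.10,
) -> Dict[str, object]:
    """Recover planted allele combinations from simulated reads.

    Simulates ``coverage`` reads per haplotype at ``accuracy`` from the
    15-variant benchmark gene, assigns reads to transcripts with the
    fidelity rules, tabulates haplotypes per isoform, and counts how many of
    the 15 planted variants appear in the correct isoform's output with the
    correct allele combination.
    """
    rng = np.random.default_rng(seed)
    genome, models, variants, planted = _hst_benchmark_gene(rng)
    cfg = SimConfig(
        seed=seed,
        per_base_accuracy=accuracy,
        coverage_per_haplotype=coverage,
    )
    reads = []
    for model in models:
        reads.extend(
            simulate_reads(
                cfg, [model], genome, variants, planted[model.transcript_id], rng=rng
            )
        )

    # read -> transcript assignment under the fidelity rules
    model_by_id = {m.transcript_id: m for m in models}
    tx_seqs = transcript_sequences(models, genome)
    alignments = [
        align_to_transcript(r.sequence, tx_seqs[tid], read_id=r.read_id, transcript_id=tid)
        for r in reads
        for tid in tx_seqs
    ]
    assignments = assign_all(alignments, model_by_id)
    kept, _ = supported_annotated_isoforms(assignments, min_support=min_support)

    genome_alns = {r.read_id: r.genome_alignment for r in reads}
    profiles = profile_reads(kept, variants, genome_alns, model_by_id)

    recovered: set = set()
    groups_by_iso = {
        iso: tabulate_haplotypes(
            profiles[iso], min_support=min_support, min_fraction=min_fraction
        )
        for iso in profiles
    }
    correct_assignment = sum(
        1 for r in reads if assignments.get(r.read_id) == r.isoform_id
    )
    for iso, vectors in planted.items():
        prof = profiles.get(iso)
        if prof is None:
            continue
        site_index = {v.key: i for i, v in enumerate(prof.variants)}
        found = {g.allele_vector for g in groups_by_iso.get(iso, [])}
        for vec in vectors:
            restricted = tuple(
                vec[i]
                for i, v in enumerate(variants)
                if v.key in site_index
            )
            if restricted in found:
                recovered.update(
                    v.key
                    for i, v in enumerate(variants)
                    if vec[i] == ALT and v.key in site_index
                )
    return {
        "n_planted": len(variants),
        "n_recovered": len(recovered),
        "n_reads": len(reads),
        "assignment_accuracy": correct_assignment / len(reads),
        "haplotypes_per_isoform": {
            iso: len(groups) for iso, groups in groups_by_iso.items()
        },
    }


def _experiment_counts(exp) -> List:
    sites = [
        EditSite(chrom=chrom, pos=pos, gene_strand=strand)
        for chrom, pos, strand, _, _ in exp.sites
    ]
    return pileup_counts(exp.alignments, sites)


def editing_null_calibration(
    seed: int,
    n_sites: int = 200,
    coverage: int = 150,
    edit_fraction: float = 0.5,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Rejection rate of the differential-editing test under the null.

    Both conditions edit at the same fraction; the fraction of sites with a
    raw Fisher p below ``alpha`` estimates the test's size.  Deep coverage
    (one replicate of ``coverage`` reads per condition) keeps the discrete
    null close to its nominal level.
    """
    cfg = SimConfig(
        seed=seed,
        n_genes=1,
        isoforms_per_gene=1,
        exon_count_range=(4, 4),
        exon_len_range=(600, 700),
        coverage_per_haplotype=coverage,
        n_replicates=1,
        fixed_strand="+",
    )
    exp = simulate_editing_experiment(
        cfg, n_sites=n_sites, fraction_ctrl=edit_fraction, fraction_kd=edit_fraction
    )
    df = differential_editing(_experiment_counts(exp), alpha=alpha)
    rate = float((df["p_value"] < alpha).mean())
    return {"n_sites": float(len(df)), "rejection_rate": rate, "alpha": alpha}


def knockdown_recovery(
    seed: int,
    n_sites: int = 60,
    coverage: int = 30,
    n_replicates: int = 3,
    fraction_ctrl: float = 0.6,
    fraction_kd: float = 0.2,
) -> Dict[str, float]:
    """Recovery of planted differentially edited sites after knockdown.

    Sites are edited at ``fraction_ctrl`` in control and ``fraction_kd``
    after knockdown, with ``n_replicates`` x ``coverage`` reads per
    condition (replicates pooled, as the analytics assume).  Reports the
    fraction of planted sites called significant and the fraction of
    recovered sites whose direction is "down".
    """
    cfg = SimConfig(
        seed=seed,
        n_genes=1,
        isoforms_per_gene=1,
        exon_count_range=(4, 4),
        exon_len_range=(500, 600),
        coverage_per_haplotype=coverage,
        n_replicates=n_replicates,
        fixed_strand="+",
    )
    exp = simulate_editing_experiment(
        cfg, n_sites=n_sites, fraction_ctrl=fraction_ctrl, fraction_kd=fraction_kd
    )
    df = differential_editing(_experiment_counts(exp))
    recovered = df[df["significant"]]
    down = recovered[recovered["direction"] == "down"]
    return {
        "n_sites": float(len(df)),
        "recovered_fraction": float(len(recovered) / len(df)),
        "down_fraction": float(len(down) / len(recovered)) if len(recovered) else 0.0,
    }
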