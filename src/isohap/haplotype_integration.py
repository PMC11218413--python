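"""Associate sequence variants with isoforms: haplotype-specific transcripts.

Two modalities are provided, mirroring how phased and unphased variant calls
are used in practice:

* *ploidy-agnostic tabulation*: for each isoform, the allele vector carried
  by each supporting read over the variant sites inside the isoform's exons
  is recorded, and the most frequent consistent combinations ("haplotypes")
  with sufficient support are emitted -- any number per isoform, which suits
  RNA editing and aneuploid samples where two haplotypes are not enough;
* *phase-set mode*: when reads carry phase-set/haplotype tags from a diploid
  phasing caller, an isoform is linked to a (phase set, haplotype) when a
  strict majority of its tagged reads agree, and the phase set's variants
  inside the isoform are attached.

A per-variant Fisher test then asks whether an isoform's allele balance
differs from the rest of its gene (haplotype-specific transcript bias), with
Benjamini-Hochberg adjustment across all tests in the run.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .alignment import SPLICED, ReadAlignment
from .annotation_io import (
    GenomeLike,
    TranscriptModel,
    Variant,
    reverse_complement,
    transcript_sequences,
    write_bed12,
    write_vcf,
)
from .stats import bh_adjust, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "IsoformProfile",
    "HaplotypeGroup",
    "PhaseSetLink",
    "HstTestResult",
    "profile_reads",
    "tabulate_haplotypes",
    "phase_set_mode",
    "hst_bias_test",
    "write_hst_table",
    "emit_hst_outputs",
]

REF, ALT, UNCOVERED = "ref", "alt", "uncovered"


@dataclass(frozen=True)
class IsoformProfile:
    """Per-read variant observations for one isoform.

    ``variants`` fixes the site ordering; each read's observation tuple is
    keyed to it, with entries in {"ref", "alt", "uncovered"}.
    """

    isoform_id: str
    variants: Tuple[Variant, ...]
    observations: Mapping[str, Tuple[str, ...]]


@dataclass(frozen=True)
class HaplotypeGroup:
    """A consistent allele combination observed together in one isoform."""

    isoform_id: str
    variants: Tuple[Variant, ...]
    allele_vector: Tuple[str, ...]  # "ref"/"alt" per variant
    support: int

    @property
    def alt_variants(self) -> Tuple[Variant, ...]:
        return tuple(
            v for v, a in zip(self.variants, self.allele_vector) if a == ALT
        )


@dataclass(frozen=True)
class PhaseSetLink:
    isoform_id: str
    phase_set: str
    haplotype: str
    variants: Tuple[Variant, ...]
    tagged_reads: int
    agreeing_reads: int


@dataclass(frozen=True)
class HstTestResult:
    """Fisher test of one variant's allele balance in one isoform vs its gene."""

    variant: Variant
    isoform_id: str
    gene_id: str
    ref_isoform: int
    alt_isoform: int
    ref_other: int
    alt_other: int
    p_value: float
    adjusted_p: float = 1.0
    degenerate: bool = False


def profile_reads(
    isoform_read_map: Mapping[str, Iterable[str]],
    variants: Sequence[Variant],
    alignments: Mapping[str, ReadAlignment],
    models: Mapping[str, TranscriptModel],
) -> Dict[str, IsoformProfile]:
    """Record each read's base at every variant inside its isoform's exons.

    The read base at a variant's genomic position is classified as ref, alt,
    or uncovered (position deleted, spliced out, outside the alignment, or a
    third base that is neither allele).  Variants outside all exons of an
    isoform are excluded from that isoform's site set (logged).
    """
    out: Dict[str, IsoformProfile] = {}
    for iso, read_ids in isoform_read_map.items():
        model = models[iso]
        inside = tuple(
            v
            for v in sorted(variants, key=lambda v: v.key)
            if v.chrom == model.chrom and model.contains(v.pos)
        )
        n_out = sum(1 for v in variants if v.chrom == model.chrom) - len(inside)
        if n_out:
            logger.debug("%s: %d variants fall outside exons, excluded", iso, n_out)
        obs: Dict[str, Tuple[str, ...]] = {}
        for rid in read_ids:
            aln = alignments.get(rid)
            if aln is None:
                continue
            row = []
            for v in inside:
                base = aln.base_at(v.pos)
                if base == v.ref_allele:
                    row.append(REF)
                elif base == v.alt_allele:
                    row.append(ALT)
                else:  # None, SPLICED, or a third base
                    row.append(UNCOVERED)
            obs[rid] = tuple(row)
        out[iso] = IsoformProfile(iso, inside, obs)
    return out


def tabulate_haplotypes(
    profile: IsoformProfile,
    min_support: int = 3,
    min_fraction: float = 0.10,
) -> List[HaplotypeGroup]:
    """Most frequent consistent allele combinations for one isoform.

    Reads with fully covered allele vectors are counted exactly.  A read
    with uncovered sites is folded into a retained haplotype only when it is
    compatible with exactly one of the complete vectors; otherwise it is
    discarded -- partial observations never create new haplotypes.  Retained
    haplotypes need support >= ``min_support`` and >= ``min_fraction`` of the
    isoform's reads.  No ploidy cap applies.
    """
    n_reads = len(profile.observations)
    if n_reads == 0 or not profile.variants:
        return []
    complete = Counter()
    partial: List[Tuple[str, ...]] = []
    for row in profile.observations.values():
        if UNCOVERED in row:
            partial.append(row)
        else:
            complete[row] += 1
    support = dict(complete)
    vectors = list(complete)
    for row in partial:
        compatible = [
            vec
            for vec in vectors
            if all(o == UNCOVERED or o == v for o, v in zip(row, vec))
        ]
        if len(compatible) == 1:
            support[compatible[0]] += 1
    out = []
    for vec, count in sorted(support.items(), key=lambda kv: (-kv[1], kv[0])):
        if count >= min_support and count >= min_fraction * n_reads:
            out.append(
                HaplotypeGroup(
                    isoform_id=profile.isoform_id,
                    variants=profile.variants,
                    allele_vector=vec,
                    support=count,
                )
            )
    return out


def phase_set_mode(
    read_tags: Mapping[str, Tuple[str, str]],
    isoform_read_map: Mapping[str, Iterable[str]],
    phase_set_variants: Mapping[str, Sequence[Variant]],
    models: Mapping[str, TranscriptModel],
    majority: float = 0.5,
) -> Dict[str, PhaseSetLink]:
    """Link isoforms to (phase set, haplotype) via tagged-read majority.

    ``read_tags`` maps read id -> (phase set, haplotype) as emitted by a
    diploid phasing caller.  An isoform is linked when a strict majority
    (> ``majority``) of its tagged reads share one (phase set, haplotype);
    the phase set's variants inside the isoform's exons are attached (an
    empty attachment is logged).
    """
    out: Dict[str, PhaseSetLink] = {}
    for iso, read_ids in isoform_read_map.items():
        tags = [read_tags[r] for r in read_ids if r in read_tags]
        if not tags:
            continue
        (ps, hap), top = Counter(tags).most_common(1)[0]
        if top <= majority * len(tags):
            continue
        model = models[iso]
        attached = tuple(
            v
            for v in phase_set_variants.get(ps, ())
            if v.chrom == model.chrom and model.contains(v.pos)
        )
        if not attached:
            logger.info(
                "isoform %s linked to phase set %s but no variants fall in its exons",
                iso,
                ps,
            )
        out[iso] = PhaseSetLink(
            isoform_id=iso,
            phase_set=ps,
            haplotype=hap,
            variants=attached,
            tagged_reads=len(tags),
            agreeing_reads=top,
        )
    return out


def hst_bias_test(
    profiles: Mapping[str, IsoformProfile],
    models: Mapping[str, TranscriptModel],
    alpha: float = 0.05,
) -> List[HstTestResult]:
    """Per-variant, per-isoform Fisher test of allele balance within a gene.

    For every variant observed in a gene with >=2 isoforms carrying reads
    that cover it, the 2x2 table [ref, alt in this isoform | ref, alt in the
    gene's other isoforms] is tested two-sided; any zero margin yields p = 1
    by convention (flagged).  Adjusted p-values are Benjamini-Hochberg across
    all tests in the run; the significant set is ``adjusted_p < alpha``.
    """
    by_gene: Dict[str, List[str]] = {}
    for iso in profiles:
        by_gene.setdefault(models[iso].gene_id, []).append(iso)
    results: List[HstTestResult] = []
    for gene, isos in sorted(by_gene.items()):
        variant_counts: Dict[Variant, Dict[str, Tuple[int, int]]] = {}
        for iso in isos:
            prof = profiles[iso]
            for idx, v in enumerate(prof.variants):
                nref = sum(1 for row in prof.observations.values() if row[idx] == REF)
                nalt = sum(1 for row in prof.observations.values() if row[idx] == ALT)
                if nref + nalt:
                    variant_counts.setdefault(v, {})[iso] = (nref, nalt)
        for v, per_iso in sorted(variant_counts.items(), key=lambda kv: kv[0].key):
            if len(per_iso) < 2:
                continue
            for iso, (nref, nalt) in sorted(per_iso.items()):
                oref = sum(r for i, (r, _) in per_iso.items() if i != iso)
                oalt = sum(a for i, (_, a) in per_iso.items() if i != iso)
                degenerate = (
                    nref + nalt == 0
                    or oref + oalt == 0
                    or nref + oref == 0
                    or nalt + oalt == 0
                )
                p = 1.0 if degenerate else fisher_exact_2x2([[nref, nalt], [oref, oalt]])
                results.append(
                    HstTestResult(
                        variant=v,
                        isoform_id=iso,
                        gene_id=gene,
                        ref_isoform=nref,
                        alt_isoform=nalt,
                        ref_other=oref,
                        alt_other=oalt,
                        p_value=p,
                        degenerate=degenerate,
                    )
                )
    adjusted = bh_adjust([r.p_value for r in results])
    return [replace(r, adjusted_p=float(q)) for r, q in zip(results, adjusted)]


def write_hst_table(results: Sequence[HstTestResult], path: Union[str, Path]) -> None:
    """TSV: chrom, pos, ref, alt, isoform, p, ref/alt counts in and out of isoform."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tpos\tref\talt\tisoform\tp_value\tref_isoform\talt_isoform\t"
            "ref_other\talt_other\tadjusted_p_bh\n"
        )
        for r in results:
            v = r.variant
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{r.isoform_id}\t{r.p_value:.6g}\t{r.ref_isoform}\t{r.alt_isoform}\t"
                f"{r.ref_other}\t{r.alt_other}\t{r.adjusted_p:.6g}\n"
            )


def _substitute(
    seq: str, model: TranscriptModel, variants: Iterable[Variant]
) -> str:
    out = list(seq)
    for v in variants:
        off = model.genomic_to_transcript(v.pos)
        if off is None or off >= len(seq):
            raise ValueError(
                f"variant {v.chrom}:{v.pos} maps outside {model.transcript_id}"
            )
        base = v.alt_allele
        if model.strand == "-":
            base = reverse_complement(base)
        out[off] = base
    return "".join(out)


def emit_hst_outputs(
    models: Mapping[str, TranscriptModel],
    haplotypes: Mapping[str, Sequence[HaplotypeGroup]],
    genome: GenomeLike,
    out_prefix: Union[str, Path],
) -> Dict[str, str]:
    """Write the haplotype-specific transcript outputs.

    Produces ``<prefix>.fasta`` (isoform sequences with alt bases substituted
    at the mapped transcript offsets, strand-aware), ``<prefix>.bed`` (one
    model row per HST) and ``<prefix>.vcf`` (each variant annotated with the
    ids of the HSTs that carry it, ``ISO=`` INFO key).  Returns the HST
    sequences keyed by HST id.
    """
    out_prefix = str(out_prefix)
    ref_seqs = transcript_sequences(models.values(), genome)
    hst_seqs: Dict[str, str] = {}
    bed_models = []
    iso_by_variant: Dict[Tuple[str, int, str, str], List[str]] = {}
    variants: Dict[Tuple[str, int, str, str], Variant] = {}
    for iso, groups in sorted(haplotypes.items()):
        model = models[iso]
        for k, hap in enumerate(groups):
            hst_id = f"{iso}|hap{k}"
            hst_seqs[hst_id] = _substitute(ref_seqs[iso], model, hap.alt_variants)
            bed_models.append(
                TranscriptModel(hst_id, model.gene_id, model.strand, model.exons)
            )
            for v in hap.alt_variants:
                variants[v.key] = v
                iso_by_variant.setdefault(v.key, []).append(hst_id)
    from .annotation_io import write_fasta

    write_fasta(hst_seqs, f"{out_prefix}.fasta")
    write_bed12(bed_models, f"{out_prefix}.bed")
    write_vcf(
        list(variants.values()),
        f"{out_prefix}.vcf",
        info_by_variant={
            key: "ISO=" + ",".join(ids) for key, ids in iso_by_variant.items()
        },
        extra_header_lines=[
            '##INFO=<ID=ISO,Number=.,Type=String,Description="Haplotype-specific transcripts carrying this variant">'
        ],
    )
    return hst_seqs
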