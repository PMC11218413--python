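"""Synthetic transcriptomes, haplotypes, editing experiments and long reads.

The generator emulates the study design the rest of the package analyses:
multi-isoform genes with shared exons and alternative splice sites,
multiple planted haplotypes per gene, consensus-grade long reads (~99%
per-base accuracy, optional 3'-anchored truncation), and a two-condition
ADAR-knockdown editing experiment with three replicates per condition.

Reads are emitted together with their ground-truth alignments (explicit op
lists against both the source transcript and the genome), so downstream
modules are testable without invoking an external aligner; FASTQ/SAM/GTF/
FASTA/VCF writers cover interchange with real tools.  All randomness flows
from a single integer seed through one numpy Generator, so outputs are
byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .alignment import (
    DELETION,
    INSERTION,
    MATCH,
    MISMATCH,
    ReadAlignment,
    genome_alignment_from_transcript,
    merge_ops,
)
from .annotation_io import (
    GenomeInterval,
    TranscriptModel,
    Variant,
    reverse_complement,
    transcript_sequences,
)

__all__ = [
    "SimConfig",
    "SimRead",
    "make_transcriptome",
    "simulate_reads",
    "simulate_editing_experiment",
    "EditingExperiment",
    "plant_variants",
    "plant_edit_sites",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))
# deterministic transversion used when planting alt alleles
_ALT_OF = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the generator.

    ``per_base_accuracy`` is the read accuracy of consensus-called nanopore
    data (default 0.99); errors are i.i.d. per base with substitution :
    insertion : deletion at 50:25:25.  ``truncation_model`` is either None
    or ``("3prime_geometric", p)``: reads keep their 3' end and lose a
    geometric(p)-distributed 5' prefix.  ``n_replicates`` applies to the
    editing experiment (three replicates per condition, pooled downstream,
    matching the knockdown design the analytics assume).
    """

    seed: int = 0
    n_genes: int = 1
    isoforms_per_gene: int = 2
    exon_count_range: Tuple[int, int] = (3, 6)
    exon_len_range: Tuple[int, int] = (80, 300)
    intron_len_range: Tuple[int, int] = (100, 600)
    per_base_accuracy: float = 0.99
    coverage_per_haplotype: int = 20
    truncation_model: Optional[Tuple[str, float]] = None
    intron_retention_rate: float = 0.0
    n_replicates: int = 3
    gene_spacing: int = 2000
    chrom: str = "chrS"
    fixed_strand: Optional[str] = None  # "+" / "-" to disable random strands

    def __post_init__(self) -> None:
        if not 0.5 < self.per_base_accuracy <= 1.0:
            raise ValueError("per_base_accuracy must be in (0.5, 1]")
        if self.coverage_per_haplotype < 1:
            raise ValueError("coverage must be >= 1")
        for lo, hi in (
            self.exon_count_range,
            self.exon_len_range,
            self.intron_len_range,
        ):
            if lo < 1 or hi < lo:
                raise ValueError("infeasible range")


@dataclass(frozen=True)
class SimRead:
    """One simulated read with its ground truth."""

    read_id: str
    sequence: str  # transcript orientation, errors applied
    isoform_id: str
    haplotype: Optional[int]
    tx_alignment: ReadAlignment  # vs the reference transcript sequence
    genome_alignment: ReadAlignment
    edited_positions: Tuple[int, ...] = ()  # genomic positions edited in this read


# ---------------------------------------------------------------------------
# transcriptome construction


def make_transcriptome(
    cfg: SimConfig,
) -> Tuple[Dict[str, str], List[TranscriptModel], Dict[str, dict]]:
    """Random genome with embedded multi-isoform genes.

    Isoforms of a gene share exons and differ by skipped exons or
    alternative 5'/3' splice sites; junction chains are unique per gene.
    Returns (genome dict, models, truth mapping isoform -> structure).
    """
    rng = np.random.default_rng(cfg.seed)
    models: List[TranscriptModel] = []
    truth: Dict[str, dict] = {}
    cursor = cfg.gene_spacing
    for g in range(cfg.n_genes):
        gene_id = f"gene{g}"
        strand = cfg.fixed_strand or ("+" if rng.integers(2) == 0 else "-")
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for k in range(n_exons):
            elen = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if k < n_exons - 1:
                pos += int(
                    rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1)
                )
        base = tuple(exons)
        chains: Set[Tuple[Tuple[int, int], ...]] = set()
        gene_models: List[Tuple[str, Tuple[Tuple[int, int], ...]]] = []

        def add(tid: str, exs: Tuple[Tuple[int, int], ...]) -> bool:
            chain = tuple((a[1], b[0]) for a, b in zip(exs, exs[1:]))
            if chain in chains:
                return False
            chains.add(chain)
            gene_models.append((tid, exs))
            return True

        add(f"{gene_id}.iso0", base)
        iso_n = 1
        attempts = 0
        while iso_n < cfg.isoforms_per_gene and attempts < 100:
            attempts += 1
            exs = list(base)
            mode = int(rng.integers(3)) if n_exons >= 3 else int(rng.integers(1, 3))
            if mode == 0 and n_exons >= 3:  # skip one internal exon
                drop = int(rng.integers(1, n_exons - 1))
                exs = exs[:drop] + exs[drop + 1 :]
            elif mode == 1:  # alternative donor: shift an internal exon end
                k = int(rng.integers(0, n_exons - 1))
                delta = int(rng.integers(10, 41))
                s, e = exs[k]
                if e - delta - s < 20:
                    continue
                exs[k] = (s, e - delta)
            else:  # alternative acceptor: shift an internal exon start
                k = int(rng.integers(1, n_exons))
                delta = int(rng.integers(10, 41))
                s, e = exs[k]
                if e - (s + delta) < 20:
                    continue
                exs[k] = (s + delta, e)
            if add(f"{gene_id}.iso{iso_n}", tuple(exs)):
                iso_n += 1
        if iso_n < cfg.isoforms_per_gene:
            raise ValueError("could not build the requested isoform count")
        for tid, exs in gene_models:
            m = TranscriptModel(
                tid,
                gene_id,
                strand,
                tuple(GenomeInterval(cfg.chrom, s, e, strand) for s, e in exs),
            )
            models.append(m)
            truth[tid] = {
                "gene_id": gene_id,
                "strand": strand,
                "exons": exs,
                "junctions": m.junctions,
            }
        cursor = pos + cfg.gene_spacing
    total = cursor + cfg.gene_spacing
    genome = {cfg.chrom: "".join(_BASES[rng.integers(0, 4, size=total)])}
    return genome, models, truth


def plant_variants(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    n_variants: int,
    rng: np.random.Generator,
    min_spacing: int = 5,
) -> List[Variant]:
    """Plant SNVs at exonic positions, pairwise >= ``min_spacing`` apart."""
    exonic: List[Tuple[str, int]] = sorted(
        {(e.chrom, p) for m in models for e in m.exons for p in range(e.start, e.end)}
    )
    chosen: List[Tuple[str, int]] = []
    order = rng.permutation(len(exonic))
    for idx in order:
        chrom, pos = exonic[idx]
        if all(c != chrom or abs(pos - p) >= min_spacing for c, p in chosen):
            chosen.append((chrom, pos))
        if len(chosen) == n_variants:
            break
    if len(chosen) < n_variants:
        raise ValueError("not enough exonic space for the requested variants")
    out = []
    for chrom, pos in sorted(chosen):
        ref = genome[chrom][pos]
        out.append(Variant(chrom, pos, ref, _ALT_OF[ref]))
    return out


# ---------------------------------------------------------------------------
# read construction


def _apply_errors(
    rng: np.random.Generator, source: str, accuracy: float
) -> List[Tuple[str, int, str]]:
    """Aligned columns ('aln', tpos, base) / ('ins', tpos, base) / ('del', tpos, '')."""
    cols: List[Tuple[str, int, str]] = []
    err = 1.0 - accuracy
    n = len(source)
    u = rng.random(n)
    for tpos in range(n):
        if u[tpos] >= err:
            cols.append(("aln", tpos, source[tpos]))
            continue
        kind = rng.random()
        if kind < 0.5:  # substitution
            base = source[tpos]
            sub = _BASES[rng.integers(0, 3)]
            if sub == base:
                sub = "T" if base != "T" else "G"
            cols.append(("aln", tpos, str(sub)))
        elif kind < 0.75:  # insertion after a correct base
            cols.append(("aln", tpos, source[tpos]))
            cols.append(("ins", tpos + 1, str(_BASES[rng.integers(0, 4)])))
        else:  # deletion
            cols.append(("del", tpos, ""))
    return cols


def _read_from_columns(
    cols: List[Tuple[str, int, str]],
    ref_seq: str,
    offset: int,
    read_id: str,
    transcript_id: str,
) -> ReadAlignment:
    """Build a transcript-space alignment by classifying columns vs the reference."""
    while cols and cols[0][0] != "aln":
        cols.pop(0)
    while cols and cols[-1][0] != "aln":
        cols.pop()
    if not cols:
        raise ValueError("read lost all bases")
    t0 = offset + cols[0][1]
    ops: List[Tuple[str, int]] = []
    seq_parts: List[str] = []
    for kind, tpos, base in cols:
        if kind == "aln":
            ref = ref_seq[offset + tpos]
            ops.append((MATCH if base == ref else MISMATCH, 1))
            seq_parts.append(base)
        elif kind == "ins":
            ops.append((INSERTION, 1))
            seq_parts.append(base)
        else:
            ops.append((DELETION, 1))
    return ReadAlignment(
        read_id=read_id,
        target_id=transcript_id,
        target_kind="transcript",
        ops=merge_ops(ops),
        target_start=t0,
        read_sequence="".join(seq_parts),
    )


def _truncation_offset(
    rng: np.random.Generator, cfg: SimConfig, length: int
) -> int:
    if cfg.truncation_model is None:
        return 0
    name, p = cfg.truncation_model
    if name != "3prime_geometric":
        raise ValueError(f"unknown truncation model {name!r}")
    drop = int(rng.geometric(p)) - 1
    return min(drop, max(0, length - 50))


def simulate_reads(
    cfg: SimConfig,
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    variants: Sequence[Variant] = (),
    haplotypes: Optional[Sequence[Sequence[str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[SimRead]:
    """Draw error-bearing reads per isoform and per haplotype.

    ``haplotypes`` is a list of allele vectors ("ref"/"alt") over
    ``variants`` in their given order; each isoform receives
    ``coverage_per_haplotype`` reads from every haplotype whose alt sites it
    covers (sites outside the isoform's exons are simply absent from its
    copy).  Without haplotypes, reads come from the reference sequence.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ref_seqs = transcript_sequences(models, genome)
    out: List[SimRead] = []
    hap_list: List[Optional[int]] = (
        list(range(len(haplotypes))) if haplotypes else [None]
    )
    for model in models:
        ref_seq = ref_seqs[model.transcript_id]
        for hap in hap_list:
            source = ref_seq
            if hap is not None:
                alt = [
                    v
                    for v, a in zip(variants, haplotypes[hap])
                    if a == "alt" and v.chrom == model.chrom and model.contains(v.pos)
                ]
                source = _substitute_tx(ref_seq, model, alt)
            for i in range(cfg.coverage_per_haplotype):
                t0 = _truncation_offset(rng, cfg, len(source))
                cols = _apply_errors(rng, source[t0:], cfg.per_base_accuracy)
                rid = f"{model.transcript_id}|h{hap if hap is not None else 'ref'}|{i}"
                tx = _read_from_columns(cols, ref_seq, t0, rid, model.transcript_id)
                gen = genome_alignment_from_transcript(tx, model)
                out.append(
                    SimRead(
                        read_id=rid,
                        sequence=tx.read_sequence or "",
                        isoform_id=model.transcript_id,
                        haplotype=hap,
                        tx_alignment=tx,
                        genome_alignment=gen,
                    )
                )
    return out


def _substitute_tx(
    ref_seq: str, model: TranscriptModel, variants: Iterable[Variant]
) -> str:
    seq = list(ref_seq)
    for v in variants:
        off = model.genomic_to_transcript(v.pos)
        if off is None:
            continue
        base = v.alt_allele if model.strand == "+" else reverse_complement(v.alt_allele)
        seq[off] = base
    return "".join(seq)


# ---------------------------------------------------------------------------
# editing experiment


@dataclass(frozen=True)
class EditingExperiment:
    """A simulated two-condition knockdown with per-condition alignments."""

    genome: Dict[str, str]
    models: List[TranscriptModel]
    sites: List[Tuple[str, int, str, float, float]]  # chrom, pos, strand, f_ctrl, f_kd
    alignments: Dict[str, List[ReadAlignment]]  # "ctrl" / "kd", replicates pooled
    reads: Dict[str, List[SimRead]]


def plant_edit_sites(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    n_sites: int,
    rng: np.random.Generator,
    fraction_ctrl: float = 0.6,
    fraction_kd: float = 0.2,
    region: str = "exonic",
    min_spacing: int = 1,
) -> List[Tuple[str, int, str, float, float]]:
    """Pick adenosine positions (strand-aware) to carry planted edits.

    ``region`` is "exonic" or "intronic" (positions inside a model's introns,
    for edit-vs-splice simulations).  On minus-strand genes the genomic base
    is T and edits appear as T->C.
    """
    cands: List[Tuple[str, int, str]] = []
    for m in models:
        want = "A" if m.strand == "+" else "T"
        if region == "exonic":
            spans = [(e.start, e.end) for e in m.exons]
        elif region == "intronic":
            spans = list(m.junctions)
        else:
            raise ValueError(region)
        for s, e in spans:
            for p in range(s, e):
                if genome[m.chrom][p] == want:
                    cands.append((m.chrom, p, m.strand))
    cands = sorted(set(cands))
    chosen: List[Tuple[str, int, str]] = []
    for idx in rng.permutation(len(cands)):
        chrom, pos, strand = cands[idx]
        if all(
            c != chrom or abs(pos - p) >= min_spacing for c, p, _ in chosen
        ):
            chosen.append((chrom, pos, strand))
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        raise ValueError("not enough adenosine positions for the requested sites")
    return [
        (chrom, pos, strand, fraction_ctrl, fraction_kd)
        for chrom, pos, strand in sorted(chosen)
    ]


def _retained_intron_model(
    model: TranscriptModel, retained: Sequence[bool]
) -> TranscriptModel:
    """Merge exons across retained introns to get the read's source structure."""
    if not any(retained):
        return model
    exons = [[model.exons[0].start, model.exons[0].end]]
    for keep, nxt in zip(retained, model.exons[1:]):
        if keep:
            exons[-1][1] = nxt.end
        else:
            exons.append([nxt.start, nxt.end])
    return TranscriptModel(
        model.transcript_id,
        model.gene_id,
        model.strand,
        tuple(
            GenomeInterval(model.chrom, s, e, model.strand) for s, e in exons
        ),
    )


def simulate_editing_experiment(
    cfg: SimConfig,
    sites: Optional[Sequence[Tuple[str, int, str, float, float]]] = None,
    n_sites: int = 20,
    fraction_ctrl: float = 0.6,
    fraction_kd: float = 0.2,
    site_region: str = "exonic",
) -> EditingExperiment:
    """Two-condition editing knockdown over a fresh synthetic transcriptome.

    Each condition receives ``n_replicates`` x ``coverage_per_haplotype``
    reads per isoform; every read is edited independently at each site it
    transcribes with its condition's fraction.  Introns are retained per
    read with ``intron_retention_rate``, so intronic sites are transcribed
    by some molecules and spliced out by the rest.
    """
    rng = np.random.default_rng(cfg.seed)
    genome, models, _ = make_transcriptome(cfg)
    if sites is None:
        sites = plant_edit_sites(
            models,
            genome,
            n_sites,
            rng,
            fraction_ctrl=fraction_ctrl,
            fraction_kd=fraction_kd,
            region=site_region,
        )
    site_list = list(sites)
    alignments: Dict[str, List[ReadAlignment]] = {"ctrl": [], "kd": []}
    reads: Dict[str, List[SimRead]] = {"ctrl": [], "kd": []}
    for cond in ("ctrl", "kd"):
        for rep in range(cfg.n_replicates):
            for model in models:
                for i in range(cfg.coverage_per_haplotype):
                    retained = [
                        bool(rng.random() < cfg.intron_retention_rate)
                        for _ in model.junctions
                    ]
                    eff = _retained_intron_model(model, retained)
                    ref_seq = transcript_sequences([eff], genome)[eff.transcript_id]
                    src = list(ref_seq)
                    edited_here: List[int] = []
                    for chrom, pos, strand, f_ctrl, f_kd in site_list:
                        if chrom != eff.chrom:
                            continue
                        off = eff.genomic_to_transcript(pos)
                        if off is None:
                            continue
                        frac = f_ctrl if cond == "ctrl" else f_kd
                        if rng.random() < frac:
                            edited = "G" if strand == "+" else "C"
                            if eff.strand == "-":
                                edited = reverse_complement(edited)
                            src[off] = edited
                            edited_here.append(pos)
                    t0 = _truncation_offset(rng, cfg, len(src))
                    cols = _apply_errors(rng, "".join(src)[t0:], cfg.per_base_accuracy)
                    rid = f"{cond}{rep}|{model.transcript_id}|{i}"
                    tx = _read_from_columns(cols, ref_seq, t0, rid, eff.transcript_id)
                    gen = genome_alignment_from_transcript(tx, eff)
                    sim = SimRead(
                        read_id=rid,
                        sequence=tx.read_sequence or "",
                        isoform_id=model.transcript_id,
                        haplotype=None,
                        tx_alignment=tx,
                        genome_alignment=gen,
                        edited_positions=tuple(sorted(edited_here)),
                    )
                    reads[cond].append(sim)
                    alignments[cond].append(gen)
    return EditingExperiment(
        genome=genome,
        models=models,
        sites=site_list,
        alignments=alignments,
        reads=reads,
    )


def write_fastq(reads: Sequence[SimRead], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
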