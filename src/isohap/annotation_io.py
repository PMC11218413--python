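"""Annotation and variant I/O with a single internal coordinate convention.

All coordinates inside this package are 0-based, half-open, on the forward
genomic strand.  Conversion to and from the 1-based conventions of GTF and
VCF happens only in the parse/write functions of this module.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeInterval",
    "TranscriptModel",
    "Variant",
    "reverse_complement",
    "parse_gtf",
    "write_gtf",
    "parse_bed12",
    "write_bed12",
    "parse_vcf",
    "write_vcf",
    "transcript_sequences",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain on the genome.

    Exons are stored in ascending genomic order regardless of strand; the
    junction chain is the list of intron gaps ``(donor_end, acceptor_start)``
    between consecutive exons (empty for single-exon transcripts).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: Tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        exs = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exs, exs[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            if a.chrom != b.chrom:
                raise ValueError("exons span multiple chromosomes")
        object.__setattr__(self, "exons", exs)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def junction_transcript_positions(self) -> Tuple[int, ...]:
        """Transcript-coordinate offsets of the splice junctions.

        Position ``p`` means the junction sits between transcript bases
        ``p-1`` and ``p`` in 5'->3' transcript orientation.
        """
        lens = [len(e) for e in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        out, acc = [], 0
        for ln in lens[:-1]:
            acc += ln
            out.append(acc)
        return tuple(out)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to its transcript offset (None if intronic)."""
        off = 0
        for e in self.exons:
            if e.start <= pos < e.end:
                plus_off = off + (pos - e.start)
                if self.strand == "+":
                    return plus_off
                return self.length - 1 - plus_off
            off += len(e)
        return None

    def contains(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV; ``pos`` is 0-based (1-based only in VCF I/O)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    phase_set: Optional[str] = None

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in ("A", "C", "G", "T"):
                raise ValueError(f"non-SNV allele {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf(path: Union[str, Path]) -> List[TranscriptModel]:
    """Parse exon features of a GTF into transcript models.

    GTF's 1-based closed intervals become 0-based half-open.  Records missing
    transcript_id/gene_id are skipped with a warning; duplicate transcript_ids
    keep the first-seen gene/strand (logged).
    """
    exons: Dict[str, List[GenomeInterval]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            if fields[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            tid, gid = attrs.get("transcript_id"), attrs.get("gene_id")
            if not tid or not gid:
                logger.warning("%s:%d: exon missing transcript_id/gene_id, skipped", path, lineno)
                continue
            chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
            if tid in meta and meta[tid] != (gid, strand):
                logger.warning("duplicate transcript_id %s: first-seen definition kept", tid)
                continue
            meta.setdefault(tid, (gid, strand))
            exons.setdefault(tid, []).append(GenomeInterval(chrom, start, end, strand))
    if not exons:
        raise ValueError(f"no exon records parsed from {path}")
    models = []
    for tid, exs in exons.items():
        gid, strand = meta[tid]
        models.append(TranscriptModel(tid, gid, strand, tuple(exs)))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{e.chrom}\tisohap\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED12

_NAME_SEP = ";"


def write_bed12(models: Iterable[TranscriptModel], path: Union[str, Path]) -> None:
    """Write models as BED12; the name field is ``transcript_id;gene_id``."""
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(len(e)) for e in m.exons)
            starts = ",".join(str(e.start - m.start) for e in m.exons)
            name = f"{m.transcript_id}{_NAME_SEP}{m.gene_id}"
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        name,
                        "0",
                        m.strand,
                        str(m.start),
                        str(m.end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def parse_bed12(path: Union[str, Path]) -> List[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            tid, _, gid = name.partition(_NAME_SEP)
            exons = tuple(
                GenomeInterval(chrom, chrom_start + st, chrom_start + st + sz, strand)
                for st, sz in zip(starts, sizes)
            )
            models.append(TranscriptModel(tid, gid or name, strand, exons))
    return models


# ---------------------------------------------------------------------------
# VCF

def parse_vcf(*paths: Union[str, Path]) -> List[Variant]:
    """Parse one or more VCFs, keeping SNVs only, deduplicated by site/alleles.

    Multi-allelic records are split; indels and other non-SNV alleles are
    dropped (count logged).  Passing several files returns their union --
    the calls of independent variant callers are combined for sensitivity.
    A per-sample PS FORMAT value, when present, is carried as the phase set.
    """
    import pysam

    seen: Dict[Tuple[str, int, str, str], Variant] = {}
    dropped = 0
    for path in paths:
        try:
            vf = pysam.VariantFile(str(path))
        except (OSError, ValueError) as exc:
            raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
        with vf:
            for rec in vf:
                ref = (rec.ref or "").upper()
                for alt in rec.alts or ():
                    alt = alt.upper()
                    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                        dropped += 1
                        continue
                    phase_set = None
                    for sample in rec.samples.values():
                        ps = sample.get("PS")
                        if ps is not None:
                            phase_set = str(ps)
                            break
                    v = Variant(rec.chrom, rec.pos - 1, ref, alt, phase_set)
                    seen.setdefault(v.key, v)
    if dropped:
        logger.info("parse_vcf: dropped %d non-SNV allele records", dropped)
    return sorted(seen.values(), key=lambda v: v.key)


def write_vcf(
    variants: Sequence[Variant],
    path: Union[str, Path],
    info_by_variant: Optional[Mapping[Tuple[str, int, str, str], str]] = None,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write a minimal VCF 4.2; ``info_by_variant`` supplies per-record INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.key):
            info = (info_by_variant or {}).get(v.key, ".")
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / transcript sequences

GenomeLike = Union[str, Path, Mapping[str, str]]


def _chrom_fetch(genome: GenomeLike):
    """Return ``fetch(chrom, start, end)`` over a dict or an indexed FASTA."""
    if isinstance(genome, Mapping):
        def fetch(chrom: str, start: int, end: int) -> str:
            if chrom not in genome:
                raise KeyError(f"chromosome {chrom!r} absent from genome")
            return genome[chrom][start:end]
        return fetch
    from pyfaidx import Fasta

    fa = Fasta(str(genome))

    def fetch(chrom: str, start: int, end: int) -> str:
        if chrom not in fa:
            raise KeyError(f"chromosome {chrom!r} absent from {genome}")
        return str(fa[chrom][start:end])

    return fetch


def transcript_sequences(
    models: Iterable[TranscriptModel], genome: GenomeLike
) -> Dict[str, str]:
    """Spliced transcript sequences, 5'->3' in transcript orientation."""
    fetch = _chrom_fetch(genome)
    out: Dict[str, str] = {}
    for m in models:
        seq = "".join(fetch(m.chrom, e.start, e.end).upper() for e in m.exons)
        if m.strand == "-":
            seq = reverse_complement(seq)
        out[m.transcript_id] = seq
    return out


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
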