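"""Read-alignment container and coordinate algebra shared by all modules.

A :class:`ReadAlignment` is an explicit operation list (match / mismatch /
insertion / deletion / intron) against either a transcript or the genome.
Keeping alignments in this form lets the fidelity, collapse, haplotype and
editing modules walk bases exactly, and lets the simulator emit ground-truth
alignments without an external aligner.  SAM interchange goes through pysam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .annotation_io import GenomeLike, TranscriptModel, _chrom_fetch, reverse_complement

__all__ = [
    "ReadAlignment",
    "SPLICED",
    "MATCH",
    "MISMATCH",
    "INSERTION",
    "DELETION",
    "INTRON",
    "merge_ops",
    "flipped",
    "genome_alignment_from_transcript",
    "project_to_transcript",
    "alignments_from_sam",
    "write_sam",
]

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"
INTRON = "intron"

READ_CONSUMING = frozenset({MATCH, MISMATCH, INSERTION})
TARGET_CONSUMING = frozenset({MATCH, MISMATCH, DELETION, INTRON})

#: Sentinel returned by :meth:`ReadAlignment.base_at` when the queried
#: position falls inside an intron of the alignment (the read spliced it out).
SPLICED = "<spliced>"

Op = Tuple[str, int]


def merge_ops(ops: Iterable[Op]) -> Tuple[Op, ...]:
    """Merge adjacent operations of the same kind; drop zero-length ops."""
    out: List[Op] = []
    for kind, length in ops:
        if length == 0:
            continue
        if length < 0:
            raise ValueError("negative op length")
        if out and out[-1][0] == kind:
            out[-1] = (kind, out[-1][1] + length)
        else:
            out.append((kind, length))
    return tuple(out)


@dataclass(frozen=True)
class ReadAlignment:
    """One read's alignment to a transcript or a genomic chromosome.

    ``target_start`` is 0-based on the target; for genome alignments the
    operation list is in ascending genomic order and ``read_sequence`` (the
    aligned portion only, clips excluded) is in reference orientation, with
    ``strand`` recording the read's orientation.
    """

    read_id: str
    target_id: str
    target_kind: str  # "transcript" | "genome"
    ops: Tuple[Op, ...]
    target_start: int = 0
    mapping_quality: int = 60
    read_sequence: Optional[str] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.target_kind not in ("transcript", "genome"):
            raise ValueError(f"bad target_kind {self.target_kind!r}")
        object.__setattr__(self, "ops", merge_ops(self.ops))
        for kind, length in self.ops:
            if kind == INTRON and self.target_kind != "genome":
                raise ValueError("intron ops are only valid on genome alignments")
            if kind not in READ_CONSUMING | TARGET_CONSUMING:
                raise ValueError(f"unknown op kind {kind!r}")
        if self.read_sequence is not None:
            need = sum(l for k, l in self.ops if k in READ_CONSUMING)
            if len(self.read_sequence) != need:
                raise ValueError(
                    f"read_sequence length {len(self.read_sequence)} != "
                    f"read-consuming op total {need}"
                )

    # -- totals -----------------------------------------------------------
    @property
    def aligned_read_bases(self) -> int:
        """Read bases inside the alignment (soft clips are never stored)."""
        return sum(l for k, l in self.ops if k in READ_CONSUMING)

    @property
    def matched_bases(self) -> int:
        return sum(l for k, l in self.ops if k == MATCH)

    @property
    def target_end(self) -> int:
        return self.target_start + sum(l for k, l in self.ops if k in TARGET_CONSUMING)

    # -- queries ----------------------------------------------------------
    def base_at(self, pos: int) -> Optional[str]:
        """Read base aligned to target position ``pos``.

        Returns the base character, ``None`` when the position is outside the
        alignment span or deleted in the read, or :data:`SPLICED` when an
        intron of this alignment spans the position.
        """
        if pos < self.target_start or pos >= self.target_end:
            return None
        tpos, rpos = self.target_start, 0
        for kind, length in self.ops:
            if kind in (MATCH, MISMATCH):
                if tpos <= pos < tpos + length:
                    if self.read_sequence is None:
                        raise ValueError("base_at requires read_sequence")
                    return self.read_sequence[rpos + (pos - tpos)]
                tpos += length
                rpos += length
            elif kind == INSERTION:
                rpos += length
            elif kind == DELETION:
                if tpos <= pos < tpos + length:
                    return None
                tpos += length
            elif kind == INTRON:
                if tpos <= pos < tpos + length:
                    return SPLICED
                tpos += length
        return None

    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        """Intron intervals (donor_end, acceptor_start) of a genome alignment."""
        out = []
        tpos = self.target_start
        for kind, length in self.ops:
            if kind == INTRON:
                out.append((tpos, tpos + length))
            if kind in TARGET_CONSUMING:
                tpos += length
        return tuple(out)


def flipped(aln: ReadAlignment, target_length: int) -> ReadAlignment:
    """The same alignment expressed against the reverse-complemented target."""
    seq = None
    if aln.read_sequence is not None:
        seq = reverse_complement(aln.read_sequence)
    return replace(
        aln,
        ops=tuple(reversed(aln.ops)),
        target_start=target_length - aln.target_end,
        read_sequence=seq,
        strand="-" if aln.strand == "+" else "+",
    )


# ---------------------------------------------------------------------------
# transcript <-> genome projection


def genome_alignment_from_transcript(
    aln: ReadAlignment, model: TranscriptModel
) -> ReadAlignment:
    """Re-express a transcript-space alignment in genomic coordinates.

    Introns of ``model`` are spliced into the op list; for minus-strand
    transcripts the alignment is first flipped to the forward genomic strand.
    """
    if aln.target_kind != "transcript":
        raise ValueError("expected a transcript-space alignment")
    if model.strand == "-":
        aln = flipped(aln, model.length)
    # Transcript-plus coordinates ascend with the genome.
    boundaries: List[int] = []  # transcript offsets where an intron is inserted
    intron_lens: List[int] = []
    acc = 0
    for a, b in zip(model.exons, model.exons[1:]):
        acc += len(a)
        boundaries.append(acc)
        intron_lens.append(b.start - a.end)
    ops: List[Op] = []
    tpos = aln.target_start  # transcript-plus position
    next_j = 0
    while next_j < len(boundaries) and boundaries[next_j] <= tpos:
        next_j += 1
    for kind, length in aln.ops:
        if kind == INSERTION:
            ops.append((kind, length))
            continue
        remaining = length
        while remaining > 0:
            if next_j < len(boundaries) and tpos == boundaries[next_j]:
                ops.append((INTRON, intron_lens[next_j]))
                next_j += 1
                continue
            limit = boundaries[next_j] if next_j < len(boundaries) else tpos + remaining
            take = min(remaining, limit - tpos)
            ops.append((kind, take))
            tpos += take
            remaining -= take
    g_start = model.start + aln.target_start
    for j, b in enumerate(boundaries):
        if aln.target_start >= b:
            g_start += intron_lens[j]
    return ReadAlignment(
        read_id=aln.read_id,
        target_id=model.chrom,
        target_kind="genome",
        ops=tuple(ops),
        target_start=g_start,
        mapping_quality=aln.mapping_quality,
        read_sequence=aln.read_sequence,
        strand=model.strand,
    )


def project_to_transcript(
    aln: ReadAlignment, model: TranscriptModel
) -> Optional[ReadAlignment]:
    """Project a genomic alignment onto a transcript model's coordinates.

    Read bases over the model's exons keep their op kind; read bases falling
    in the model's introns become insertions; model-exon bases skipped by the
    read (deletions or read introns) become deletions.  Read bases aligned
    outside the model's genomic span are clipped.  Returns None when no read
    base overlaps the model's exons.
    """
    if aln.target_kind != "genome":
        raise ValueError("expected a genome-space alignment")
    exons = model.exons

    def tx_offset(gpos: int) -> Optional[int]:
        off = 0
        for e in exons:
            if gpos < e.start:
                return None
            if gpos < e.end:
                return off + (gpos - e.start)
            off += len(e)
        return None

    def exonic_segments(g0: int, g1: int):
        """Split [g0, g1) into (is_exonic, seg_len) pieces in order."""
        segs = []
        pos = g0
        for e in exons:
            if pos >= g1:
                break
            if pos < e.start:
                cut = min(g1, e.start)
                segs.append((False, cut - pos))
                pos = cut
            if pos >= g1:
                break
            if pos < e.end:
                cut = min(g1, e.end)
                segs.append((True, cut - pos))
                pos = cut
        if pos < g1:
            segs.append((False, g1 - pos))
        return segs

    ops: List[Op] = []
    read_chunks: List[str] = []
    tx_start: Optional[int] = None
    gpos, rpos = aln.target_start, 0
    seq = aln.read_sequence
    for kind, length in aln.ops:
        if kind == INSERTION:
            inside = model.start < gpos < model.end
            if inside and tx_start is not None or inside and tx_offset(gpos) is not None:
                ops.append((INSERTION, length))
                if seq is not None:
                    read_chunks.append(seq[rpos : rpos + length])
            rpos += length
            continue
        for is_exonic, seg in exonic_segments(gpos, gpos + length):
            if kind in (MATCH, MISMATCH):
                if is_exonic:
                    if tx_start is None:
                        tx_start = tx_offset(gpos)
                    ops.append((kind, seg))
                elif model.start <= gpos and gpos + seg <= model.end:
                    ops.append((INSERTION, seg))
                if seq is not None and (is_exonic or (model.start <= gpos and gpos + seg <= model.end)):
                    read_chunks.append(seq[rpos : rpos + seg])
                gpos += seg
                rpos += seg
            elif kind in (DELETION, INTRON):
                if is_exonic:
                    if tx_start is None:
                        tx_start = tx_offset(gpos)
                    ops.append((DELETION, seg))
                gpos += seg
    # trim leading/trailing non-read-consuming ops
    merged = list(merge_ops(ops))
    while merged and merged[0][0] == DELETION:
        tx_start = (tx_start or 0) + merged[0][1]
        merged.pop(0)
    while merged and merged[-1][0] == DELETION:
        merged.pop()
    if not merged or tx_start is None:
        return None
    out = ReadAlignment(
        read_id=aln.read_id,
        target_id=model.transcript_id,
        target_kind="transcript",
        ops=tuple(merged),
        target_start=tx_start,
        mapping_quality=aln.mapping_quality,
        read_sequence="".join(read_chunks) if seq is not None else None,
    )
    if model.strand == "-":
        out = flipped(out, model.length)
    return out


# ---------------------------------------------------------------------------
# SAM interchange

_CIGAR_TO_OP = {0: MATCH, 1: INSERTION, 2: DELETION, 3: INTRON, 7: MATCH, 8: MISMATCH}


def alignments_from_sam(
    path: Union[str, "Path"],
    reference: Optional[GenomeLike] = None,
    target_kind: str = "genome",
) -> List[ReadAlignment]:
    """Load SAM/BAM records as :class:`ReadAlignment` objects.

    CIGAR ``M`` runs are split into match/mismatch by comparison against
    ``reference`` when given (otherwise kept as matches); ``=``/``X`` are
    taken as is.  Secondary/supplementary records are kept (multi-mapping is
    meaningful for transcriptome assignment); unmapped records are skipped.
    """
    import pysam

    fetch = _chrom_fetch(reference) if reference is not None else None
    out: List[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            seq = rec.query_alignment_sequence
            ops: List[Op] = []
            gpos, rpos = rec.reference_start, 0
            for code, length in rec.cigartuples:
                if code in (4, 5):  # clips: excluded from the op list
                    continue
                kind = _CIGAR_TO_OP.get(code)
                if kind is None:
                    continue
                if kind == MATCH and fetch is not None and seq is not None:
                    ref = fetch(rec.reference_name, gpos, gpos + length).upper()
                    qry = seq[rpos : rpos + length].upper()
                    run_kind, run_len = None, 0
                    for rb, qb in zip(ref, qry):
                        k = MATCH if rb == qb else MISMATCH
                        if k == run_kind:
                            run_len += 1
                        else:
                            if run_kind:
                                ops.append((run_kind, run_len))
                            run_kind, run_len = k, 1
                    if run_kind:
                        ops.append((run_kind, run_len))
                    gpos += length
                    rpos += length
                    continue
                ops.append((kind, length))
                if kind in READ_CONSUMING:
                    rpos += length
                if kind in TARGET_CONSUMING:
                    gpos += length
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    target_id=rec.reference_name,
                    target_kind=target_kind,
                    ops=tuple(ops),
                    target_start=rec.reference_start,
                    mapping_quality=rec.mapping_quality,
                    read_sequence=seq.upper() if seq is not None else None,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


_OP_TO_CIGAR = {MATCH: 7, MISMATCH: 8, INSERTION: 1, DELETION: 2, INTRON: 3}


def write_sam(
    alignments: Sequence[ReadAlignment],
    target_lengths: Mapping[str, int],
    path: Union[str, "Path"],
) -> None:
    """Write alignments as plain-text SAM with ``=``/``X`` CIGAR ops."""
    import pysam

    names = list(target_lengths)
    header = pysam.AlignmentHeader.from_references(
        names, [target_lengths[n] for n in names]
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            rec.reference_name = aln.target_id
            rec.reference_start = aln.target_start
            rec.mapping_quality = aln.mapping_quality
            rec.flag = 16 if aln.strand == "-" else 0
            rec.cigartuples = [(_OP_TO_CIGAR[k], l) for k, l in aln.ops]
            if aln.read_sequence is not None:
                rec.query_sequence = aln.read_sequence
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(aln.read_sequence)
                )
            fh.write(rec)


# ---------------------------------------------------------------------------
# sequence-level realignment (used for read -> transcript assignment)

_EDLIB_CIGAR_RE = None


def align_to_transcript(
    read_seq: str,
    transcript_seq: str,
    read_id: str = "read",
    transcript_id: str = "transcript",
    try_reverse: bool = True,
    mapping_quality: int = 60,
) -> ReadAlignment:
    """Align a read to a transcript sequence (infix, affine-free edit model).

    Uses edlib in infix (HW) mode so a truncated read may align anywhere
    within the transcript without end penalties.  When ``try_reverse`` is
    set, the reverse complement is also tried and the orientation with the
    smaller edit distance wins (cDNA reads are unstranded).
    """
    import re

    import edlib

    global _EDLIB_CIGAR_RE
    if _EDLIB_CIGAR_RE is None:
        _EDLIB_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

    def run(seq: str):
        return edlib.align(seq, transcript_seq, mode="HW", task="path")

    fwd = run(read_seq)
    best, seq_used = fwd, read_seq
    if try_reverse:
        rev_seq = reverse_complement(read_seq)
        rev = run(rev_seq)
        if rev["editDistance"] < fwd["editDistance"]:
            best, seq_used = rev, rev_seq
    start = best["locations"][0][0]
    kind_map = {"=": MATCH, "X": MISMATCH, "I": INSERTION, "D": DELETION, "M": MATCH}
    ops = [
        (kind_map[sym], int(n)) for n, sym in _EDLIB_CIGAR_RE.findall(best["cigar"])
    ]
    return ReadAlignment(
        read_id=read_id,
        target_id=transcript_id,
        target_kind="transcript",
        ops=tuple(ops),
        target_start=start,
        mapping_quality=mapping_quality,
        read_sequence=seq_used,
    )
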