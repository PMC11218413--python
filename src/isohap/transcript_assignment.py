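"""Annotation-reliant assignment of long reads to annotated transcripts.

Reads are first aligned (ungapped) to annotated transcript sequences; the
top-scoring candidates are then re-examined with two fidelity rules before a
read may support a transcript:

* the *stringent* rule: at least 80% of the read's aligned bases must match
  the transcript, and the alignment must reach within 25 bp of both the
  first and the last exon of the transcript;
* the *splice-check* rule: at every splice junction of the transcript, at
  least 4 of the 6 flanking bases (3 per side) must be matched and no indel
  larger than 3 bp may touch the junction window.

Transcripts keeping at least ``min_support`` passing reads enter the final
isoform set; the remaining reads are handed to novel-isoform collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .alignment import (
    DELETION,
    INSERTION,
    INTRON,
    MATCH,
    MISMATCH,
    ReadAlignment,
)
from .annotation_io import TranscriptModel

__all__ = [
    "FidelityMetrics",
    "compute_fidelity",
    "passes_stringent",
    "passes_check_splice",
    "assign_read",
    "assign_all",
    "supported_annotated_isoforms",
    "write_read_map",
    "read_read_map",
]

#: Flank half-window around a junction (bases on each side that are scored).
JUNCTION_FLANK = 3


@dataclass(frozen=True)
class FidelityMetrics:
    """Per-read, per-transcript alignment fidelity summary.

    ``per_junction_flank_matches`` holds, for each junction of the transcript
    in 5'->3' order, the number of matched bases among the 6 bases flanking
    the junction, or ``None`` when the alignment does not cover the full
    window (an uncovered junction, distinct from 0 matches).
    """

    match_fraction: float
    matched_bases: int
    covers_first_exon_25bp: bool
    covers_last_exon_25bp: bool
    per_junction_flank_matches: Tuple[Optional[int], ...]
    per_junction_max_indel: Tuple[int, ...]


def compute_fidelity(
    aln: ReadAlignment, model: TranscriptModel, end_window: int = 25
) -> FidelityMetrics:
    """Score a transcript-space alignment against its transcript model.

    The match fraction's denominator is the read's aligned bases (matches,
    mismatches and insertions; clips are never part of the op list), so
    inserted bases count against the read.
    """
    if aln.target_kind != "transcript":
        raise ValueError("fidelity is computed on transcript-space alignments")
    junction_pos = model.junction_transcript_positions()
    aligned = aln.aligned_read_bases
    matched = aln.matched_bases
    fraction = matched / aligned if aligned else 0.0

    length = model.length
    covers_first = aln.target_start <= end_window
    covers_last = (length - aln.target_end) <= end_window

    flank: List[Optional[int]] = []
    max_indel: List[int] = []
    for p in junction_pos:
        lo, hi = p - JUNCTION_FLANK, p + JUNCTION_FLANK  # window [lo, hi)
        if lo < aln.target_start or hi > aln.target_end:
            flank.append(None)
            max_indel.append(0)
            continue
        matches = 0
        biggest = 0
        tpos = aln.target_start
        for kind, oplen in aln.ops:
            if kind == MATCH:
                matches += max(0, min(tpos + oplen, hi) - max(tpos, lo))
                tpos += oplen
            elif kind == MISMATCH:
                tpos += oplen
            elif kind == DELETION:
                if tpos < hi and tpos + oplen > lo:
                    biggest = max(biggest, oplen)
                tpos += oplen
            elif kind == INSERTION:
                # the insertion sits between target bases tpos-1 and tpos
                if lo <= tpos <= hi:
                    biggest = max(biggest, oplen)
            elif kind == INTRON:  # pragma: no cover - excluded by target_kind
                tpos += oplen
        flank.append(matches)
        max_indel.append(biggest)
    return FidelityMetrics(
        match_fraction=fraction,
        matched_bases=matched,
        covers_first_exon_25bp=covers_first,
        covers_last_exon_25bp=covers_last,
        per_junction_flank_matches=tuple(flank),
        per_junction_max_indel=tuple(max_indel),
    )


def passes_stringent(m: FidelityMetrics, min_match: float = 0.8) -> bool:
    """80%-of-bases-match rule plus coverage of both transcript ends."""
    return (
        m.match_fraction >= min_match
        and m.covers_first_exon_25bp
        and m.covers_last_exon_25bp
    )


def passes_check_splice(
    m: FidelityMetrics, min_flank: int = 4, max_indel: int = 3
) -> bool:
    """Every junction needs >=4 of 6 flanking matches and no indel >3 bp.

    A junction the alignment does not cover fails the read outright: a read
    must provide evidence across every junction of the transcript it
    supports.
    """
    for matches, indel in zip(m.per_junction_flank_matches, m.per_junction_max_indel):
        if matches is None or matches < min_flank or indel > max_indel:
            return False
    return True


def assign_read(
    read_id: str,
    candidates: Sequence[ReadAlignment],
    models: Mapping[str, TranscriptModel],
    min_match: float = 0.8,
    end_window: int = 25,
    min_flank: int = 4,
    max_indel: int = 3,
    stringent: bool = True,
    check_splice: bool = True,
) -> Optional[str]:
    """Assign one read to the best passing transcript among its candidates.

    Only candidates tied at the maximum mapping quality are examined.  Among
    those passing the enabled fidelity rules the winner has the highest match
    fraction; ties break on larger matched-base count, then lexicographically
    smallest transcript id.  Returns None (unassigned) when nothing passes.
    """
    cands = [c for c in candidates if c.read_id == read_id]
    if not cands:
        return None
    top_q = max(c.mapping_quality for c in cands)
    best: Optional[Tuple[float, int, str]] = None
    for aln in cands:
        if aln.mapping_quality != top_q:
            continue
        model = models.get(aln.target_id)
        if model is None:
            continue
        m = compute_fidelity(aln, model, end_window=end_window)
        if stringent and not passes_stringent(m, min_match=min_match):
            continue
        if check_splice and not passes_check_splice(
            m, min_flank=min_flank, max_indel=max_indel
        ):
            continue
        key = (m.match_fraction, m.matched_bases, aln.target_id)
        if best is None or (key[0], key[1], _neg_lex(key[2])) > (
            best[0],
            best[1],
            _neg_lex(best[2]),
        ):
            best = key
    return best[2] if best else None


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smallest id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def assign_all(
    alignments: Iterable[ReadAlignment],
    models: Mapping[str, TranscriptModel],
    **kwargs,
) -> Dict[str, Optional[str]]:
    """Run :func:`assign_read` for every read present in ``alignments``."""
    by_read: Dict[str, List[ReadAlignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    return {
        rid: assign_read(rid, cands, models, **kwargs)
        for rid, cands in by_read.items()
    }


def supported_annotated_isoforms(
    assignments: Mapping[str, Optional[str]], min_support: int = 3
) -> Tuple[Dict[str, Set[str]], Set[str]]:
    """Keep transcripts with >= ``min_support`` reads; pool the rest.

    Returns (kept transcript -> supporting read ids, unassigned read ids).
    Reads of dropped transcripts return to the unassigned pool, so every
    input read lands in exactly one of the two outputs.
    """
    support: Dict[str, Set[str]] = {}
    unassigned: Set[str] = set()
    for rid, tid in assignments.items():
        if tid is None:
            unassigned.add(rid)
        else:
            support.setdefault(tid, set()).add(rid)
    kept: Dict[str, Set[str]] = {}
    for tid, reads in support.items():
        if len(reads) >= min_support:
            kept[tid] = reads
        else:
            unassigned |= reads
    return kept, unassigned


def write_read_map(
    read_map: Mapping[str, Iterable[str]], path: Union[str, Path]
) -> None:
    """TSV of ``isoform_id<TAB>comma-separated read ids``."""
    with open(path, "w") as fh:
        for iso in sorted(read_map):
            reads = ",".join(sorted(read_map[iso]))
            fh.write(f"{iso}\t{reads}\n")


def read_read_map(path: Union[str, Path]) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            iso, _, reads = line.rstrip("\n").partition("\t")
            out[iso] = set(reads.split(",")) if reads else set()
    return out
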