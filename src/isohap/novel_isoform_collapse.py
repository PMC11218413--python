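"""Novel isoform detection from reads left unassigned to annotation.

The collapse pipeline mirrors the annotation-free branch of long-read
isoform callers: splice junctions of each read's genomic alignment are
corrected against an evidence set (annotation and/or short-read junctions),
reads are grouped by their exact junction chain, transcription start/end
sites are called per group with a fuzzy window, and first-pass isoforms are
confirmed by realigning the reads to the isoform sequences under the same
splice-fidelity rules used for annotated transcripts.
"""

from __future__ import annotations

import hashlib
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .alignment import ReadAlignment, align_to_transcript
from .annotation_io import (
    GenomeInterval,
    GenomeLike,
    TranscriptModel,
    transcript_sequences,
)
from .transcript_assignment import assign_all

__all__ = [
    "JunctionEvidence",
    "CorrectedRead",
    "FirstPassIsoform",
    "correct_junctions",
    "group_by_junction_chain",
    "call_ends",
    "finalize_isoforms",
    "collapse_novel",
]


@dataclass
class JunctionEvidence:
    """Known splice boundaries (donor ends, acceptor starts) per chromosome."""

    donors: Dict[str, List[int]] = field(default_factory=dict)
    acceptors: Dict[str, List[int]] = field(default_factory=dict)
    weights: Dict[Tuple[str, int, int], float] = field(default_factory=dict)

    @classmethod
    def from_models(cls, models: Iterable[TranscriptModel]) -> "JunctionEvidence":
        ev = cls()
        for m in models:
            for d, a in m.junctions:
                ev.add(m.chrom, d, a)
        ev.finalize()
        return ev

    @classmethod
    def from_junction_bed(cls, path) -> "JunctionEvidence":
        """Short-read junction BED: chrom, intron start, intron end[, name, score, strand]."""
        ev = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                weight = float(f[4]) if len(f) > 4 else 1.0
                ev.add(f[0], int(f[1]), int(f[2]), weight)
        ev.finalize()
        return ev

    def add(self, chrom: str, donor_end: int, acceptor_start: int, weight: float = 1.0) -> None:
        if not donor_end < acceptor_start:
            raise ValueError("junction donor must precede acceptor")
        self.donors.setdefault(chrom, []).append(donor_end)
        self.acceptors.setdefault(chrom, []).append(acceptor_start)
        key = (chrom, donor_end, acceptor_start)
        self.weights[key] = self.weights.get(key, 0.0) + weight

    def update(self, other: "JunctionEvidence") -> "JunctionEvidence":
        for (chrom, d, a), w in other.weights.items():
            self.add(chrom, d, a, w)
        self.finalize()
        return self

    def finalize(self) -> None:
        for d in (self.donors, self.acceptors):
            for chrom in d:
                d[chrom] = sorted(set(d[chrom]))


def _snap(pos: int, sites: Sequence[int], window: int) -> Optional[int]:
    """Nearest evidence boundary within ``window``; ties pick the leftmost."""
    if not sites:
        return None
    i = bisect_left(sites, pos)
    best: Optional[int] = None
    for j in (i - 1, i):
        if 0 <= j < len(sites):
            cand = sites[j]
            dist = abs(cand - pos)
            if dist > window:
                continue
            if best is None or dist < abs(best - pos) or (
                dist == abs(best - pos) and cand < best
            ):
                best = cand
    return best


@dataclass(frozen=True)
class CorrectedRead:
    """A read's corrected genomic structure used for grouping and end calling."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    chain: Tuple[Tuple[int, int], ...]


def correct_junctions(
    aln: ReadAlignment, evidence: JunctionEvidence, window: int = 10
) -> Optional[CorrectedRead]:
    """Snap each junction boundary to the nearest evidence boundary.

    Boundaries already in the evidence set are kept; others snap to the
    nearest evidence boundary within ``window`` bp (ties toward the smaller
    shift, then the leftmost coordinate).  A junction with no evidence within
    the window rejects the read for isoform building (returns None).
    """
    if aln.target_kind != "genome":
        raise ValueError("junction correction needs a genomic alignment")
    chrom = aln.target_id
    chain: List[Tuple[int, int]] = []
    for donor, acceptor in aln.junctions():
        d = _snap(donor, evidence.donors.get(chrom, ()), window)
        a = _snap(acceptor, evidence.acceptors.get(chrom, ()), window)
        if d is None or a is None or not d < a:
            return None
        chain.append((d, a))
    return CorrectedRead(
        read_id=aln.read_id,
        chrom=chrom,
        strand=aln.strand,
        start=aln.target_start,
        end=aln.target_end,
        chain=tuple(chain),
    )


def group_by_junction_chain(
    reads: Iterable[CorrectedRead], single_exon_overlap: float = 0.5
) -> Dict[Tuple[str, Tuple[Tuple[int, int], ...], int], List[CorrectedRead]]:
    """Group reads by exact junction-chain equality.

    Spliced reads group on ``(chrom, chain)``.  Single-exon reads form one
    group per locus cluster, built by single-linkage over >=50% reciprocal
    overlap; the trailing integer in the key separates those clusters (0 for
    spliced groups).
    """
    spliced: Dict[Tuple[str, Tuple[Tuple[int, int], ...]], List[CorrectedRead]] = {}
    mono: Dict[str, List[CorrectedRead]] = {}
    for r in reads:
        if r.chain:
            spliced.setdefault((r.chrom, r.chain), []).append(r)
        else:
            mono.setdefault(r.chrom, []).append(r)
    out: Dict[Tuple[str, Tuple[Tuple[int, int], ...], int], List[CorrectedRead]] = {}
    for (chrom, chain), members in spliced.items():
        out[(chrom, chain, 0)] = members
    for chrom, members in mono.items():
        members = sorted(members, key=lambda r: (r.start, r.end))
        clusters: List[List[CorrectedRead]] = []
        for r in members:
            placed = False
            for cl in clusters:
                if any(_reciprocal_overlap(r, m) >= single_exon_overlap for m in cl):
                    cl.append(r)
                    placed = True
                    break
            if not placed:
                clusters.append([r])
        for k, cl in enumerate(clusters):
            out[(chrom, (), k)] = cl
    return out


def _reciprocal_overlap(a: CorrectedRead, b: CorrectedRead) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


@dataclass(frozen=True)
class FirstPassIsoform:
    """A candidate isoform: junction chain plus called start/end positions.

    ``tss``/``tes`` are genomic left/right coordinates; 5' vs 3' identity
    follows the strand.
    """

    chrom: str
    strand: str
    chain: Tuple[Tuple[int, int], ...]
    tss: int
    tes: int
    supporting_reads: frozenset

    def model(self, transcript_id: str, gene_id: str) -> TranscriptModel:
        starts = [self.tss] + [a for _, a in self.chain]
        ends = [d for d, _ in self.chain] + [self.tes]
        exons = tuple(
            GenomeInterval(self.chrom, s, e, self.strand)
            for s, e in zip(starts, ends)
        )
        return TranscriptModel(transcript_id, gene_id, self.strand, exons)


def _cluster_positions(
    positions: Sequence[int], window: int
) -> List[List[int]]:
    """Single-linkage clustering of sorted positions at ``window`` bp."""
    clusters: List[List[int]] = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def _representative(cluster: Sequence[int], outward: str) -> int:
    """Most frequent position; ties resolve outward (min for left, max for right)."""
    counts: Dict[int, int] = {}
    for p in cluster:
        counts[p] = counts.get(p, 0) + 1
    best = max(counts.values())
    cands = [p for p, c in counts.items() if c == best]
    return min(cands) if outward == "left" else max(cands)


def call_ends(
    group: Sequence[CorrectedRead],
    max_per_chain: int = 2,
    end_window: int = 100,
) -> List[FirstPassIsoform]:
    """Call up to ``max_per_chain`` TSS and TES clusters for one chain group.

    Read 5' and 3' ends are clustered by single linkage at ``end_window`` bp;
    each cluster is represented by its most frequent position.  The most
    supported clusters are retained and isoforms are emitted for every
    (TSS, TES) pairing supported by at least one read consistent with both.
    """
    if not group:
        raise ValueError("empty group")
    chrom = group[0].chrom
    chain = group[0].chain
    strand = _majority_strand(group)

    def top_clusters(positions: Sequence[int], outward: str):
        clusters = _cluster_positions(positions, end_window)
        ranked = sorted(
            clusters,
            key=lambda cl: (-len(cl), _representative(cl, outward)),
        )
        kept = ranked[:max_per_chain]
        assign = {}
        for cl in kept:
            rep = _representative(cl, outward)
            for p in set(cl):
                assign[p] = rep
        return assign

    left_assign = top_clusters([r.start for r in group], "left")
    right_assign = top_clusters([r.end for r in group], "right")
    pairs: Dict[Tuple[int, int], Set[str]] = {}
    for r in group:
        lrep = left_assign.get(r.start)
        rrep = right_assign.get(r.end)
        if lrep is None or rrep is None:
            continue
        pairs.setdefault((lrep, rrep), set()).add(r.read_id)
    out = []
    for (tss, tes), readset in sorted(pairs.items()):
        first_donor = chain[0][0] if chain else tes
        last_acceptor = chain[-1][1] if chain else tss
        if chain and not (tss < first_donor and tes > last_acceptor):
            continue
        out.append(
            FirstPassIsoform(
                chrom=chrom,
                strand=strand,
                chain=chain,
                tss=tss,
                tes=tes,
                supporting_reads=frozenset(readset),
            )
        )
    return out


def _majority_strand(group: Sequence[CorrectedRead]) -> str:
    plus = sum(1 for r in group if r.strand == "+")
    return "+" if plus * 2 >= len(group) else "-"


def _isoform_id(iso: FirstPassIsoform, locus: str) -> str:
    key = f"{iso.chrom}:{iso.chain}:{iso.tss}:{iso.tes}".encode()
    return f"{hashlib.sha1(key).hexdigest()[:8]}_{locus}"


def _locus_label(
    iso: FirstPassIsoform, annotated: Optional[Iterable[TranscriptModel]]
) -> str:
    if annotated:
        junctions = set(iso.chain)
        for m in annotated:
            if m.chrom == iso.chrom and (
                junctions & set(m.junctions)
                or (not iso.chain and m.start < iso.tes and iso.tss < m.end)
            ):
                return m.gene_id
    return f"{iso.chrom}:{iso.tss}"


def finalize_isoforms(
    first_pass: Sequence[FirstPassIsoform],
    read_sequences: Mapping[str, str],
    genome: GenomeLike,
    annotated_models: Optional[Sequence[TranscriptModel]] = None,
    min_support: int = 3,
    **fidelity_kwargs,
) -> Tuple[Dict[str, TranscriptModel], Dict[str, Set[str]]]:
    """Confirm first-pass isoforms by realignment under the fidelity rules.

    Every generating read is realigned against the sequences of the
    first-pass isoforms at its locus; reads are assigned with the same
    stringent/splice-check machinery used for annotated transcripts, and
    isoforms retaining >= ``min_support`` reads survive.
    """
    models: Dict[str, TranscriptModel] = {}
    candidates_by_read: Dict[str, Set[str]] = {}
    for iso in first_pass:
        tid = _isoform_id(iso, _locus_label(iso, annotated_models))
        models[tid] = iso.model(tid, _locus_label(iso, annotated_models))
        for rid in iso.supporting_reads:
            candidates_by_read.setdefault(rid, set()).add(tid)
    if not models:
        return {}, {}
    seqs = transcript_sequences(models.values(), genome)
    alignments: List[ReadAlignment] = []
    for rid, tids in candidates_by_read.items():
        seq = read_sequences.get(rid)
        if seq is None:
            continue
        for tid in tids:
            alignments.append(
                align_to_transcript(seq, seqs[tid], read_id=rid, transcript_id=tid)
            )
    assignments = assign_all(alignments, models, **fidelity_kwargs)
    read_map: Dict[str, Set[str]] = {}
    for rid, tid in assignments.items():
        if tid is not None:
            read_map.setdefault(tid, set()).add(rid)
    kept_models: Dict[str, TranscriptModel] = {}
    kept_map: Dict[str, Set[str]] = {}
    for tid, reads in read_map.items():
        if len(reads) >= min_support:
            kept_models[tid] = models[tid]
            kept_map[tid] = reads
    return kept_models, kept_map


def collapse_novel(
    alignments: Sequence[ReadAlignment],
    evidence: JunctionEvidence,
    genome: GenomeLike,
    read_sequences: Optional[Mapping[str, str]] = None,
    annotated_models: Optional[Sequence[TranscriptModel]] = None,
    min_support: int = 3,
    correction_window: int = 10,
    end_window: int = 100,
    max_ends_per_chain: int = 2,
    **fidelity_kwargs,
) -> Tuple[Dict[str, TranscriptModel], Dict[str, Set[str]]]:
    """Full collapse: correct, group, call ends, realign, filter support.

    ``read_sequences`` defaults to the sequences carried on the alignments.
    Returns (novel isoform models by id, isoform -> supporting read ids).
    """
    if read_sequences is None:
        read_sequences = {
            a.read_id: a.read_sequence
            for a in alignments
            if a.read_sequence is not None
        }
    corrected = []
    for aln in alignments:
        c = correct_junctions(aln, evidence, window=correction_window)
        if c is not None:
            corrected.append(c)
    groups = group_by_junction_chain(corrected)
    first_pass: List[FirstPassIsoform] = []
    for members in groups.values():
        first_pass.extend(
            call_ends(members, max_per_chain=max_ends_per_chain, end_window=end_window)
        )
    return finalize_isoforms(
        first_pass,
        read_sequences,
        genome,
        annotated_models=annotated_models,
        min_support=min_support,
        **fidelity_kwargs,
    )
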