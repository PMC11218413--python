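"""Long-read A-to-I editing analytics.

Inosine is read as guanosine by sequencing, so candidate edits surface as
A->G mismatches on genes of the forward strand and T->C on the reverse
strand.  Given candidate sites (from variant callers) and condition-labelled
genomic alignments from an ADAR-knockdown design, this module counts edited
and unedited reads per site, tests for differential editing after knockdown,
flags type I hyperediting (single sites with a high edited fraction) and
type II hyperediting (dense clusters of sites), tests for coordinated
editing of site pairs on single molecules, and reports sites whose editing
is mutually exclusive with splicing of the surrounding intron.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .alignment import SPLICED, ReadAlignment
from .annotation_io import TranscriptModel, Variant
from .stats import fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "EditSite",
    "EditSiteCounts",
    "HyperRegion",
    "candidate_inosines",
    "pileup_counts",
    "differential_editing",
    "classify_type1",
    "type2_regions",
    "coordination_test",
    "intron_editing",
    "write_edit_counts",
    "write_intron_table",
]

CTRL, KD = "ctrl", "kd"


@dataclass(frozen=True)
class EditSite:
    """A candidate A-to-I site with the strand of its host gene."""

    chrom: str
    pos: int
    gene_strand: str
    known: bool = False  # present in a user-supplied known-sites catalogue

    @property
    def ref_base(self) -> str:
        return "A" if self.gene_strand == "+" else "T"

    @property
    def edited_base(self) -> str:
        return "G" if self.gene_strand == "+" else "C"


@dataclass(frozen=True)
class EditSiteCounts:
    """Edited/unedited read counts per condition plus spliced-out reads."""

    site: EditSite
    edited_ctrl: int = 0
    unedited_ctrl: int = 0
    edited_kd: int = 0
    unedited_kd: int = 0
    spliced_out: int = 0

    def coverage(self, condition: str) -> int:
        if condition == CTRL:
            return self.edited_ctrl + self.unedited_ctrl
        if condition == KD:
            return self.edited_kd + self.unedited_kd
        raise ValueError(condition)

    def edited_fraction(self, condition: str) -> float:
        cov = self.coverage(condition)
        edited = self.edited_ctrl if condition == CTRL else self.edited_kd
        return edited / cov if cov else 0.0


@dataclass(frozen=True)
class HyperRegion:
    """A maximal type II hyperediting region (>=3 edits per 150 bp window)."""

    chrom: str
    start: int
    end: int
    sites: Tuple[int, ...]

    @property
    def n_edits(self) -> int:
        return len(self.sites)


def candidate_inosines(
    variants: Sequence[Variant],
    gene_models: Sequence[TranscriptModel],
    known_sites: Optional[Set[Tuple[str, int]]] = None,
) -> Tuple[List[EditSite], int]:
    """Filter variant calls to strand-consistent A-to-I candidates.

    Keeps A->G variants inside forward-strand genes and T->C inside
    reverse-strand genes (an A->G on the negative strand).  Sites in
    unannotated or strand-ambiguous regions are dropped and counted.
    ``known_sites`` (a set of (chrom, pos)) marks sites found in an external
    editing catalogue.
    """
    gene_extents: Dict[str, Dict[str, Tuple[int, int]]] = {}
    strand_of: Dict[str, str] = {}
    for m in gene_models:
        lo, hi = gene_extents.setdefault(m.chrom, {}).get(m.gene_id, (m.start, m.end))
        gene_extents[m.chrom][m.gene_id] = (min(lo, m.start), max(hi, m.end))
        strand_of[m.gene_id] = m.strand
    kept: List[EditSite] = []
    dropped = 0
    for v in variants:
        strands = {
            strand_of[g]
            for g, (lo, hi) in gene_extents.get(v.chrom, {}).items()
            if lo <= v.pos < hi
        }
        if len(strands) != 1:
            dropped += 1
            continue
        strand = strands.pop()
        expected = ("A", "G") if strand == "+" else ("T", "C")
        if (v.ref_allele, v.alt_allele) != expected:
            dropped += 1
            continue
        kept.append(
            EditSite(
                chrom=v.chrom,
                pos=v.pos,
                gene_strand=strand,
                known=bool(known_sites and (v.chrom, v.pos) in known_sites),
            )
        )
    if dropped:
        logger.info("candidate_inosines: dropped %d strand-inconsistent sites", dropped)
    return kept, dropped


def pileup_counts(
    alignments: Mapping[str, Sequence[ReadAlignment]],
    sites: Sequence[EditSite],
) -> List[EditSiteCounts]:
    """Count edited/unedited reads per site, replicates of a condition summed.

    ``alignments`` maps condition labels ("ctrl"/"kd", replicates already
    concatenated or given as one list per condition) to genomic alignments.
    Reads showing a base other than the reference or edited base, or a
    deletion, are excluded from both counts; reads whose intron spans the
    site are tallied in ``spliced_out`` (across both conditions).  Sites with
    no overlapping reads are retained with zero counts.
    """
    by_chrom: Dict[str, Dict[str, List[ReadAlignment]]] = {}
    starts: Dict[str, Dict[str, List[int]]] = {}
    for cond, alns in alignments.items():
        if cond not in (CTRL, KD):
            raise ValueError(f"condition must be 'ctrl' or 'kd', got {cond!r}")
        for aln in alns:
            by_chrom.setdefault(aln.target_id, {}).setdefault(cond, []).append(aln)
    for chrom, conds in by_chrom.items():
        for cond in conds:
            conds[cond].sort(key=lambda a: a.target_start)
            starts.setdefault(chrom, {})[cond] = [a.target_start for a in conds[cond]]
    out = []
    for site in sites:
        tallies = {CTRL: [0, 0], KD: [0, 0]}
        spliced = 0
        for cond, alns in by_chrom.get(site.chrom, {}).items():
            idx = bisect_right(starts[site.chrom][cond], site.pos)
            for aln in alns[:idx]:
                if aln.target_end <= site.pos:
                    continue
                base = aln.base_at(site.pos)
                if base == SPLICED:
                    spliced += 1
                elif base == site.edited_base:
                    tallies[cond][0] += 1
                elif base == site.ref_base:
                    tallies[cond][1] += 1
        out.append(
            EditSiteCounts(
                site=site,
                edited_ctrl=tallies[CTRL][0],
                unedited_ctrl=tallies[CTRL][1],
                edited_kd=tallies[KD][0],
                unedited_kd=tallies[KD][1],
                spliced_out=spliced,
            )
        )
    return out


def differential_editing(
    counts: Sequence[EditSiteCounts],
    min_cov: int = 10,
    min_delta: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher test of editing change after knockdown, per site.

    A site is significant when coverage >= ``min_cov`` in either condition,
    the edited-fraction change is >= ``min_delta`` in magnitude, and the raw
    p-value is < ``alpha`` (uncorrected, matching the discovery criterion the
    long-read analysis uses).  Direction is "down" when the edited fraction
    falls after knockdown.  Returns one row per input site with filter and
    significance columns; zero-coverage fractions are 0 and flagged.
    """
    rows = []
    for c in counts:
        p = fisher_exact_2x2(
            [[c.edited_kd, c.unedited_kd], [c.edited_ctrl, c.unedited_ctrl]]
        )
        f_ctrl = c.edited_fraction(CTRL)
        f_kd = c.edited_fraction(KD)
        delta = f_kd - f_ctrl
        rows.append(
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "gene_strand": c.site.gene_strand,
                "edited_ctrl": c.edited_ctrl,
                "unedited_ctrl": c.unedited_ctrl,
                "edited_kd": c.edited_kd,
                "unedited_kd": c.unedited_kd,
                "fraction_ctrl": f_ctrl,
                "fraction_kd": f_kd,
                "delta": delta,
                "p_value": p,
                "zero_coverage": c.coverage(CTRL) == 0 or c.coverage(KD) == 0,
                "passes_coverage": max(c.coverage(CTRL), c.coverage(KD)) >= min_cov,
                "direction": "down" if delta < 0 else ("up" if delta > 0 else "none"),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["significant"] = (
        df["passes_coverage"] & (df["delta"].abs() >= min_delta) & (df["p_value"] < alpha)
    )
    return df


def classify_type1(
    counts: EditSiteCounts, threshold: float = 0.40, condition: str = CTRL
) -> bool:
    """Type I hyperediting: strictly more than 40% of residues edited.

    Zero coverage returns False (flagged via the coverage accessor).
    """
    cov = counts.coverage(condition)
    if cov == 0:
        return False
    return counts.edited_fraction(condition) > threshold


def type2_regions(
    positions: Mapping[str, Sequence[int]] | Sequence[Tuple[str, int]],
    window: int = 150,
    min_sites: int = 3,
) -> List[HyperRegion]:
    """Maximal regions where every seed window holds >=3 edits per 150 bp.

    Every length-``window`` genomic window containing >= ``min_sites`` sites
    is a seed; overlapping or adjacent seed windows merge, and each merged
    region reports the sites it covers with bounds at the outermost sites.
    """
    if not isinstance(positions, Mapping):
        grouped: Dict[str, List[int]] = {}
        for chrom, pos in positions:
            grouped.setdefault(chrom, []).append(pos)
        positions = grouped
    regions: List[HyperRegion] = []
    for chrom in sorted(positions):
        pos = sorted(set(positions[chrom]))
        if len(pos) < min_sites:
            continue
        # Seed windows [s, s+window) containing a run of min_sites sites
        # exist iff pos[i + min_sites - 1] - pos[i] < window; the union of
        # those windows is then [last - window + 1, first + window).
        spans: List[Tuple[int, int]] = []
        for i in range(len(pos) - min_sites + 1):
            j = i + min_sites - 1
            if pos[j] - pos[i] < window:
                spans.append((pos[j] - window + 1, pos[i] + window))
        if not spans:
            continue
        merged: List[List[int]] = []
        for lo, hi in sorted(spans):
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            members = pos[bisect_left(pos, lo) : bisect_right(pos, hi - 1)]
            regions.append(
                HyperRegion(
                    chrom=chrom,
                    start=members[0],
                    end=members[-1],
                    sites=tuple(members),
                )
            )
    return regions


def coordination_test(
    sites: Sequence[EditSite],
    alignments: Sequence[ReadAlignment],
    min_dist: int = 50,
    k_nearest: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test pairs of sites for coordinated editing on single molecules.

    Each site is paired with up to ``k_nearest`` nearest candidate sites at
    least ``min_dist`` bp away on the same chromosome (union of directed
    neighbourhoods; each unordered pair tested once).  Over reads covering
    both positions with an edited or unedited call, a 2x2 table of edit
    status at site 1 x site 2 is tested two-sided; rows with ``p_value`` <
    ``alpha`` carry ``coordinated=True``.  Pairs with no doubly-covered read
    are skipped (counted in the ``skipped_pairs`` attribute of the result).
    """
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    pairs: Set[Tuple[int, int]] = set()
    for i, s in enumerate(ordered):
        dists = []
        for j, t in enumerate(ordered):
            if j == i or t.chrom != s.chrom:
                continue
            d = abs(t.pos - s.pos)
            if d >= min_dist:
                dists.append((d, t.pos, j))
        dists.sort()
        for _, _, j in dists[:k_nearest]:
            pairs.add((min(i, j), max(i, j)))

    # per-read edit status at each site index
    status: Dict[int, Dict[str, bool]] = {i: {} for i in range(len(ordered))}
    by_chrom: Dict[str, List[int]] = {}
    for i, s in enumerate(ordered):
        by_chrom.setdefault(s.chrom, []).append(i)
    for aln in alignments:
        for i in by_chrom.get(aln.target_id, ()):
            s = ordered[i]
            if not (aln.target_start <= s.pos < aln.target_end):
                continue
            base = aln.base_at(s.pos)
            if base == s.edited_base:
                status[i][aln.read_id] = True
            elif base == s.ref_base:
                status[i][aln.read_id] = False

    rows = []
    skipped = 0
    for i, j in sorted(pairs):
        shared = status[i].keys() & status[j].keys()
        if not shared:
            skipped += 1
            continue
        a = sum(1 for r in shared if status[i][r] and status[j][r])
        b = sum(1 for r in shared if status[i][r] and not status[j][r])
        c = sum(1 for r in shared if not status[i][r] and status[j][r])
        d = len(shared) - a - b - c
        p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "chrom": ordered[i].chrom,
                "pos1": ordered[i].pos,
                "pos2": ordered[j].pos,
                "both_edited": a,
                "only_site1": b,
                "only_site2": c,
                "neither": d,
                "p_value": p,
                "coordinated": p < alpha,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["skipped_pairs"] = skipped
    return df


def intron_editing(
    counts: Sequence[EditSiteCounts],
    min_edited: int = 10,
    min_spliced: int = 10,
    type1_threshold: float = 0.40,
    require_type1: bool = True,
) -> List[EditSiteCounts]:
    """Sites edited in some molecules and spliced out in others.

    Keeps sites that are type I hyperedited in the control condition (when
    ``require_type1``), have >= ``min_edited`` edited reads and >=
    ``min_spliced`` reads where the position falls inside the read's intron.
    """
    out = []
    for c in counts:
        if require_type1 and not classify_type1(c, threshold=type1_threshold):
            continue
        if c.edited_ctrl >= min_edited and c.spliced_out >= min_spliced:
            out.append(c)
    return out


def write_edit_counts(
    df: pd.DataFrame, path: Union[str, Path], significant_only: bool = True
) -> None:
    """TSV of differential-editing results: chrom, pos, per-condition counts, p."""
    sub = df[df["significant"]] if significant_only and "significant" in df else df
    cols = [
        "chrom",
        "pos",
        "unedited_ctrl",
        "edited_ctrl",
        "unedited_kd",
        "edited_kd",
        "p_value",
    ]
    view = sub[cols].copy()
    view["pos"] = view["pos"] + 1  # 1-based in reports
    view.to_csv(path, sep="\t", index=False)


def write_intron_table(
    counts: Sequence[EditSiteCounts], path: Union[str, Path]
) -> None:
    """TSV of edit-vs-splice sites: chrom, pos, unedited, edited, spliced_out."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tunedited\tedited\tspliced_out\n")
        for c in counts:
            fh.write(
                f"{c.site.chrom}\t{c.site.pos + 1}\t{c.unedited_ctrl}\t"
                f"{c.edited_ctrl}\t{c.spliced_out}\n"
            )
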