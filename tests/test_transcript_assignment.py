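"""Fidelity metrics, the stringent/splice-check rules, and read assignment."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import flank_oracle
from isohap.alignment import (
    DELETION,
    INSERTION,
    MATCH,
    MISMATCH,
    ReadAlignment,
)
from isohap.annotation_io import GenomeInterval, TranscriptModel
from isohap.transcript_assignment import (
    assign_read,
    compute_fidelity,
    passes_check_splice,
    passes_stringent,
    supported_annotated_isoforms,
)


def two_exon_model(first=500, second=500, gap=200, tid="t1"):
    return TranscriptModel(
        tid,
        "g1",
        "+",
        (
            GenomeInterval("chr1", 0, first),
            GenomeInterval("chr1", first + gap, first + gap + second),
        ),
    )


def tx_aln(ops, start=0, tid="t1", mapq=60):
    return ReadAlignment(
        read_id="r", target_id=tid, target_kind="transcript", ops=tuple(ops),
        target_start=start, mapping_quality=mapq,
    )


def test_perfect_alignment_metrics():
    model = two_exon_model()
    m = compute_fidelity(tx_aln([(MATCH, 1000)]), model)
    assert m.match_fraction == 1.0
    assert m.covers_first_exon_25bp and m.covers_last_exon_25bp
    assert m.per_junction_flank_matches == (6,)
    assert m.per_junction_max_indel == (0,)


def test_match_fraction_arithmetic():
    model = two_exon_model()
    m = compute_fidelity(tx_aln([(MATCH, 790), (MISMATCH, 210)]), model)
    assert m.match_fraction == pytest.approx(0.79)


def test_mismatch_two_bases_downstream_of_junction():
    """One mismatch 2 bp past the junction leaves 5 of 6 flanking matches."""
    model = two_exon_model()
    m = compute_fidelity(tx_aln([(MATCH, 502), (MISMATCH, 1), (MATCH, 497)]), model)
    assert m.per_junction_flank_matches == (5,)


def test_uncovered_junction_is_sentinel_not_zero():
    model = two_exon_model()
    m = compute_fidelity(tx_aln([(MATCH, 100)], start=0), model)
    assert m.per_junction_flank_matches == (None,)
    assert not passes_check_splice(m)


@st.composite
def op_lists(draw):
    n = draw(st.integers(1, 12))
    kinds = draw(
        st.lists(
            st.sampled_from([MATCH, MISMATCH, INSERTION, DELETION]),
            min_size=n,
            max_size=n,
        )
    )
    lens = draw(st.lists(st.integers(1, 12), min_size=n, max_size=n))
    ops = [(k, l) for k, l in zip(kinds, lens)]
    # alignments must start/end with a target+read consuming op
    ops = [(MATCH, 1)] + ops + [(MATCH, 1)]
    return ops


@settings(derandomize=True, max_examples=200)
@given(
    ops=op_lists(),
    start=st.integers(0, 10),
    junctions=st.lists(st.integers(5, 180), min_size=1, max_size=4, unique=True),
)
def test_fidelity_agrees_with_base_walk_oracle(ops, start, junctions):
    """Flank/indel accounting matches an independent per-base walk (<=200 bp)."""
    junctions = sorted(junctions)
    exon_lens = [junctions[0]] + [
        b - a for a, b in zip(junctions, junctions[1:])
    ] + [200 - junctions[-1]]
    exons, pos = [], 0
    for ln in exon_lens:
        exons.append(GenomeInterval("chr1", pos, pos + ln))
        pos += ln + 50
    model = TranscriptModel("t1", "g1", "+", tuple(exons))
    aln = tx_aln(ops, start=start)
    m = compute_fidelity(aln, model)
    want_flank, want_indel = flank_oracle(aln.ops, start, junctions)
    assert list(m.per_junction_flank_matches) == want_flank
    for got, want, covered in zip(
        m.per_junction_max_indel, want_indel, want_flank
    ):
        if covered is not None:
            assert got == want


@pytest.mark.parametrize(
    "ops,start,stringent_ok",
    [
        # exactly 80% matched, ends covered -> pass (inclusive boundary)
        ([(MATCH, 800), (MISMATCH, 200)], 0, True),
        # 79% matched -> fail
        ([(MATCH, 790), (MISMATCH, 210)], 0, False),
        # perfect but missing the last exon window -> fail
        ([(MATCH, 900)], 0, False),
        # starts exactly at the 25 bp window edge -> pass
        ([(MATCH, 975)], 25, True),
        # starts one base too far in -> fail
        ([(MATCH, 974)], 26, False),
    ],
)
def test_stringent_boundaries(ops, start, stringent_ok):
    model = two_exon_model()
    m = compute_fidelity(tx_aln(ops, start=start), model)
    assert passes_stringent(m) is stringent_ok


@pytest.mark.parametrize(
    "ops,splice_ok",
    [
        ([(MATCH, 1000)], True),
        # two mismatched flank bases (4 of 6 matched) -> pass
        ([(MATCH, 497), (MISMATCH, 2), (MATCH, 501)], True),
        # three mismatched flank bases (3 of 6) -> fail
        ([(MATCH, 497), (MISMATCH, 3), (MATCH, 500)], False),
        # 3 bp insertion at the junction -> pass; 4 bp -> fail
        ([(MATCH, 500), (INSERTION, 3), (MATCH, 500)], True),
        ([(MATCH, 500), (INSERTION, 4), (MATCH, 500)], False),
    ],
)
def test_check_splice_boundaries(ops, splice_ok):
    model = two_exon_model()
    m = compute_fidelity(tx_aln(ops), model)
    assert passes_check_splice(m) is splice_ok


def test_assign_read_prefers_passing_candidate():
    good = two_exon_model(tid="tA")
    bad = two_exon_model(tid="tB")
    models = {"tA": good, "tB": bad}
    cands = [
        tx_aln([(MATCH, 1000)], tid="tA"),
        # fails check_splice: junction flank destroyed
        tx_aln([(MATCH, 496), (MISMATCH, 8), (MATCH, 496)], tid="tB"),
    ]
    assert assign_read("r", cands, models) == "tA"
    random.Random(0).shuffle(cands)
    assert assign_read("r", cands, models) == "tA"


def test_assign_read_tie_breaks_on_smallest_id():
    models = {t: two_exon_model(tid=t) for t in ("tB", "tA")}
    cands = [tx_aln([(MATCH, 1000)], tid=t) for t in ("tB", "tA")]
    assert assign_read("r", cands, models) == "tA"


def test_assign_read_only_top_mapq_examined():
    models = {t: two_exon_model(tid=t) for t in ("tA", "tB")}
    cands = [
        tx_aln([(MATCH, 790), (MISMATCH, 210)], tid="tA", mapq=60),  # fails stringent
        tx_aln([(MATCH, 1000)], tid="tB", mapq=10),  # perfect but lower mapq
    ]
    assert assign_read("r", cands, models) is None


def test_assign_read_empty_candidates():
    assert assign_read("r", [], {}) is None


def test_supported_isoforms_threshold_and_partition():
    assignments = {
        "r1": "tA", "r2": "tA", "r3": "tA",  # kept (3 reads)
        "r4": "tB", "r5": "tB",  # dropped (2 reads)
        "r6": None,
    }
    kept, unassigned = supported_annotated_isoforms(assignments, min_support=3)
    assert set(kept) == {"tA"}
    assert unassigned == {"r4", "r5", "r6"}
    # partition: every read in exactly one place
    assert set().union(*kept.values()) | unassigned == set(assignments)
    assert not set().union(*kept.values()) & unassigned


def test_supported_isoforms_empty():
    kept, unassigned = supported_annotated_isoforms({}, min_support=3)
    assert kept == {} and unassigned == set()
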