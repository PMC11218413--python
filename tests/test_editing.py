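"""A-to-I editing analytics: strand filters, pileups, tests and regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import fisher_oracle, type2_oracle
from isohap.alignment import INTRON, MATCH, ReadAlignment
from isohap.annotation_io import GenomeInterval, TranscriptModel, Variant
from isohap.inosine_editing import (
    EditSite,
    EditSiteCounts,
    candidate_inosines,
    classify_type1,
    coordination_test,
    differential_editing,
    intron_editing,
    pileup_counts,
    type2_regions,
)


def gene(tid, gene_id, strand, start=0, end=1000):
    return TranscriptModel(
        tid, gene_id, strand, (GenomeInterval("chr1", start, end, strand),)
    )


@pytest.mark.parametrize(
    "ref,alt,strand,kept",
    [
        ("A", "G", "+", True),   # A->G on a forward gene
        ("A", "G", "-", False),  # wrong strand
        ("T", "C", "-", True),   # A->G on the negative strand
        ("T", "C", "+", False),
        ("A", "C", "+", False),  # not an editing signature
    ],
)
def test_candidate_strand_rules(ref, alt, strand, kept):
    sites, dropped = candidate_inosines(
        [Variant("chr1", 100, ref, alt)], [gene("t", "g", strand)]
    )
    assert (len(sites) == 1) is kept
    assert dropped == (0 if kept else 1)


def test_candidate_ambiguous_strand_dropped():
    models = [gene("t1", "g1", "+"), gene("t2", "g2", "-")]
    sites, dropped = candidate_inosines([Variant("chr1", 100, "A", "G")], models)
    assert sites == [] and dropped == 1


def test_candidate_known_sites_flag():
    (site,), _ = candidate_inosines(
        [Variant("chr1", 100, "A", "G")], [gene("t", "g", "+")],
        known_sites={("chr1", 100)},
    )
    assert site.known


def read_with_base(read_id, base, pos=50, length=100):
    seq = "A" * pos + base + "A" * (length - pos - 1)
    return ReadAlignment(
        read_id=read_id, target_id="chr1", target_kind="genome",
        ops=((MATCH, length),), target_start=0, read_sequence=seq,
    )


def spliced_over(read_id, pos=50):
    return ReadAlignment(
        read_id=read_id, target_id="chr1", target_kind="genome",
        ops=((MATCH, 20), (INTRON, 60), (MATCH, 20)), target_start=pos - 40,
        read_sequence="A" * 40,
    )


SITE = EditSite("chr1", 50, "+")


def test_pileup_counts_edited_unedited_and_excluded():
    alns = {
        "ctrl": [read_with_base(f"g{i}", "G") for i in range(10)]
        + [read_with_base(f"a{i}", "A") for i in range(5)]
        + [read_with_base(f"n{i}", "T") for i in range(3)],
        "kd": [],
    }
    (c,) = pileup_counts(alns, [SITE])
    assert c.edited_ctrl == 10 and c.unedited_ctrl == 5
    assert c.edited_kd == 0 and c.unedited_kd == 0


def test_pileup_counts_spliced_out():
    alns = {"ctrl": [spliced_over(f"s{i}") for i in range(7)], "kd": []}
    (c,) = pileup_counts(alns, [SITE])
    assert c.spliced_out == 7
    assert c.edited_ctrl == 0 and c.unedited_ctrl == 0


def test_pileup_keeps_uncovered_sites_with_zero_counts():
    (c,) = pileup_counts({"ctrl": [], "kd": []}, [SITE])
    assert c.coverage("ctrl") == 0 and c.coverage("kd") == 0


def counts(e_ctrl, u_ctrl, e_kd, u_kd, spliced=0, strand="+"):
    return EditSiteCounts(
        site=EditSite("chr1", 50, strand),
        edited_ctrl=e_ctrl, unedited_ctrl=u_ctrl,
        edited_kd=e_kd, unedited_kd=u_kd, spliced_out=spliced,
    )


def test_differential_editing_recovers_knockdown_site():
    df = differential_editing([counts(8, 2, 1, 9)])
    row = df.iloc[0]
    assert row["significant"]
    assert row["direction"] == "down"
    assert row["p_value"] == pytest.approx(fisher_oracle(1, 9, 8, 2), abs=1e-12)


def test_differential_editing_coverage_disjunction():
    # coverage 9 in both conditions -> excluded
    assert not differential_editing([counts(5, 4, 4, 5)]).iloc[0]["significant"]
    # coverage 10 in one condition is enough to be considered
    assert differential_editing([counts(9, 1, 0, 9)]).iloc[0]["significant"]


def test_differential_editing_delta_filter():
    # 0.50 vs 0.45 edited: only a 5% change -> excluded even at huge coverage
    df = differential_editing([counts(100, 100, 90, 110)])
    assert not df.iloc[0]["significant"]


@pytest.mark.parametrize(
    "e,u,expected",
    [(5, 5, True), (4, 6, False), (0, 10, False), (5, 0, True)],
)
def test_type1_strictly_above_forty_percent(e, u, expected):
    assert classify_type1(counts(e, u, 0, 0)) is expected


def test_type1_zero_coverage_false():
    assert classify_type1(counts(0, 0, 5, 5)) is False


def test_type2_three_sites_within_window():
    (region,) = type2_regions({"chr1": [1000, 1050, 1140]})
    assert (region.start, region.end, region.n_edits) == (1000, 1140, 3)


def test_type2_sparse_sites_no_region():
    assert type2_regions({"chr1": [1000, 1200, 1400]}) == []


def test_type2_mixed_configuration_matches_oracle():
    pos = [1000, 1050, 1140, 1260, 1280, 1300]
    regions = type2_regions({"chr1": pos})
    assert [(r.start, r.end, r.sites) for r in regions] == type2_oracle(pos)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.integers(0, 1500), min_size=1, max_size=30),
    st.integers(20, 300),
    st.integers(2, 4),
)
def test_type2_matches_all_window_oracle(positions, window, min_sites):
    regions = type2_regions({"chr1": positions}, window=window, min_sites=min_sites)
    assert [(r.start, r.end, r.sites) for r in regions] == type2_oracle(
        positions, window=window, min_sites=min_sites
    )


def coordinated_reads(n_both, n_neither, pos1=100, pos2=200):
    """Reads covering both sites, edited at both or at neither."""
    reads = []
    for i in range(n_both + n_neither):
        edited = i < n_both
        seq = list("A" * 200)
        seq[pos1 - 50] = "G" if edited else "A"
        seq[pos2 - 50] = "G" if edited else "A"
        reads.append(
            ReadAlignment(
                read_id=f"r{i}", target_id="chr1", target_kind="genome",
                ops=((MATCH, 200),), target_start=50, read_sequence="".join(seq),
            )
        )
    return reads


def test_coordination_close_pair_excluded():
    sites = [EditSite("chr1", 100, "+"), EditSite("chr1", 140, "+")]
    df = coordination_test(sites, coordinated_reads(10, 10, 100, 140), min_dist=50)
    assert df.empty


def test_coordination_detects_co_edited_pair():
    sites = [EditSite("chr1", 100, "+"), EditSite("chr1", 200, "+")]
    df = coordination_test(sites, coordinated_reads(10, 10))
    row = df.iloc[0]
    assert row["p_value"] == pytest.approx(2 / 184756, abs=1e-12)
    assert row["coordinated"]


def test_coordination_false_positive_rate_under_independence():
    """Independent editing at two sites rejects at most ~alpha of trials."""
    rng = np.random.default_rng(0)
    n_trials, hits = 200, 0
    for _ in range(n_trials):
        reads = []
        for i in range(30):
            seq = list("A" * 200)
            seq[50] = "G" if rng.random() < 0.5 else "A"
            seq[150] = "G" if rng.random() < 0.5 else "A"
            reads.append(
                ReadAlignment(
                    read_id=f"r{i}", target_id="chr1", target_kind="genome",
                    ops=((MATCH, 200),), target_start=50,
                    read_sequence="".join(seq),
                )
            )
        sites = [EditSite("chr1", 100, "+"), EditSite("chr1", 200, "+")]
        df = coordination_test(sites, reads)
        hits += int(df.iloc[0]["coordinated"])
    rate = hits / n_trials
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_trials)


def test_coordination_skips_pairs_without_shared_reads():
    sites = [EditSite("chr1", 100, "+"), EditSite("chr1", 5000, "+")]
    df = coordination_test(sites, coordinated_reads(5, 5))
    assert df.empty
    assert df.attrs["skipped_pairs"] == 1


@pytest.mark.parametrize(
    "e,u,spliced,kept",
    [
        (12, 15, 11, True),   # 44% edited, both thresholds met
        (12, 15, 9, False),   # too few spliced-out reads
        (9, 11, 20, False),   # 45% edited but only 9 edited reads
    ],
)
def test_intron_editing_thresholds(e, u, spliced, kept):
    result = intron_editing([counts(e, u, 0, 0, spliced=spliced)])
    assert (len(result) == 1) is kept


def test_intron_editing_requires_type1():
    # 30% edited: plenty of reads but below the type I fraction
    assert intron_editing([counts(30, 70, 0, 0, spliced=20)]) == []
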