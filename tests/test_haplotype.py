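"""Read variant profiles, haplotype tabulation, phase sets and the bias test."""

import pytest

from conftest import fisher_oracle
from isohap.alignment import DELETION, MATCH, ReadAlignment
from isohap.annotation_io import GenomeInterval, TranscriptModel, Variant
from isohap.haplotype_integration import (
    ALT,
    REF,
    UNCOVERED,
    IsoformProfile,
    emit_hst_outputs,
    hst_bias_test,
    phase_set_mode,
    profile_reads,
    tabulate_haplotypes,
)


def one_exon_model(tid="t1", start=0, end=100, strand="+", gene="g1"):
    return TranscriptModel(
        tid, gene, strand, (GenomeInterval("chr1", start, end, strand),)
    )


def genome_read(read_id, seq, start=0, ops=None):
    return ReadAlignment(
        read_id=read_id, target_id="chr1", target_kind="genome",
        ops=ops or ((MATCH, len(seq)),), target_start=start, read_sequence=seq,
    )


VAR = Variant("chr1", 10, "A", "G")


@pytest.mark.parametrize(
    "base,expected",
    [("G", ALT), ("A", REF), ("T", UNCOVERED), ("C", UNCOVERED)],
)
def test_profile_classifies_each_base(base, expected):
    seq = "A" * 10 + base + "A" * 89
    profiles = profile_reads(
        {"t1": ["r1"]}, [VAR], {"r1": genome_read("r1", seq)}, {"t1": one_exon_model()}
    )
    assert profiles["t1"].observations["r1"] == (expected,)


def test_profile_deletion_spanning_site_is_uncovered():
    aln = genome_read(
        "r1", "A" * 95, ops=((MATCH, 8), (DELETION, 5), (MATCH, 87))
    )
    profiles = profile_reads(
        {"t1": ["r1"]}, [VAR], {"r1": aln}, {"t1": one_exon_model()}
    )
    assert profiles["t1"].observations["r1"] == (UNCOVERED,)


def test_profile_excludes_intronic_variants():
    model = TranscriptModel(
        "t1", "g1", "+",
        (GenomeInterval("chr1", 0, 50), GenomeInterval("chr1", 200, 250)),
    )
    intronic = Variant("chr1", 100, "A", "G")
    profiles = profile_reads({"t1": []}, [intronic], {}, {"t1": model})
    assert profiles["t1"].variants == ()


def prof(vectors, tid="t1", n_variants=2):
    variants = tuple(Variant("chr1", 10 + 7 * i, "A", "G") for i in range(n_variants))
    obs = {f"r{i}": tuple(v) for i, v in enumerate(vectors)}
    return IsoformProfile(tid, variants, obs)


def test_tabulate_single_haplotype():
    groups = tabulate_haplotypes(prof([(ALT, ALT)] * 10))
    assert len(groups) == 1
    assert groups[0].allele_vector == (ALT, ALT)
    assert groups[0].support == 10


def test_tabulate_is_ploidy_agnostic():
    """Three well-supported allele combinations are all reported."""
    vectors = [(REF, REF)] * 5 + [(ALT, REF)] * 5 + [(ALT, ALT)] * 5
    groups = tabulate_haplotypes(prof(vectors))
    assert {g.allele_vector for g in groups} == {(REF, REF), (ALT, REF), (ALT, ALT)}


def test_tabulate_discards_rare_vectors():
    vectors = [(ALT, ALT)] * 10 + [(REF, ALT)] * 2
    groups = tabulate_haplotypes(prof(vectors), min_support=3)
    assert {g.allele_vector for g in groups} == {(ALT, ALT)}


def test_tabulate_min_fraction_applies():
    vectors = [(ALT, ALT)] * 50 + [(REF, REF)] * 4
    groups = tabulate_haplotypes(prof(vectors), min_support=3, min_fraction=0.10)
    assert {g.allele_vector for g in groups} == {(ALT, ALT)}  # 4/54 < 10%


def test_partial_reads_fold_into_unique_compatible_haplotype():
    vectors = [(ALT, ALT)] * 5 + [(REF, REF)] * 5 + [(UNCOVERED, ALT)] * 2
    groups = tabulate_haplotypes(prof(vectors))
    by_vec = {g.allele_vector: g.support for g in groups}
    assert by_vec[(ALT, ALT)] == 7  # partials compatible only with alt,alt
    assert by_vec[(REF, REF)] == 5


def test_ambiguous_partial_reads_are_discarded():
    vectors = [(ALT, ALT)] * 5 + [(ALT, REF)] * 5 + [(ALT, UNCOVERED)] * 4
    groups = tabulate_haplotypes(prof(vectors))
    assert {g.support for g in groups} == {5}


def test_phase_set_majority_links_isoform():
    tags = {f"r{i}": ("PS1", "1") for i in range(8)}
    tags.update({f"r{i}": ("PS1", "2") for i in range(8, 10)})
    links = phase_set_mode(
        tags,
        {"t1": [f"r{i}" for i in range(10)]},
        {"PS1": [VAR]},
        {"t1": one_exon_model()},
    )
    assert links["t1"].haplotype == "1"
    assert links["t1"].variants == (VAR,)


def test_phase_set_even_split_is_no_link():
    tags = {f"r{i}": ("PS1", "1") for i in range(5)}
    tags.update({f"r{i}": ("PS1", "2") for i in range(5, 10)})
    links = phase_set_mode(
        tags, {"t1": [f"r{i}" for i in range(10)]}, {"PS1": [VAR]},
        {"t1": one_exon_model()},
    )
    assert links == {}


def test_phase_set_without_exonic_variants_attaches_nothing():
    far = Variant("chr1", 5000, "A", "G")
    tags = {f"r{i}": ("PS1", "1") for i in range(6)}
    links = phase_set_mode(
        tags, {"t1": [f"r{i}" for i in range(6)]}, {"PS1": [far]},
        {"t1": one_exon_model()},
    )
    assert links["t1"].variants == ()


def test_phase_set_untagged_isoform_has_no_output():
    links = phase_set_mode({}, {"t1": ["r1"]}, {}, {"t1": one_exon_model()})
    assert links == {}


def make_profiles(counts_a, counts_b):
    """Two isoforms of one gene with given (ref, alt) read counts at one site."""
    v = Variant("chr1", 10, "A", "G")
    def obs(n_ref, n_alt, tag):
        rows = {}
        for i in range(n_ref):
            rows[f"{tag}ref{i}"] = (REF,)
        for i in range(n_alt):
            rows[f"{tag}alt{i}"] = (ALT,)
        return rows
    models = {
        "tA": one_exon_model("tA"),
        "tB": one_exon_model("tB"),
    }
    profiles = {
        "tA": IsoformProfile("tA", (v,), obs(*counts_a, "a")),
        "tB": IsoformProfile("tB", (v,), obs(*counts_b, "b")),
    }
    return profiles, models


def test_hst_bias_no_association():
    profiles, models = make_profiles((5, 5), (5, 5))
    results = hst_bias_test(profiles, models)
    assert all(r.p_value == pytest.approx(1.0) for r in results)


def test_hst_bias_full_polarization():
    profiles, models = make_profiles((10, 0), (0, 10))
    results = hst_bias_test(profiles, models)
    for r in results:
        assert r.p_value == pytest.approx(2 / 184756, abs=1e-12)
        assert r.p_value == pytest.approx(
            fisher_oracle(r.ref_isoform, r.alt_isoform, r.ref_other, r.alt_other),
            abs=1e-12,
        )
    assert any(r.adjusted_p < 0.05 for r in results)


def test_hst_bias_zero_margin_flagged():
    profiles, models = make_profiles((5, 0), (5, 0))  # no alt reads at all
    results = hst_bias_test(profiles, models)
    assert all(r.degenerate and r.p_value == 1.0 for r in results)


def test_hst_bias_needs_two_isoforms():
    profiles, models = make_profiles((5, 5), (5, 5))
    del profiles["tB"]
    assert hst_bias_test(profiles, models) == []


def test_emit_hst_outputs_substitution_and_strand(tmp_path):
    genome = {"chr1": "TTAAGGCCTT"}
    plus = TranscriptModel("tp", "g", "+", (GenomeInterval("chr1", 2, 8, "+"),))
    minus = TranscriptModel("tm", "g", "-", (GenomeInterval("chr1", 2, 8, "-"),))
    v = Variant("chr1", 3, "A", "G")
    from isohap.haplotype_integration import HaplotypeGroup

    haps = {
        "tp": [
            HaplotypeGroup("tp", (v,), (ALT,), 5),
            HaplotypeGroup("tp", (v,), (REF,), 5),
        ],
        "tm": [HaplotypeGroup("tm", (v,), (ALT,), 5)],
    }
    seqs = emit_hst_outputs(
        {"tp": plus, "tm": minus}, haps, genome, tmp_path / "hst"
    )
    assert seqs["tp|hap0"] == "AGGGCC"  # A->G at transcript offset 1
    assert seqs["tp|hap1"] == "AAGGCC"  # all-ref haplotype: reference sequence
    # minus strand: transcript is revcomp GGCCTT; the genomic A->G at pos 3
    # maps to transcript offset 4 and reads as T->C there
    assert seqs["tm|hap0"] == "GGCCCT"
    vcf = (tmp_path / "hst.vcf").read_text()
    assert "ISO=tm|hap0,tp|hap0" in vcf
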