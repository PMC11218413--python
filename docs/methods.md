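# Methods

## Coordinate model and containers

All coordinates are 0-based half-open on the forward genomic strand;
conversion to the 1-based conventions of GTF and VCF happens only at format
boundaries. A transcript is an ascending exon chain with its junction chain
derived as the intron gaps; a read alignment is an explicit operation list
(match / mismatch / insertion / deletion / intron) against a transcript or
chromosome. Keeping alignments in op-list form lets every module walk bases
exactly — fidelity windows, variant profiles and editing pileups all share
`ReadAlignment.base_at` — and lets the simulator emit ground-truth
alignments so no external aligner is needed anywhere in the test loop.
Variants do not carry a strand; strand interpretation (A→G vs T→C) is
resolved against gene annotation inside the editing module.

## Read-to-transcript assignment

Reads are aligned to transcript sequences (infix edit-distance alignment via
edlib, both orientations tried) and only candidates tied at the maximum
mapping quality are examined. Two rules gate support, with all thresholds
inclusive (≥ / ≤):

* *stringent*: match fraction ≥ 0.8 — denominator is the read's aligned
  bases, so insertions count against the read and clips are excluded — and
  the alignment must start within 25 bp of the transcript 5′ end and end
  within 25 bp of the 3′ end;
* *splice check*: at every junction, ≥ 4 of the 6 flanking bases (3 per
  side) matched, and no deletion overlapping, or insertion point touching,
  the 6-base window may exceed 3 bp. A junction the alignment does not
  fully cover fails the read: a read must provide evidence across the whole
  isoform it supports (this is the sentinel "uncovered", distinct from 0
  matches).

Ties among passing candidates break on match fraction, then matched-base
count, then lexicographically smallest transcript id, making assignment
deterministic and order-independent. Transcripts keeping ≥ 3 reads enter
the final set; reads of dropped transcripts return to the unassigned pool,
so every read ends in exactly one place.

## Novel isoform collapse

Junction boundaries of unassigned reads snap to the nearest evidence
boundary (annotation and/or short-read junctions) within 10 bp — a
configurable default; ties prefer the smaller shift, then the leftmost
coordinate — and a junction with no evidence within the window rejects the
read. Reads group by exact junction chain; single-exon reads group by
single-linkage clusters of ≥ 50% reciprocal overlap (the format gives no
junctions to group on). Per group, read ends are clustered by single
linkage at a 100 bp fuzzy window; each cluster's representative is its most
frequent position with ties resolved outward (leftmost for starts,
rightmost for ends, keeping transcripts maximal), at most two start and two
end clusters are retained by support, and isoforms are emitted only for
(TSS, TES) pairings observed together in at least one read — pairing by
co-occurrence rather than the full cross product, since a start and an end
never seen on the same molecule are weak evidence of a transcript.
First-pass isoforms are confirmed by realigning their generating reads to
the rebuilt isoform sequences (edlib again) under the same fidelity rules;
≥ 3 surviving reads keep an isoform. Isoform ids hash the chain and ends,
so they are stable across runs. Strand of a novel isoform follows the read
majority.

## Haplotype-specific transcripts

For each isoform, each supporting read's base at every variant inside the
isoform's exons is classified ref / alt / uncovered (uncovered covers
deletions, spliced-out positions, third bases and positions outside the
alignment). Reads with complete vectors are counted exactly; a read with
uncovered sites folds into a complete vector only when compatible with
exactly one, otherwise it is discarded — partial observations never found
new haplotypes, which protects against fragmenting true haplotypes under
3′-biased truncation. Retained haplotypes need ≥ 3 reads and ≥ 10% of the
isoform's reads (mirroring the isoform support default; both configurable).
No ploidy cap applies. In phase-set mode an isoform links to a (phase set,
haplotype) when a strict majority (> 0.5) of its tagged reads agree.

The bias test builds, per variant and isoform, the 2×2 table of ref/alt
reads in the isoform vs the gene's other isoforms, tested two-sided with
the exact Fisher core; any zero margin returns p = 1 flagged as degenerate.
Adjustment is Benjamini–Hochberg across all tests in a run (the output
header records this choice); the test is per-variant, matching the output
table's one-row-per-variant shape, rather than per phase set.

## Editing analytics

Candidate sites keep A→G calls in forward-strand genes and T→C in
reverse-strand genes; sites in unannotated or strand-ambiguous regions are
dropped and counted, and an optional known-sites BED marks catalogue
membership. Pileups count edited and unedited bases per condition with
replicates summed; other bases and deletions are excluded, and reads whose
intron strictly contains the position are tallied as spliced-out.
Differential editing requires coverage ≥ 10 in *either* condition (a
disjunction, per the discovery criterion), an edited-fraction change
≥ 0.10, and raw two-sided Fisher p < 0.05 — uncorrected by design, since
the discovery criterion this mirrors found corrected p-values too
conservative at long-read coverage. Type I hyperediting is strictly > 40%
edited. Type II regions are unions of all 150 bp windows containing ≥ 3
sites, merged when overlapping or adjacent, with bounds at the outermost
member sites (the merge rule is this package's choice; the closed form is
provably identical to enumerating every integer window start). The
coordination test pairs each site with its ≤ 20 nearest candidates ≥ 50 bp
away — neighbourhoods are directed and their union is tested, so a pair may
enter through either endpoint — and tests co-editing over doubly covered
molecules without multiple-testing correction. The edit-vs-splice table
keeps sites type I hyperedited in control with ≥ 10 edited and ≥ 10
spliced-out reads.

## Synthetic data

The generator emulates consensus-called nanopore cDNA: per-base accuracy
0.99 by default with i.i.d. errors at 50:25:25
substitution:insertion:deletion, optional 3′-anchored geometric truncation,
multi-isoform genes built by exon skipping and alternative 5′/3′ splice
sites, planted SNVs spaced ≥ 5 bp, and a knockdown design of three
replicates per condition whose counts are pooled before testing — the
pooled-replicate design is what gives the differential test its power (the
exact power of the Fisher test for a 0.6→0.2 editing drop is 0.851 at a
single 30× replicate but 0.9999 at three pooled ones). Randomness flows
from one integer seed through one numpy generator, so outputs are
byte-identical across runs. What the generator does *not* model: glitch /
junk / chimera reads, homopolymer-dependent error profiles, coverage
biases, or correlated errors — so green tests here demonstrate algorithmic
correctness under the stated error model, not robustness to every artefact
of real nanopore data.

## Numerical choices

The shared Fisher core enumerates the conditional hypergeometric
distribution in exact integer arithmetic: a table contributes iff its
probability numerator is ≤ the observed one, so ties are decided exactly
rather than by a floating-point slack; the only rounding is the final
rational-to-float conversion. Above N = 2000 the classic floating
implementation takes over (big-integer enumeration is wasteful there and
the distinction is far below any decision threshold). The suite verifies
agreement with exhaustive enumeration to 1e-12 for every table with
N ≤ 60 and cross-checks scipy.

Null calibration of the differential-editing test uses 200 sites at 150
reads per condition with editing fraction 0.5 in both conditions. Fisher's
conditional test is conservative on discrete tables — its exact size at
30 reads per condition is ≈ 0.027 — so calibration is run at a depth where
the size (0.043, computed by exhaustive binomial enumeration) is close to
nominal; the suite checks the Monte-Carlo rejection rate within two
standard errors of 0.05. Desk-scale problem sizes throughout (50-transcript
collapse, 60-site recovery, 20-seed recovery sweeps) were chosen so the
whole validation runs in well under a minute each while keeping Monte-Carlo
error small relative to the margins tested.

## Known limitations

The infix edit-distance realignment has no affine gap or splice-aware
scoring, so it stands in for an ungapped transcriptome aligner, not a
spliced genomic one; genomic alignments are expected as input (SAM/BAM or
simulated). Junction correction shifts boundaries without re-optimising the
base-level alignment around them. The editing pileup loads alignments into
memory, which suits desk-scale and gene-panel work rather than
whole-transcriptome BAMs. Phase-set mode attaches a phase set's variants
without re-checking each read's bases (it trusts the upstream phaser).
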