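# Methods

This note documents the procedures the package implements, the defaults
it ships, the numerical choices behind the TSD caller, what the
synthetic-data generator does and does not emulate, and the known
limitations. Every number quoted here is computed by the test suite or
by `scripts/acceptance.py` at run time; nothing is asserted that the
code does not itself measure.

## Coordinate model

All internal coordinates are 0-based half-open on "chr"-prefixed
chromosome names. Conversions happen only at the format boundary:
UCSC rmsk tables are already 0-based half-open and are taken as-is; DGV
positions are 1-based inclusive and are shifted on read (`start−1`) and
shifted back on write; DGV's bare chromosome names gain the `chr`
prefix on read. The two dialects disagree by exactly the off-by-one
that silently breaks interval-containment tests, which is why the
conversion is centralised in `genome_io` and round-trip-tested
(read → write reproduces the original 1-based numbers byte-for-byte in
the coordinate columns).

Genome access always returns uppercase A/C/G/T/N; soft-masking is
discarded, ambiguity code N is preserved. Flanks are always extracted
on the forward strand regardless of element strand, because target-site
duplications are direct repeats in genome orientation.

## Catalogue assembly

HML-2 LTR records are selected by exact repeat-model name
(default `{LTR5, LTR5_Hs}`); the older relatives LTR5A/LTR5B never
match because no prefix matching is used. Internal segments default to
`{HERVK-int}`.

Within a chromosome, records sorted by start are linked pairwise when
they share strand and the signed gap `next.start − prev.end` lies in
`[min_gap, max_gap]` = [−1, 100] bp; −1 admits a one-base overlap, as
adjacent RepeatMasker fragments of one element sometimes do. Maximal
linked chains are parsed greedily left-to-right: `LTR int+ LTR` becomes
a provirus, a leftover `LTR int+` (or `int+ LTR`) a truncated provirus,
a lone LTR a solo LTR. Chains with more than two LTRs (tandem
elements) are split greedily into (LTR, int+, LTR) triples; the greedy
order makes the result deterministic and input-order invariant (both
property-tested). Orphan internal segments without a qualifying LTR
are logged and dropped: the scan and TSD stages are LTR-anchored.

Two quality flags are set, never used to exclude: `short_ltr` for LTR
components under 50 bp and `adjacent_ltr` when another selected LTR
lies within 10 bp. The autosomal LTR count reported by the pipeline
counts raw selected records on chr1–chr22, not merged loci — annotation
tables sometimes split one LTR into several rows, so this count is an
upper bound on distinct elements and downstream stages accept a
`skip_flagged` option instead of a hard filter.

## Deletion scan and classification

Three filters nominate candidates from a variant table:

1. subtype `loss` or `deletion`, compared case-insensitively;
2. the deletion interval fully contains the locus (containment, not
   overlap — a deletion clipping one LTR edge cannot represent a
   preintegration allele);
3. effective deletion length strictly less than 1500 bp, where
   `effective_len = deletion_len` for a solo LTR and
   `deletion_len − (span_length − one_LTR_length)` for proviruses and
   truncated proviruses. The subtraction removes the internal portion
   so the residual is comparable to a solo-LTR deletion: a
   preintegration deletion of a provirus removes span + one TSD copy,
   and after subtracting `span − LTR` the residual is `LTR + TSD`, the
   same quantity a solo-LTR deletion leaves. The "one LTR" is the
   locus's leftmost LTR, a deterministic choice; for the elements this
   pipeline assembles the two LTRs of a provirus have near-identical
   lengths, so the choice is immaterial in practice.

Identical (locus, deletion-interval) pairs contributed by different
studies are collapsed into one candidate with the accessions ';'-joined.

Classification replaces manual genome-browser curation with a fixed
breakpoint-consistency rule. With a TSD call of length `L` at a locus
spanning `[es, ee)` and a deletion `[ds, de)`:

* **preintegration_consistent** — the deletion removes the element plus
  exactly one TSD copy: breakpoints within `breakpoint_tol` of
  `(es − L, ee)` or of `(es, ee + L)`;
* **regional_indel** — the deletion contains the element plus both
  copies plus more than `breakpoint_tol` of extra sequence on each
  side (`ds < es − L − tol` and `de > ee + L + tol`);
* **ambiguous** — everything else, including loci with no TSD call.

`breakpoint_tol` defaults to 10 bp because public SV breakpoints are
imprecise at about that scale; the rule is monotone (tightening the
tolerance can only demote candidates to ambiguous, never promote them),
which is property-tested.

## TSD inference

### Acceptance rules

A putative TSD of length `n` is accepted when

* 4 ≤ n ≤ 500 (search range of the flank windows),
* identity > 0.75 (strict), and
* mismatches + gap columns ≤ 1 for n < 10, ≤ 2 for 10 ≤ n < 20,
  ≤ 3 for n ≥ 20.

The strict identity bound interacts with the band caps at exactly one
grid cell: a 4-bp repeat with one mismatch has identity 3/4 = 0.75 and
is rejected even though the cap alone would allow it. The caller
implements the strict reading; the recovery tests treat that cell with
the over-threshold group.

### Search procedure

For each locus the caller fetches `max_len + max_offset` bp of forward
flank on each side of the locus span (the outermost annotated component
boundaries; truncated proviruses anchor the same way) and then searches
window lengths `L` from 500 down to 4. For each `L` and boundary
offsets `oL, oR ∈ [0, 2]` — up to two intervening bases are tolerated
between a repeat copy and the element, a geometry seen at real loci —
the left window ending `oL` bp before the span and the right window
starting `oR` bp after it are aligned globally.

Alignment is Needleman–Wunsch with match +1, mismatch −1, linear gap
−2; N matches nothing, including another N. Traceback is
deterministic: at score ties it prefers a substitution column, then a
gap in the left-window sequence, then a gap in the right-window
sequence (equivalently, of all optimal alignments it selects the one
whose move sequence read from the back is smallest under that order).
The DP is vectorised row-wise in numpy; the traceback re-derives moves
from the score matrix. Correctness is tested two independent ways:
exhaustive enumeration of *all* alignments of short strings (score
optimality and canonical selection), and score agreement with
Biopython's `PairwiseAligner` on longer random pairs.

The candidate's reported call comes from the alignment **block** after
trimming terminal gap-only columns: block column count is the TSD
length (so a copy may be length±gaps bp on the genome), block
mismatch+gap columns the reported mismatch count, block matches /
block length the identity, and the block's footprint on each window
gives the per-copy genomic intervals and the boundary offsets (which
must stay ≤ 2 after trimming). The band cap, however, is tested
against the **full** alignment's mismatch+gap total. This asymmetry is
deliberate: a window one base longer than the true repeat drags in one
flank base per side, which the optimal alignment parks as two terminal
gap columns; charging those gaps against the cap lets the greedy
longest-first search stop at the true repeat (reported from the
trimmed block) instead of creeping past it, while an un-trimmed
reading would report spurious +1 lengths and a post-trim-only cap
would accept windows arbitrarily longer than the repeat.

The first (largest) `L` with any accepted candidate wins; among
candidates at that `L` the caller prefers the smallest mismatch+gap
count, then the smallest `oL + oR`, then the smallest `oL`.

### Efficiency and the oracle

Scanning ~500 lengths × 9 offset pairs per locus would be prohibitive
with a quadratic aligner, so each window pair is prescreened with a
banded edit distance (edlib, k = 3). The skip is lossless: edit
distance is the minimum of mismatches+gaps over *all* alignments, so it
lower-bounds the optimal alignment's total, and any pair whose edit
distance exceeds 3 — the largest cap in any band — would fail the cap
regardless. `brute_force_tsd` applies the identical acceptance and
tie-break rules by plain exhaustive enumeration with no prescreen and
no early exit (inputs capped at 64 bp), and the suite checks equality
of the two on hundreds of random, planted and band-edge flank pairs
plus a derandomised property test.

## Synthetic data

The generator emulates the three real inputs. Background sequence is
i.i.d. with GC 0.41 (the human genome-wide value). Elements are
planted with ≥ 1 kb spacing: solo LTRs of 968 bp (the length of a
well-characterised solo LTR on chromosome 7), proviruses and truncated
proviruses with 1.2–7 kb internal segments and LTR–internal gaps drawn
from the legal [−1, 100] band. TSD creation follows the integration
mechanism: the bases at the target site are duplicated to both sides of
the element, then 0–4 mutations (substitutions by default; single-base
deletions or insertions optionally) are injected into the right-hand
copy. The annotation file describes LTR and internal components
exactly but never the TSDs — real RepeatMasker output does not annotate
them either. The variant file contains, per requested scenario, a
deletion spanning the element plus one TSD copy (a preintegration
allele), a deletion spanning element + both copies + 200 bp margins (a
regional indel — margins chosen well above the 10 bp breakpoint
tolerance so the two classes cannot blur), and decoy gain/duplication
records that the subtype filter must remove. A `pseudo_tsd` scenario
plants a solo LTR between two long homologous segments that did not
arise from integration; the caller is expected to call it (flank
alignment cannot distinguish the two — that is the point of modelling
it) and truth labels it pseudo for reporting.

Identical (seed, config) pairs produce byte-identical outputs; a truth
ledger records every planted interval, mutation position and intended
variant classification, and `truth_compare` scores a pipeline run
against it.

**Identifiability.** Exact-recovery testing is only meaningful if the
planted length is the *unique* answer the acceptance rules admit, so
the generator guarantees that by construction rather than by luck:

* the background base on each side of the cassette is forced to differ
  from the adjacent copy's edge base, so the repeat cannot be extended
  by a coincidental one-base match;
* mutations are placed in the copy interior (positions 1..L−2): an
  edge mutation can be realigned at equal score as a gap plus a
  flanking-base mismatch, making planted (L, m) evidence-identical to
  (L+1, m+1);
* after planting, the generator evaluates the caller's own acceptance
  rule on every window pair up to 8 bp beyond the planted length and
  resamples the local background (the spacing tail and a 12 bp pad)
  until no longer-than-planted window passes — for over-threshold
  mutation loads, until nothing at or beyond the planted length passes.

Real flanks offer no such guarantees: microhomology, homopolymer runs
and nearby repeats genuinely blur TSD boundaries, so calls on real
genomes carry an ambiguity the synthetic panels deliberately exclude.
Passing the recovery tests therefore demonstrates that the search
implements its rules exactly, not that real TSD lengths are always
unambiguous. An optional low-complexity decoy mode is not implemented;
chance calls at zero-TSD loci are tolerated and reported, not
suppressed.

## Panel sizes and runtime

The shipped panels are sized for a single CPU: the recovery panel
plants 54 loci covering every (length, load) cell over lengths
{4, 9, 10, 19, 20, 50, 111, 250, 450, 500} plus negative-strand and
over-threshold cells on six 45 kb chromosomes; the discrimination panel
plants 100 short-TSD loci with alternating deletion scenarios on eight
40 kb chromosomes; the study panel mirrors the catalogued landscape
(twenty 5–6 bp TSD loci, the long-duplication set 13–450 bp including a
truncated provirus and two proviruses, one pseudo-TSD locus, two
excluded-family decoys). Each simulates and analyses in a couple of
seconds; the full acceptance script, including 500 oracle-equivalence
pairs, runs in about half a minute.

## Known limitations

* The alignment-search procedure is this package's own fully specified
  definition; catalogues built with other aligners or parameters can
  assign slightly different lengths to the same locus. One documented
  field observation places a 250-bp repeat's copy-to-copy difference at
  2 mismatches while quoting a higher identity against the sequenced
  preintegration allele than 248/250; copy-vs-preintegration identity
  requires wet-lab data and is out of scope here.
* Orthology checks against non-human primate genomes, allele-frequency
  estimation and any PCR validation are out of scope.
* The scan trusts the variant table's breakpoints to ±10 bp; variants
  with grossly imprecise breakpoints fall into the ambiguous class
  rather than being rescued.
* `count_autosomal_ltrs` counts annotation rows, not merged elements;
  fragmented annotations inflate it.
* The simulator's i.i.d. background contains none of the repeat
  structure (Alu/L1 neighbourhoods, segmental duplications) that makes
  some real loci hard; only the pseudo-TSD scenario models one such
  mechanism, and only as a labelled generation case.
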