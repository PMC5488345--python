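"""Assembly of the HML-2 locus catalogue from repeat annotations.

HERV-K (HML-2) elements appear in RepeatMasker output as LTR5/LTR5_Hs
long-terminal-repeat fragments and HERVK-int internal (ORF) fragments.
This module selects the HML-2 LTR models (exact-name matching, so the
older relatives LTR5A and LTR5B stay out), then links LTRs to internal
segments on the same strand when the signed gap between neighbouring
fragments lies in [-1, 100] bp (-1 means a one-base overlap).  Linked
chains are parsed into loci:

* ``solo_ltr``            - one LTR, no internal segment;
* ``provirus``            - LTR ... internal ... LTR, same orientation;
* ``truncated_provirus``  - one LTR plus internal segment(s).

Loci whose LTRs are suspiciously short (< 50 bp) or that sit within
10 bp of another catalogued LTR are flagged, not dropped - the counts
these annotations support are soft, and downstream stages may opt to
skip flagged loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import RepeatRecord, is_autosome

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogConfig",
    "Hml2Locus",
    "select_hml2_ltrs",
    "select_internals",
    "assemble_loci",
    "count_autosomal_ltrs",
    "build_catalog",
]

STRUCTURES = ("solo_ltr", "provirus", "truncated_provirus")


@dataclass(frozen=True)
class CatalogConfig:
    """Catalogue-assembly thresholds.

    ltr_names / internal_names
        Repeat-model names counted as HML-2 LTRs and internal segments.
        Matching is exact, never prefix-based.
    min_gap, max_gap
        Signed gap (next.start - prev.end, bp) allowed between an LTR and
        the nearest internal fragment for them to belong to one element;
        -1 admits a single-base overlap.
    short_ltr_threshold, adjacency_threshold
        Flagging thresholds (bp) for dubious LTR annotations.
    """

    ltr_names: frozenset = frozenset({"LTR5", "LTR5_Hs"})
    internal_names: frozenset = frozenset({"HERVK-int"})
    min_gap: int = -1
    max_gap: int = 100
    short_ltr_threshold: int = 50
    adjacency_threshold: int = 10

    def __post_init__(self):
        if self.min_gap > self.max_gap:
            raise ValueError("min_gap > max_gap")
        if self.short_ltr_threshold < 0 or self.adjacency_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class Hml2Locus:
    """An assembled HML-2 locus; all intervals 0-based half-open."""

    locus_id: str
    chrom: str
    span: tuple[int, int]
    strand: str
    structure: str
    ltr_intervals: tuple = ()
    internal_intervals: tuple = ()
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        n_ltr, n_int = len(self.ltr_intervals), len(self.internal_intervals)
        ok = (
            (self.structure == "solo_ltr" and n_ltr == 1 and n_int == 0)
            or (self.structure == "provirus" and n_ltr == 2 and n_int >= 1)
            or (self.structure == "truncated_provirus" and n_ltr == 1 and n_int >= 1)
        )
        if not ok:
            raise ValueError(
                f"{self.structure} locus with {n_ltr} LTR / {n_int} internal intervals"
            )
        lo = min(a for a, _ in self.ltr_intervals + self.internal_intervals)
        hi = max(b for _, b in self.ltr_intervals + self.internal_intervals)
        if self.span != (lo, hi):
            raise ValueError("span does not cover the component intervals")

    @property
    def first_ltr_length(self) -> int:
        a, b = self.ltr_intervals[0]
        return b - a


def _locus_id(chrom: str, span: tuple[int, int]) -> str:
    # 1-based inclusive display form, the convention of genome browsers
    return f"{chrom}:{span[0] + 1}-{span[1]}"


def select_hml2_ltrs(records: Iterable[RepeatRecord],
                     config: CatalogConfig = CatalogConfig()) -> list[RepeatRecord]:
    """Keep exactly the records whose rep_name is a configured HML-2 LTR model."""
    return [r for r in records if r.rep_name in config.ltr_names]


def select_internals(records: Iterable[RepeatRecord],
                     config: CatalogConfig = CatalogConfig()) -> list[RepeatRecord]:
    return [r for r in records if r.rep_name in config.internal_names]


def _parse_chain(chain: list[tuple[str, RepeatRecord]], loci_out: list,
                 orphans_out: list, config: CatalogConfig) -> None:
    """Greedy left-to-right parse of one linked chain into loci.

    Chains longer than LTR-int-LTR (tandem elements) are split greedily
    into (LTR, int+, LTR) triples; a trailing LTR-int run becomes a
    truncated provirus, lone LTRs become solo, ints without any
    qualifying LTR are dropped (logged).
    """
    i = 0
    n = len(chain)
    while i < n:
        kind, rec = chain[i]
        if kind == "ltr":
            j = i + 1
            while j < n and chain[j][0] == "int":
                j += 1
            if j > i + 1 and j < n and chain[j][0] == "ltr":
                loci_out.append(([chain[i][1], chain[j][1]],
                                 [r for _, r in chain[i + 1:j]], "provirus"))
                i = j + 1
            elif j > i + 1:
                loci_out.append(([rec], [r for _, r in chain[i + 1:j]],
                                 "truncated_provirus"))
                i = j
            else:
                loci_out.append(([rec], [], "solo_ltr"))
                i += 1
        else:
            j = i
            while j < n and chain[j][0] == "int":
                j += 1
            if j < n:  # int+ then LTR: truncated provirus anchored on its right LTR
                loci_out.append(([chain[j][1]], [r for _, r in chain[i:j]],
                                 "truncated_provirus"))
                i = j + 1
            else:
                orphans_out.extend(r for _, r in chain[i:j])
                i = j


def assemble_loci(ltrs: Sequence[RepeatRecord], internals: Sequence[RepeatRecord],
                  config: CatalogConfig = CatalogConfig()) -> list[Hml2Locus]:
    """Link LTR and internal fragments into HML-2 loci.

    Two neighbouring fragments (sorted by start within a chromosome) are
    linked iff they share chromosome and strand and the signed gap
    next.start - prev.end lies in [min_gap, max_gap].  Output is sorted by
    (chrom, span start) and invariant under input ordering.
    """
    by_chrom: dict[str, list[tuple[str, RepeatRecord]]] = {}
    for kind, recs in (("ltr", ltrs), ("int", internals)):
        for r in recs:
            by_chrom.setdefault(r.chrom, []).append((kind, r))

    raw_loci: list[tuple[list, list, str]] = []
    orphans: list[RepeatRecord] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda kr: (kr[1].start, kr[1].end))
        chain: list[tuple[str, RepeatRecord]] = []
        prev: RepeatRecord | None = None
        for kind, rec in items:
            linked = (
                prev is not None
                and rec.strand == prev.strand
                and config.min_gap <= rec.start - prev.end <= config.max_gap
            )
            if not linked and chain:
                _parse_chain(chain, raw_loci, orphans, config)
                chain = []
            chain.append((kind, rec))
            prev = rec
        if chain:
            _parse_chain(chain, raw_loci, orphans, config)

    if orphans:
        logger.info(
            "dropped %d orphan internal segment(s) without a qualifying LTR", len(orphans)
        )

    # adjacency flag: any other selected LTR within adjacency_threshold bp
    ltrs_by_chrom: dict[str, list[RepeatRecord]] = {}
    for r in ltrs:
        ltrs_by_chrom.setdefault(r.chrom, []).append(r)

    def near_another_ltr(rec: RepeatRecord) -> bool:
        for other in ltrs_by_chrom.get(rec.chrom, ()):
            if other is rec:
                continue
            gap = max(other.start - rec.end, rec.start - other.end)
            if gap <= config.adjacency_threshold:
                return True
        return False

    loci: list[Hml2Locus] = []
    for ltr_recs, int_recs, structure in raw_loci:
        comp = ltr_recs + int_recs
        span = (min(r.start for r in comp), max(r.end for r in comp))
        flags = set()
        if any(r.length < config.short_ltr_threshold for r in ltr_recs):
            flags.add("short_ltr")
        if any(near_another_ltr(r) for r in ltr_recs):
            flags.add("adjacent_ltr")
        loci.append(
            Hml2Locus(
                locus_id=_locus_id(ltr_recs[0].chrom, span),
                chrom=ltr_recs[0].chrom,
                span=span,
                strand=ltr_recs[0].strand,
                structure=structure,
                ltr_intervals=tuple(sorted((r.start, r.end) for r in ltr_recs)),
                internal_intervals=tuple(sorted((r.start, r.end) for r in int_recs)),
                flags=frozenset(flags),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.span))
    return loci


def count_autosomal_ltrs(ltrs: Iterable[RepeatRecord]) -> int:
    """Number of selected LTR *records* (not loci) on chr1-chr22."""
    return sum(1 for r in ltrs if is_autosome(r.chrom))


def build_catalog(records: Iterable[RepeatRecord],
                  config: CatalogConfig = CatalogConfig()) -> list[Hml2Locus]:
    """Convenience: select LTR + internal models and assemble loci."""
    records = list(records)
    return assemble_loci(
        select_hml2_ltrs(records, config), select_internals(records, config), config
    )
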