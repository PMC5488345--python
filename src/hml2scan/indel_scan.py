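"""Intersection of deletion-type structural variants with the HML-2 catalogue.

An insertional polymorphism leaves two alleles in the population: the
reference allele carrying the element bracketed by its two TSD copies,
and the preintegration allele carrying a single copy of the target site.
A structural-variant *deletion* that removes the element plus exactly one
TSD copy is therefore the signature of a preintegration allele; a
deletion that swallows the element, both TSD copies and extra sequence on
each side is merely a regional indel.

The scan applies three filters to the variant table - (i) subtype "loss"
or "deletion" (case-insensitive); (ii) the deletion fully contains the
locus (the LTR for a solo LTR, the whole annotated span otherwise);
(iii) effective deletion length strictly below 1500 bp, where for
proviruses the internal (non-LTR) portion of the span is first subtracted
so the residual is comparable to a solo-LTR deletion - and then
classifies each candidate by breakpoint consistency against the locus's
TSD call, replacing the manual genome-browser curation this kind of scan
traditionally needs with a fixed ±10 bp breakpoint tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genome_io import VariantRecord
from .hml2_catalog import Hml2Locus
from .tsd_caller import TsdCall

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "CandidateSite",
    "filter_variants",
    "match_deletions",
    "classify_candidate",
    "classify_all",
]

STATUSES = ("preintegration_consistent", "regional_indel", "ambiguous")


@dataclass(frozen=True)
class ScanConfig:
    """Scan filters and the breakpoint-consistency tolerance.

    allowed_subtypes : variant subtypes treated as deletions (lower-case).
    max_len          : strict upper bound (bp) on the effective deletion length.
    breakpoint_tol   : bp slack when matching deletion breakpoints to the
                       element-plus-one-TSD-copy geometry.
    """

    allowed_subtypes: frozenset = frozenset({"loss", "deletion"})
    max_len: int = 1500
    breakpoint_tol: int = 10

    def __post_init__(self):
        if self.max_len <= 0:
            raise ValueError("max_len must be > 0")
        if self.breakpoint_tol < 0:
            raise ValueError("breakpoint_tol must be >= 0")


@dataclass(frozen=True)
class CandidateSite:
    """A (locus, deletion-variant) pair that passed the scan filters."""

    locus_id: str
    variant_accession: str
    chrom: str
    deletion_start: int
    deletion_end: int
    deletion_len: int
    effective_len: int
    status: str | None = None
    tsd_len_used: int | None = None

    def __post_init__(self):
        if self.effective_len > self.deletion_len:
            raise ValueError("effective_len exceeds deletion_len")
        if self.status is not None and self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def filter_variants(variants: Iterable[VariantRecord],
                    config: ScanConfig = ScanConfig()) -> list[VariantRecord]:
    """Filter (i): keep deletion-type subtypes, case-insensitively."""
    kept = []
    for v in variants:
        if v.var_subtype.lower() in config.allowed_subtypes:
            kept.append(v)
        else:
            logger.debug("variant %s rejected by subtype filter (%s)",
                         v.accession, v.var_subtype)
    return kept


def _required_interval(locus: Hml2Locus) -> tuple[int, int]:
    # solo LTR: the LTR itself; provirus/truncated: the whole annotated span
    # (for a solo LTR the two coincide).
    return locus.span


def match_deletions(catalog: Sequence[Hml2Locus],
                    variants: Sequence[VariantRecord],
                    config: ScanConfig = ScanConfig()) -> list[CandidateSite]:
    """Filters (ii) + (iii): containment and effective-length bound.

    A pair is emitted iff the deletion fully contains the locus's required
    interval and its effective length is strictly less than ``max_len``.
    One locus may pair with several deletions and vice versa; identical
    (locus, deletion-interval) pairs reported by different studies are
    collapsed into one candidate with the accessions ';'-joined.
    """
    trees: dict[str, IntervalTree] = {}
    for v in variants:
        trees.setdefault(v.chrom, IntervalTree()).addi(v.start, v.end, v)

    merged: dict[tuple, dict] = {}
    for locus in catalog:
        tree = trees.get(locus.chrom)
        if tree is None:
            continue
        req_start, req_end = _required_interval(locus)
        internal_extra = (locus.span[1] - locus.span[0]) - locus.first_ltr_length
        for iv in sorted(tree.overlap(req_start, req_end)):
            v: VariantRecord = iv.data
            if not (v.start <= req_start and v.end >= req_end):
                logger.debug("variant %s rejected: does not cover locus %s",
                             v.accession, locus.locus_id)
                continue
            deletion_len = v.length
            effective_len = deletion_len
            if locus.structure != "solo_ltr":
                effective_len = deletion_len - internal_extra
            if effective_len >= config.max_len:
                logger.debug("variant %s rejected by length filter at locus %s "
                             "(effective %d bp)", v.accession, locus.locus_id,
                             effective_len)
                continue
            key = (locus.locus_id, v.start, v.end)
            slot = merged.setdefault(key, {
                "locus": locus, "variant": v, "accessions": set(),
                "deletion_len": deletion_len, "effective_len": effective_len,
            })
            slot["accessions"].add(v.accession)

    candidates = []
    for (locus_id, dstart, dend), slot in sorted(merged.items()):
        candidates.append(
            CandidateSite(
                locus_id=locus_id,
                variant_accession=";".join(sorted(slot["accessions"])),
                chrom=slot["locus"].chrom,
                deletion_start=dstart,
                deletion_end=dend,
                deletion_len=slot["deletion_len"],
                effective_len=slot["effective_len"],
            )
        )
    return candidates


def classify_candidate(candidate: CandidateSite, locus: Hml2Locus,
                       tsd: TsdCall | None,
                       config: ScanConfig = ScanConfig()) -> CandidateSite:
    """Breakpoint-consistency classification of one candidate.

    preintegration_consistent: the deletion removes the element plus
    exactly one TSD copy - its breakpoints sit within ``breakpoint_tol``
    of (span_start - tsd_len, span_end) or (span_start, span_end +
    tsd_len).  regional_indel: the deletion contains the element plus
    both copies plus more than ``breakpoint_tol`` of extra sequence on
    each side.  Everything else (including a missing TSD call) is
    ambiguous.
    """
    if tsd is None:
        return replace(candidate, status="ambiguous", tsd_len_used=None)
    tol = config.breakpoint_tol
    es, ee = locus.span
    ds, de = candidate.deletion_start, candidate.deletion_end
    L = tsd.length
    left_copy = abs(ds - (es - L)) <= tol and abs(de - ee) <= tol
    right_copy = abs(ds - es) <= tol and abs(de - (ee + L)) <= tol
    if left_copy or right_copy:
        status = "preintegration_consistent"
    elif ds < es - L - tol and de > ee + L + tol:
        status = "regional_indel"
    else:
        status = "ambiguous"
    return replace(candidate, status=status, tsd_len_used=L)


def classify_all(candidates: Sequence[CandidateSite],
                 catalog: Sequence[Hml2Locus],
                 tsd_calls: Mapping[str, TsdCall] | Sequence[TsdCall],
                 config: ScanConfig = ScanConfig()) -> list[CandidateSite]:
    """Classify every candidate against its locus's TSD call."""
    loci = {l.locus_id: l for l in catalog}
    if not isinstance(tsd_calls, Mapping):
        tsd_calls = {c.locus_id: c for c in tsd_calls}
    out = []
    for cand in candidates:
        locus = loci.get(cand.locus_id)
        if locus is None:
            raise KeyError(f"candidate references unknown locus {cand.locus_id}")
        out.append(classify_candidate(cand, locus, tsd_calls.get(cand.locus_id), config))
    return out
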