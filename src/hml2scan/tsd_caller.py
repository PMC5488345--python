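"""Target-site-duplication inference from LTR-flanking sequence.

Retroviral integration duplicates the few bases at the target site, so an
HML-2 element (solo LTR, provirus or truncated provirus) should be
bracketed by a direct repeat - the TSD.  Given a locus, this module
searches the two genomic flanks for the longest such repeat in the
4-500 bp range, allowing up to two intervening bases between a repeat
copy and the element boundary, and accepting a candidate only when the
two copies align globally with identity > 0.75 and no more than 1 / 2 / 3
mismatch-or-gap columns for repeat lengths < 10 / < 20 / >= 20 bp.

The search is anchored and per-length: for each window length L (tried
from longest to shortest) and boundary offsets oL, oR in [0, max_offset],
the left-flank window ending oL bp before the locus and the right-flank
window starting oR bp after it are aligned with Needleman-Wunsch (match
+1, mismatch -1, gap -2, N never matches, deterministic traceback that
prefers a substitution column over a gap in the left-window sequence over
a gap in the right-window sequence).  Terminal gap-only columns of the
optimal alignment are trimmed; the trimmed block defines the reported TSD
length (alignment columns), per-copy genomic intervals, mismatch+gap
count and identity.  Acceptance tests the *full* alignment's mismatch+gap
total against the length band cap - so flank bases a too-long window
drags in still cost their terminal gaps - while identity and the offsets
are taken from the trimmed block.  The first accepted (longest) L wins;
ties at one L prefer fewer mismatches+gaps, then smaller oL+oR, then
smaller oL.

``brute_force_tsd`` applies exactly the same rules by plain exhaustive
enumeration, with no prescreening or early exit, and is the validation
oracle for the optimised search (which skips a window pair whenever its
banded edit distance already exceeds the largest cap, 3 - edit distance
lower-bounds the optimal alignment's mismatch+gap count, so the skip is
lossless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .genome_io import GenomeAccessor
from .hml2_catalog import Hml2Locus

logger = logging.getLogger(__name__)

__all__ = [
    "TsdConfig",
    "AlignmentResult",
    "TsdCall",
    "FlankCall",
    "mismatch_cap",
    "global_align",
    "search_flanks",
    "brute_force_tsd",
    "infer_tsd",
    "call_all",
]

GAP = "-"
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4
_MAX_CAP = 3  # largest mismatch+gap budget over all length bands


@dataclass(frozen=True)
class TsdConfig:
    """TSD search parameters.

    min_len / max_len : bp window-length range searched (descending).
    min_identity      : acceptance requires identity strictly greater.
    max_offset        : bp allowed between a repeat copy and the element.
    match/mismatch/gap: Needleman-Wunsch scores (linear gap penalty).
    """

    min_len: int = 4
    max_len: int = 500
    min_identity: float = 0.75
    max_offset: int = 2
    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if not (0 <= self.min_identity < 1):
            raise ValueError("need 0 <= min_identity < 1")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with per-column bookkeeping."""

    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    gap_columns: int
    score: int

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        return self.matches / self.length


@dataclass(frozen=True)
class FlankCall:
    """A TSD call in flank-local coordinates (see :class:`TsdCall`).

    left_window / right_window are (start, end) positions of the accepted
    block's copies: left is measured in bases *upstream of the element
    start* (so (2, 14) means the copy ends 2 bp before the element and
    spans 12 bp); right is measured downstream of the element end.
    """

    length: int
    mismatch_gap_count: int
    identity: float
    left_window: tuple[int, int]
    right_window: tuple[int, int]
    left_offset: int
    right_offset: int


@dataclass(frozen=True)
class TsdCall:
    """An accepted TSD with genomic intervals for both copies."""

    locus_id: str
    chrom: str
    length: int
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    mismatch_gap_count: int
    identity: float
    left_offset: int
    right_offset: int
    structure: str = ""


def mismatch_cap(length: int) -> int:
    """Allowed mismatch+gap columns for a putative TSD of this length (bp)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if length < 10:
        return 1
    if length < 20:
        return 2
    return 3


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODES[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN character {exc.args[0]!r}") from None


def global_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap: int = -2) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with deterministic traceback.

    Traceback preference at score ties: substitution column, then gap in
    ``a``, then gap in ``b`` (equivalently: of all optimal alignments, the
    one whose move sequence read from the back is smallest under that
    order).  N never matches anything, including another N.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ac, bc = _encode(a), _encode(b)
    m, n = len(ac), len(bc)

    D = np.empty((m + 1, n + 1), dtype=np.int32)
    jj = np.arange(n + 1, dtype=np.int32)
    D[0] = gap * jj
    g_ramp = gap * jj[1:]
    for i in range(1, m + 1):
        eq = (bc == ac[i - 1]) & (ac[i - 1] != _N_CODE) & (bc != _N_CODE)
        sub = np.where(eq, match, mismatch).astype(np.int32)
        E = np.maximum(D[i - 1, :-1] + sub, D[i - 1, 1:] + gap)
        # D[i, j] = max(E[j], D[i, j-1] + gap) via a cumulative max
        t = np.empty(n + 1, dtype=np.int32)
        t[0] = gap * i
        t[1:] = E - g_ramp
        D[i] = np.maximum.accumulate(t) + gap * jj

    out_a: list[str] = []
    out_b: list[str] = []
    matches = mismatches = gaps = 0
    i, j = m, n
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0:
            is_match = ac[i - 1] == bc[j - 1] and ac[i - 1] != _N_CODE
            if here == D[i - 1, j - 1] + (match if is_match else mismatch):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                if is_match:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
                continue
        if j > 0 and here == D[i, j - 1] + gap:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            gaps += 1
            j -= 1
            continue
        out_a.append(a[i - 1])
        out_b.append(GAP)
        gaps += 1
        i -= 1
    return AlignmentResult(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        score=int(D[m, n]),
    )


def _evaluate_window_pair(lw: str, rw: str, L: int, oL: int, oR: int,
                          config: TsdConfig) -> FlankCall | None:
    """Align one window pair and apply the acceptance rules; None if rejected."""
    aln = global_align(lw, rw, config.match, config.mismatch, config.gap)
    full_mm_gap = aln.mismatches + aln.gap_columns
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    s, e = 0, len(cols)
    while s < e and GAP in cols[s]:
        s += 1
    while e > s and GAP in cols[e - 1]:
        e -= 1
    block = cols[s:e]
    length = len(block)
    if length == 0:
        return None
    matches = sum(1 for x, y in block if x == y and x != "N")
    identity = matches / length
    if not (config.min_len <= length <= config.max_len):
        return None
    if identity <= config.min_identity:
        return None
    if full_mm_gap > mismatch_cap(length):
        return None
    # characters of each window consumed outside the trimmed block
    a_pre = sum(1 for x, _ in cols[:s] if x != GAP)
    a_post = sum(1 for x, _ in cols[e:] if x != GAP)
    b_pre = sum(1 for _, y in cols[:s] if y != GAP)
    b_post = sum(1 for _, y in cols[e:] if y != GAP)
    left_offset = oL + a_post
    right_offset = oR + b_pre
    if left_offset > config.max_offset or right_offset > config.max_offset:
        return None
    # left window spans [oL+L, oL) upstream of the element start
    return FlankCall(
        length=length,
        mismatch_gap_count=length - matches,
        identity=identity,
        left_window=(oL + a_post, oL + L - a_pre),
        right_window=(oR + b_pre, oR + L - b_post),
        left_offset=left_offset,
        right_offset=right_offset,
    )


def search_flanks(left: str, right: str, config: TsdConfig = TsdConfig(),
                  prescreen: bool = True) -> FlankCall | None:
    """Greedy longest-first TSD search over two flank sequences.

    ``left`` must end exactly at the element start; ``right`` must begin
    exactly at the element end.  Windows that cannot contain an acceptable
    repeat are skipped via a banded edit-distance prescreen unless
    ``prescreen`` is False.
    """
    nl, nr = len(left), len(right)
    top = min(config.max_len, max(nl, nr))
    for L in range(top, config.min_len - 1, -1):
        best: FlankCall | None = None
        best_key = None
        for oL in range(config.max_offset + 1):
            if oL + L > nl:
                continue
            lw = left[nl - oL - L: nl - oL]
            for oR in range(config.max_offset + 1):
                if oR + L > nr:
                    continue
                rw = right[oR: oR + L]
                if prescreen:
                    d = edlib.align(lw, rw, mode="NW", task="distance", k=_MAX_CAP)
                    if d["editDistance"] == -1:
                        continue
                cand = _evaluate_window_pair(lw, rw, L, oL, oR, config)
                if cand is None:
                    continue
                key = (cand.mismatch_gap_count, oL + oR, oL)
                if best is None or key < best_key:
                    best, best_key = cand, key
        if best is not None:
            return best
    return None


def brute_force_tsd(left: str, right: str,
                    config: TsdConfig = TsdConfig()) -> FlankCall | None:
    """Exhaustive oracle: enumerate every (L, oL, oR) window pair.

    Applies the identical acceptance and tie-break rules with no
    prescreen and no early exit, collecting every passing candidate and
    then selecting by (largest L, fewest mismatches+gaps, smallest
    oL+oR, smallest oL).  Inputs are capped at 64 bp for tractability.
    """
    if len(left) > 64 or len(right) > 64:
        raise ValueError("brute_force_tsd accepts flanks of at most 64 bp")
    nl, nr = len(left), len(right)
    passing: list[tuple[tuple, FlankCall]] = []
    for L in range(config.min_len, min(config.max_len, max(nl, nr)) + 1):
        for oL in range(config.max_offset + 1):
            for oR in range(config.max_offset + 1):
                if oL + L > nl or oR + L > nr:
                    continue
                lw = left[nl - oL - L: nl - oL]
                rw = right[oR: oR + L]
                cand = _evaluate_window_pair(lw, rw, L, oL, oR, config)
                if cand is not None:
                    key = (-L, cand.mismatch_gap_count, oL + oR, oL)
                    passing.append((key, cand))
    if not passing:
        return None
    return min(passing, key=lambda kc: kc[0])[1]


def infer_tsd(genome: GenomeAccessor, locus: Hml2Locus,
              config: TsdConfig = TsdConfig()) -> TsdCall | None:
    """Infer the TSD of one locus from the reference genome, or None.

    Flanks anchor to the outermost annotated component boundaries (the
    locus span) on the forward strand; TSDs are direct repeats in genome
    orientation, so element strand plays no role.
    """
    start, end = locus.span
    n = genome.chrom_lengths[locus.chrom]
    width = config.max_len + config.max_offset
    left = genome.fetch(locus.chrom, max(0, start - width), start)
    right = genome.fetch(locus.chrom, end, min(n, end + width))
    if len(left) < config.min_len or len(right) < config.min_len:
        logger.info("locus %s too close to a contig edge for even a %d bp flank",
                    locus.locus_id, config.min_len)
        return None
    hit = search_flanks(left, right, config)
    if hit is None:
        return None
    la, lb = hit.left_window   # bases upstream of the element start
    ra, rb = hit.right_window  # bases downstream of the element end
    return TsdCall(
        locus_id=locus.locus_id,
        chrom=locus.chrom,
        length=hit.length,
        left_interval=(start - lb, start - la),
        right_interval=(end + ra, end + rb),
        mismatch_gap_count=hit.mismatch_gap_count,
        identity=hit.identity,
        left_offset=hit.left_offset,
        right_offset=hit.right_offset,
        structure=locus.structure,
    )


def call_all(genome: GenomeAccessor, catalog: Sequence[Hml2Locus],
             config: TsdConfig = TsdConfig(),
             skip_flagged: bool = False) -> list[TsdCall]:
    """Run :func:`infer_tsd` over a catalogue, ordered by (chrom, start)."""
    calls: list[TsdCall] = []
    for locus in sorted(catalog, key=lambda l: (l.chrom, l.span)):
        if skip_flagged and locus.flags:
            continue
        try:
            call = infer_tsd(genome, locus, config)
        except Exception:
            logger.exception("TSD inference failed for locus %s", locus.locus_id)
            continue
        if call is not None:
            calls.append(call)
    return calls
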