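"""Synthetic genomes with planted ERV insertions and matching annotations.

Every pipeline stage is testable without external downloads: the
simulator emits (i) a genome in which HML-2-like elements - solo LTRs,
proviruses and truncated proviruses - are planted on an i.i.d.
background, each bracketed by a direct-repeat TSD created exactly the way
integration creates one (the bases at the target site are duplicated to
both sides of the element, then a configurable number of mutations is
injected into the right-hand copy); (ii) a RepeatMasker-dialect table
annotating the LTR and internal components (TSDs deliberately
unannotated, as in real RepeatMasker output); (iii) a DGV-dialect variant
table containing, per requested scenario, a deletion spanning the element
plus one TSD copy (a preintegration allele) or the element plus both
copies plus 200 bp margins (a regional indel), along with optional decoy
gain variants; and (iv) a ground-truth ledger against which pipeline
output can be scored.

A ``pseudo_tsd`` element plants a solo LTR between two long homologous
segments that did *not* arise from integration - the recombination-borne
mimic the TSD caller cannot (and is not expected to) distinguish; truth
labels it pseudo for reporting.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .genome_io import (
    DictGenome,
    RepeatRecord,
    VariantRecord,
    reverse_complement,
    write_dgv,
    write_repeatmasker,
)
from .tsd_caller import TsdConfig, mismatch_cap, _evaluate_window_pair

__all__ = [
    "ElementSpec",
    "SimConfig",
    "PlantedElement",
    "TruthVariant",
    "SyntheticTruth",
    "SyntheticBundle",
    "simulate",
    "truth_compare",
    "RecoveryReport",
    "write_truth",
    "read_truth",
    "study_config",
    "recovery_panel_config",
    "discrimination_config",
]

_BASES = np.array(list("ACGT"))

SCENARIOS = ("preintegration_deletion", "regional_indel", "pseudo_tsd")


@dataclass(frozen=True)
class ElementSpec:
    """One element to plant.

    tsd_len 0 means no target-site duplication; tsd_mutations changes are
    injected into the right-hand copy (substitutions by default, or a
    single-base deletion/insertion per mutation for kind "del"/"ins").
    offset_bases places 0-2 intervening bases between the left TSD copy
    and the element, the geometry occasionally seen at real loci.
    """

    structure: str = "solo_ltr"
    ltr_len: int = 968
    internal_len: int = 5000
    internal_gap: int = 5
    strand: str = "+"
    tsd_len: int = 6
    tsd_mutations: int = 0
    mutation_kind: str = "sub"
    offset_bases: int = 0
    ltr_name: str = "LTR5_Hs"
    scenarios: tuple = ()
    pseudo_len: int = 300
    chrom: str | None = None

    def __post_init__(self):
        if self.structure not in ("solo_ltr", "provirus", "truncated_provirus"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not (0 <= self.tsd_len <= 500):
            raise ValueError("tsd_len must be in [0, 500]")
        if not (-1 <= self.internal_gap <= 100):
            raise ValueError("internal_gap must be in [-1, 100]")
        if not (0 <= self.offset_bases <= 2):
            raise ValueError("offset_bases must be in [0, 2]")
        if self.mutation_kind not in ("sub", "del", "ins"):
            raise ValueError(f"unknown mutation_kind {self.mutation_kind!r}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")


@dataclass(frozen=True)
class SimConfig:
    """Genome shape plus the list of elements to plant.

    Identical (seed, config) pairs produce byte-identical outputs.
    Elements are placed round-robin over the chromosomes (unless pinned),
    in order, with >= 1 kb of background between cassettes.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 200_000
    gc: float = 0.41
    elements: tuple = ()
    decoy_variants: int = 0
    chrom_names: tuple = ()
    min_spacing: int = 1000
    regional_margin: int = 200

    def names(self) -> tuple:
        if self.chrom_names:
            return tuple(self.chrom_names)
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))


@dataclass(frozen=True)
class PlantedElement:
    """Ground truth for one planted element (0-based half-open intervals)."""

    locus_id: str
    chrom: str
    span: tuple[int, int]
    structure: str
    strand: str
    ltr_name: str
    ltr_intervals: tuple
    internal_intervals: tuple
    tsd_len: int
    left_copy: tuple[int, int] | None
    right_copy: tuple[int, int] | None
    offset_bases: int
    mutation_positions: tuple
    expected_mismatch_gap: int
    pseudo: bool
    scenarios: tuple


@dataclass(frozen=True)
class TruthVariant:
    """Intended classification of one emitted DGV record."""

    accession: str
    chrom: str
    start: int
    end: int
    var_subtype: str
    element_locus_id: str
    intended: str  # preintegration_consistent | regional_indel | filtered


@dataclass(frozen=True)
class SyntheticTruth:
    run_id: str
    elements: tuple
    variants: tuple


@dataclass(frozen=True)
class SyntheticBundle:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    sequences: dict
    repeats: tuple
    variants: tuple
    truth: SyntheticTruth

    @property
    def genome(self) -> DictGenome:
        return DictGenome(self.sequences)

    def write(self, outdir: str | os.PathLike) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "rmsk": os.path.join(outdir, "rmsk.tsv"),
            "dgv": os.path.join(outdir, "dgv.tsv"),
            "truth_elements": os.path.join(outdir, "truth_elements.tsv"),
            "truth_variants": os.path.join(outdir, "truth_variants.tsv"),
        }
        with open(paths["genome"], "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_repeatmasker(self.repeats, paths["rmsk"],
                           {c: len(s) for c, s in self.sequences.items()})
        write_dgv(self.variants, paths["dgv"])
        write_truth(self.truth, paths["truth_elements"], paths["truth_variants"])
        return paths


def _run_id(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate_copy(rng: np.random.Generator, seq: str, n_mut: int,
                 kind: str, gc: float) -> tuple[str, tuple]:
    """Inject n_mut changes; returns (mutated copy, positions).

    Mutations are restricted to the copy interior (never its first or
    last base): an edge mutation can be realigned at equal score as a gap
    plus a flanking-base mismatch, which would leave the planted length
    ambiguous.
    """
    if n_mut == 0:
        return seq, ()
    interior = np.arange(1, len(seq) - 1) if len(seq) > 2 else np.arange(len(seq))
    if n_mut > len(interior):
        raise ValueError("more mutations than mutable TSD bases")
    positions = sorted(rng.choice(interior, size=n_mut, replace=False).tolist())
    chars = list(seq)
    if kind == "sub":
        for p in positions:
            alternatives = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alternatives[rng.integers(0, 3)]
    elif kind == "del":
        for p in reversed(positions):
            del chars[p]
    else:  # ins
        for p in reversed(positions):
            chars.insert(p, str(_BASES[rng.integers(0, 4)]))
    return "".join(chars), tuple(positions)


_PAD = 12  # post-cassette background emitted with the cassette (bp)


def _has_overlong_pass(lctx: str, rctx: str, max_true: int,
                       cfg: TsdConfig) -> bool:
    """True if any window pair near the cassette would be accepted with a
    block longer than ``max_true``.

    ``lctx`` ends exactly at the element start, ``rctx`` begins exactly at
    the element end.  Blocks can exceed the window length by at most one
    column within the mismatch+gap caps, so scanning window lengths up to
    ``max_true + 8`` covers every chance repeat that could outrank the
    planted one; longer chance repeats would need > 3 edits and fail the
    caps outright.
    """
    for L in range(max(cfg.min_len, max_true), max_true + 9):
        for oL in range(cfg.max_offset + 1):
            if oL + L > len(lctx):
                continue
            lw = lctx[len(lctx) - oL - L: len(lctx) - oL]
            for oR in range(cfg.max_offset + 1):
                if oR + L > len(rctx):
                    continue
                rw = rctx[oR: oR + L]
                d = edlib.align(lw, rw, mode="NW", task="distance", k=3)
                if d["editDistance"] == -1:
                    continue
                cand = _evaluate_window_pair(lw, rw, L, oL, oR, cfg)
                if cand is not None and cand.length > max_true:
                    return True
    return False


def _element_body(rng: np.random.Generator, spec: ElementSpec,
                  gc: float) -> tuple[str, list, list]:
    """Build the element sequence and its component intervals (body-local).

    A provirus is LTR - gap - internal - gap - LTR; internal_gap -1 means
    the neighbouring components overlap by one base (shared base, as the
    annotations of real elements sometimes do).
    """
    g = spec.internal_gap
    ltr_intervals: list[tuple[int, int]] = []
    internal_intervals: list[tuple[int, int]] = []
    if spec.structure == "solo_ltr":
        ltr_intervals.append((0, spec.ltr_len))
        total = spec.ltr_len
    elif spec.structure == "truncated_provirus":
        ltr_intervals.append((0, spec.ltr_len))
        a = spec.ltr_len + g
        internal_intervals.append((a, a + spec.internal_len))
        total = a + spec.internal_len
    else:
        ltr_intervals.append((0, spec.ltr_len))
        a = spec.ltr_len + g
        internal_intervals.append((a, a + spec.internal_len))
        b = a + spec.internal_len + g
        ltr_intervals.append((b, b + spec.ltr_len))
        total = b + spec.ltr_len
    body = _random_seq(rng, total, gc)
    if spec.strand == "-":
        body = reverse_complement(body)
    return body, ltr_intervals, internal_intervals


def simulate(config: SimConfig) -> SyntheticBundle:
    """Generate genome, rmsk-dialect and DGV-dialect data plus ground truth."""
    rng = np.random.default_rng(config.seed)
    names = config.names()
    parts: dict[str, list[str]] = {c: [] for c in names}
    cursor: dict[str, int] = {c: 0 for c in names}
    repeats: list[RepeatRecord] = []
    truth_elements: list[PlantedElement] = []
    truth_variants: list[TruthVariant] = []
    variants: list[VariantRecord] = []
    acc_counter = 0

    def emit(chrom: str, seq: str) -> int:
        parts[chrom].append(seq)
        start = cursor[chrom]
        cursor[chrom] += len(seq)
        return start

    def _other_base(b: str) -> str:
        return "ACGT"[("ACGT".index(b) + 1) % 4]

    for i, spec in enumerate(config.elements):
        chrom = spec.chrom or names[i % len(names)]
        if chrom not in parts:
            raise ValueError(f"element pinned to unknown chromosome {chrom!r}")
        spacing = config.min_spacing + int(rng.integers(0, 500))
        spacing_seq = _random_seq(rng, spacing, config.gc)

        pseudo = "pseudo_tsd" in spec.scenarios
        body, ltr_local, int_local = _element_body(rng, spec, config.gc)
        if pseudo:
            dup = _random_seq(rng, spec.pseudo_len, config.gc)
            dup2, mut_pos = _mutate_copy(rng, dup, spec.tsd_mutations,
                                         spec.mutation_kind, config.gc)
            left_seq, offset_seq, right_seq = dup, "", dup2
            tsd_len = 0
        else:
            tsd = _random_seq(rng, spec.tsd_len, config.gc)
            tsd2, mut_pos = _mutate_copy(rng, tsd, spec.tsd_mutations,
                                         spec.mutation_kind, config.gc)
            left_seq, right_seq = tsd, tsd2
            offset_seq = _random_seq(rng, spec.offset_bases, config.gc)
            tsd_len = spec.tsd_len

        # Identifiability guards: the planted repeat must be the *unique*
        # rule-consistent longest repeat at this locus, or ground truth
        # would not be well defined.  (1) Edge guards force the background
        # bases bracketing the cassette to differ from the repeat's edge
        # bases, so the repeat cannot be coincidentally extended by one.
        # (2) The local background (spacing tail + a 12 bp pad after the
        # right copy) is resampled until no window pair near the cassette
        # would be accepted with a block longer than the planted length
        # (for over-cap loads: no block at the planted length either).
        pad_seq = ""
        if right_seq:
            cap_cfg = TsdConfig()
            if pseudo or tsd_len == 0:
                max_true = None
            else:
                within = (spec.tsd_mutations <= mismatch_cap(tsd_len)
                          and (tsd_len - spec.tsd_mutations) / tsd_len
                          > cap_cfg.min_identity)
                max_true = tsd_len if within else tsd_len - 1
            for attempt in range(300):
                if not pseudo and attempt and attempt % 50 == 0:
                    # a pathological target site (e.g. mutations sliding
                    # along an edge-reaching homopolymer): redraw it
                    left_seq = _random_seq(rng, spec.tsd_len, config.gc)
                    right_seq, mut_pos = _mutate_copy(
                        rng, left_seq, spec.tsd_mutations,
                        spec.mutation_kind, config.gc)
                elif not pseudo and attempt and attempt % 5 == 0 and mut_pos:
                    right_seq, mut_pos = _mutate_copy(
                        rng, left_seq, spec.tsd_mutations,
                        spec.mutation_kind, config.gc)
                if spacing_seq.endswith(right_seq[0]):
                    spacing_seq = spacing_seq[:-1] + _other_base(right_seq[0])
                pad_seq = _random_seq(rng, _PAD, config.gc)
                if pad_seq[0] == left_seq[-1]:
                    pad_seq = _other_base(pad_seq[0]) + pad_seq[1:]
                if max_true is None or not _has_overlong_pass(
                        spacing_seq + left_seq + offset_seq,
                        right_seq + pad_seq, max_true, cap_cfg):
                    break
                spacing_seq = spacing_seq[:-_PAD] + _random_seq(rng, _PAD, config.gc)
            else:
                raise RuntimeError(
                    "could not build an identifiable background for a planted TSD"
                )
        emit(chrom, spacing_seq)
        left_start = emit(chrom, left_seq)
        emit(chrom, offset_seq)
        body_start = emit(chrom, body)
        right_start = emit(chrom, right_seq)
        if pad_seq:
            emit(chrom, pad_seq)
        span = (body_start, body_start + len(body))
        locus_id = f"{chrom}:{span[0] + 1}-{span[1]}"

        for a, b in ltr_local:
            repeats.append(RepeatRecord(chrom, body_start + a, body_start + b,
                                        spec.strand, spec.ltr_name, "LTR", "ERVK"))
        for a, b in int_local:
            repeats.append(RepeatRecord(chrom, body_start + a, body_start + b,
                                        spec.strand, "HERVK-int", "LTR", "ERVK"))

        truth_elements.append(PlantedElement(
            locus_id=locus_id,
            chrom=chrom,
            span=span,
            structure=spec.structure,
            strand=spec.strand,
            ltr_name=spec.ltr_name,
            ltr_intervals=tuple((body_start + a, body_start + b) for a, b in ltr_local),
            internal_intervals=tuple((body_start + a, body_start + b) for a, b in int_local),
            tsd_len=tsd_len,
            left_copy=(left_start, left_start + len(left_seq)) if left_seq else None,
            right_copy=(right_start, right_start + len(right_seq)) if right_seq else None,
            offset_bases=spec.offset_bases if not pseudo else 0,
            mutation_positions=mut_pos,
            expected_mismatch_gap=spec.tsd_mutations,
            pseudo=pseudo,
            scenarios=tuple(spec.scenarios),
        ))

        for scen in spec.scenarios:
            if scen == "pseudo_tsd":
                continue
            acc_counter += 1
            accession = f"essv{acc_counter:05d}"
            subtype = "deletion" if acc_counter % 2 else "loss"
            if scen == "preintegration_deletion":
                dstart, dend = left_start, span[1]
                intended = "preintegration_consistent"
            else:  # regional indel: both copies + margins
                m = config.regional_margin
                dstart = left_start - m
                dend = right_start + len(right_seq) + m
                intended = "regional_indel"
            variants.append(VariantRecord(accession, chrom, dstart, dend,
                                          "CNV", subtype))
            truth_variants.append(TruthVariant(accession, chrom, dstart, dend,
                                               subtype, locus_id, intended))

    # decoy variants: gain/duplication records covering random planted loci;
    # filter (i) must remove them before any interval work happens
    real = [e for e in truth_elements if not e.pseudo]
    for k in range(config.decoy_variants):
        if not real:
            break
        e = real[int(rng.integers(0, len(real)))]
        acc_counter += 1
        accession = f"essv{acc_counter:05d}"
        subtype = "duplication" if k % 2 else "gain"
        dstart = max(0, e.span[0] - int(rng.integers(0, 50)))
        dend = e.span[1] + int(rng.integers(0, 50))
        variants.append(VariantRecord(accession, e.chrom, dstart, dend, "CNV", subtype))
        truth_variants.append(TruthVariant(accession, e.chrom, dstart, dend,
                                           subtype, e.locus_id, "filtered"))

    sequences: dict[str, str] = {}
    for chrom in names:
        used = cursor[chrom]
        if used + config.min_spacing > config.chrom_len:
            raise ValueError(
                f"elements do not fit on {chrom}: need {used + config.min_spacing} bp, "
                f"chrom_len is {config.chrom_len}"
            )
        tail = _random_seq(rng, config.chrom_len - used, config.gc)
        sequences[chrom] = "".join(parts[chrom]) + tail

    truth = SyntheticTruth(
        run_id=_run_id(config),
        elements=tuple(truth_elements),
        variants=tuple(truth_variants),
    )
    return SyntheticBundle(config=config, sequences=sequences,
                           repeats=tuple(repeats), variants=tuple(variants),
                           truth=truth)


# ---------------------------------------------------------------------------
# Truth ledger IO
# ---------------------------------------------------------------------------

def _iv(v) -> str:
    return "." if v is None else f"{v[0]}-{v[1]}"


def _parse_iv(s: str):
    if s in (".", "", "nan"):
        return None
    a, b = s.rsplit("-", 1)
    return (int(a), int(b))


def write_truth(truth: SyntheticTruth, elements_path, variants_path) -> None:
    with open(elements_path, "w") as fh:
        fh.write(f"# run_id={truth.run_id}\n")
        fh.write("locus_id\tchrom\tspan\tstructure\tstrand\tltr_name\tltr_intervals"
                 "\tinternal_intervals\ttsd_len\tleft_copy\tright_copy\toffset_bases"
                 "\tmutation_positions\texpected_mismatch_gap\tpseudo\tscenarios\n")
        for e in truth.elements:
            fh.write("\t".join([
                e.locus_id, e.chrom, _iv(e.span), e.structure, e.strand, e.ltr_name,
                ";".join(_iv(x) for x in e.ltr_intervals) or ".",
                ";".join(_iv(x) for x in e.internal_intervals) or ".",
                str(e.tsd_len), _iv(e.left_copy), _iv(e.right_copy),
                str(e.offset_bases),
                ",".join(map(str, e.mutation_positions)) or ".",
                str(e.expected_mismatch_gap), str(int(e.pseudo)),
                ";".join(e.scenarios) or ".",
            ]) + "\n")
    with open(variants_path, "w") as fh:
        fh.write(f"# run_id={truth.run_id}\n")
        fh.write("accession\tchrom\tstart\tend\tvar_subtype\telement_locus_id\tintended\n")
        for v in truth.variants:
            fh.write(f"{v.accession}\t{v.chrom}\t{v.start}\t{v.end}\t{v.var_subtype}"
                     f"\t{v.element_locus_id}\t{v.intended}\n")


def _read_run_id(path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# run_id="):
        raise ValueError(f"{path}: missing run_id header")
    return first.split("=", 1)[1]


def read_truth(elements_path, variants_path) -> SyntheticTruth:
    run_id = _read_run_id(elements_path)
    if _read_run_id(variants_path) != run_id:
        raise ValueError("truth element/variant files come from different runs")
    edf = pd.read_csv(elements_path, sep="\t", skiprows=1, dtype=str,
                      keep_default_na=False)
    vdf = pd.read_csv(variants_path, sep="\t", skiprows=1, dtype=str,
                      keep_default_na=False)
    elements = []
    for r in edf.itertuples(index=False):
        d = dict(zip(edf.columns, r))
        elements.append(PlantedElement(
            locus_id=d["locus_id"], chrom=d["chrom"], span=_parse_iv(d["span"]),
            structure=d["structure"], strand=d["strand"], ltr_name=d["ltr_name"],
            ltr_intervals=tuple(_parse_iv(x) for x in d["ltr_intervals"].split(";")
                                if x != "."),
            internal_intervals=tuple(_parse_iv(x) for x in d["internal_intervals"].split(";")
                                     if x != "."),
            tsd_len=int(d["tsd_len"]),
            left_copy=_parse_iv(d["left_copy"]),
            right_copy=_parse_iv(d["right_copy"]),
            offset_bases=int(d["offset_bases"]),
            mutation_positions=tuple(int(x) for x in d["mutation_positions"].split(",")
                                     if x not in (".", "")),
            expected_mismatch_gap=int(d["expected_mismatch_gap"]),
            pseudo=bool(int(d["pseudo"])),
            scenarios=tuple(x for x in d["scenarios"].split(";") if x != "."),
        ))
    variants = []
    for r in vdf.itertuples(index=False):
        d = dict(zip(vdf.columns, r))
        variants.append(TruthVariant(
            accession=d["accession"], chrom=d["chrom"], start=int(d["start"]),
            end=int(d["end"]), var_subtype=d["var_subtype"],
            element_locus_id=d["element_locus_id"], intended=d["intended"],
        ))
    return SyntheticTruth(run_id=run_id, elements=tuple(elements),
                          variants=tuple(variants))


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """Planted-vs-called comparison for one pipeline run."""

    n_elements: int
    n_tsd_expected: int
    n_tsd_called: int
    n_tsd_length_exact: int
    n_tsd_mismatch_exact: int
    n_tsd_missing: int
    n_no_tsd_false_calls: int
    n_pseudo_called: int
    n_variants_scored: int
    n_classified_correct: int
    n_crossovers: int
    n_missing_candidates: int
    n_filtered_leaked: int
    tsd_details: tuple = ()
    classification_details: tuple = ()

    def summary(self) -> str:
        return (
            f"elements={self.n_elements} "
            f"tsd: {self.n_tsd_length_exact}/{self.n_tsd_expected} exact length, "
            f"{self.n_tsd_mismatch_exact}/{self.n_tsd_expected} exact mismatch count, "
            f"{self.n_tsd_missing} missing; "
            f"classification: {self.n_classified_correct}/{self.n_variants_scored} correct, "
            f"{self.n_crossovers} crossovers, {self.n_missing_candidates} missing, "
            f"{self.n_filtered_leaked} filtered-subtype leaks"
        )


def truth_compare(truth: SyntheticTruth, candidates: Sequence,
                  tsd_calls: Sequence, run_id: str | None = None) -> RecoveryReport:
    """Score pipeline output against the simulator's ground truth.

    Elements whose planted mutation load is *within* the acceptance rules
    (load <= cap(length) and implied identity > 0.75) are expected to be
    recovered at the exact planted length and mismatch count; pseudo-TSD
    elements and zero-TSD elements are tallied separately.  Variants are
    scored by intended-vs-observed classification; a crossover is a
    preintegration allele called regional or vice versa.
    """
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(
            f"run identifier mismatch: truth is {truth.run_id}, got {run_id}"
        )
    calls = {c.locus_id: c for c in tsd_calls}

    n_expected = n_called = n_len = n_mm = n_missing = 0
    n_false = n_pseudo_called = 0
    tsd_details = []
    for e in truth.elements:
        call = calls.get(e.locus_id)
        if e.pseudo:
            if call is not None:
                n_pseudo_called += 1
            continue
        if e.tsd_len == 0:
            if call is not None:
                n_false += 1
            continue
        within = (e.expected_mismatch_gap <= mismatch_cap(e.tsd_len)
                  and (e.tsd_len - e.expected_mismatch_gap) / e.tsd_len > 0.75)
        if not within:
            continue  # over-threshold loads are scored by the caller separately
        n_expected += 1
        if call is None:
            n_missing += 1
            tsd_details.append((e.locus_id, e.tsd_len, e.expected_mismatch_gap,
                                None, None))
            continue
        n_called += 1
        if call.length == e.tsd_len:
            n_len += 1
        if call.mismatch_gap_count == e.expected_mismatch_gap:
            n_mm += 1
        tsd_details.append((e.locus_id, e.tsd_len, e.expected_mismatch_gap,
                            call.length, call.mismatch_gap_count))

    by_accession: dict[str, str] = {}
    for c in candidates:
        for acc in c.variant_accession.split(";"):
            by_accession[acc] = c.status or "unclassified"

    n_scored = n_correct = n_cross = n_missing_cand = n_leaked = 0
    cls_details = []
    for v in truth.variants:
        observed = by_accession.get(v.accession, "missing")
        if v.intended == "filtered":
            if observed != "missing":
                n_leaked += 1
            continue
        n_scored += 1
        if observed == v.intended:
            n_correct += 1
        elif observed == "missing":
            n_missing_cand += 1
        elif {observed, v.intended} == {"preintegration_consistent", "regional_indel"}:
            n_cross += 1
        cls_details.append((v.accession, v.intended, observed))

    return RecoveryReport(
        n_elements=len(truth.elements),
        n_tsd_expected=n_expected,
        n_tsd_called=n_called,
        n_tsd_length_exact=n_len,
        n_tsd_mismatch_exact=n_mm,
        n_tsd_missing=n_missing,
        n_no_tsd_false_calls=n_false,
        n_pseudo_called=n_pseudo_called,
        n_variants_scored=n_scored,
        n_classified_correct=n_correct,
        n_crossovers=n_cross,
        n_missing_candidates=n_missing_cand,
        n_filtered_leaked=n_leaked,
        tsd_details=tuple(tsd_details),
        classification_details=tuple(cls_details),
    )


# ---------------------------------------------------------------------------
# Canned configurations
# ---------------------------------------------------------------------------

def study_config(seed: int = 0) -> SimConfig:
    """A study-scale synthetic genome echoing the catalogued HML-2 landscape.

    Twenty solo LTRs with conventional 5-6 bp TSDs; eight long-TSD loci
    with the lengths and mismatch loads of the reported long-duplication
    set (13, 18, 61, 96, 111-truncated-provirus, 206-provirus, 250, 450-
    provirus); preintegration-deletion scenarios on five solo-LTR loci and
    one truncated provirus, regional indels on three, plus decoy gains.
    """
    elements = []
    # conventional short-TSD solo LTRs
    for i in range(20):
        scen = ()
        if i < 4:
            scen = ("preintegration_deletion",)
        elif i < 7:
            scen = ("regional_indel",)
        elements.append(ElementSpec(
            structure="solo_ltr", tsd_len=5 + (i % 2), tsd_mutations=0,
            strand="+" if i % 2 else "-", scenarios=scen,
        ))
    long_set = [
        (13, 2, "solo_ltr"),
        (18, 2, "solo_ltr"),
        (61, 0, "solo_ltr"),
        (96, 3, "solo_ltr"),
        (111, 1, "truncated_provirus"),
        (206, 1, "provirus"),
        (250, 2, "solo_ltr"),
        (450, 0, "provirus"),
    ]
    for j, (L, m, structure) in enumerate(long_set):
        scen = ("preintegration_deletion",) if L in (111, 250) else ()
        elements.append(ElementSpec(
            structure=structure, tsd_len=L, tsd_mutations=m,
            internal_len=1500, internal_gap=(5 if j % 2 else -1),
            strand="+" if j % 2 else "-", scenarios=scen,
            offset_bases=2 if L == 96 else 0,
        ))
    # one pseudo-TSD locus: homologous flanks without an integration TSD
    elements.append(ElementSpec(structure="solo_ltr", tsd_len=0,
                                tsd_mutations=2, scenarios=("pseudo_tsd",)))
    # older-family decoy annotations that the catalogue must exclude
    elements.append(ElementSpec(structure="solo_ltr", tsd_len=0, ltr_name="LTR5B"))
    elements.append(ElementSpec(structure="solo_ltr", tsd_len=0, ltr_name="LTR5A"))
    return SimConfig(seed=seed, n_chroms=4, chrom_len=60_000,
                     elements=tuple(elements), decoy_variants=4)


def recovery_panel_config(seed: int = 0,
                          lengths: Sequence[int] = (4, 9, 10, 19, 20, 50, 111,
                                                    250, 450, 500),
                          include_overcap: bool = True) -> SimConfig:
    """Planted-TSD recovery panel: every length x mutation-load cell.

    For each length L: substitution loads 0..cap(L) (the in-band cells),
    one extra load-0 locus on the '-' strand, and - when
    ``include_overcap`` - a load of cap(L)+1 that must yield no call or a
    strictly shorter one.  Boundary offsets are left at zero here: an
    offset plus a low mutation load is evidence-identical to a slightly
    longer repeat with an edge mismatch, so offset geometries are
    exercised by dedicated tests rather than by this exact-recovery grid.
    """
    elements = []
    for L in lengths:
        cap = mismatch_cap(L)
        for m in range(cap + 1):
            elements.append(ElementSpec(structure="solo_ltr", tsd_len=L,
                                        tsd_mutations=m))
        elements.append(ElementSpec(structure="solo_ltr", tsd_len=L,
                                    tsd_mutations=0, strand="-"))
        if include_overcap:
            elements.append(ElementSpec(structure="solo_ltr", tsd_len=L,
                                        tsd_mutations=cap + 1))
    return SimConfig(seed=seed, n_chroms=6, chrom_len=45_000,
                     elements=tuple(elements))


def discrimination_config(seed: int = 0, n_loci: int = 100) -> SimConfig:
    """Preintegration vs regional-indel discrimination panel.

    ``n_loci`` solo LTRs with short TSDs (4-20 bp, mutation loads within
    both acceptance rules), alternating preintegration-deletion and
    regional-indel scenarios, plus decoy gain variants.
    """
    elements = []
    tsd_cycle = (5, 6, 4, 12, 20, 8, 15, 6, 5, 10)
    for i in range(n_loci):
        L = tsd_cycle[i % len(tsd_cycle)]
        m = 1 if (i % 4 == 0 and L >= 9) else 0
        scen = ("preintegration_deletion",) if i % 2 == 0 else ("regional_indel",)
        elements.append(ElementSpec(
            structure="solo_ltr", ltr_len=968, tsd_len=L, tsd_mutations=m,
            strand="+" if i % 3 else "-", scenarios=scen,
        ))
    return SimConfig(seed=seed, n_chroms=8, chrom_len=40_000,
                     elements=tuple(elements), decoy_variants=10)
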