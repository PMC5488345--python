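"""Readers and writers for the pipeline's external formats.

Three inputs are consumed: an indexed genome FASTA, a RepeatMasker
annotation table in the UCSC ``rmsk`` tab-separated dialect, and a DGV
(Database of Genomic Variants) structural-variant table.  Everything is
normalised at the format boundary to one internal coordinate convention:
0-based, half-open intervals on "chr"-prefixed chromosome names.  The
UCSC rmsk table is already 0-based half-open; DGV positions are 1-based
inclusive and are shifted on read (and shifted back on write), because
the two dialects disagree by exactly the off-by-one that silently breaks
interval containment tests.

Reports (candidate sites and TSD calls) are written as commented-header
TSV or as BED; both are deterministic given record order.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "RepeatRecord",
    "VariantRecord",
    "GenomeAccessor",
    "FastaGenome",
    "DictGenome",
    "normalize_chrom",
    "read_repeatmasker",
    "read_dgv",
    "write_dgv",
    "write_repeatmasker",
    "fetch_flanks",
    "write_report",
    "read_report",
]

_AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the "chrN" dialect.

    DGV omits the "chr" prefix, the UCSC tables carry it; comparisons in
    the pipeline must be dialect-insensitive.
    """
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass(frozen=True)
class RepeatRecord:
    """One row of a RepeatMasker annotation, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str = ""
    rep_family: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"repeat interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """One DGV structural-variant row after coordinate normalisation."""

    accession: str
    chrom: str
    start: int
    end: int
    var_type: str
    var_subtype: str
    sample_size: str = ""
    source: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"variant interval start >= end: {self.accession} "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAccessor:
    """Random access to an immutable genome: ``fetch`` + ``chrom_lengths``.

    ``fetch(chrom, a, b)`` returns exactly ``b - a`` uppercase characters
    over {A,C,G,T,N}; soft-masked lower-case bases are uppercased, N is
    preserved.  Subclasses provide ``_raw_fetch``.
    """

    chrom_lengths: dict

    def fetch(self, chrom: str, start: int, end: int) -> str:
        chrom = normalize_chrom(chrom)
        if chrom not in self.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        n = self.chrom_lengths[chrom]
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {chrom} (length {n})"
            )
        seq = self._raw_fetch(chrom, start, end).upper()
        if len(seq) != end - start:
            raise RuntimeError(
                f"fetch returned {len(seq)} bp for a {end - start} bp request"
            )
        return seq

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError


class FastaGenome(GenomeAccessor):
    """Indexed-FASTA genome (pyfaidx-backed); builds the .fai on demand."""

    def __init__(self, path: str | os.PathLike):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self.chrom_lengths = {
            normalize_chrom(name): len(rec) for name, rec in self._fasta.records.items()
        }
        self._names = {normalize_chrom(name): name for name in self._fasta.records}

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        if start == end:
            return ""
        return str(self._fasta[self._names[chrom]][start:end])


class DictGenome(GenomeAccessor):
    """In-memory genome backed by a {chrom: sequence} mapping."""

    def __init__(self, seqs: dict):
        self._seqs = {normalize_chrom(c): s.upper() for c, s in seqs.items()}
        self.chrom_lengths = {c: len(s) for c, s in self._seqs.items()}

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]


# ---------------------------------------------------------------------------
# RepeatMasker (UCSC rmsk dialect)
# ---------------------------------------------------------------------------

# Joined table: bin swScore milliDiv milliDel milliIns genoName genoStart
# genoEnd genoLeft strand repName repClass repFamily repStart repEnd repLeft id
_RMSK_NCOL_BIN = 17
_RMSK_NCOL_NOBIN = 16


def read_repeatmasker(path: str | os.PathLike) -> list[RepeatRecord]:
    """Read a UCSC rmsk tab-separated table into RepeatRecords.

    Both the joined-table dialect (leading ``bin`` column, 17 columns) and
    the bin-less 16-column dialect are accepted; genoStart/genoEnd are taken
    as already 0-based half-open.  '#'-prefixed header lines and blank lines
    are skipped.  The RepeatMasker complement symbol 'C' is read as '-'.
    Rows are returned in file order.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == _RMSK_NCOL_BIN:
                off = 5
            elif len(parts) == _RMSK_NCOL_NOBIN:
                off = 4
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 16 or 17 tab-separated "
                    f"columns, found {len(parts)}"
                )
            try:
                start = int(parts[off + 1])
                end = int(parts[off + 2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer genoStart/genoEnd"
                ) from None
            strand = parts[off + 4].strip()
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            try:
                rec = RepeatRecord(
                    chrom=normalize_chrom(parts[off]),
                    start=start,
                    end=end,
                    strand=strand,
                    rep_name=parts[off + 5].strip(),
                    rep_class=parts[off + 6].strip(),
                    rep_family=parts[off + 7].strip() if len(parts) > off + 7 else "",
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            records.append(rec)
    return records


def write_repeatmasker(records: Iterable[RepeatRecord], path: str | os.PathLike,
                       chrom_lengths: dict | None = None) -> None:
    """Write records in the joined (17-column, leading bin) rmsk dialect."""
    chrom_lengths = chrom_lengths or {}
    with open(path, "w") as fh:
        fh.write(
            "#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart"
            "\tgenoEnd\tgenoLeft\tstrand\trepName\trepClass\trepFamily"
            "\trepStart\trepEnd\trepLeft\tid\n"
        )
        for i, r in enumerate(records):
            geno_left = -(chrom_lengths.get(r.chrom, r.end) - r.end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        0, 10000, 0, 0, 0,
                        r.chrom, r.start, r.end, geno_left, r.strand,
                        r.rep_name, r.rep_class, r.rep_family,
                        1, r.length, 0, i + 1,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# DGV structural variants
# ---------------------------------------------------------------------------

_DGV_REQUIRED = ("variantaccession", "chr", "start", "end", "varianttype", "variantsubtype")


def read_dgv(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a DGV tab-separated variant table.

    The header must name at least variantaccession, chr, start, end,
    varianttype and variantsubtype.  DGV's 1-based inclusive positions are
    converted to 0-based half-open, and chromosome names gain the "chr"
    prefix.  Rows are returned in file order; no subtype filtering happens
    here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in _DGV_REQUIRED if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing mandatory DGV column(s): {', '.join(missing)}")
    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = dict(zip(df.columns, row))
        try:
            start1 = int(d[cols["start"]])
            end1 = int(d[cols["end"]])
        except ValueError:
            raise ValueError(f"{path}: line {idx}: non-integer coordinate") from None
        try:
            rec = VariantRecord(
                accession=d[cols["variantaccession"]].strip(),
                chrom=normalize_chrom(d[cols["chr"]]),
                start=start1 - 1,
                end=end1,
                var_type=d[cols["varianttype"]].strip(),
                var_subtype=d[cols["variantsubtype"]].strip(),
                sample_size=d.get(cols.get("samplesize", ""), ""),
                source=d.get(cols.get("reference", ""), ""),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from None
        records.append(rec)
    return records


def write_dgv(records: Iterable[VariantRecord], path: str | os.PathLike) -> None:
    """Write records back to the DGV dialect (1-based inclusive, bare chrom)."""
    with open(path, "w") as fh:
        fh.write(
            "variantaccession\tchr\tstart\tend\tvarianttype\tvariantsubtype"
            "\tsamplesize\treference\n"
        )
        for r in records:
            chrom = r.chrom[3:] if r.chrom.startswith("chr") else r.chrom
            fh.write(
                f"{r.accession}\t{chrom}\t{r.start + 1}\t{r.end}\t{r.var_type}"
                f"\t{r.var_subtype}\t{r.sample_size}\t{r.source}\n"
            )


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

def fetch_flanks(genome: GenomeAccessor, chrom: str, start: int, end: int,
                 width: int) -> tuple[str, str]:
    """Forward-strand flanks of ``width`` bp around [start, end), clipped.

    TSDs are direct repeats in genome orientation, so element strand is
    deliberately ignored here: left = genome[start-width, start) clipped at
    0, right = genome[end, end+width) clipped at the chromosome end.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    chrom = normalize_chrom(chrom)
    if chrom not in genome.chrom_lengths:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    n = genome.chrom_lengths[chrom]
    left = genome.fetch(chrom, max(0, start - width), start)
    right = genome.fetch(chrom, end, min(n, end + width))
    return left, right


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _record_columns(record) -> list[str]:
    return [f.name for f in fields(record)]


def _render_value(v) -> str:
    if v is None:
        return "."
    if isinstance(v, (frozenset, set)):
        return ",".join(sorted(map(str, v))) or "."
    if isinstance(v, tuple):
        if len(v) == 2 and all(isinstance(x, int) for x in v):
            return f"{v[0]}-{v[1]}"
        return ";".join(_render_value(x) for x in v) or "."
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def _as_row(record) -> list[str]:
    return [_render_value(getattr(record, f.name)) for f in fields(record)]


def write_report(records: Sequence, path: str | os.PathLike, fmt: str = "tsv",
                 header_extra: Sequence[str] = ()) -> None:
    """Write a homogeneous record sequence as TSV (commented header) or BED.

    BED lines are 0-based half-open.  TSD calls emit one BED line per TSD
    copy (two per call); candidate sites emit one line per deletion
    interval.  Output is deterministic given record order.
    """
    if fmt not in ("tsv", "bed"):
        raise ValueError(f"unknown report format {fmt!r}")
    buf = io.StringIO()
    if fmt == "tsv":
        for line in header_extra:
            buf.write(f"# {line}\n")
        if records:
            buf.write("# " + "\t".join(_record_columns(records[0])) + "\n")
        else:
            buf.write("# (empty report)\n")
        for r in records:
            buf.write("\t".join(_as_row(r)) + "\n")
    else:
        for r in records:
            if hasattr(r, "left_interval"):  # a TSD call: one line per copy
                for tag, (a, b) in (("L", r.left_interval), ("R", r.right_interval)):
                    buf.write(f"{r.chrom}\t{a}\t{b}\t{r.locus_id}|TSD_{tag}\n")
            elif hasattr(r, "deletion_start"):  # a candidate site
                buf.write(
                    f"{r.chrom}\t{r.deletion_start}\t{r.deletion_end}"
                    f"\t{r.locus_id}|{r.variant_accession}\n"
                )
            else:
                raise TypeError(f"cannot render {type(r).__name__} as BED")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_report(path: str | os.PathLike, record_type) -> list:
    """Read back a TSV report written by :func:`write_report`.

    ``record_type`` is the dataclass the report was written from; interval
    columns ("a-b") become tuples and "." becomes None.
    """
    recs = []
    colnames = [f.name for f in fields(record_type)]
    types = {f.name: f.type for f in fields(record_type)}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(colnames):
                raise ValueError(f"{path}: expected {len(colnames)} columns, got {len(parts)}")
            kwargs = {}
            for name, raw in zip(colnames, parts):
                t = str(types[name])
                if raw == ".":
                    kwargs[name] = None
                elif "tuple" in t:
                    a, b = raw.rsplit("-", 1)
                    kwargs[name] = (int(a), int(b))
                elif "int" in t:
                    kwargs[name] = int(raw)
                elif "float" in t:
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
            recs.append(record_type(**kwargs))
    return recs
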