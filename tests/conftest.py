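import numpy as np
import pytest

from hml2scan.genome_io import DictGenome, RepeatRecord
from hml2scan.hml2_catalog import Hml2Locus

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_solo_locus(chrom="chr1", start=5000, end=5968, strand="+",
                    flags=frozenset()) -> Hml2Locus:
    return Hml2Locus(
        locus_id=f"{chrom}:{start + 1}-{end}",
        chrom=chrom,
        span=(start, end),
        strand=strand,
        structure="solo_ltr",
        ltr_intervals=((start, end),),
        flags=flags,
    )


def ltr(chrom, start, end, strand="+", name="LTR5_Hs") -> RepeatRecord:
    return RepeatRecord(chrom, start, end, strand, name, "LTR", "ERVK")


def internal(chrom, start, end, strand="+") -> RepeatRecord:
    return RepeatRecord(chrom, start, end, strand, "HERVK-int", "LTR", "ERVK")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_genome():
    """A tiny genome with one solo LTR bracketed by an exact 12-bp TSD."""
    rng = np.random.default_rng(7)
    tsd = "ACGTTGCAGGAT"
    left_bg = random_seq(rng, 600)
    body = random_seq(rng, 300)
    right_bg = random_seq(rng, 600)
    # guard bases so the planted repeat cannot be extended by chance
    if left_bg.endswith(tsd[0]):
        left_bg = left_bg[:-1] + ("C" if tsd[0] != "C" else "G")
    if right_bg.startswith(tsd[-1]):
        right_bg = ("C" if tsd[-1] != "C" else "G") + right_bg[1:]
    seq = left_bg + tsd + body + tsd + right_bg
    start = len(left_bg) + len(tsd)
    end = start + len(body)
    genome = DictGenome({"chr1": seq})
    locus = make_solo_locus("chr1", start, end)
    return genome, locus, tsd
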