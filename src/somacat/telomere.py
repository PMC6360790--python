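"""Relative telomere length from motif-bearing read counts.

Reads containing tandem copies of the telomeric repeat are counted,
normalised by mean genomic coverage, and the tumour (or Barrett's) sample
is expressed as a log2 ratio against its matched normal.  Zero means equal
telomere content; negative values mean telomere shortening in the tumour.

The canonical human telomeric repeat TTAGGG is the default motif; the
variant spelling TTAAGG used by some counting tools is selectable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

CANONICAL_MOTIF = "TTAGGG"

_ACGT = set("ACGT")


@dataclass(frozen=True)
class TelomereInput:
    """Motif-read count plus mean genomic coverage for one sample."""

    sample_id: str
    motif_read_count: int
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.motif_read_count < 0:
            raise ValueError("motif_read_count must be >= 0")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")

    @property
    def normalised_count(self) -> float:
        return self.motif_read_count / self.mean_coverage


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def count_motif_reads(
    reads: Iterable[str],
    motif: str = CANONICAL_MOTIF,
    min_copies: int = 3,
) -> int:
    """Count reads containing >= min_copies tandem copies of the motif.

    Both the motif and its reverse complement are searched, so reads from
    either strand of the telomere are counted.
    """
    motif = motif.upper()
    if not motif or not set(motif) <= _ACGT:
        raise ValueError(f"motif must be a non-empty ACGT string, got {motif!r}")
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    pattern = re.compile(
        f"(?:{re.escape(motif)}){{{min_copies},}}|(?:{re.escape(_revcomp(motif))}){{{min_copies},}}"
    )
    return sum(1 for read in reads if pattern.search(read.upper()))


def count_motif_reads_fastq(path, motif: str = CANONICAL_MOTIF, min_copies: int = 3) -> int:
    """Count motif-bearing reads straight from a FASTQ file (optionally gzip)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return count_motif_reads((entry.sequence for entry in fh), motif, min_copies)


def telomere_ratio(tumour: TelomereInput, normal: TelomereInput) -> float | None:
    """log2 of coverage-normalised motif-read counts, tumour over normal.

    Returns None (undefined, flagged upstream) when either count is zero
    rather than raising.
    """
    if tumour.motif_read_count == 0 or normal.motif_read_count == 0:
        return None
    return math.log2(tumour.normalised_count / normal.normalised_count)
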