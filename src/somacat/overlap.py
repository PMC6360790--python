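"""Weak-evidence variant sharing between two samples of one donor.

A variant called in one sample is deemed present in the other when a
pileup at that position shows no alternate allele in the matched normal,
at least 10 reads of coverage, and at least one good-quality
alt-supporting read — where good quality means non-duplicate, mapping
quality >= 10, >= 34 aligned bases and <= 3 mismatches.  The overlap
fraction is reported over the union of both call sets and per direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadQualityFilter:
    """Read-level quality thresholds for pileup evidence."""

    exclude_duplicates: bool = True
    min_mapping_quality: int = 10
    min_aligned_bases: int = 34
    max_mismatches: int = 3


DEFAULT_FILTER = ReadQualityFilter()


@dataclass(frozen=True)
class PileupEvidence:
    """Evidence for one variant position in one queried sample."""

    chrom: str
    pos: int
    coverage: int
    good_alt_reads: int
    normal_alt_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.good_alt_reads <= self.coverage):
            raise ValueError("good_alt_reads must be within [0, coverage]")
        if self.normal_alt_reads < 0:
            raise ValueError("normal_alt_reads must be >= 0")


def is_good_read(
    duplicate: bool,
    mapping_quality: int,
    aligned_bases: int,
    mismatches: int,
    filter: ReadQualityFilter = DEFAULT_FILTER,
) -> bool:
    """Whether a read passes the pileup quality filter."""
    if filter.exclude_duplicates and duplicate:
        return False
    return (
        mapping_quality >= filter.min_mapping_quality
        and aligned_bases >= filter.min_aligned_bases
        and mismatches <= filter.max_mismatches
    )


def variant_present(
    evidence: PileupEvidence,
    min_coverage: int = 10,
    min_good_alt: int = 1,
) -> bool:
    """Weak-evidence presence call at one position.

    Requires a clean matched normal (zero alt reads), adequate coverage
    and at least one good-quality alt-supporting read.
    """
    return (
        evidence.normal_alt_reads == 0
        and evidence.coverage >= min_coverage
        and evidence.good_alt_reads >= min_good_alt
    )


@dataclass(frozen=True)
class OverlapResult:
    """Sharing fractions for a sample pair."""

    union_fraction: float
    fraction_a_in_b: float
    fraction_b_in_a: float
    n_union: int
    n_calls_a: int
    n_calls_b: int


VariantKey = Hashable  # typically (chrom, pos) or (chrom, pos, ref, alt)


def overlap_fraction(
    calls_a: Iterable[VariantKey],
    calls_b: Iterable[VariantKey],
    evidence_a: Mapping[VariantKey, PileupEvidence],
    evidence_b: Mapping[VariantKey, PileupEvidence],
    min_coverage: int = 10,
) -> OverlapResult:
    """Fraction of union variants with evidence present in both samples.

    A union variant counts as present in a sample when
    :func:`variant_present` holds for that sample's pileup evidence at the
    position.  Variants missing an evidence row are counted absent and
    logged.  The union metric is symmetric under swapping the samples;
    per-direction fractions (calls of one sample with evidence in the
    other) are also reported.
    """
    set_a, set_b = set(calls_a), set(calls_b)
    union = set_a | set_b

    def present(v: VariantKey, evidence: Mapping[VariantKey, PileupEvidence]) -> bool:
        ev = evidence.get(v)
        if ev is None:
            logger.warning("no pileup evidence for %s; counting absent", v)
            return False
        return variant_present(ev, min_coverage=min_coverage)

    in_a = {v for v in union if present(v, evidence_a)}
    in_b = {v for v in union if present(v, evidence_b)}
    both = in_a & in_b

    def frac(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return OverlapResult(
        union_fraction=frac(len(both), len(union)),
        fraction_a_in_b=frac(sum(1 for v in set_a if v in in_b), len(set_a)),
        fraction_b_in_a=frac(sum(1 for v in set_b if v in in_a), len(set_b)),
        n_union=len(union),
        n_calls_a=len(set_a),
        n_calls_b=len(set_b),
    )
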