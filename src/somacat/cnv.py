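"""Ploidy-conditional copy-number event calling on segment tables.

Only high-level events are called, gated by the sample's average genome
ploidy: an amplification needs total CN >= 6 in a near-diploid genome
(ploidy <= 2.7) but >= 9 in a duplicated genome; a loss is a homozygous
deletion (CN = 0) when near-diploid, or CN < ploidy - 2.7 when duplicated.
A second, ploidy-independent deletion definition (CN <= 1) is used for
genome-fraction-altered summaries; both are exposed behind a switch because
the two conventions serve different reporting purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLOIDY_CUTOFF = 2.7
AMP_CN_DIPLOID = 6.0
AMP_CN_DUPLICATED = 9.0


@dataclass(frozen=True)
class CnSegment:
    """One allele-specific copy-number segment (1-based inclusive bp)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")
        if self.minor_cn is not None and self.minor_cn > self.total_cn + 1e-9:
            raise ValueError("minor_cn exceeds total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleCnProfile:
    """A sample's segments plus its average genome ploidy."""

    sample_id: str
    segments: list[CnSegment]
    ploidy: float

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        by_chrom: dict[str, list[CnSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")
        self._by_chrom = {c: sorted(v, key=lambda s: s.start) for c, v in by_chrom.items()}

    def chromosome_segments(self, chrom: str) -> list[CnSegment]:
        return self._by_chrom.get(chrom, [])

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)


def call_amplification(total_cn: float, ploidy: float) -> bool:
    """High-level amplification, gated by average genome ploidy."""
    if ploidy <= PLOIDY_CUTOFF:
        return total_cn >= AMP_CN_DIPLOID
    return total_cn >= AMP_CN_DUPLICATED


def call_loss(total_cn: float, ploidy: float) -> bool:
    """Homozygous deletion (near-diploid) or significant loss (duplicated)."""
    if ploidy <= PLOIDY_CUTOFF:
        return total_cn == 0
    return total_cn < ploidy - PLOIDY_CUTOFF


def _segment_altered(seg: CnSegment, ploidy: float, deletion_rule: str) -> bool:
    if deletion_rule == "methods":
        return call_amplification(seg.total_cn, ploidy) or call_loss(seg.total_cn, ploidy)
    if deletion_rule == "results":
        return seg.total_cn <= 1 or seg.total_cn >= AMP_CN_DIPLOID
    raise ValueError(f"unknown deletion_rule {deletion_rule!r} (use 'methods' or 'results')")


def genome_fraction_altered(
    profile: SampleCnProfile,
    genome_size: int,
    deletion_rule: str = "results",
) -> float:
    """Fraction of the genome in amplified or deleted segments.

    ``deletion_rule='results'`` uses the ploidy-independent convention
    (deletion CN <= 1, amplification CN >= 6); ``'methods'`` uses the
    ploidy-gated event calls.
    """
    covered = sum(s.length for s in profile.segments)
    if genome_size < covered:
        raise ValueError(f"genome_size {genome_size} smaller than covered length {covered}")
    altered = sum(
        s.length for s in profile.segments if _segment_altered(s, profile.ploidy, deletion_rule)
    )
    return altered / genome_size


def call_events(profile: SampleCnProfile) -> pd.DataFrame:
    """Per-segment ploidy-gated amplification/loss calls."""
    rows = []
    for seg in profile.segments:
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "total_cn": seg.total_cn,
                "minor_cn": seg.minor_cn,
                "amplified": call_amplification(seg.total_cn, profile.ploidy),
                "lost": call_loss(seg.total_cn, profile.ploidy),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn", "amplified", "lost"],
    )


def annotate_genes(profile: SampleCnProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Highest-severity copy-number call per gene interval.

    ``genes`` carries 1-based inclusive chrom/start/end/name (BED input is
    converted on read).  A gene is amplified/lost if any overlapping
    segment (>= 1 bp intersection) is so called; both flags can co-occur
    and genes with no overlapping segment are flagged uncovered.
    """
    rows = []
    for g in genes.itertuples(index=False):
        segs = [
            s
            for s in profile.chromosome_segments(str(g.chrom))
            if s.start <= g.end and s.end >= g.start
        ]
        rows.append(
            {
                "gene": g.name,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "amplified": any(call_amplification(s.total_cn, profile.ploidy) for s in segs),
                "lost": any(call_loss(s.total_cn, profile.ploidy) for s in segs),
                "uncovered": len(segs) == 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "amplified", "lost", "uncovered"]
    )


def profiles_from_frame(segments: pd.DataFrame, ploidies: dict[str, float]) -> dict[str, SampleCnProfile]:
    """Build per-sample profiles from a segment table plus a ploidy map."""
    profiles: dict[str, SampleCnProfile] = {}
    for sid, group in segments.groupby("sample_id"):
        if sid not in ploidies:
            raise ValueError(f"no ploidy for sample {sid}")
        segs = [
            CnSegment(
                sample_id=str(sid),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                total_cn=float(r.total_cn),
                minor_cn=float(r.minor_cn) if "minor_cn" in segments.columns and not pd.isna(r.minor_cn) else None,
            )
            for r in group.itertuples(index=False)
        ]
        profiles[str(sid)] = SampleCnProfile(sample_id=str(sid), segments=segs, ploidy=ploidies[sid])
    return profiles
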