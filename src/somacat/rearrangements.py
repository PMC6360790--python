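"""Structural-variant classification into the 32-subclass rearrangement scheme.

Events are typed (deletion, duplication, inversion, translocation), sized
into five bins, and flagged clustered or non-clustered from breakend
density: breakends are grouped per chromosome by single-linkage interval
clustering at the window size, and a group whose breakends include a 1 Mb
span holding at least ``min_count`` breakends is clustered.  The resulting
{clustered, non-clustered} x ({del, dup, inv} x 5 size bins + translocation)
histogram — 32 classes — feeds the shared signature machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SV_TYPES = ("del", "dup", "inv", "translocation")

_TYPE_ALIASES = {
    "del": "del", "deletion": "del",
    "dup": "dup", "duplication": "dup", "tandem-duplication": "dup",
    "inv": "inv", "inversion": "inv",
    "translocation": "translocation", "tra": "translocation", "ctx": "translocation",
}

SIZE_BIN_LABELS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SIZE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)  # half-open upper edges


def _build_class_labels() -> tuple[str, ...]:
    labels = []
    for clust in ("clustered", "non-clustered"):
        for typ in ("del", "dup", "inv"):
            for size in SIZE_BIN_LABELS:
                labels.append(f"{clust}:{typ}:{size}")
        labels.append(f"{clust}:translocation")
    return tuple(labels)


#: The 32 rearrangement class labels: 2 x (3 types x 5 sizes + translocation).
REARRANGEMENT_LABELS: tuple[str, ...] = _build_class_labels()
_LABEL_INDEX = {lab: i for i, lab in enumerate(REARRANGEMENT_LABELS)}


@dataclass(frozen=True)
class SvEvent:
    """A paired-breakend structural variant (1-based coordinates).

    Intra-chromosomal events are normalised so pos1 <= pos2; the
    ``clustered`` flag is assigned by :func:`cluster_breakpoints`, never
    taken from input.
    """

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    clustered: bool = False

    def __post_init__(self) -> None:
        typ = _TYPE_ALIASES.get(self.sv_type.lower())
        if typ is None:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        object.__setattr__(self, "sv_type", typ)
        if typ == "translocation":
            if self.chrom1 == self.chrom2:
                raise ValueError("translocation must join two chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{typ} must be intra-chromosomal")
            if self.pos1 > self.pos2:
                lo, hi = self.pos2, self.pos1
                object.__setattr__(self, "pos1", lo)
                object.__setattr__(self, "pos2", hi)
            if self.size <= 0:
                raise ValueError("intra-chromosomal event must have positive size")

    @property
    def size(self) -> int | None:
        """Event size in bp; undefined (None) for translocations."""
        if self.sv_type == "translocation":
            return None
        return abs(self.pos2 - self.pos1)

    @property
    def breakends(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom1, self.pos1), (self.chrom2, self.pos2))


@dataclass
class RearrangementCatalogue:
    """Counts over the 32 rearrangement classes for one sample."""

    sample_id: str
    counts: np.ndarray
    class_labels: Sequence[str] = field(default=REARRANGEMENT_LABELS)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.class_labels), name=self.sample_id)


def assign_size_bin(size: int) -> str:
    """Half-open size bins; events under 1 kb fall into the smallest bin."""
    if size is None or size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if size < 1000:
        logger.info("event of %d bp (< 1 kb) assigned to smallest bin", size)
    for edge, label in zip(_SIZE_EDGES, SIZE_BIN_LABELS):
        if size < edge:
            return label
    return SIZE_BIN_LABELS[-1]


def classify_event(event: SvEvent) -> str:
    """32-class label for a (clustered-flagged) event."""
    prefix = "clustered" if event.clustered else "non-clustered"
    if event.sv_type == "translocation":
        return f"{prefix}:translocation"
    return f"{prefix}:{event.sv_type}:{assign_size_bin(event.size)}"


def cluster_breakpoints(
    events: Sequence[SvEvent],
    window: int = 1_000_000,
    min_count: int = 10,
) -> list[SvEvent]:
    """Assign clustered flags from breakend density (one sample's events).

    Each event contributes both breakends.  Per chromosome, breakends are
    single-linkage grouped (linked when within ``window`` bp); a group is
    clustered when it has >= ``min_count`` breakends and some ``window``-bp
    span inside it holds >= ``min_count`` of them.  An event is clustered
    iff either of its breakends lies in a clustered group.  Order-independent.
    """
    # (chrom, pos, event index) for every breakend
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, ev in enumerate(events):
        for chrom, pos in ev.breakends:
            by_chrom.setdefault(chrom, []).append((pos, idx))

    clustered_events: set[int] = set()
    for chrom, ends in by_chrom.items():
        ends.sort()
        pos = np.array([p for p, _ in ends], dtype=np.int64)
        # single-linkage groups: split where the gap exceeds the window
        split = np.flatnonzero(np.diff(pos) > window)
        bounds = np.concatenate([[0], split + 1, [len(pos)]])
        for gi in range(len(bounds) - 1):
            lo, hi = bounds[gi], bounds[gi + 1]
            group = pos[lo:hi]
            if len(group) < min_count:
                continue
            # sliding window: does any window-bp span hold >= min_count?
            j = np.searchsorted(group, group + window, side="right")
            if (j - np.arange(len(group)) >= min_count).any():
                clustered_events.update(idx for _p, idx in ends[lo:hi])

    return [replace(ev, clustered=(i in clustered_events)) for i, ev in enumerate(events)]


def build_rearrangement_catalogue(events: Iterable[SvEvent], sample_id: str | None = None) -> RearrangementCatalogue:
    """Histogram a sample's clustered-flagged events over the 32 classes."""
    events = list(events)
    counts = np.zeros(len(REARRANGEMENT_LABELS), dtype=np.int64)
    sid = sample_id
    for ev in events:
        if sid is None:
            sid = ev.sample_id
        counts[_LABEL_INDEX[classify_event(ev)]] += 1
    return RearrangementCatalogue(sample_id=sid or "sample", counts=counts)


def catalogue_matrix(catalogues: Sequence[RearrangementCatalogue]) -> pd.DataFrame:
    """32 classes x samples matrix ready for signature extraction."""
    return pd.DataFrame(
        {c.sample_id: c.counts for c in catalogues}, index=list(REARRANGEMENT_LABELS)
    )


def select_samples_for_signatures(
    catalogues: Sequence[RearrangementCatalogue],
    min_sv: int = 10,
) -> tuple[list[RearrangementCatalogue], list[RearrangementCatalogue]]:
    """Partition samples into (included, excluded) by total SV count.

    Samples with fewer than ``min_sv`` events carry too little information
    for rearrangement-signature extraction and are excluded (logged).
    """
    if min_sv < 1:
        raise ValueError("min_sv must be >= 1")
    included = [c for c in catalogues if c.total >= min_sv]
    excluded = [c for c in catalogues if c.total < min_sv]
    for c in excluded:
        logger.info("excluding %s (%d SV events < %d)", c.sample_id, c.total, min_sv)
    if len(included) < 2:
        raise ValueError(
            f"only {len(included)} sample(s) have >= {min_sv} SV events; "
            "signature extraction needs at least 2"
        )
    return included, excluded


def events_from_frame(df: pd.DataFrame) -> list[SvEvent]:
    """Build events from a frame with sample_id, chrom1, pos1, chrom2, pos2, sv_type."""
    return [
        SvEvent(
            sample_id=str(r.sample_id),
            chrom1=str(r.chrom1),
            pos1=int(r.pos1),
            chrom2=str(r.chrom2),
            pos2=int(r.pos2),
            sv_type=str(r.sv_type),
        )
        for r in df.itertuples(index=False)
    ]
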