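"""Kataegis detection from inter-mutation distances.

Somatic substitutions are ordered by chromosome and position; the
inter-mutation distance (IMD) sequence is log10-transformed and segmented
by exact penalised least-squares piecewise constant fitting (PCF).  A
segment spanning IMDs d_i..d_j covers mutations i..j+1 and is emitted as a
kataegis region when it contains at least ``min_mutations`` (default 6)
mutations and the mean IMD on the raw bp scale is at most ``max_mean_imd``
(default 1000 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalogue import MutationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KataegisRegion:
    """A localised hypermutation cluster (coordinates 1-based, inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float
    adjacent: bool = False  # True when it abuts another qualifying segment


def intermutation_distances(
    records: Iterable[MutationRecord],
) -> dict[str, np.ndarray]:
    """Per-chromosome ordered IMD arrays for one sample's SNVs.

    Duplicate positions are collapsed with a warning; chromosomes with
    fewer than two mutations yield empty arrays.
    """
    positions: dict[str, list[int]] = {}
    for rec in records:
        positions.setdefault(rec.chrom, []).append(rec.pos)
    out: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        arr = np.unique(np.asarray(pos, dtype=np.int64))
        if len(arr) < len(pos):
            logger.warning("%s: collapsed %d duplicate position(s)", chrom, len(pos) - len(arr))
        out[chrom] = np.diff(arr) if len(arr) >= 2 else np.array([], dtype=np.int64)
    return out


def pcf_segment(
    values: Sequence[float],
    gamma: float,
    kmin: int = 1,
) -> list[tuple[int, int, float]]:
    """Exact penalised piecewise-constant segmentation.

    Minimises sum of within-segment squared error plus ``gamma`` per
    segment, over all partitions into segments of length >= ``kmin``, by
    dynamic programming.  Returns (start_index, end_index, segment_mean)
    triples (inclusive indices) partitioning the input.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("empty input")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if n < kmin:
        # single segment is the only admissible partition
        return [(0, n - 1, float(y.mean()))]

    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    INF = np.inf
    # best[j] = min cost of segmenting the first j points
    best = np.full(n + 1, INF)
    back = np.full(n + 1, -1, dtype=int)
    best[0] = 0.0
    for end in range(kmin, n + 1):  # end = number of points covered
        # candidate segment starts i: final segment y[i..end-1] has >= kmin
        # points; best[i] is finite only for admissible prefixes
        i_arr = np.arange(0, end - kmin + 1)
        n_seg = end - i_arr
        s = c1[end] - c1[i_arr]
        q = c2[end] - c2[i_arr]
        sse = q - s * s / n_seg
        costs = best[i_arr] + gamma + sse
        pick = int(np.argmin(costs))
        if not np.isfinite(costs[pick]):
            continue
        best[end] = costs[pick]
        back[end] = int(i_arr[pick])

    if not np.isfinite(best[n]):
        # no partition with all segments >= kmin (n < 2*kmin and n >= kmin
        # handled above); fall back to single segment
        return [(0, n - 1, float(y.mean()))]

    bounds = []
    end = n
    while end > 0:
        start = back[end]
        bounds.append((start, end - 1))
        end = start
    bounds.reverse()
    return [(i, j, float(y[i : j + 1].mean())) for i, j in bounds]


def pcf_objective(values: Sequence[float], segments: Sequence[tuple[int, int, float]], gamma: float) -> float:
    """Penalised objective of a segmentation (for exactness checks)."""
    y = np.asarray(values, dtype=float)
    total = gamma * len(segments)
    for i, j, _m in segments:
        seg = y[i : j + 1]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total


def call_kataegis(
    records: Iterable[MutationRecord],
    gamma: float = 12.0,
    kmin: int = 2,
    min_mutations: int = 6,
    max_mean_imd: float = 1000.0,
) -> list[KataegisRegion]:
    """Detect kataegis regions for one or more samples.

    Segmentation runs per sample per chromosome on log10 IMDs; the mean-IMD
    threshold is evaluated on the raw bp scale.  Adjacent qualifying
    segments are emitted separately and flagged.
    """
    by_sample: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    regions: list[KataegisRegion] = []
    for sample_id, recs in sorted(by_sample.items()):
        by_chrom: dict[str, list[int]] = {}
        for rec in recs:
            by_chrom.setdefault(rec.chrom, []).append(rec.pos)
        for chrom, raw_pos in sorted(by_chrom.items()):
            pos = np.unique(np.asarray(raw_pos, dtype=np.int64))
            if len(pos) < 2:
                continue
            imd = np.diff(pos).astype(float)
            logd = np.log10(np.maximum(imd, 1.0))
            segments = pcf_segment(logd, gamma=gamma, kmin=kmin)
            qualifying = []
            for i, j, _mean in segments:
                n_mut = j - i + 2  # IMDs i..j span mutations i..j+1
                mean_imd = float(imd[i : j + 1].mean())
                if n_mut >= min_mutations and mean_imd <= max_mean_imd:
                    qualifying.append((i, j, n_mut, mean_imd))
            for idx, (i, j, n_mut, mean_imd) in enumerate(qualifying):
                adjacent = any(
                    q[1] + 1 == i or j + 1 == q[0] for qi, q in enumerate(qualifying) if qi != idx
                )
                regions.append(
                    KataegisRegion(
                        sample_id=sample_id,
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j + 1]),
                        n_mutations=n_mut,
                        mean_imd=mean_imd,
                        adjacent=adjacent,
                    )
                )
    return regions


def regions_to_bed(regions: Iterable[KataegisRegion]) -> pd.DataFrame:
    """BED-like frame (0-based half-open) for export."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start - 1,
            "end": r.end,
            "sample_id": r.sample_id,
            "n_mutations": r.n_mutations,
            "mean_imd": r.mean_imd,
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "n_mutations", "mean_imd"])


def rainfall_points(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """(chrom, position, IMD to previous mutation) triples for rainfall export."""
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec.pos)
    for chrom, pos in sorted(by_chrom.items()):
        arr = np.unique(pos)
        for i in range(1, len(arr)):
            rows.append({"chrom": chrom, "pos": int(arr[i]), "imd": int(arr[i] - arr[i - 1])})
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd"])
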