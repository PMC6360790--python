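"""Criteria-based detection of localised complex genomic events.

Per chromosome, a deterministic feature vector is computed from the SV
events and copy-number segments, and three conjunctive rules flag:

* chromothripsis-like — long oscillation between two copy-number states,
  clustered SVs, retained heterozygosity in the oscillating region, and a
  diverse ("random-join") mix of SV types;
* BFB-like — telomeric loss plus a high inversion-breakend fraction plus a
  ploidy-gated amplification;
* local complexity — clustered SV breakpoints with several copy-number
  changepoints or an extreme amplification (CN > 9).

All thresholds are explicit configuration: the underlying criteria were
designed for expert manual review, so the defaults here operationalise
them rather than reproduce any particular reviewer's judgement.  SV-type
diversity is measured as normalised Shannon entropy of the chromosome's
event-type composition — a stated proxy for "random joins".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import SampleCnProfile, call_amplification, call_loss
from .rearrangements import SvEvent

SV_TYPE_SET = ("del", "dup", "inv", "translocation")


@dataclass(frozen=True)
class ComplexEventThresholds:
    """Tunable rule thresholds (all artifact configuration, documented)."""

    osc_min: int = 8                  # min alternation length - 1 for oscillation
    het_min: float = 0.5              # min fraction of oscillating segments with minor CN >= 1
    entropy_min: float = 0.5          # min normalised SV-type entropy ("random joins" proxy)
    inv_min: float = 0.5              # min inversion-breakend fraction for BFB
    amp_min: float = 6.0              # amplification gate (ploidy rule applies)
    cp_min: int = 3                   # min copy-number changepoints for local complexity
    extreme_amp_cn: float = 9.0       # CN above which a region counts as highly amplified
    telomere_window: int = 1_000_000  # bp from a chromosome end that counts as telomeric


DEFAULT_THRESHOLDS = ComplexEventThresholds()


@dataclass
class ChromosomeFeatures:
    """Deterministic per-chromosome feature vector."""

    sample_id: str
    chrom: str
    n_breakends: int = 0
    inversion_breakend_fraction: float = 0.0
    n_cn_oscillations: int = 0
    max_total_cn: float = 0.0
    telomeric_loss: bool = False
    het_retention_fraction: float = 0.0
    has_clustered_sv: bool = False
    n_cn_changepoints: int = 0
    sv_type_entropy: float = 0.0


@dataclass
class ComplexEventReport:
    """Flags plus the rule trace that produced them."""

    features: ChromosomeFeatures
    flags: list[str] = field(default_factory=list)
    rule_trace: list[str] = field(default_factory=list)


def _longest_two_state_alternation(values: np.ndarray) -> tuple[int, int, int]:
    """Longest run alternating between exactly two distinct values.

    Returns (run_length, start_index, end_index); run_length 0 or 1 means
    no alternation.
    """
    n = len(values)
    if n < 2:
        return (n, 0, max(n - 1, 0))
    best_len, best_i, best_j = 1, 0, 0
    i = 0
    while i < n - 1:
        if values[i + 1] == values[i]:
            i += 1
            continue
        a, b = values[i], values[i + 1]
        j = i + 1
        while j + 1 < n:
            expect = a if (j + 1 - i) % 2 == 0 else b
            if values[j + 1] == expect:
                j += 1
            else:
                break
        if j - i + 1 > best_len:
            best_len, best_i, best_j = j - i + 1, i, j
        i = j if j > i else i + 1
    return (best_len, best_i, best_j)


def sv_type_entropy(events: Sequence[SvEvent]) -> float:
    """Normalised Shannon entropy of SV-type composition (0..1)."""
    if not events:
        return 0.0
    counts = np.array([sum(1 for e in events if e.sv_type == t) for t in SV_TYPE_SET], dtype=float)
    p = counts[counts > 0] / counts.sum()
    if len(p) <= 1:
        return 0.0
    return float(-(p * np.log(p)).sum() / math.log(len(SV_TYPE_SET)))


def chromosome_features(
    events: Sequence[SvEvent],
    profile: SampleCnProfile,
    chrom: str,
    chrom_size: int | None = None,
    thresholds: ComplexEventThresholds = DEFAULT_THRESHOLDS,
) -> ChromosomeFeatures:
    """Compute the feature vector for one sample chromosome.

    ``events`` should already carry clustered flags; only breakends on
    ``chrom`` contribute.  ``chrom_size`` anchors the telomeric windows;
    when absent the covered segment extent is used as a proxy.
    """
    feats = ChromosomeFeatures(sample_id=profile.sample_id, chrom=chrom)

    chrom_events = [e for e in events if chrom in (e.chrom1, e.chrom2)]
    breakends = [(c, p) for e in chrom_events for (c, p) in e.breakends if c == chrom]
    feats.n_breakends = len(breakends)
    if breakends:
        inv_be = sum(
            1 for e in chrom_events for (c, _p) in e.breakends if c == chrom and e.sv_type == "inv"
        )
        feats.inversion_breakend_fraction = inv_be / len(breakends)
    feats.has_clustered_sv = any(e.clustered for e in chrom_events)
    feats.sv_type_entropy = sv_type_entropy(chrom_events)

    segments = profile.chromosome_segments(chrom)
    if segments:
        cn = np.array([round(s.total_cn) for s in segments], dtype=int)
        feats.max_total_cn = float(max(s.total_cn for s in segments))
        feats.n_cn_changepoints = int((np.diff(cn) != 0).sum())
        run_len, i, j = _longest_two_state_alternation(cn)
        feats.n_cn_oscillations = max(run_len - 1, 0)
        osc_segments = segments[i : j + 1] if run_len >= 2 else []
        with_minor = [s for s in osc_segments if s.minor_cn is not None]
        if with_minor:
            feats.het_retention_fraction = sum(1 for s in with_minor if s.minor_cn >= 1) / len(with_minor)
        # telomeric loss: a lost/deleted segment near either chromosome end
        extent_end = chrom_size if chrom_size is not None else max(s.end for s in segments)
        win = thresholds.telomere_window
        for s in segments:
            deleted = call_loss(s.total_cn, profile.ploidy) or s.total_cn <= 1
            if deleted and (s.start <= win or s.end >= extent_end - win + 1):
                feats.telomeric_loss = True
                break
    return feats


def flag_chromothripsis(
    features: ChromosomeFeatures,
    thresholds: ComplexEventThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, list[str]]:
    """Oscillating CN + clustered SVs + retained heterozygosity + diverse joins."""
    trace = []
    if features.n_cn_oscillations >= thresholds.osc_min:
        trace.append(f"n_cn_oscillations={features.n_cn_oscillations}>={thresholds.osc_min}")
    if features.has_clustered_sv:
        trace.append("has_clustered_sv")
    if features.het_retention_fraction >= thresholds.het_min:
        trace.append(f"het_retention_fraction={features.het_retention_fraction:.2f}>={thresholds.het_min}")
    if features.sv_type_entropy >= thresholds.entropy_min:
        trace.append(f"sv_type_entropy={features.sv_type_entropy:.2f}>={thresholds.entropy_min}")
    return (len(trace) == 4, trace)


def flag_bfb(
    features: ChromosomeFeatures,
    ploidy: float,
    thresholds: ComplexEventThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, list[str]]:
    """Telomeric loss + inversion-dominated breakends + focal amplification."""
    trace = []
    if features.telomeric_loss:
        trace.append("telomeric_loss")
    if features.inversion_breakend_fraction >= thresholds.inv_min:
        trace.append(
            f"inversion_breakend_fraction={features.inversion_breakend_fraction:.2f}>={thresholds.inv_min}"
        )
    if call_amplification(features.max_total_cn, ploidy):
        trace.append(f"max_total_cn={features.max_total_cn:g} amplified at ploidy {ploidy:g}")
    return (len(trace) == 3, trace)


def flag_local_complexity(
    features: ChromosomeFeatures,
    thresholds: ComplexEventThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, list[str]]:
    """Clustered breakpoints with CN changes or extreme amplification."""
    trace = []
    if not features.has_clustered_sv:
        return (False, trace)
    trace.append("has_clustered_sv")
    fired = False
    if features.n_cn_changepoints >= thresholds.cp_min:
        trace.append(f"n_cn_changepoints={features.n_cn_changepoints}>={thresholds.cp_min}")
        fired = True
    if features.max_total_cn > thresholds.extreme_amp_cn:
        trace.append(f"max_total_cn={features.max_total_cn:g}>{thresholds.extreme_amp_cn:g}")
        fired = True
    return (fired, trace if fired else [])


def detect_complex_events(
    events: Sequence[SvEvent],
    profile: SampleCnProfile,
    chrom_sizes: dict[str, int] | None = None,
    thresholds: ComplexEventThresholds = DEFAULT_THRESHOLDS,
) -> list[ComplexEventReport]:
    """Run all three flags over every chromosome of one sample."""
    chroms = set(profile.chromosomes) | {c for e in events for c in (e.chrom1, e.chrom2)}
    reports = []
    for chrom in sorted(chroms):
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        feats = chromosome_features(events, profile, chrom, chrom_size=size, thresholds=thresholds)
        report = ComplexEventReport(features=feats)
        ct, ct_trace = flag_chromothripsis(feats, thresholds)
        bfb, bfb_trace = flag_bfb(feats, profile.ploidy, thresholds)
        lc, lc_trace = flag_local_complexity(feats, thresholds)
        if ct:
            report.flags.append("chromothripsis-like")
            report.rule_trace += [f"chromothripsis:{t}" for t in ct_trace]
        if bfb:
            report.flags.append("bfb-like")
            report.rule_trace += [f"bfb:{t}" for t in bfb_trace]
        if lc:
            report.flags.append("local-complexity")
            report.rule_trace += [f"local:{t}" for t in lc_trace]
        reports.append(report)
    return reports


def reports_to_frame(reports: Sequence[ComplexEventReport]) -> pd.DataFrame:
    """Flat per-chromosome table of features, flags and rule traces."""
    rows = []
    for r in reports:
        f = r.features
        rows.append(
            {
                "sample_id": f.sample_id,
                "chrom": f.chrom,
                "n_breakends": f.n_breakends,
                "inversion_breakend_fraction": f.inversion_breakend_fraction,
                "n_cn_oscillations": f.n_cn_oscillations,
                "max_total_cn": f.max_total_cn,
                "telomeric_loss": f.telomeric_loss,
                "het_retention_fraction": f.het_retention_fraction,
                "has_clustered_sv": f.has_clustered_sv,
                "n_cn_changepoints": f.n_cn_changepoints,
                "sv_type_entropy": f.sv_type_entropy,
                "flags": ";".join(r.flags),
                "rule_trace": ";".join(r.rule_trace),
            }
        )
    return pd.DataFrame(rows)
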