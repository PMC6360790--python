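"""Ground-truthed synthetic cohort generation.

Every pipeline stage has a matching generator here that produces inputs
with the statistical structure the stage assumes, plus a truth manifest
sufficient to score recovery:

* substitution catalogues drawn from known signature mixtures
  (Dirichlet exposures, multinomial class sampling);
* genomic mutation positions with exponential background inter-arrival
  and injected hypermutation clusters;
* SV sets drawn from known 32-class mixtures, clustered classes placed in
  constructive foci so the density rule fires;
* copy-number profiles with configurable ploidy and engineered
  chromothripsis / breakage-fusion-bridge chromosomes;
* Poisson telomere-motif read counts;
* paired samples with a configured true variant-sharing fraction.

All randomness flows from one seed through spawned child generators, so a
fixed seed reproduces every output byte-for-byte and modules can be
regenerated independently.

The default synthetic genome is three 50 Mb chromosomes — large enough
for realistic inter-mutation spacing, small enough that a full cohort
generates in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogue import SBS96_LABELS, MutationRecord, revcomp
from .cnv import CnSegment, SampleCnProfile
from .rearrangements import (
    REARRANGEMENT_LABELS,
    SIZE_BIN_LABELS,
    SvEvent,
)
from .overlap import PileupEvidence

DEFAULT_CHROM_SIZES = {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000}

_SIZE_BIN_RANGES = {
    "1-10kb": (1_000, 10_000),
    "10-100kb": (10_000, 100_000),
    "100kb-1Mb": (100_000, 1_000_000),
    "1-10Mb": (1_000_000, 10_000_000),
    ">10Mb": (10_000_000, 30_000_000),
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# signatures / catalogues
# ---------------------------------------------------------------------------

def synthetic_signature_matrix(k: int = 5, m: int = 96, seed: int = 12345) -> pd.DataFrame:
    """A bundled set of well-separated synthetic signatures.

    Each signature concentrates 80% of its mass on its own disjoint block
    of classes with a flat 20% background, which keeps pairwise cosines
    low (well under 0.5) and makes recovery unambiguous.  Deterministic in
    ``seed``; no external catalogue download is required for tests.
    """
    rng = np.random.default_rng(seed)
    labels = list(SBS96_LABELS) if m == 96 else [f"c{i}" for i in range(m)]
    S = np.zeros((m, k))
    blocks = np.array_split(np.arange(m), k)
    for i in range(k):
        block = blocks[i]
        peak = rng.dirichlet(np.full(len(block), 0.8))
        back = rng.dirichlet(np.ones(m))
        S[block, i] += 0.8 * peak
        S[:, i] += 0.2 * back
    S /= S.sum(axis=0)
    return pd.DataFrame(S, index=labels, columns=[f"SYN{i + 1}" for i in range(k)])


def simulate_catalogues(
    signatures: pd.DataFrame,
    n_samples: int = 30,
    mutations_per_sample: int = 2000,
    dirichlet_alpha: float = 1.0,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample catalogues from a known signature mixture.

    Exposure proportions are Dirichlet(alpha); classes are multinomial
    over the mixed signature profile.  Returns (catalogues, true exposure
    proportions), both with samples in columns.
    """
    rng = _rng(rng)
    S = signatures.to_numpy(dtype=float)
    m, k = S.shape
    sample_ids = [f"sim{j + 1:03d}" for j in range(n_samples)]
    W = rng.dirichlet(np.full(k, dirichlet_alpha), size=n_samples).T  # k x n
    counts = np.zeros((m, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = S @ W[:, j]
        p = p / p.sum()
        counts[:, j] = rng.multinomial(mutations_per_sample, p)
    catalogues = pd.DataFrame(counts, index=list(signatures.index), columns=sample_ids)
    truth = pd.DataFrame(W, index=list(signatures.columns), columns=sample_ids)
    return catalogues, truth


# ---------------------------------------------------------------------------
# mutation positions with injected kataegis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KataegisInjection:
    """One engineered hypermutation cluster."""

    chrom: str
    n_mutations: int
    target_imd: float  # geometric mean inter-mutation distance (bp)


_CONTEXT_CHOICES = [f + "C" + t for f in "ACGT" for t in "ACGT"] + [
    f + "T" + t for f in "ACGT" for t in "ACGT"
]
_ALTS = {"C": ["A", "G", "T"], "T": ["A", "C", "G"]}


def _random_snv(sample_id: str, chrom: str, pos: int, rng) -> MutationRecord:
    ctx = _CONTEXT_CHOICES[rng.integers(0, len(_CONTEXT_CHOICES))]
    ref = ctx[1]
    alt = _ALTS[ref][rng.integers(0, 3)]
    return MutationRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt, context=ctx)


def simulate_positions(
    chrom_sizes: dict[str, int] | None = None,
    background_mean_imd: float = 100_000.0,
    injections: list[KataegisInjection] | None = None,
    sample_id: str = "sim001",
    rng=0,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Background mutations plus injected kataegis clusters.

    Background positions arrive with exponential inter-mutation spacing
    (default mean 100 kb); each injection places ``n_mutations``
    consecutive mutations with geometric IMDs at the target mean, at a
    uniform start position.  Returns (records, truth regions BED-like
    frame with 1-based inclusive start/end).
    """
    chrom_sizes = chrom_sizes or DEFAULT_CHROM_SIZES
    rng = _rng(rng)
    injections = injections or []
    records: list[MutationRecord] = []
    truth_rows = []
    for chrom, size in chrom_sizes.items():
        gaps = rng.exponential(background_mean_imd, size=max(int(3 * size / background_mean_imd), 10))
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = pos[pos <= size]
        for p in pos:
            records.append(_random_snv(sample_id, chrom, int(p), rng))
    for inj in injections:
        size = chrom_sizes[inj.chrom]
        span_estimate = int(inj.n_mutations * inj.target_imd * 10)
        if span_estimate >= size:
            raise ValueError(f"injection {inj} exceeds chromosome length {size}")
        start = int(rng.integers(1, size - span_estimate))
        gaps = rng.geometric(1.0 / inj.target_imd, size=inj.n_mutations - 1)
        cluster = np.concatenate([[start], start + np.cumsum(gaps)]).astype(np.int64)
        for p in cluster:
            records.append(_random_snv(sample_id, inj.chrom, int(p), rng))
        truth_rows.append(
            {
                "sample_id": sample_id,
                "chrom": inj.chrom,
                "start": int(cluster[0]),
                "end": int(cluster[-1]),
                "n_mutations": inj.n_mutations,
            }
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "chrom", "start", "end", "n_mutations"])
    return records, truth


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

def _parse_class(label: str) -> tuple[bool, str, str | None]:
    parts = label.split(":")
    clustered = parts[0] == "clustered"
    if parts[1] == "translocation":
        return clustered, "translocation", None
    return clustered, parts[1], parts[2]


def simulate_svs(
    n_events: int,
    class_mixture: np.ndarray | pd.Series,
    chrom_sizes: dict[str, int] | None = None,
    sample_id: str = "sim001",
    rng=0,
) -> tuple[list[SvEvent], pd.DataFrame]:
    """Draw SV events from a known 32-class mixture.

    Events of clustered classes are placed constructively into per-
    chromosome foci (all breakends of a focus within a small span) so the
    >= 10-breakends-per-1 Mb rule fires by construction; non-clustered
    events are scattered.  Returns (events without clustered flags
    assigned, truth frame with the drawn class per event).
    """
    chrom_sizes = chrom_sizes or DEFAULT_CHROM_SIZES
    rng = _rng(rng)
    if isinstance(class_mixture, pd.Series):
        class_mixture = class_mixture.reindex(list(REARRANGEMENT_LABELS)).fillna(0.0).to_numpy()
    p = np.asarray(class_mixture, dtype=float)
    p = p / p.sum()
    chroms = list(chrom_sizes)
    draws = rng.choice(len(REARRANGEMENT_LABELS), size=n_events, p=p)
    # one clustered focus per chromosome, kept clear of the ends
    foci = {c: int(rng.integers(2_000_000, chrom_sizes[c] - 2_000_000)) for c in chroms}
    events, truth_rows = [], []
    for d in draws:
        label = REARRANGEMENT_LABELS[d]
        clustered, typ, size_bin = _parse_class(label)
        if typ == "translocation":
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            chrom1, chrom2 = chroms[c1], chroms[c2]
            if clustered:
                pos1 = foci[chrom1] + int(rng.integers(0, 50_000))
                pos2 = foci[chrom2] + int(rng.integers(0, 50_000))
            else:
                pos1 = int(rng.integers(1, chrom_sizes[chrom1]))
                pos2 = int(rng.integers(1, chrom_sizes[chrom2]))
            ev = SvEvent(sample_id, chrom1, pos1, chrom2, pos2, "translocation")
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo, hi = _SIZE_BIN_RANGES[size_bin]
            size = int(rng.integers(lo, hi))
            if clustered:
                pos1 = foci[chrom] + int(rng.integers(0, 50_000))
            else:
                pos1 = int(rng.integers(1, chrom_sizes[chrom] - size))
            ev = SvEvent(sample_id, chrom, pos1, chrom, pos1 + size, typ)
        events.append(ev)
        truth_rows.append({"sample_id": sample_id, "true_class": label})
    truth = pd.DataFrame(truth_rows)
    return events, truth


# ---------------------------------------------------------------------------
# copy-number profiles and engineered complex chromosomes
# ---------------------------------------------------------------------------

@dataclass
class ComplexChromosome:
    """Segments plus SV events engineered on one chromosome."""

    chrom: str
    tag: str  # chromothripsis | bfb | quiet
    segments: list[CnSegment] = field(default_factory=list)
    events: list[SvEvent] = field(default_factory=list)


def _quiet_chromosome(sample_id: str, chrom: str, size: int, ploidy: float, rng) -> ComplexChromosome:
    cn = round(ploidy)
    segments = [
        CnSegment(sample_id, chrom, 1, size, total_cn=float(cn), minor_cn=float(max(cn // 2, 1)))
    ]
    events: list[SvEvent] = []
    # a couple of scattered background SVs, far apart: never clustered
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(1_000_000, size - 6_000_000))
        events.append(SvEvent(sample_id, chrom, pos, chrom, pos + int(rng.integers(3_000_000, 5_000_000)),
                              str(rng.choice(["del", "dup"]))))
    return ComplexChromosome(chrom=chrom, tag="quiet", segments=segments, events=events)


def _chromothripsis_chromosome(sample_id: str, chrom: str, size: int, ploidy: float, rng) -> ComplexChromosome:
    """>= 12 segments alternating two CN states, minor CN 1 retained,
    >= 10 clustered mixed-type SVs inside the shattered region."""
    n_seg = int(rng.integers(13, 19))
    region_start = int(rng.integers(2_000_000, size // 2))
    seg_len = int(rng.integers(100_000, 300_000))
    base_cn = round(ploidy)
    hi_cn = base_cn + 1
    segments = []
    pos = region_start
    for i in range(n_seg):
        cn = base_cn if i % 2 == 0 else hi_cn
        segments.append(
            CnSegment(sample_id, chrom, pos, pos + seg_len - 1, total_cn=float(cn), minor_cn=1.0)
        )
        pos += seg_len
    region_end = pos - 1
    # flanks at ploidy
    flank_cn = float(round(ploidy))
    segments.insert(0, CnSegment(sample_id, chrom, 1, region_start - 1, flank_cn, minor_cn=1.0))
    segments.append(CnSegment(sample_id, chrom, region_end + 1, size, flank_cn, minor_cn=1.0))
    # clustered mixed-type joins: concentrated in a sub-1 Mb focus inside
    # the shattered region so the breakend-density rule holds by construction
    events = []
    n_sv = int(rng.integers(12, 25))
    types = ["del", "dup", "inv"]
    focus_len = min(region_end - region_start - 20_000, 780_000)
    focus = int(rng.integers(region_start, region_end - focus_len - 20_000))
    for i in range(n_sv):
        p1 = focus + int(rng.integers(0, focus_len))
        p2 = p1 + int(rng.integers(2_000, 20_000))
        events.append(SvEvent(sample_id, chrom, p1, chrom, p2, types[i % 3]))
    return ComplexChromosome(chrom=chrom, tag="chromothripsis", segments=segments, events=events)


def _bfb_chromosome(sample_id: str, chrom: str, size: int, ploidy: float, rng) -> ComplexChromosome:
    """Telomeric-end deletion plus an amplified (CN >= 10) region whose
    breakends are mostly fold-back inversions."""
    tel_len = int(rng.integers(200_000, 800_000))  # lost telomeric segment
    amp_start = int(rng.integers(5_000_000, size // 2))
    amp_len = int(rng.integers(1_000_000, 3_000_000))
    amp_cn = float(rng.integers(10, 16))
    base_cn = float(round(ploidy))
    segments = [
        CnSegment(sample_id, chrom, 1, tel_len, total_cn=0.0, minor_cn=0.0),
        CnSegment(sample_id, chrom, tel_len + 1, amp_start - 1, base_cn, minor_cn=1.0),
        CnSegment(sample_id, chrom, amp_start, amp_start + amp_len - 1, amp_cn, minor_cn=1.0),
        CnSegment(sample_id, chrom, amp_start + amp_len, size, base_cn, minor_cn=1.0),
    ]
    events = []
    n_inv = int(rng.integers(8, 15))
    for _ in range(n_inv):
        p1 = int(rng.integers(amp_start, amp_start + amp_len - 60_000))
        events.append(SvEvent(sample_id, chrom, p1, chrom, p1 + int(rng.integers(2_000, 50_000)), "inv"))
    n_other = int(rng.integers(0, max(n_inv // 3, 1)))
    for _ in range(n_other):
        p1 = int(rng.integers(amp_start, amp_start + amp_len - 60_000))
        events.append(SvEvent(sample_id, chrom, p1, chrom, p1 + int(rng.integers(2_000, 50_000)),
                              str(rng.choice(["del", "dup"]))))
    return ComplexChromosome(chrom=chrom, tag="bfb", segments=segments, events=events)


def simulate_complex_chromosome(
    tag: str,
    chrom: str = "chr1",
    size: int = 50_000_000,
    ploidy: float = 2.0,
    sample_id: str = "sim001",
    rng=0,
) -> ComplexChromosome:
    """Engineer one chromosome tagged chromothripsis, bfb or quiet."""
    rng = _rng(rng)
    builders = {
        "chromothripsis": _chromothripsis_chromosome,
        "bfb": _bfb_chromosome,
        "quiet": _quiet_chromosome,
    }
    if tag not in builders:
        raise ValueError(f"unknown tag {tag!r}")
    return builders[tag](sample_id, chrom, size, ploidy, rng)


def simulate_cn(
    tags: dict[str, str],
    chrom_sizes: dict[str, int] | None = None,
    ploidy: float = 2.0,
    sample_id: str = "sim001",
    rng=0,
) -> tuple[SampleCnProfile, list[SvEvent], pd.DataFrame]:
    """Build a sample CN profile with engineered event chromosomes.

    ``tags`` maps chromosome name to one of chromothripsis / bfb / quiet.
    Returns (profile, SV events across all chromosomes, truth tag frame).
    """
    chrom_sizes = chrom_sizes or DEFAULT_CHROM_SIZES
    rng = _rng(rng)
    segments: list[CnSegment] = []
    events: list[SvEvent] = []
    rows = []
    for chrom, tag in tags.items():
        cc = simulate_complex_chromosome(tag, chrom, chrom_sizes[chrom], ploidy, sample_id, rng)
        segments += cc.segments
        events += cc.events
        rows.append({"sample_id": sample_id, "chrom": chrom, "tag": tag})
    profile = SampleCnProfile(sample_id=sample_id, segments=segments, ploidy=ploidy)
    return profile, events, pd.DataFrame(rows, columns=["sample_id", "chrom", "tag"])


# ---------------------------------------------------------------------------
# telomere counts
# ---------------------------------------------------------------------------

def simulate_telomere(
    tumour_mean: float = 300.0,
    tumour_coverage: float = 60.0,
    normal_mean: float = 250.0,
    normal_coverage: float = 40.0,
    n_pairs: int = 1,
    rng=0,
) -> pd.DataFrame:
    """Poisson motif-read counts for tumour/normal pairs."""
    rng = _rng(rng)
    rows = []
    for i in range(n_pairs):
        rows.append(
            {
                "pair_id": f"pair{i + 1:03d}",
                "tumour_count": int(rng.poisson(tumour_mean)),
                "tumour_coverage": tumour_coverage,
                "normal_count": int(rng.poisson(normal_mean)),
                "normal_coverage": normal_coverage,
            }
        )
    return pd.DataFrame(rows)


def simulate_telomere_reads(
    n_motif_reads: int,
    n_background_reads: int,
    motif: str = "TTAGGG",
    read_length: int = 100,
    min_copies: int = 3,
    rng=0,
) -> list[str]:
    """Short synthetic reads, a known number carrying tandem motif copies."""
    rng = _rng(rng)
    bases = np.array(list("ACGT"))
    reads = []
    for i in range(n_motif_reads):
        copies = motif * (min_copies + int(rng.integers(0, 3)))
        if rng.random() < 0.5:
            copies = revcomp(copies)
        pad = "".join(rng.choice(bases, size=max(read_length - len(copies), 0)))
        reads.append(copies + pad)
    for _ in range(n_background_reads):
        reads.append("".join(rng.choice(bases, size=read_length)))
    return reads


# ---------------------------------------------------------------------------
# paired samples with configured variant sharing
# ---------------------------------------------------------------------------

def simulate_pair(
    n_variants_each: int = 500,
    sharing_fraction: float = 0.8,
    depth: int = 60,
    vaf: float = 0.3,
    chrom: str = "chr1",
    chrom_size: int = 50_000_000,
    rng=0,
) -> tuple[list[tuple], list[tuple], dict, dict, pd.DataFrame]:
    """Two call sets of one donor with a configured true sharing fraction.

    ``sharing_fraction`` is the fraction of the union of both call sets
    that is truly present in both samples (the scale on which overlap is
    measured).  Shared variants get strong alt evidence in both samples;
    private ones get alt evidence only in their own sample.  Returns
    (calls_a, calls_b, evidence_a, evidence_b, truth frame).
    """
    rng = _rng(rng)
    # per-sample calls N = shared + private; union fraction f = s/(s + 2p)
    # with p = N - s gives s = 2Nf/(1+f)
    n_shared = int(round(2 * n_variants_each * sharing_fraction / (1 + sharing_fraction)))
    n_private = n_variants_each - n_shared
    total = n_shared + 2 * n_private
    # rejection-free unique positions: draw extra, deduplicate, trim
    draw = rng.integers(1, chrom_size, size=total * 2 + 16)
    positions = np.unique(draw)
    rng.shuffle(positions)
    positions = np.sort(positions[:total])
    if len(positions) < total:
        raise ValueError("chromosome too small for the requested variant count")
    keys = [(chrom, int(p)) for p in positions]
    shared = keys[:n_shared]
    private_a = keys[n_shared : n_shared + n_private]
    private_b = keys[n_shared + n_private :]
    calls_a = shared + private_a
    calls_b = shared + private_b

    def _evidence(key, carries: bool):
        cov = max(int(rng.poisson(depth)), 10)
        alt = int(rng.binomial(cov, vaf)) if carries else 0
        if carries and alt == 0:
            alt = 1  # deep coverage: carriers always leave at least one read
        return PileupEvidence(chrom=key[0], pos=key[1], coverage=cov,
                              good_alt_reads=alt, normal_alt_reads=0)

    evidence_a = {k: _evidence(k, k in set(shared) | set(private_a)) for k in keys}
    evidence_b = {k: _evidence(k, k in set(shared) | set(private_b)) for k in keys}
    truth = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "shared": [k in set(shared) for k in keys],
        }
    )
    return calls_a, calls_b, evidence_a, evidence_b, truth


# ---------------------------------------------------------------------------
# whole-cohort convenience with file output
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Configuration for a full synthetic cohort.

    Defaults follow the study conditions the acceptance checks assume:
    30 samples, 5 signatures, Dirichlet(1) exposures, 2000 mutations per
    sample, 100 kb background IMD, three 50 Mb chromosomes.
    """

    n_samples: int = 30
    n_signatures: int = 5
    mutations_per_sample: int = 2000
    dirichlet_alpha: float = 1.0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    background_mean_imd: float = 100_000.0
    n_sv_per_sample: int = 200
    ploidy: float = 2.0
    telomere_tumour_mean: float = 300.0
    telomere_tumour_coverage: float = 60.0
    telomere_normal_mean: float = 250.0
    telomere_normal_coverage: float = 40.0
    overlap_sharing_fraction: float = 0.8
    seed: int = 0


def simulate_cohort(spec: CohortSpec, out_dir) -> dict[str, Path]:
    """Generate a full cohort and write every standard-format file.

    Emits a mutation table + VCFs, BEDPE, segment and ploidy tables, a
    telomere table, pileup evidence tables, and truth manifests; returns
    the paths keyed by content.
    """
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    children = master.spawn(6)
    paths: dict[str, Path] = {}

    # catalogues
    signatures = synthetic_signature_matrix(k=spec.n_signatures, seed=spec.seed + 12345)
    catalogues, exposures = simulate_catalogues(
        signatures,
        n_samples=spec.n_samples,
        mutations_per_sample=spec.mutations_per_sample,
        dirichlet_alpha=spec.dirichlet_alpha,
        rng=children[0],
    )
    paths["signatures"] = out / "true_signatures.tsv"
    signatures.to_csv(paths["signatures"], sep="\t", index_label="class")
    paths["catalogues"] = out / "catalogues.tsv"
    catalogues.to_csv(paths["catalogues"], sep="\t", index_label="class")
    paths["true_exposures"] = out / "true_exposures.tsv"
    exposures.to_csv(paths["true_exposures"], sep="\t", index_label="signature")

    # positions with kataegis for the first sample
    injections = [KataegisInjection(chrom=list(spec.chrom_sizes)[0], n_mutations=12, target_imd=100.0)]
    records, kat_truth = simulate_positions(
        spec.chrom_sizes, spec.background_mean_imd, injections, rng=children[1]
    )
    paths["mutations"] = out / "mutations.tsv"
    sio.write_mutation_table(records, paths["mutations"])
    paths["mutations_vcf"] = out / "mutations.vcf"
    sio.write_vcf(records, paths["mutations_vcf"], spec.chrom_sizes)
    paths["kataegis_truth"] = out / "kataegis_truth.tsv"
    kat_truth.to_csv(paths["kataegis_truth"], sep="\t", index=False)

    # SVs
    mixture = np.ones(len(REARRANGEMENT_LABELS))
    events, sv_truth = simulate_svs(spec.n_sv_per_sample, mixture, spec.chrom_sizes, rng=children[2])
    paths["svs"] = out / "svs.bedpe"
    sio.write_bedpe(events, paths["svs"])
    paths["sv_truth"] = out / "sv_truth.tsv"
    sv_truth.to_csv(paths["sv_truth"], sep="\t", index=False)

    # CN profile with one engineered chromosome of each kind
    chroms = list(spec.chrom_sizes)
    tags = {chroms[0]: "chromothripsis", chroms[1]: "bfb", chroms[2 % len(chroms)]: "quiet"}
    profile, cn_events, cn_truth = simulate_cn(tags, spec.chrom_sizes, spec.ploidy, rng=children[3])
    seg_rows = [
        {"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start, "end": s.end,
         "total_cn": s.total_cn, "minor_cn": s.minor_cn}
        for s in profile.segments
    ]
    paths["segments"] = out / "segments.tsv"
    pd.DataFrame(seg_rows).to_csv(paths["segments"], sep="\t", index=False)
    paths["ploidy"] = out / "ploidy.tsv"
    pd.DataFrame([{"sample_id": profile.sample_id, "ploidy": profile.ploidy}]).to_csv(
        paths["ploidy"], sep="\t", index=False
    )
    paths["cn_truth"] = out / "cn_truth.tsv"
    cn_truth.to_csv(paths["cn_truth"], sep="\t", index=False)

    # telomere counts
    tel = simulate_telomere(
        spec.telomere_tumour_mean, spec.telomere_tumour_coverage,
        spec.telomere_normal_mean, spec.telomere_normal_coverage,
        n_pairs=spec.n_samples, rng=children[4],
    )
    paths["telomere"] = out / "telomere.tsv"
    tel.to_csv(paths["telomere"], sep="\t", index=False)

    # paired overlap evidence
    calls_a, calls_b, ev_a, ev_b, ov_truth = simulate_pair(
        sharing_fraction=spec.overlap_sharing_fraction,
        chrom=chroms[0], chrom_size=spec.chrom_sizes[chroms[0]], rng=children[5],
    )
    for name, calls, ev in (("a", calls_a, ev_a), ("b", calls_b, ev_b)):
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": "C", "alt": "T",
             "coverage": ev[k].coverage, "good_alt_reads": ev[k].good_alt_reads,
             "normal_alt_reads": ev[k].normal_alt_reads, "called": k in set(calls)}
            for k in sorted(ev)
        ]
        paths[f"pileup_{name}"] = out / f"pileup_{name}.tsv"
        pd.DataFrame(rows).to_csv(paths[f"pileup_{name}"], sep="\t", index=False)
    paths["overlap_truth"] = out / "overlap_truth.tsv"
    ov_truth.to_csv(paths["overlap_truth"], sep="\t", index=False)

    paths["chrom_sizes"] = out / "chrom_sizes.tsv"
    with open(paths["chrom_sizes"], "w") as fh:
        for c, s in spec.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    return paths
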