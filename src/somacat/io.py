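"""Readers and writers for the plain-text formats the pipeline consumes.

Coordinates are 1-based inclusive in memory.  BEDPE and BED are 0-based
half-open on disk and are converted on read; kataegis regions are written
back out 0-based half-open (BED convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .catalogue import MutationRecord

_MUTATION_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a multi-sample tab-separated mutation table.

    Columns: sample_id, chrom, pos, ref, alt and optionally context.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} missing columns {missing}")
    has_context = "context" in df.columns
    records = []
    for row in df.itertuples(index=False):
        ctx = getattr(row, "context", None) if has_context else None
        if isinstance(ctx, float):  # NaN from pandas
            ctx = None
        records.append(
            MutationRecord(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                context=ctx,
            )
        )
    return records


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "context": r.context if r.context is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_MUTATION_COLUMNS + ["context"]).to_csv(
        path, sep="\t", index=False
    )


def read_vcf(path, sample_id: str) -> list[MutationRecord]:
    """Read one sample's somatic calls from a VCF (v4.x) file.

    Multi-allelic sites contribute one record per ALT allele.  The optional
    ``CONTEXT`` INFO field (3-base uppercase triplet) is honoured.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ctx = rec.info.get("CONTEXT") if "CONTEXT" in rec.info else None
            for alt in rec.alts or ():
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        context=str(ctx) if ctx else None,
                    )
                )
    return records


def write_vcf(records: Iterable[MutationRecord], path, chrom_sizes: dict[str, int]) -> None:
    """Write somatic calls as a minimal uncompressed VCF v4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Trinucleotide context">\n')
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = f"CONTEXT={r.context}" if r.context else "."
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def read_bedpe(path, default_sample: str | None = None) -> pd.DataFrame:
    """Read SV breakpoint pairs from BEDPE (0-based half-open, converted).

    Expects at least chrom1, start1, end1, chrom2, start2, end2, name
    columns; an ``sv_type`` column (or 8th column) holds the event type and
    an optional ``sample_id`` column the sample.  Returns a frame with
    1-based ``pos1``/``pos2`` breakend coordinates.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "sv_type"]
    if df.shape[1] >= 9:
        names.append("sample_id")
    df = df.iloc[:, : len(names)]
    df.columns = names
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"] if "sample_id" in df else default_sample,
            "chrom1": df["chrom1"],
            "pos1": df["start1"].astype(int) + 1,  # BEDPE start is 0-based
            "chrom2": df["chrom2"],
            "pos2": df["start2"].astype(int) + 1,
            "sv_type": df["sv_type"],
        }
    )
    if out["sample_id"].isna().any():
        raise ValueError("BEDPE lacks a sample_id column and no default_sample given")
    return out


def write_bedpe(events, path) -> None:
    """Write SV events as BEDPE (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for i, ev in enumerate(events):
            fh.write(
                f"{ev.chrom1}\t{ev.pos1 - 1}\t{ev.pos1}\t{ev.chrom2}\t{ev.pos2 - 1}\t{ev.pos2}"
                f"\tsv{i}\t{ev.sv_type}\t{ev.sample_id}\n"
            )


def read_segments(path) -> pd.DataFrame:
    """Read an ASCAT-like copy-number segment table.

    Columns: sample_id, chrom, start, end, total_cn and optionally minor_cn
    (1-based inclusive coordinates).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    needed = {"sample_id", "chrom", "start", "end", "total_cn"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"segment table {path} missing columns {sorted(missing)}")
    return df


def read_ploidy_table(path) -> dict[str, float]:
    """Per-sample average genome ploidy: two columns sample_id, ploidy."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return dict(zip(df["sample_id"], df["ploidy"].astype(float)))


def read_telomere_table(path) -> pd.DataFrame:
    """Pre-counted telomere-motif reads: sample_id, motif_read_count, mean_coverage."""
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def read_pileup_table(path) -> pd.DataFrame:
    """Pileup evidence rows: chrom, pos, ref, alt, coverage, good_alt_reads, normal_alt_reads."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_bed(path) -> pd.DataFrame:
    """Gene/feature intervals from BED; returns 1-based inclusive start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) + 1,  # BED start is 0-based
            "end": df["end"].astype(int),
            "name": df["name"] if "name" in df else [f"iv{i}" for i in range(len(df))],
        }
    )
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chromosome-sizes file (name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes
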