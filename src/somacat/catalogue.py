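"""Per-sample 96-class trinucleotide substitution catalogues.

Somatic single-base substitutions are classified on the pyrimidine strand
into the conventional 96 classes (6 substitution types x 16 flanking-base
contexts).  Purine-strand calls are reverse-complemented before labelling,
so ``G>T`` in context ``TGA`` and ``C>A`` in context ``TCA`` land in the
same class.  The resulting per-sample count vectors are the input to
signature extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-strand substitution types, in conventional order.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = ("A", "C", "G", "T")


def _build_class_labels() -> tuple[str, ...]:
    # substitution-type major, then 16 contexts in lexicographic order
    labels = []
    for sub in SUBSTITUTION_TYPES:
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: The 96 class labels in fixed order (type-major, contexts lexicographic).
SBS96_LABELS: tuple[str, ...] = _build_class_labels()

_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


class InvalidMutationError(ValueError):
    """Raised for malformed substitution inputs (non-ACGT base, ref == alt...)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise InvalidMutationError(f"non-ACGT base in {seq!r}") from exc


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or indel call.

    ``context``, when present, is the 3-base reference triplet centred on
    ``pos`` (uppercase); its middle base must equal ``ref`` for SNVs.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvalidMutationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: ref equals alt ({self.ref})"
            )
        if self.is_snv and self.context is not None:
            if len(self.context) != 3:
                raise InvalidMutationError(
                    f"{self.chrom}:{self.pos}: context {self.context!r} is not a triplet"
                )
            if self.context[1] != self.ref:
                raise InvalidMutationError(
                    f"{self.chrom}:{self.pos}: context middle base "
                    f"{self.context[1]!r} != ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class Catalogue:
    """Non-negative count vector over a fixed class alphabet for one sample."""

    sample_id: str
    class_labels: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.class_labels) != len(self.counts):
            raise ValueError("class_labels and counts length mismatch")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("duplicate class labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def classify_snv(ref: str, alt: str, context: str) -> str:
    """Classify one substitution into its 96-class label.

    The substitution is expressed on the pyrimidine strand: if ``ref`` is a
    purine (A/G) the call and its context are reverse-complemented first.

    Parameters
    ----------
    ref, alt : single bases in ``{A, C, G, T}``.
    context : 3-base reference triplet whose middle base equals ``ref``.

    Returns
    -------
    str
        A label of the form ``"X[R>A]Y"``, e.g. ``"C[T>G]T"``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref not in _BASES or alt not in _BASES:
        raise InvalidMutationError(f"ref/alt must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise InvalidMutationError(f"ref equals alt ({ref})")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise InvalidMutationError(f"context must be an ACGT triplet, got {context!r}")
    if context[1] != ref:
        raise InvalidMutationError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref in ("A", "G"):  # purine strand: flip to pyrimidine
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class CatalogueBuild:
    """Result of catalogue construction: per-sample catalogues plus a skip log."""

    catalogues: list[Catalogue]
    skipped: list[tuple[MutationRecord, str]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        """Catalogue matrix with the 96 classes as rows, samples as columns."""
        data = {c.sample_id: c.counts for c in self.catalogues}
        return pd.DataFrame(data, index=list(SBS96_LABELS))


def _context_from_fasta(reference, chrom: str, pos: int) -> str | None:
    """Uppercase 3-base triplet centred on the 1-based position, or None."""
    try:
        seq = str(reference[chrom][pos - 2 : pos + 1]).upper()
    except (KeyError, IndexError):
        return None
    return seq if len(seq) == 3 else None


def build_catalogues(
    records: Iterable[MutationRecord],
    reference=None,
) -> CatalogueBuild:
    """Build 96-class catalogues, one per sample.

    Indels and multi-nucleotide events never enter the catalogue; they are
    returned in the skip log (they still count toward mutation burden, which
    is reported elsewhere).  SNVs lacking a context are looked up in
    ``reference`` (a :class:`pyfaidx.Fasta` or mapping of chrom -> sequence);
    an ``N``-containing context skips the record with a log entry.
    """
    per_sample: dict[str, np.ndarray] = {}
    skipped: list[tuple[MutationRecord, str]] = []
    for rec in records:
        counts = per_sample.setdefault(rec.sample_id, np.zeros(96, dtype=np.int64))
        if not rec.is_snv:
            skipped.append((rec, "not an SNV"))
            continue
        context = rec.context
        if context is None:
            if reference is None:
                raise ValueError(
                    f"record {rec.sample_id} {rec.chrom}:{rec.pos} has no context "
                    "and no reference FASTA was provided"
                )
            context = _context_from_fasta(reference, rec.chrom, rec.pos)
            if context is None:
                skipped.append((rec, "context not retrievable from reference"))
                continue
        try:
            label = classify_snv(rec.ref, rec.alt, context)
        except InvalidMutationError as exc:
            skipped.append((rec, str(exc)))
            logger.warning("skipping %s:%s (%s)", rec.chrom, rec.pos, exc)
            continue
        counts[_LABEL_INDEX[label]] += 1
    catalogues = [
        Catalogue(sample_id=sid, class_labels=SBS96_LABELS, counts=cnt)
        for sid, cnt in sorted(per_sample.items())
    ]
    return CatalogueBuild(catalogues=catalogues, skipped=skipped)


def mutation_burden(records: Iterable[MutationRecord], genome_mb: float) -> pd.Series:
    """Mutations (SNVs plus indels pooled) per megabase, per sample."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
    return pd.Series(counts, dtype=float).sort_index() / genome_mb


def write_catalogue_matrix(build: CatalogueBuild, path) -> None:
    """Write the catalogue matrix as TSV: classes in rows, samples in columns."""
    build.as_frame().to_csv(path, sep="\t", index_label="class")


def read_catalogue_matrix(path) -> pd.DataFrame:
    """Read a class x sample catalogue matrix written by :func:`write_catalogue_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)
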