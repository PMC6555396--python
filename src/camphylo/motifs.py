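"""Codon-aversion and amino-acid-aversion motifs.

A gene's *codon aversion motif* is the set of codons — out of all 64, stop
codons included — that never occur among the in-frame, non-overlapping codons
of its coding sequence, stored as a lexicographically sorted tuple.  The
*amino-acid aversion motif* is the analogous set over the 20 standard amino
acids after translation.  A species is summarised by the set of unique motifs
across all of its genes (a :class:`SpeciesProfile`), which downstream modules
compare by set overlap.

This module also provides the standard preprocessing applied to RefSeq-style
CDS FASTA input: longest-isoform selection, removal of records with annotated
translational exceptions, and optional removal of partial annotations.
"""

from __future__ import annotations

import gzip
import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    ConfigurationError,
    EmptySequenceError,
    EmptySpeciesError,
    SequenceTooShortError,
)

logger = logging.getLogger(__name__)

Mode = Literal["codon", "amino_acid"]

#: All 64 codons over {A,C,G,T}, lexicographically sorted.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)
CODON_SET = frozenset(CODONS)

#: The 20 standard amino acids, sorted.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

STOP_SYMBOL = "*"
UNKNOWN_AA = "X"

_DEFAULT_GENE_PATTERN = re.compile(r"\[gene=([^\]]+)\]")
DEFAULT_EXCEPTION_MARKERS = ("exception", "transl_except")
DEFAULT_PARTIAL_MARKERS = ("partial",)

_FASTA_SUFFIXES = (".fasta", ".fa", ".fna", ".ffn")


@dataclass(frozen=True, order=True)
class AversionMotif:
    """A sorted tuple of codons (or amino acids) absent from one gene.

    Instances are immutable and hashable so motifs can live in sets and be
    counted.  ``elements`` is always strictly sorted and duplicate-free; the
    empty motif (a gene that uses the whole alphabet) is valid.
    """

    elements: tuple[str, ...]
    mode: Mode = field(default="codon", compare=True)

    def __post_init__(self):
        alphabet = CODON_SET if self.mode == "codon" else AMINO_ACID_SET
        if self.mode not in ("codon", "amino_acid"):
            raise ConfigurationError(f"unknown motif mode {self.mode!r}")
        if list(self.elements) != sorted(set(self.elements)):
            raise ValueError("motif elements must be strictly sorted and unique")
        bad = [e for e in self.elements if e not in alphabet]
        if bad:
            raise ValueError(f"invalid motif elements for mode {self.mode}: {bad}")

    @classmethod
    def from_observed(cls, observed: Iterable[str], mode: Mode = "codon") -> "AversionMotif":
        """Motif = alphabet complement of the observed tokens."""
        alphabet = CODON_SET if mode == "codon" else AMINO_ACID_SET
        return cls(tuple(sorted(alphabet - set(observed))), mode)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, item) -> bool:
        return item in self.elements

    def to_text(self) -> str:
        return ",".join(self.elements)

    @classmethod
    def from_text(cls, text: str, mode: Mode = "codon") -> "AversionMotif":
        elements = tuple(e for e in text.strip().split(",") if e)
        return cls(elements, mode)


@dataclass
class GeneRecord:
    """One CDS record with flags derived from its FASTA header."""

    gene_id: str | None
    species: str
    sequence: str
    is_partial: bool = False
    has_exception: bool = False
    record_id: str = ""


@dataclass
class SpeciesProfile:
    """A species' unique aversion motifs with per-motif occurrence counts."""

    species: str
    motif_counts: dict[AversionMotif, int]
    mode: Mode = "codon"

    def __post_init__(self):
        if not self.motif_counts:
            raise EmptySpeciesError(f"species {self.species!r} has no motifs")
        modes = {m.mode for m in self.motif_counts}
        if modes != {self.mode}:
            raise ConfigurationError(
                f"profile {self.species!r}: motif modes {modes} != {self.mode!r}"
            )
        if any(c < 1 for c in self.motif_counts.values()):
            raise ValueError("motif occurrence counts must be >= 1")

    @property
    def motifs(self) -> frozenset[AversionMotif]:
        return frozenset(self.motif_counts)

    @property
    def n_genes(self) -> int:
        return sum(self.motif_counts.values())


def normalize_sequence(raw: str, record_id: str = "<unknown>") -> str:
    """Uppercase, map RNA U to T, and strip all whitespace.

    Other characters (IUPAC ambiguity codes and anything else) pass through
    and are handled by the extractors.  Raises
    :class:`~camphylo.errors.EmptySequenceError` naming the record if nothing
    is left.
    """
    seq = "".join(raw.split()).upper().replace("U", "T")
    if not seq:
        raise EmptySequenceError(f"record {record_id!r}: empty sequence")
    return seq


def _iter_codons(sequence: str, record_id: str = "<unknown>"):
    n = len(sequence)
    if n % 3:
        logger.warning(
            "record %s: dropping trailing incomplete codon (%d nt)",
            record_id, n % 3,
        )
    for i in range(0, n - n % 3, 3):
        yield sequence[i : i + 3]


def extract_codon_motif(sequence: str, record_id: str = "<unknown>") -> AversionMotif:
    """Codons of the 64-codon table absent from an in-frame reading.

    The reading frame starts at position 0 and codons do not overlap.  A
    trailing incomplete codon is dropped with a logged warning.  Codons
    containing characters outside {A,C,G,T} (ambiguity codes) mark no table
    entry as used.
    """
    if len(sequence) < 3:
        raise SequenceTooShortError(
            f"record {record_id!r}: sequence of length {len(sequence)} < 3"
        )
    observed = {c for c in _iter_codons(sequence, record_id) if c in CODON_SET}
    return AversionMotif.from_observed(observed, "codon")


def translate(sequence: str, table_id: int = 1, record_id: str = "<unknown>") -> str:
    """In-frame translation under an NCBI genetic-code table.

    Stop codons emit ``*``; codons containing ambiguity characters emit ``X``;
    translation runs through internal stops.  Default table 1 is the standard
    code.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ConfigurationError(f"unknown genetic-code table id {table_id!r}") from None
    if len(sequence) < 3:
        raise SequenceTooShortError(
            f"record {record_id!r}: sequence of length {len(sequence)} < 3"
        )
    stops = set(table.stop_codons)
    out = []
    for codon in _iter_codons(sequence, record_id):
        if codon in stops:
            out.append(STOP_SYMBOL)
        else:
            out.append(table.forward_table.get(codon, UNKNOWN_AA))
    return "".join(out)


def extract_aa_motif(protein: str) -> AversionMotif:
    """Standard amino acids absent from a protein string.

    Stop symbols (``*``) and ``X`` are ignored: they are neither alphabet
    members nor usage marks.
    """
    observed = set(protein) & AMINO_ACID_SET
    return AversionMotif.from_observed(observed, "amino_acid")


def parse_fasta_header(
    description: str,
    gene_pattern: re.Pattern | str = _DEFAULT_GENE_PATTERN,
    exception_markers: Sequence[str] = DEFAULT_EXCEPTION_MARKERS,
    partial_markers: Sequence[str] = DEFAULT_PARTIAL_MARKERS,
) -> tuple[str | None, bool, bool]:
    """Extract (gene_id, is_partial, has_exception) from a FASTA description.

    The default gene pattern matches the ``[gene=...]`` bracketed attribute of
    RefSeq CDS FASTA; exception/partial detection is case-insensitive
    substring matching, configurable because annotation markers vary.
    """
    if isinstance(gene_pattern, str):
        gene_pattern = re.compile(gene_pattern)
    m = gene_pattern.search(description)
    gene_id = m.group(1) if m else None
    low = description.lower()
    is_partial = any(marker in low for marker in partial_markers)
    has_exception = any(marker in low for marker in exception_markers)
    return gene_id, is_partial, has_exception


def species_label_from_path(path: str | Path) -> str:
    """File stem minus .fasta/.fa/.fna/.ffn/.gz suffixes."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    for suf in _FASTA_SUFFIXES:
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return name


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b" or path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    species: str | None = None,
    gene_pattern: re.Pattern | str = _DEFAULT_GENE_PATTERN,
    exception_markers: Sequence[str] = DEFAULT_EXCEPTION_MARKERS,
    partial_markers: Sequence[str] = DEFAULT_PARTIAL_MARKERS,
) -> list[GeneRecord]:
    """Read one species' CDS FASTA (plain or gzip) into :class:`GeneRecord` s.

    gzip is detected by magic bytes or a ``.gz`` suffix; the species label
    defaults to the file stem.
    """
    path = Path(path)
    label = species if species is not None else species_label_from_path(path)
    records: list[GeneRecord] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            gene_id, is_partial, has_exception = parse_fasta_header(
                rec.description, gene_pattern, exception_markers, partial_markers
            )
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    species=label,
                    sequence=str(rec.seq),
                    is_partial=is_partial,
                    has_exception=has_exception,
                    record_id=rec.id,
                )
            )
    logger.info("%s: read %d records from %s", label, len(records), path)
    return records


def select_longest_isoforms(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Keep, per gene identifier, only the longest record.

    Ties break toward the first appearance in file order.  Records without a
    parsable gene identifier are always retained.
    """
    best: dict[str, GeneRecord] = {}
    order: list[str] = []
    untagged: list[tuple[int, GeneRecord]] = []
    for idx, rec in enumerate(records):
        if rec.gene_id is None:
            untagged.append((idx, rec))
            continue
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif len(rec.sequence) > len(cur.sequence):
            best[rec.gene_id] = rec
    # preserve original file order across tagged and untagged records
    chosen = {id(best[g]) for g in order} | {id(r) for _, r in untagged}
    return [r for r in records if id(r) in chosen]


def filter_records(
    records: Sequence[GeneRecord],
    drop_exceptions: bool = True,
    drop_partials: bool = False,
    source: str = "<records>",
) -> list[GeneRecord]:
    """Drop records flagged as annotated exceptions and/or partials.

    Defaults match the main analysis: exceptions removed, partials kept.
    """
    kept = []
    n_exc = n_part = 0
    for rec in records:
        if drop_exceptions and rec.has_exception:
            n_exc += 1
            continue
        if drop_partials and rec.is_partial:
            n_part += 1
            continue
        kept.append(rec)
    if n_exc or n_part:
        logger.info(
            "%s: removed %d exception and %d partial records", source, n_exc, n_part
        )
    if records and not kept:
        raise EmptySpeciesError(f"{source}: all records removed by filters")
    return kept


def build_species_profile(
    records: Sequence[GeneRecord],
    mode: Mode = "codon",
    table_id: int = 1,
    species: str | None = None,
) -> SpeciesProfile:
    """Assemble a species' motif profile from filtered gene records.

    Every gene contributes with equal weight regardless of annotation.  Genes
    whose sequence is empty or shorter than one codon after normalization are
    skipped with a logged warning; if none remain an empty-species error is
    raised.
    """
    if mode not in ("codon", "amino_acid"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    label = species if species is not None else (records[0].species if records else "<unknown>")
    counts: Counter[AversionMotif] = Counter()
    n_skipped = 0
    for rec in records:
        try:
            seq = normalize_sequence(rec.sequence, rec.record_id)
            if mode == "codon":
                motif = extract_codon_motif(seq, rec.record_id)
            else:
                motif = extract_aa_motif(translate(seq, table_id, rec.record_id))
        except (EmptySequenceError, SequenceTooShortError) as exc:
            logger.warning("%s: skipping gene: %s", label, exc)
            n_skipped += 1
            continue
        counts[motif] += 1
    if not counts:
        raise EmptySpeciesError(
            f"species {label!r}: no usable genes ({n_skipped} skipped)"
        )
    if n_skipped:
        logger.info("%s: skipped %d unusable genes", label, n_skipped)
    return SpeciesProfile(species=label, motif_counts=dict(counts), mode=mode)


def profile_from_fasta(
    path: str | Path,
    mode: Mode = "codon",
    table_id: int = 1,
    species: str | None = None,
    longest_isoforms: bool = True,
    drop_exceptions: bool = True,
    drop_partials: bool = False,
) -> SpeciesProfile:
    """Full preprocessing pipeline: FASTA → filters → profile."""
    records = read_fasta(path, species=species)
    if not records:
        raise EmptySpeciesError(f"{path}: no FASTA records")
    if longest_isoforms:
        records = select_longest_isoforms(records)
    records = filter_records(
        records, drop_exceptions=drop_exceptions, drop_partials=drop_partials,
        source=str(path),
    )
    return build_species_profile(records, mode=mode, table_id=table_id, species=species or records[0].species)
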