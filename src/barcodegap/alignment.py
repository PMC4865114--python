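"""Aligned barcode datasets: FASTA I/O, label parsing, trimming, subsetting.

The universal input of the pipeline is an aligned multi-FASTA whose
description lines carry binomial taxonomic labels, e.g.::

    >Oerstedia dorsalis KU839732
    ACGT...

Labels are parsed with a small grammar: the label is the run of tokens up
to (but excluding) the first token containing a digit; the genus is the
first token and the epithet, if any, the second.  Epithets drawn from the
open-nomenclature placeholder set ("sp.", "cf.", "aff." and their
dot-less forms) mark a label as imprecise — such records cannot be
assigned to the intraspecific or interspecific comparison bin with
certainty and are purged before distance analysis.

Record identifiers are taken from the first digit-bearing token of the
header (an accession-style token); headers without one use the full label
with spaces replaced by underscores.  Identifiers must be unique within a
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentError,
    DuplicateIdError,
    EmptyDatasetError,
    FormatError,
    LabelError,
    MissingTaxonError,
)

#: Epithets that do NOT constitute a species-level identification.
PLACEHOLDER_EPITHETS = frozenset({"sp", "sp.", "cf", "cf.", "aff", "aff."})

#: Unambiguous nucleotide states.
BASES = "ACGT"

#: IUPAC ambiguity codes expanded to the unambiguous bases they may denote.
IUPAC_EXPANSION: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ALLOWED_RESIDUES = frozenset(IUPAC_EXPANSION) | {"-"}

GAP = "-"


@dataclass(frozen=True)
class TaxonLabel:
    """A parsed binomial (or partial) taxonomic label.

    ``precise`` is true iff a species-level epithet other than an
    open-nomenclature placeholder is present.
    """

    genus: str
    epithet: str | None
    precise: bool
    full: str

    def species_key(self) -> tuple:
        """Case-insensitive (genus, epithet) key for conspecificity tests."""
        return (self.genus.lower(), (self.epithet or "").lower())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.full


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    label: TaxonLabel
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedDataset:
    """An ordered collection of equal-length, labelled sequence records."""

    records: list
    length: int = field(default=-1)

    def __post_init__(self):
        if not self.records:
            raise EmptyDatasetError("dataset has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if self.length == -1:
            self.length = length
        elif self.length != length:
            raise AlignmentError(
                f"declared length {self.length} != sequence length {length}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    def labels(self) -> dict:
        """id -> TaxonLabel mapping."""
        return {r.id: r.label for r in self.records}

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


def parse_taxon_label(header: str, placeholders: frozenset = PLACEHOLDER_EPITHETS) -> TaxonLabel:
    """Parse a FASTA description line into a :class:`TaxonLabel`.

    The label is the run of leading tokens free of digits; genus is the
    first token, epithet the second (when present).
    """
    header = header.strip()
    if not header:
        raise LabelError("empty header")
    tokens = []
    for tok in header.split():
        if any(ch.isdigit() for ch in tok):
            break
        tokens.append(tok)
    if not tokens:
        raise LabelError(f"no alphabetic label tokens in header: {header!r}")
    genus = tokens[0]
    epithet = tokens[1] if len(tokens) > 1 else None
    precise = epithet is not None and epithet.lower() not in placeholders
    full = " ".join(tokens[:2]) if epithet else genus
    return TaxonLabel(genus=genus, epithet=epithet, precise=precise, full=full)


def _record_id(header: str, label: TaxonLabel) -> str:
    for tok in header.split():
        if any(ch.isdigit() for ch in tok):
            return tok
    return label.full.replace(" ", "_")


def normalize_residues(raw: str) -> str:
    """Upper-case, map U->T and ?->N, and validate the residue alphabet."""
    s = raw.upper().replace("U", "T").replace("?", "N").replace(".", GAP)
    bad = set(s) - ALLOWED_RESIDUES
    if bad:
        raise FormatError(f"invalid residue characters: {sorted(bad)}")
    return s


def read_fasta_alignment(path, placeholders: frozenset = PLACEHOLDER_EPITHETS) -> AlignedDataset:
    """Read an aligned multi-FASTA into an :class:`AlignedDataset`.

    Raises :class:`FormatError` for non-FASTA content,
    :class:`AlignmentError` on unequal lengths and
    :class:`DuplicateIdError` on id collisions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path} does not look like FASTA (no leading '>')")
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        header = bio_rec.description
        label = parse_taxon_label(header, placeholders)
        records.append(
            SequenceRecord(
                id=_record_id(header, label),
                label=label,
                residues=normalize_residues(str(bio_rec.seq)),
            )
        )
    if not records:
        raise FormatError(f"{path} contains no FASTA records")
    return AlignedDataset(records=records)


def write_fasta(ds: AlignedDataset, path, wrap: int = 70) -> None:
    """Write the dataset as multi-FASTA, header = 'Genus epithet ID'."""
    bio_records = []
    for r in ds:
        parts = [r.label.full]
        if r.id != r.label.full.replace(" ", "_"):
            parts.append(r.id)
        header = " ".join(parts)
        bio_records.append(
            _BioSeqRecord(Seq(r.residues), id=header.split()[0], description=header)
        )
    with open(path, "w") as fh:
        for rec in bio_records:
            fh.write(f">{rec.description}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def trim_terminal_gap_columns(
    ds: AlignedDataset, max_terminal_gap_fraction: float = 0.0
) -> AlignedDataset:
    """Delete gappy leading and lagging alignment columns.

    Columns are scanned from each end inward; a column is removed while its
    gap fraction exceeds ``max_terminal_gap_fraction``.  The scan stops at
    the first retained column, so internal gap columns are untouched.
    """
    n = len(ds)
    gap_frac = []
    for col in range(ds.length):
        gaps = sum(1 for r in ds.records if r.residues[col] == GAP)
        gap_frac.append(gaps / n)
    start = 0
    while start < ds.length and gap_frac[start] > max_terminal_gap_fraction:
        start += 1
    end = ds.length
    while end > start and gap_frac[end - 1] > max_terminal_gap_fraction:
        end -= 1
    if start >= end:
        raise EmptyDatasetError("all alignment columns removed by terminal trimming")
    if start == 0 and end == ds.length:
        return ds
    return AlignedDataset(
        records=[
            SequenceRecord(r.id, r.label, r.residues[start:end]) for r in ds.records
        ]
    )


def purge_imprecise_labels(ds: AlignedDataset) -> AlignedDataset:
    """Drop records whose labels lack a species-level epithet.

    Sequences labelled e.g. "Micrura sp." cannot be funnelled into the
    intraspecific or interspecific bin and are excluded before distance
    analysis.  Idempotent; record order preserved.
    """
    kept = [r for r in ds.records if r.label.precise]
    if not kept:
        raise EmptyDatasetError("no records with precise species-level labels")
    if len(kept) == len(ds.records):
        return ds
    return AlignedDataset(records=kept)


TAXONOMY_LEVELS = ("genus", "family", "subclass", "phylum")


class TaxonomyMap:
    """Maps labels or genera to higher taxonomic groups.

    Backed by a TSV with header ``label  genus  family  subclass  phylum``.
    Lookup tries the full label first, then the genus token.
    """

    def __init__(self, rows: Iterable[Mapping[str, str]]):
        self._by_key: dict = {}
        for row in rows:
            key = row["label"].strip()
            self._by_key[key.lower()] = {
                lvl: row[lvl].strip() for lvl in TAXONOMY_LEVELS
            }
        if not self._by_key:
            raise FormatError("taxonomy map is empty")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        import csv

        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = {"label", *TAXONOMY_LEVELS} - set(reader.fieldnames or ())
            if missing:
                raise FormatError(f"taxonomy TSV missing columns: {sorted(missing)}")
            return cls(list(reader))

    def group(self, label: TaxonLabel, level: str) -> str:
        if level not in TAXONOMY_LEVELS:
            raise ValueError(f"unknown taxonomic level: {level}")
        row = self._by_key.get(label.full.lower()) or self._by_key.get(
            label.genus.lower()
        )
        if row is None:
            raise MissingTaxonError([label.full], level=level)
        return row[level]


def subset_by_group(
    ds: AlignedDataset, tmap: TaxonomyMap, level: str, name: str
) -> AlignedDataset:
    """Select the records whose mapped group at ``level`` equals ``name``."""
    offenders = []
    kept = []
    for r in ds.records:
        try:
            group = tmap.group(r.label, level)
        except MissingTaxonError:
            offenders.append(r.label.full)
            continue
        if group.lower() == name.lower():
            kept.append(r)
    if offenders:
        raise MissingTaxonError(offenders, level=level)
    if not kept:
        raise EmptyDatasetError(f"no records in {level}={name}")
    return AlignedDataset(records=kept)
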