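"""Sequence and domain-annotation I/O.

Reads protein FASTA files and tab-separated domain-annotation tables (the
shape exported by InterPro/dbCAN-style annotation runs), removes exact
duplicate sequences, and slices annotated domains (CBM2, AA10) out of full
protein sequences. All residue coordinates are 1-based inclusive, matching
the residue numbering convention of structural biology (e.g. a CBM2 spanning
residues 263-364 has length 102).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import ParseError, ValidationError

#: Domain families consumed downstream; anything else becomes "other".
KNOWN_FAMILIES = ("CBM2", "AA10")

DOMAIN_TABLE_COLUMNS = ("protein_id", "family", "start", "end")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: uppercase amino-acid string, no gaps."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has empty sequence")
        if "-" in self.sequence or "." in self.sequence:
            raise ValidationError(f"record {self.id!r} contains gap characters")


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain of a protein: family plus 1-based inclusive coordinates."""

    protein_id: str
    family: str  # "CBM2", "AA10" or "other"
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"annotation for {self.protein_id!r}: invalid range "
                f"{self.start}-{self.end} (need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainSequence:
    """The residues of one annotated domain, sliced from its parent protein."""

    protein_id: str
    family: str
    start: int
    end: int
    residues: str

    def __post_init__(self):
        if len(self.residues) != self.end - self.start + 1:
            raise ValidationError(
                f"domain {self.protein_id}:{self.start}-{self.end}: residue "
                f"string length {len(self.residues)} != span"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    Sequences are uppercased; record order is preserved. An empty file
    yields an empty list. A record with an empty sequence raises
    :class:`ParseError` naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq,
                                      description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


def domains_to_fasta(domains: Iterable[DomainSequence], path: str | Path) -> None:
    """Write domain subsequences as FASTA, ids as protein_id/start-end."""
    recs = [SequenceRecord(id=f"{d.protein_id}/{d.start}-{d.end}",
                           sequence=d.residues) for d in domains]
    write_fasta(recs, path)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(records: list[SequenceRecord]) -> tuple[list[SequenceRecord], int]:
    """Remove exact full-sequence duplicates, keeping the first occurrence.

    Returns ``(unique, removed_count)``. Identity is exact string equality
    of the uppercased sequence; clustering below 100% identity is out of
    scope (delegated to external tools).
    """
    seen: set[str] = set()
    unique = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            unique.append(rec)
    return unique, len(records) - len(unique)


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV domain table with header protein_id/family/start/end.

    Rows with families other than CBM2/AA10 are retained with
    ``family="other"``. Non-integer or inverted coordinates raise
    :class:`ValidationError` carrying the 1-based row number.
    """
    annotations = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != list(DOMAIN_TABLE_COLUMNS):
            raise ParseError(
                f"{path}: expected header {DOMAIN_TABLE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(fields)}")
            pid, family, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if family not in KNOWN_FAMILIES:
                family = "other"
            try:
                annotations.append(
                    DomainAnnotation(protein_id=pid, family=family,
                                     start=start, end=end))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return annotations


def write_domain_table(annotations: Iterable[DomainAnnotation],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_TABLE_COLUMNS) + "\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.family}\t{a.start}\t{a.end}\n")


# ---------------------------------------------------------------------------
# Domain extraction
# ---------------------------------------------------------------------------

def extract_domains(records: list[SequenceRecord],
                    annotations: list[DomainAnnotation]) -> list[DomainSequence]:
    """Slice each annotated domain out of its parent protein (1-based incl.).

    Raises :class:`ValidationError` listing dangling protein ids, or naming
    the first out-of-range annotation.
    """
    by_id = {r.id: r for r in records}
    missing = sorted({a.protein_id for a in annotations
                      if a.protein_id not in by_id})
    if missing:
        raise ValidationError(
            "annotations reference unknown protein ids: " + ", ".join(missing))
    domains = []
    for a in annotations:
        parent = by_id[a.protein_id]
        if a.end > len(parent.sequence):
            raise ValidationError(
                f"annotation {a.protein_id}:{a.start}-{a.end} exceeds "
                f"sequence length {len(parent.sequence)}")
        domains.append(DomainSequence(
            protein_id=a.protein_id, family=a.family, start=a.start,
            end=a.end, residues=parent.sequence[a.start - 1:a.end]))
    return domains
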