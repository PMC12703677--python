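"""Alignment column mapping, residue-combination counting, tree annotation
and screen accounting.

Given an MSA of CBM2 (or AA10) sequences, reference residue positions such
as Met266/Met286/His288 of ScLPMO10C are mapped to alignment columns, and
the residue combination every sequence carries at those columns is counted
(e.g. the REF vs HQY second-sphere combinations of AA10 subclades). Motif
classes are painted onto Newick tree tips as an annotation table, clade
compositions are summarised, and the screen totals are assembled into a
report with recomputed percentages (MMH occurrence among unique proteins,
AA10 association among confirmed, REF fraction among AA10-linked).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio import AlignIO

from .errors import ParseError, ValidationError
from .motif_scan import ProteinMotifClass

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: tree-tip colour code per motif class (green = MMH-in-CBM2 branches)
CLASS_COLORS = {
    "REF-MMH": "green",
    "MMH-only": "orange",
    "REF-only": "blue",
    "none": "gray",
    "unknown": "black",
}


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Ordered aligned sequences; '-' is the gap character."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(
                f"aligned strings have unequal lengths: {sorted(lengths)}")
        if len(self.ids) != len(set(self.ids)):
            raise ValidationError("duplicate sequence ids in alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    ids = [rec.id for rec in msa]
    return Alignment(ids=ids, rows={rec.id: str(rec.seq).upper() for rec in msa})


@dataclass(frozen=True)
class ColumnMap:
    """Reference ungapped 1-based positions -> 0-based alignment columns."""

    reference_id: str
    positions: tuple[int, ...]
    columns: tuple[int, ...]


def map_reference_positions(alignment: Alignment, reference_id: str,
                            positions: Sequence[int]) -> ColumnMap:
    """Map ungapped reference positions to alignment columns.

    Column ``c`` maps position ``p`` iff the reference row has exactly ``p``
    non-gap characters in columns ``0..c`` and column ``c`` is not a gap.
    """
    if reference_id not in alignment.rows:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    row = alignment.rows[reference_id]
    ungapped_len = len(row) - row.count(GAP)
    pos_to_col: dict[int, int] = {}
    count = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            count += 1
            pos_to_col[count] = col
    columns = []
    for p in positions:
        if not 1 <= p <= ungapped_len:
            raise ValidationError(
                f"position {p} outside ungapped length {ungapped_len} of "
                f"reference {reference_id!r}")
        columns.append(pos_to_col[p])
    return ColumnMap(reference_id=reference_id, positions=tuple(positions),
                     columns=tuple(columns))


# ---------------------------------------------------------------------------
# Combination counting
# ---------------------------------------------------------------------------

@dataclass
class CombinationTable:
    """Counts of residue combinations at the mapped columns.

    Rows are (combination key, count, member ids), sorted by descending
    count then key; counts sum to the number of aligned sequences.
    """

    positions: tuple[int, ...]
    rows: list[tuple[str, int, list[str]]]

    def counts(self) -> dict[str, int]:
        return {key: n for key, n, _ in self.rows}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("combination\tcount\tmembers\n")
            for key, n, members in self.rows:
                fh.write(f"{key}\t{n}\t{','.join(members)}\n")


def _combo_char(ch: str) -> str:
    if ch == GAP:
        return GAP
    return ch if ch in CANONICAL else "X"


def count_combinations(alignment: Alignment, colmap: ColumnMap) -> CombinationTable:
    """Tally the residue tuple at the mapped columns for every sequence.

    Gaps render as '-', non-canonical residues as 'X'. Each sequence lands
    in exactly one row.
    """
    for col in colmap.columns:
        if not 0 <= col < alignment.length:
            raise ValidationError(f"column {col} outside alignment")
    members: dict[str, list[str]] = {}
    for sid in alignment.ids:
        row = alignment.rows[sid]
        key = "".join(_combo_char(row[c]) for c in colmap.columns)
        members.setdefault(key, []).append(sid)
    rows = sorted(((key, len(ids), ids) for key, ids in members.items()),
                  key=lambda r: (-r[1], r[0]))
    return CombinationTable(positions=colmap.positions, rows=rows)


# ---------------------------------------------------------------------------
# Tree annotation
# ---------------------------------------------------------------------------

@dataclass
class TreeAnnotation:
    """Per-tip motif-class table suitable for external tree-colouring tools."""

    tips: list[str]
    classes: dict[str, str]
    colors: dict[str, str] = field(default_factory=dict)
    tree: Optional[dendropy.Tree] = None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tip\tclass\tcolor\n")
            for tip in self.tips:
                fh.write(f"{tip}\t{self.classes[tip]}\t{self.colors[tip]}\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy's reader errors vary by cause
        raise ParseError(f"{path}: {exc}") from None
    tree.is_rooted = True  # clades read as written in the Newick string
    return tree


def annotate_tree_tips(tree: dendropy.Tree | str | Path,
                       class_map: Mapping[str, ProteinMotifClass | str],
                       ) -> TreeAnnotation:
    """Annotate every tree tip with its motif class and colour code.

    Tips absent from ``class_map`` are annotated "unknown". Duplicate tip
    labels raise :class:`ValidationError`.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_tree(tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in tips if tips.count(t) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    classes = {}
    for tip in tips:
        entry = class_map.get(tip)
        if entry is None:
            classes[tip] = "unknown"
        elif isinstance(entry, ProteinMotifClass):
            classes[tip] = entry.motif_class
        else:
            classes[tip] = str(entry)
    colors = {tip: CLASS_COLORS.get(cls, "black")
              for tip, cls in classes.items()}
    return TreeAnnotation(tips=tips, classes=classes, colors=colors, tree=tree)


@dataclass
class CladeComposition:
    n_tips: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]


def clade_composition(annotation: TreeAnnotation,
                      tips: Optional[Iterable[str]] = None,
                      mrca_of: Optional[tuple[str, str]] = None,
                      ) -> CladeComposition:
    """Class counts and fractions within a clade.

    The clade is an explicit tip list, or the leaf set under the MRCA of two
    named tips (requires the annotation to carry its tree). Fractions sum
    to 1; an empty clade is an error.
    """
    if mrca_of is not None:
        if annotation.tree is None:
            raise ValidationError("MRCA clade spec requires a tree")
        taxa = annotation.tree.taxon_namespace.get_taxa(labels=list(mrca_of))
        if len(taxa) != 2:
            raise ValidationError(f"MRCA tips {mrca_of} not all in tree")
        node = annotation.tree.mrca(taxa=taxa)
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
    if tips is None:
        tips = annotation.tips
    tips = list(tips)
    if not tips:
        raise ValidationError("empty clade")
    unknown = set(tips) - set(annotation.tips)
    if unknown:
        raise ValidationError(f"clade tips not in tree: {sorted(unknown)}")
    counts: dict[str, int] = {}
    for tip in tips:
        cls = annotation.classes[tip]
        counts[cls] = counts.get(cls, 0) + 1
    n = len(tips)
    return CladeComposition(
        n_tips=n, class_counts=counts,
        class_fractions={cls: c / n for cls, c in counts.items()})


# ---------------------------------------------------------------------------
# Screen report
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ScreenReport:
    """Screen totals with percentages recomputed from the integer counts.

    ``confirmed`` partitions into AA10-linked and CBM2-only (proteins whose
    confirmed MMH-CBM2 has no catalytic domain). Percentages are never
    stored: they are recomputed on demand at one-decimal (half-up) and
    integer precision.
    """

    retrieved: int
    unique: int
    regex_hits: int
    aa10_linked: int
    cbm2_only: int
    ref_positive: int

    def __post_init__(self):
        checks = [
            (self.unique <= self.retrieved, "unique <= retrieved"),
            (self.regex_hits <= self.unique, "regex_hits <= unique"),
            (self.confirmed <= self.regex_hits, "confirmed <= regex_hits"),
            (self.ref_positive <= self.aa10_linked,
             "ref_positive <= aa10_linked"),
            (min(self.retrieved, self.unique, self.regex_hits,
                 self.aa10_linked, self.cbm2_only, self.ref_positive) >= 0,
             "counts nonnegative"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValidationError(f"inconsistent counts: violated {name}")

    @property
    def confirmed(self) -> int:
        return self.aa10_linked + self.cbm2_only

    def percentages(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """MMH occurrence, AA10 association and REF fraction, in percent."""
        def pct(num, den):
            return round_half_up(100.0 * num / den, ndigits) if den else None
        return {
            "mmh_occurrence": pct(self.confirmed, self.unique),
            "aa10_association": pct(self.aa10_linked, self.confirmed),
            "ref_fraction": pct(self.ref_positive, self.aa10_linked),
        }

    def to_dict(self) -> dict:
        return {
            "counts": {
                "retrieved": self.retrieved,
                "unique": self.unique,
                "regex_hits": self.regex_hits,
                "confirmed": self.confirmed,
                "aa10_linked": self.aa10_linked,
                "cbm2_only": self.cbm2_only,
                "ref_positive": self.ref_positive,
            },
            "percentages": self.percentages(1),
            "percentages_integer": self.percentages(0),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_screen_report(retrieved: int, unique: int, regex_hits: int,
                        aa10_linked: int, cbm2_only: int,
                        ref_positive: int) -> ScreenReport:
    """Validate the screen counts and wrap them in a :class:`ScreenReport`."""
    return ScreenReport(retrieved=retrieved, unique=unique,
                        regex_hits=regex_hits, aa10_linked=aa10_linked,
                        cbm2_only=cbm2_only, ref_positive=ref_positive)
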