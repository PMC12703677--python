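"""Motif grammars and domain scanning.

The copper-site grammar searched in CBM2 modules is MMH: a methionine, any
gap, a second methionine, exactly one residue, a histidine — the regular
expression ``M.*M.H`` in ScLPMO10C numbering instantiated by Met266, Met286
and His288. AA10 catalytic domains are searched for the second-coordination-
sphere REF motif: Arg, a 3-10 residue gap, Glu, one residue, Phe
(Arg212/Glu217/Phe219 in ScLPMO10C).

A motif pattern is an ordered list of anchored residue letters with bounded
(possibly unbounded) spacers between consecutive anchors. ``scan_motif``
enumerates every distinct anchor-position tuple satisfying the grammar;
dataset-level counting uses presence per domain, and the canonical hit for
downstream geometric checks is the tuple with the smallest last anchor, then
smallest first anchor (deterministic, and matching the annotated site in the
worked cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .sequence_io import DomainSequence

# Spacer bounds are gaps BETWEEN consecutive anchors: (min, max), max=None
# meaning unbounded (limited only by the domain length).
Spacer = tuple[int, Optional[int]]


@dataclass(frozen=True)
class MotifPattern:
    """Anchored-residue motif grammar.

    ``anchors`` are single residue letters; ``spacers[i]`` bounds the number
    of residues between ``anchors[i]`` and ``anchors[i+1]``.
    """

    name: str
    anchors: tuple[str, ...]
    spacers: tuple[Spacer, ...]
    families: tuple[str, ...] = ()          # domain families this applies to
    experimental: bool = False

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValidationError(f"pattern {self.name!r}: need >= 2 anchors")
        if len(self.spacers) != len(self.anchors) - 1:
            raise ValidationError(
                f"pattern {self.name!r}: {len(self.anchors)} anchors need "
                f"{len(self.anchors) - 1} spacers")
        for lo, hi in self.spacers:
            if lo < 0 or (hi is not None and hi < lo):
                raise ValidationError(
                    f"pattern {self.name!r}: invalid spacer bounds ({lo},{hi})")


#: M, any gap, M, exactly one residue, H  ("M.*M.H"); CBM2 domains.
MMH = MotifPattern("MMH", ("M", "M", "H"), ((0, None), (1, 1)),
                   families=("CBM2",))

#: R, gap 3-10, E, one residue, F  ("RX(3,10)EXF"); AA10 domains.
REF = MotifPattern("REF", ("R", "E", "F"), ((3, 10), (1, 1)),
                   families=("AA10",))

#: Expanded copper-site grammar (two Met, two His) of AfLPMO10B-like CBM2s.
#: No authoritative spacing is published for it; flagged experimental.
MMHH = MotifPattern("MMHH", ("M", "M", "H", "H"), ((0, None), (1, 1), (1, 1)),
                    families=("CBM2",), experimental=True)

DEFAULT_PATTERNS = (MMH, REF)


@dataclass(frozen=True)
class MotifHit:
    """One anchor-position tuple matching a pattern within a domain.

    Positions are 1-based within the domain subsequence.
    """

    protein_id: str
    family: str
    motif: str
    anchor_positions: tuple[int, ...]
    anchor_residues: tuple[str, ...]
    domain_start: int = 1  # parent-protein position of domain residue 1


@dataclass
class ProteinMotifClass:
    """Motif co-occurrence class of a protein.

    ``REF-MMH``: REF hit in an AA10 domain and a (structurally confirmed,
    when confirmation is enabled) MMH hit in a CBM2 domain; ``MMH-only`` /
    ``REF-only`` / ``none`` accordingly.
    """

    protein_id: str
    motif_class: str  # "REF-MMH" | "MMH-only" | "REF-only" | "none"
    supporting_hits: list[MotifHit] = field(default_factory=list)


CLASSES = ("REF-MMH", "MMH-only", "REF-only", "none")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_motif(domain: DomainSequence, pattern: MotifPattern) -> list[MotifHit]:
    """Enumerate all anchor-position tuples of ``pattern`` in a domain.

    Non-canonical residues (X, B, Z, ...) never match an anchor letter.
    Tuples are returned sorted by (last anchor, first anchor, full tuple),
    so the first element is the canonical hit.
    """
    seq = domain.residues
    n = len(seq)
    hits: list[tuple[int, ...]] = []

    def extend(tup: tuple[int, ...], level: int) -> None:
        if level == len(pattern.anchors):
            hits.append(tup)
            return
        lo, hi = pattern.spacers[level - 1]
        prev = tup[-1]
        first = prev + 1 + lo
        last = n if hi is None else min(n, prev + 1 + hi)
        letter = pattern.anchors[level]
        for pos in range(first, last + 1):
            if seq[pos - 1] == letter:
                extend(tup + (pos,), level + 1)

    first_letter = pattern.anchors[0]
    for pos in range(1, n + 1):
        if seq[pos - 1] == first_letter:
            extend((pos,), 1)

    hits.sort(key=lambda t: (t[-1], t[0], t))
    return [MotifHit(protein_id=domain.protein_id, family=domain.family,
                     motif=pattern.name, anchor_positions=t,
                     anchor_residues=tuple(seq[p - 1] for p in t),
                     domain_start=domain.start)
            for t in hits]


def canonical_hit(hits: Sequence[MotifHit]) -> Optional[MotifHit]:
    """Hit with smallest last-anchor position, ties by first anchor."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.anchor_positions[-1],
                                    h.anchor_positions[0],
                                    h.anchor_positions))


def scan_dataset(domains: Iterable[DomainSequence],
                 patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
                 ) -> dict[str, list[MotifHit]]:
    """Scan every domain with the patterns matching its family.

    Returns protein_id -> all hits across that protein's domains. A protein
    is motif-positive for a pattern if at least one domain of the pattern's
    family has at least one hit (presence semantics).
    """
    result: dict[str, list[MotifHit]] = {}
    for dom in domains:
        for pat in patterns:
            if pat.families and dom.family not in pat.families:
                continue
            found = scan_motif(dom, pat)
            if found:
                result.setdefault(dom.protein_id, []).extend(found)
    return result


def positive_proteins(hits_by_protein: Mapping[str, list[MotifHit]],
                      motif: str, family: str | None = None) -> set[str]:
    """Ids of proteins with >= 1 hit of ``motif`` (optionally in ``family``)."""
    out = set()
    for pid, hits in hits_by_protein.items():
        for h in hits:
            if h.motif == motif and (family is None or h.family == family):
                out.add(pid)
                break
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_protein(protein_id: str,
                     hits: Sequence[MotifHit],
                     confirmation: Optional[bool] = None,
                     require_confirmation: bool = True) -> ProteinMotifClass:
    """Assign the REF/MMH co-occurrence class of one protein.

    ``confirmation`` is the structural-verification verdict for the protein's
    CBM2 MMH site (None when no verification was run). With
    ``require_confirmation`` (the default), a regex MMH hit only counts when
    structurally confirmed; a hit that failed geometry — or that could not be
    verified for lack of a model — does not.
    """
    mmh_hits = [h for h in hits if h.motif == "MMH" and h.family == "CBM2"]
    ref_hits = [h for h in hits if h.motif == "REF" and h.family == "AA10"]
    has_mmh = bool(mmh_hits)
    if has_mmh and require_confirmation:
        has_mmh = confirmation is True
    has_ref = bool(ref_hits)
    if has_mmh and has_ref:
        cls = "REF-MMH"
    elif has_mmh:
        cls = "MMH-only"
    elif has_ref:
        cls = "REF-only"
    else:
        cls = "none"
    supporting = (mmh_hits if has_mmh else []) + (ref_hits if has_ref else [])
    return ProteinMotifClass(protein_id=protein_id, motif_class=cls,
                             supporting_hits=supporting)


def classify_dataset(hits_by_protein: Mapping[str, Sequence[MotifHit]],
                     confirmations: Optional[Mapping[str, bool]] = None,
                     protein_ids: Optional[Iterable[str]] = None,
                     require_confirmation: bool = True,
                     ) -> dict[str, ProteinMotifClass]:
    """Classify every protein (ids without hits classify as "none")."""
    ids = set(hits_by_protein)
    if protein_ids is not None:
        ids |= set(protein_ids)
    confirmations = confirmations or {}
    return {pid: classify_protein(pid, list(hits_by_protein.get(pid, [])),
                                  confirmation=confirmations.get(pid),
                                  require_confirmation=require_confirmation)
            for pid in sorted(ids)}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def hits_to_tsv(hits_by_protein: Mapping[str, Sequence[MotifHit]],
                path: str | Path) -> None:
    """Write hits as TSV: protein_id, family, motif, comma-joined positions."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily\tmotif\tpositions\n")
        for pid in sorted(hits_by_protein):
            for h in hits_by_protein[pid]:
                pos = ",".join(str(p) for p in h.anchor_positions)
                fh.write(f"{h.protein_id}\t{h.family}\t{h.motif}\t{pos}\n")
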