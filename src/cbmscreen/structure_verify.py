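"""Geometric confirmation of MMH motifs on predicted 3-D models.

A regex match only establishes that the residues occur in the right order;
whether they form a copper site is a question of geometry. This module reads
Cα coordinates from PDB-format models (e.g. AlphaFold predictions) and
checks, within a CBM2 domain's residue range, for two methionines and a
histidine mutually within a Cα–Cα distance threshold (8.5 Å by default).

"Within 8.5 Å" is interpreted in its strictest reading — all three pairwise
Cα–Cα distances at or below the threshold (``geometry_mode="all_pairs"``).
The looser reading, each Met within the threshold of the His only, is
available as ``geometry_mode="pair_to_his"``. By default every Met/Met/His
triplet in the domain range is searched (``anchor_mode="whole_domain"``);
``anchor_mode="regex_anchors"`` restricts the search to the residues the
sequence scan anchored.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import ParseError, ValidationError
from .motif_scan import MotifHit
from .sequence_io import DomainAnnotation

DEFAULT_THRESHOLD = 8.5  # Å, Cα–Cα

GEOMETRY_MODES = ("all_pairs", "pair_to_his")
ANCHOR_MODES = ("whole_domain", "regex_anchors")

MET, HIS = "MET", "HIS"


@dataclass
class StructureModel:
    """Cα-only model: residue index -> (3-letter name, Cα coordinate in Å)."""

    protein_id: str
    residues: dict[int, tuple[str, np.ndarray]]
    chain_id: str = "A"

    def indices_of(self, resname: str, start: int, end: int) -> list[int]:
        return [i for i, (name, _) in sorted(self.residues.items())
                if name == resname and start <= i <= end]

    def ca(self, index: int) -> np.ndarray:
        try:
            return self.residues[index][1]
        except KeyError:
            raise ValidationError(
                f"{self.protein_id}: residue {index} has no Cα record"
            ) from None


@dataclass
class GeometricVerification:
    """Outcome of the Met/Met/His distance check for one protein."""

    protein_id: str
    triplet: Optional[tuple[int, int, int]]  # (met1, met2, his) indices
    distances: Optional[tuple[float, float, float]]  # d(M1,M2), d(M1,H), d(M2,H)
    passed: bool
    threshold: float
    status: str = "failed"  # confirmed | failed | no_candidates | unverified
    reason: str = ""
    geometry_mode: str = "all_pairs"
    review: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _prescan_atom_lines(path: str | Path) -> None:
    """Cheap format validation so errors can carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable ATOM record") from None
            icode = line[26]
            if icode != " ":
                raise ValidationError(
                    f"{path}:{lineno}: insertion code {icode!r} not supported")


def read_structure(path: str | Path, protein_id: str | None = None,
                   chain_id: str | None = None) -> StructureModel:
    """Read Cα atoms from a PDB file into a :class:`StructureModel`.

    Non-Cα atoms are ignored; residues lacking a Cα are absent from the
    model (referencing them later raises). For disordered Cα atoms the
    first/highest-occupancy altloc is kept.
    """
    path = Path(path)
    _prescan_atom_lines(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ParseError(f"{path}: {exc}") from None
    model = next(iter(structure))
    chains = list(model)
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValidationError(f"{path}: no chain {chain_id!r}")
    chain = chains[0]
    residues: dict[int, tuple[str, np.ndarray]] = {}
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        if "CA" not in res:
            continue  # Cα-only contract: residue dropped
        residues[resseq] = (res.resname.strip(),
                            np.asarray(res["CA"].coord, dtype=float))
    return StructureModel(protein_id=protein_id or path.stem,
                          residues=residues, chain_id=chain.id)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _pairwise(model: StructureModel,
              triplet: tuple[int, int, int]) -> tuple[float, float, float]:
    m1, m2, h = (model.ca(i) for i in triplet)
    return (float(np.linalg.norm(m1 - m2)),
            float(np.linalg.norm(m1 - h)),
            float(np.linalg.norm(m2 - h)))


def _criterion_distances(dists: tuple[float, float, float],
                         geometry_mode: str) -> tuple[float, ...]:
    if geometry_mode == "all_pairs":
        return dists
    return dists[1:]  # pair_to_his: the two Met–His distances only


def verify_motif_geometry(model: StructureModel,
                          start: int, end: int,
                          threshold: float = DEFAULT_THRESHOLD,
                          geometry_mode: str = "all_pairs",
                          anchor_indices: Optional[Sequence[int]] = None,
                          ) -> GeometricVerification:
    """Search residues ``start..end`` for a passing Met/Met/His triplet.

    Enumerates every (Met, Met, His) triplet in the range (or only the
    regex-anchored residues when ``anchor_indices`` is given), ranks by the
    largest criterion distance, and reports the best triplet. ``passed`` is
    true iff the best triplet's criterion distances are all <= threshold.
    """
    if geometry_mode not in GEOMETRY_MODES:
        raise ValidationError(f"unknown geometry mode {geometry_mode!r}")
    mets = model.indices_of(MET, start, end)
    hises = model.indices_of(HIS, start, end)
    if anchor_indices is not None:
        allowed = set(anchor_indices)
        mets = [i for i in mets if i in allowed]
        hises = [i for i in hises if i in allowed]
    if len(mets) < 2 or not hises:
        return GeometricVerification(
            protein_id=model.protein_id, triplet=None, distances=None,
            passed=False, threshold=threshold, status="no_candidates",
            reason=f"{len(mets)} Met / {len(hises)} His in range "
                   f"{start}-{end} (need 2 Met, 1 His)",
            geometry_mode=geometry_mode)

    best: Optional[tuple[float, tuple[int, int, int],
                         tuple[float, float, float]]] = None
    for m1, m2 in itertools.combinations(mets, 2):
        for h in hises:
            dists = _pairwise(model, (m1, m2, h))
            crit = max(_criterion_distances(dists, geometry_mode))
            if best is None or crit < best[0]:
                best = (crit, (m1, m2, h), dists)
    crit, triplet, dists = best
    passed = crit <= threshold
    return GeometricVerification(
        protein_id=model.protein_id, triplet=triplet, distances=dists,
        passed=passed, threshold=threshold,
        status="confirmed" if passed else "failed",
        geometry_mode=geometry_mode)


def verify_mmhh_geometry(model: StructureModel, start: int, end: int,
                         threshold: float = DEFAULT_THRESHOLD,
                         ) -> GeometricVerification:
    """Expanded-motif (M,M,H,H) check — experimental.

    Requires every Met–Met and Met–His pair within the threshold among some
    (Met, Met, His, His) quadruplet; the reported triplet/distances describe
    the (M, M, first H) face of the best quadruplet.
    """
    mets = model.indices_of(MET, start, end)
    hises = model.indices_of(HIS, start, end)
    if len(mets) < 2 or len(hises) < 2:
        return GeometricVerification(
            protein_id=model.protein_id, triplet=None, distances=None,
            passed=False, threshold=threshold, status="no_candidates",
            reason=f"{len(mets)} Met / {len(hises)} His (need 2 of each)")
    best = None
    for m1, m2 in itertools.combinations(mets, 2):
        for h1, h2 in itertools.combinations(hises, 2):
            pairs = [(m1, m2), (m1, h1), (m2, h1), (m1, h2), (m2, h2)]
            ds = [float(np.linalg.norm(model.ca(a) - model.ca(b)))
                  for a, b in pairs]
            crit = max(ds)
            if best is None or crit < best[0]:
                best = (crit, (m1, m2, h1), tuple(ds[:3]))
    crit, triplet, dists = best
    return GeometricVerification(
        protein_id=model.protein_id, triplet=triplet, distances=dists,
        passed=crit <= threshold, threshold=threshold,
        status="confirmed" if crit <= threshold else "failed")


# ---------------------------------------------------------------------------
# Dataset-level confirmation
# ---------------------------------------------------------------------------

def confirm_hits(hits_by_protein: Mapping[str, Sequence[MotifHit]],
                 models: Mapping[str, StructureModel],
                 annotations: Sequence[DomainAnnotation],
                 threshold: float = DEFAULT_THRESHOLD,
                 geometry_mode: str = "all_pairs",
                 anchor_mode: str = "whole_domain",
                 ) -> dict[str, GeometricVerification]:
    """Structurally confirm every MMH-positive protein.

    For each protein with an MMH hit in a CBM2 domain, runs the geometric
    check over that domain's residue range in the protein's model. Proteins
    without a model get status ``unverified`` and are excluded from
    confirmed counts (they go on the review list, never auto-resolved).
    A protein with several CBM2 domains is confirmed if any one passes.
    """
    if anchor_mode not in ANCHOR_MODES:
        raise ValidationError(f"unknown anchor mode {anchor_mode!r}")
    cbm2_ranges: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        if ann.family == "CBM2":
            cbm2_ranges.setdefault(ann.protein_id, []).append(ann)

    results: dict[str, GeometricVerification] = {}
    for pid, hits in hits_by_protein.items():
        mmh_hits = [h for h in hits if h.motif == "MMH" and h.family == "CBM2"]
        if not mmh_hits:
            continue
        if pid not in models:
            results[pid] = GeometricVerification(
                protein_id=pid, triplet=None, distances=None, passed=False,
                threshold=threshold, status="unverified",
                reason="no structural model supplied",
                review=["missing model"])
            continue
        model = models[pid]
        best: Optional[GeometricVerification] = None
        for ann in cbm2_ranges.get(pid, []):
            anchors = None
            if anchor_mode == "regex_anchors":
                anchors = sorted({ann.start + p - 1
                                  for h in mmh_hits
                                  if h.domain_start == ann.start
                                  for p in h.anchor_positions})
            ver = verify_motif_geometry(model, ann.start, ann.end,
                                        threshold=threshold,
                                        geometry_mode=geometry_mode,
                                        anchor_indices=anchors)
            if best is None or (ver.passed and not best.passed):
                best = ver
            if ver.passed:
                break
        results[pid] = best if best is not None else GeometricVerification(
            protein_id=pid, triplet=None, distances=None, passed=False,
            threshold=threshold, status="no_candidates",
            reason="no CBM2 annotation for MMH-positive protein")
    return results


def confirmed_ids(results: Mapping[str, GeometricVerification]) -> set[str]:
    return {pid for pid, v in results.items() if v.passed}


def review_list(results: Mapping[str, GeometricVerification]) -> list[str]:
    """Proteins needing manual inspection (unverified / no candidates)."""
    return sorted(pid for pid, v in results.items()
                  if v.status in ("unverified", "no_candidates"))
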