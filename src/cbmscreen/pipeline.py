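"""End-to-end screen orchestration.

``run_screen`` wires the stages in the discovery order — read, deduplicate,
extract domains, regex scan, structural confirmation, REF co-occurrence,
classification, accounting — and writes per-stage artifacts with
deterministic filenames plus a JSON run report. Identical config and inputs
produce a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import motif_scan, sequence_io, structure_verify
from .cooccurrence_phylo import ScreenReport, build_screen_report
from .errors import CbmScreenError

log = logging.getLogger("cbmscreen")

ARTIFACTS = {
    "unique_fasta": "unique.fasta",
    "domains_fasta": "domains.fasta",
    "hits": "motif_hits.tsv",
    "verifications": "verifications.tsv",
    "classes": "classes.tsv",
    "report": "screen_report.json",
}


@dataclass
class RunConfig:
    """Fully serializable screen configuration, echoed into the report."""

    fasta: str
    domains: str
    out_dir: str
    structures_dir: Optional[str] = None
    threshold_angstrom: float = structure_verify.DEFAULT_THRESHOLD
    geometry_mode: str = "all_pairs"
    anchor_mode: str = "whole_domain"
    require_confirmation: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScreenResult:
    report: ScreenReport
    report_dict: dict
    artifacts: dict[str, Path]


def _write_verifications(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstatus\ttriplet\td_m1_m2\td_m1_h\td_m2_h"
                 "\tthreshold\n")
        for pid in sorted(results):
            v = results[pid]
            trip = (",".join(str(i) for i in v.triplet) if v.triplet else "")
            ds = (tuple(f"{d:.3f}" for d in v.distances) if v.distances
                  else ("", "", ""))
            fh.write(f"{pid}\t{v.status}\t{trip}\t{ds[0]}\t{ds[1]}\t{ds[2]}"
                     f"\t{v.threshold:g}\n")


def _write_classes(classes, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\n")
        for pid in sorted(classes):
            fh.write(f"{pid}\t{classes[pid].motif_class}\n")


def run_screen(config: RunConfig) -> ScreenResult:
    """Run the whole screen; artifacts land in ``config.out_dir``.

    Any stage error aborts with the stage named; artifacts written so far
    are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in ARTIFACTS.items()}
    stage = "read"
    try:
        records = sequence_io.read_fasta(config.fasta)
        annotations = sequence_io.read_domain_table(config.domains)
        log.info("read %d records, %d annotations", len(records),
                 len(annotations))

        stage = "deduplicate"
        unique, removed = sequence_io.deduplicate(records)
        sequence_io.write_fasta(unique, paths["unique_fasta"])
        unique_ids = {r.id for r in unique}
        annotations = [a for a in annotations if a.protein_id in unique_ids]

        stage = "extract"
        domains = sequence_io.extract_domains(unique, annotations)
        sequence_io.domains_to_fasta(domains, paths["domains_fasta"])

        stage = "scan"
        hits = motif_scan.scan_dataset(domains)
        motif_scan.hits_to_tsv(hits, paths["hits"])
        mmh_positive = motif_scan.positive_proteins(hits, "MMH", "CBM2")
        log.info("%d MMH-regex-positive proteins", len(mmh_positive))

        stage = "verify"
        if config.require_confirmation:
            models = {}
            if config.structures_dir:
                sdir = Path(config.structures_dir)
                for pid in sorted(mmh_positive):
                    pdb = sdir / f"{pid}.pdb"
                    if pdb.exists():
                        models[pid] = structure_verify.read_structure(pdb, pid)
            verifications = structure_verify.confirm_hits(
                hits, models, annotations,
                threshold=config.threshold_angstrom,
                geometry_mode=config.geometry_mode,
                anchor_mode=config.anchor_mode)
            confirmed = structure_verify.confirmed_ids(verifications)
            confirmations = {pid: v.passed
                             for pid, v in verifications.items()}
        else:
            verifications = {}
            confirmed = set(mmh_positive)
            confirmations = {pid: True for pid in mmh_positive}
        _write_verifications(verifications, paths["verifications"])

        stage = "classify"
        classes = motif_scan.classify_dataset(
            hits, confirmations=confirmations,
            protein_ids=unique_ids,
            require_confirmation=config.require_confirmation)
        _write_classes(classes, paths["classes"])

        stage = "report"
        has_aa10 = {a.protein_id for a in annotations if a.family == "AA10"}
        ref_positive_all = motif_scan.positive_proteins(hits, "REF", "AA10")
        aa10_linked = confirmed & has_aa10
        cbm2_only = confirmed - has_aa10
        ref_positive = aa10_linked & ref_positive_all
        report = build_screen_report(
            retrieved=len(records), unique=len(unique),
            regex_hits=len(mmh_positive),
            aa10_linked=len(aa10_linked), cbm2_only=len(cbm2_only),
            ref_positive=len(ref_positive))
        report_dict = {
            "config": config.to_dict(),
            "report": report.to_dict(),
            "removed_duplicates": removed,
            "class_totals": _class_totals(classes),
            "review_list": structure_verify.review_list(verifications),
            "alternate_denominators": {
                # exposed alongside the primary choices wherever the
                # numerator/denominator pairing is ambiguous
                "ref_fraction_of_confirmed": _pct(len(ref_positive),
                                                  report.confirmed),
                "mmh_occurrence_of_retrieved": _pct(report.confirmed,
                                                    len(records)),
            },
        }
        with open(paths["report"], "w") as fh:
            json.dump(report_dict, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return ScreenResult(report=report, report_dict=report_dict,
                            artifacts=paths)
    except CbmScreenError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc


def _class_totals(classes) -> dict[str, int]:
    totals: dict[str, int] = {c: 0 for c in motif_scan.CLASSES}
    for entry in classes.values():
        totals[entry.motif_class] = totals.get(entry.motif_class, 0) + 1
    return totals


def _pct(num: int, den: int) -> Optional[float]:
    from .cooccurrence_phylo import round_half_up
    return round_half_up(100.0 * num / den, 1) if den else None
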