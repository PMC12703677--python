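"""Synthetic benchmark generation with ground-truth ledgers.

Every input the screen and the assay fitters consume can be generated here
with known truth, so the whole pipeline is testable without database
downloads: multi-domain proteins with planted MMH/REF motifs and matching
Cα-only coordinate models, gapped alignments with planted residue
combinations, one-site binding isotherms, stopped-flow traces, calibration
standards and reductant-depletion series.

Design of the structural generator: residues follow a self-avoiding random
walk with 3.8 Å Cα–Cα steps, but every Met/His Cα inside the CBM2 range —
other than the planted triplet — is placed on a lattice with >= 12 Å
spacing, so no spurious triplet can pass an 8.5 Å check and the geometric
verdict is exactly the planted label. Consistent positives get a planted
triangle with all pairwise distances U(4, 8) Å; violators get one pair at
U(9.5, 15) Å (failing at 8.5 Å, still passing at 20 Å). Sequence
backgrounds of unplanted domains are scrubbed of accidental regex matches;
near-miss decoys (M..M without the trailing H, REF spaced 2 or 11) are
planted to exercise the grammar bounds.

Every generator is a pure function of its seed: rerunning with the same
seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .errors import ValidationError
from .motif_scan import MMH, REF, MotifPattern, scan_motif
from .sequence_io import (DomainAnnotation, DomainSequence, SequenceRecord,
                          write_domain_table, write_fasta)

DEFAULT_SEED = 20251124

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: motif letters down-weighted x0.5 in background so spurious motif rates
#: stay low but nonzero (spurious regex hits exercise geometric filtering)
_WEIGHTS = np.array([0.5 if aa in "MHREF" else 1.0 for aa in AMINO_ACIDS])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

AA10_LEN = 200     # residues, typical AA10 catalytic domain
LINKER_LEN = 20
CBM2_LEN = 100     # mirrors the ScCBM2 263-364 span (102 aa)

#: planted MMH anchors, 1-based within the CBM2 domain — the Met266/Met286/
#: His288 layout of a domain starting at residue 263
MMH_ANCHORS = (4, 24, 26)
#: planted REF anchors within the AA10 domain (gap 4, inside the 3-10 bound)
REF_ANCHORS = (50, 55, 57)

_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
_THREE["X"] = "UNK"

#: protein-concentration grid of the cellulose-binding assay, μg/mL
ISOTHERM_GRID_UG_ML = (0.0, 10.0, 25.0, 50.0, 75.0, 150.0, 300.0, 500.0)
#: ScCBM2-like molar mass used to express the grid in μM
CBM2_MASS_KDA = 10.8
ISOTHERM_GRID_UM = tuple(x / CBM2_MASS_KDA for x in ISOTHERM_GRID_UG_ML)

#: stopped-flow reagent grids, μM after mixing
ASCA_GRID_UM = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)
H2O2_GRID_UM = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Serialized ground truth for one generated dataset."""

    seed: int
    proteins: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "proteins": self.proteins,
                       "params": self.params}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], proteins=d["proteins"], params=d["params"])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _background(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=n, p=_WEIGHTS))


def _scrub(seq: list[str], pattern: MotifPattern,
           keep_anchors: tuple[int, ...] = ()) -> None:
    """Mutate residues until ``pattern`` has no match (in place).

    The last anchor of the first remaining hit is replaced by a letter
    outside the motif alphabet; planted anchor positions are never touched.
    """
    protected = set(keep_anchors)
    guard = 0
    while True:
        dom = DomainSequence(protein_id="_", family=pattern.families[0]
                             if pattern.families else "other",
                             start=1, end=len(seq), residues="".join(seq))
        hits = scan_motif(dom, pattern)
        hits = [h for h in hits
                if not set(h.anchor_positions) <= protected]
        if not hits:
            return
        for pos in reversed(hits[0].anchor_positions):
            if pos not in protected:
                seq[pos - 1] = "L"
                break
        guard += 1
        if guard > 10 * len(seq):  # pragma: no cover - safety valve
            raise RuntimeError("scrubbing did not terminate")


@dataclass
class DomainDataset:
    """A generated screen input: proteins, annotations and truth."""

    records: list[SequenceRecord]
    annotations: list[DomainAnnotation]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": out / "proteins.fasta",
                 "domains": out / "domains.tsv",
                 "truth": out / "truth.json"}
        write_fasta(self.records, paths["fasta"])
        write_domain_table(self.annotations, paths["domains"])
        self.truth.to_json(paths["truth"])
        return paths


def gen_domain_dataset(n_proteins: int = 200,
                       mmh_fraction: float = 0.25,
                       ref_fraction: float = 0.5,
                       geometry_violator_fraction: float = 0.2,
                       n_duplicates: int = 0,
                       decoy_fraction: float = 0.2,
                       seed: int = DEFAULT_SEED) -> DomainDataset:
    """Generate multi-domain proteins with planted MMH/REF motifs.

    Each protein is AA10 (200 aa) + linker (20 aa) + CBM2 (100 aa).
    ``round(n·mmh_fraction)`` proteins carry a planted MMH in the CBM2 (the
    Fig-1-like M…M.H layout); of those, ``round(·geometry_violator_fraction)``
    are flagged geometry-violating (regex-positive decoys for the structural
    filter). ``round(n·ref_fraction)`` carry a planted REF in the AA10.
    Unplanted domains are scrubbed of accidental matches, and a fraction of
    the negatives carries near-miss decoys. ``n_duplicates`` extra records
    repeating earlier sequences (fresh ids) are appended for dedup tests.
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    for frac in (mmh_fraction, ref_fraction, geometry_violator_fraction,
                 decoy_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("fractions must lie in [0, 1]")
    rng = _rng(seed)
    n_mmh = round(n_proteins * mmh_fraction)
    n_viol = round(n_mmh * geometry_violator_fraction)
    n_ref = round(n_proteins * ref_fraction)

    order = rng.permutation(n_proteins)
    mmh_set = set(order[:n_mmh].tolist())
    viol_set = set(order[:n_viol].tolist())
    ref_set = set(rng.permutation(n_proteins)[:n_ref].tolist())

    records, annotations = [], []
    truth = SyntheticTruth(seed=seed, params={
        "n_proteins": n_proteins, "mmh_fraction": mmh_fraction,
        "ref_fraction": ref_fraction,
        "geometry_violator_fraction": geometry_violator_fraction,
        "n_duplicates": n_duplicates, "decoy_fraction": decoy_fraction})

    cbm2_start = AA10_LEN + LINKER_LEN + 1
    cbm2_end = cbm2_start + CBM2_LEN - 1
    for i in range(n_proteins):
        pid = f"syn{i + 1:04d}"
        has_mmh = i in mmh_set
        geometry_ok = has_mmh and i not in viol_set
        has_ref = i in ref_set

        aa10 = _background(rng, AA10_LEN)
        if has_ref:
            r, e, f = REF_ANCHORS
            aa10[r - 1], aa10[e - 1], aa10[f - 1] = "R", "E", "F"
            _scrub(aa10, REF, keep_anchors=REF_ANCHORS)
        else:
            if rng.random() < decoy_fraction:  # near-miss: gap 2 (< 3) or 11
                r = 50
                gap = int(rng.choice([2, 11]))
                aa10[r - 1], aa10[r + gap], aa10[r + gap + 2] = "R", "E", "F"
            _scrub(aa10, REF)

        cbm2 = _background(rng, CBM2_LEN)
        if has_mmh:
            m1, m2, h = MMH_ANCHORS
            cbm2[m1 - 1], cbm2[m2 - 1], cbm2[h - 1] = "M", "M", "H"
        else:
            if rng.random() < decoy_fraction:  # M..M with no trailing .H
                m1, m2 = MMH_ANCHORS[:2]
                cbm2[m1 - 1], cbm2[m2 - 1] = "M", "M"
                cbm2[MMH_ANCHORS[2] - 1] = "Q"
            _scrub(cbm2, MMH)

        linker = _background(rng, LINKER_LEN)
        seq = "".join(aa10) + "".join(linker) + "".join(cbm2)
        records.append(SequenceRecord(id=pid, sequence=seq))
        annotations.append(DomainAnnotation(pid, "AA10", 1, AA10_LEN))
        annotations.append(DomainAnnotation(pid, "CBM2", cbm2_start, cbm2_end))

        cls = ("REF-MMH" if has_ref and geometry_ok else
               "MMH-only" if geometry_ok else
               "REF-only" if has_ref else "none")
        truth.proteins[pid] = {
            "has_mmh": has_mmh, "geometry_ok": geometry_ok,
            "has_ref": has_ref, "class": cls,
            "cbm2_range": [cbm2_start, cbm2_end],
            "mmh_anchors": [cbm2_start + p - 1 for p in MMH_ANCHORS]
            if has_mmh else [],
        }

    for j in range(n_duplicates):
        src = records[int(rng.integers(0, n_proteins))]
        records.append(SequenceRecord(id=f"dup{j + 1:04d}",
                                      sequence=src.sequence,
                                      description=f"duplicate of {src.id}"))
    return DomainDataset(records=records, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _triangle(rng: np.random.Generator, violator: bool
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cα positions (M1, M2, H) with planted pairwise distances."""
    while True:
        d = rng.uniform(4.0, 8.0, size=3)  # d(M1,M2), d(M1,H), d(M2,H)
        if violator:
            d[int(rng.integers(0, 3))] = rng.uniform(9.5, 15.0)
        d12, d1h, d2h = d
        if d12 < d1h + d2h and d1h < d12 + d2h and d2h < d12 + d1h:
            break
    x = (d12 ** 2 + d1h ** 2 - d2h ** 2) / (2 * d12)
    y2 = d1h ** 2 - x ** 2
    return (np.zeros(3), np.array([d12, 0.0, 0.0]),
            np.array([x, np.sqrt(max(y2, 0.0)), 0.0]))


def _self_avoiding_walk(rng: np.random.Generator, n: int,
                        step: float = 3.8, min_dist: float = 3.4
                        ) -> np.ndarray:
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(50):
            v = rng.normal(size=3)
            nxt = coords[i - 1] + step * v / np.linalg.norm(v)
            if i < 2 or np.min(np.linalg.norm(coords[:i - 1] - nxt,
                                              axis=1)) >= min_dist:
                break
        coords[i] = nxt
    return coords


def _lattice(k: int) -> np.ndarray:
    """k points with pairwise separation >= 12 Å, offset from the walk."""
    pts = []
    for i in range(k):
        pts.append([100.0 + 12.0 * (i % 5),
                    100.0 + 12.0 * ((i // 5) % 5),
                    100.0 + 12.0 * (i // 25)])
    return np.array(pts) if pts else np.empty((0, 3))


def structure_to_pdb(protein_id: str, sequence: str,
                     coords: np.ndarray, chain: str = "A") -> str:
    """Render a Cα-only chain as wwPDB v3.3 fixed-width ATOM records."""
    lines = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords), start=1):
        resname = _THREE.get(aa, "UNK")
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:<3s} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C")
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_structures(dataset: DomainDataset,
                   seed: int = DEFAULT_SEED,
                   out_dir: Optional[str | Path] = None) -> dict[str, str]:
    """Generate Cα-only PDB models consistent with the truth ledger.

    Returns protein_id -> PDB text; with ``out_dir`` the files are also
    written as ``<protein_id>.pdb``. Only the first occurrence of each
    distinct sequence gets a model (duplicate records share the original's
    geometry fate after dedup, so no model is emitted for them).
    """
    rng = _rng(seed + 1)
    out: dict[str, str] = {}
    for rec in dataset.records:
        info = dataset.truth.proteins.get(rec.id)
        if info is None:
            continue
        n = len(rec.sequence)
        coords = _self_avoiding_walk(rng, n)
        lo, hi = info["cbm2_range"]
        planted = set(info["mmh_anchors"])
        # park every stray Met/His in the CBM2 range on the >=12 Å lattice
        stray = [i for i in range(lo, hi + 1)
                 if rec.sequence[i - 1] in "MH" and i not in planted]
        for pt, idx in zip(_lattice(len(stray)), stray):
            coords[idx - 1] = pt
        if planted:
            m1, m2, h = sorted(planted)[0], sorted(planted)[1], max(planted)
            a, b, c = _triangle(rng, violator=not info["geometry_ok"])
            off = np.array([-100.0, -100.0, -100.0])
            coords[m1 - 1], coords[m2 - 1], coords[h - 1] = a + off, b + off, c + off
        out[rec.id] = structure_to_pdb(rec.id, rec.sequence, coords)
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for pid, text in out.items():
            (out_path / f"{pid}.pdb").write_text(text)
    return out


def gen_random_structure(n_residues: int, seed: int,
                         met_his_rich: bool = True) -> tuple[str, np.ndarray]:
    """An unconstrained random walk structure (for oracle comparisons).

    With ``met_his_rich`` the Met/His frequencies are boosted so triplet
    enumeration is non-trivial.
    """
    rng = _rng(seed)
    if met_his_rich:
        letters = list(AMINO_ACIDS)
        w = np.array([3.0 if aa in "MH" else 1.0 for aa in letters])
        seq = "".join(rng.choice(letters, size=n_residues, p=w / w.sum()))
    else:
        seq = "".join(_background(rng, n_residues))
    coords = _self_avoiding_walk(rng, n_residues)
    return seq, coords


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAlignment:
    """Generated MSA plus the ledger of planted residue tuples."""

    ids: list[str]
    rows: dict[str, str]
    reference_id: str
    reference_positions: tuple[int, ...]
    tuples: dict[str, str]          # planted combination per sequence
    ungapped: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in self.ids:
                fh.write(f">{sid}\n{self.rows[sid]}\n")


def gen_alignment(tuples: dict[str, str],
                  reference_tuple: str = "MMH",
                  reference_id: str = "ref",
                  n_background_columns: int = 60,
                  gap_prob: float = 0.15,
                  gap_free: bool = False,
                  seed: int = DEFAULT_SEED) -> SyntheticAlignment:
    """Generate an MSA carrying a known residue tuple per sequence.

    ``tuples`` maps sequence id -> the combination it should show at the
    reference-mapped columns ('-' allowed). The reference sequence carries
    ``reference_tuple`` at the same columns and is gap-free at them, so its
    ungapped positions map exactly onto the planted columns. With
    ``gap_free`` no gaps are inserted anywhere (column = position − 1).
    """
    k = len(reference_tuple)
    if any(len(v) != k for v in tuples.values()):
        raise ValidationError("all planted tuples must have the reference's "
                              "length")
    rng = _rng(seed)
    length = n_background_columns + k
    target_cols = np.sort(rng.choice(length, size=k, replace=False))

    ids = [reference_id] + sorted(tuples)
    rows: dict[str, str] = {}
    for sid in ids:
        planted = reference_tuple if sid == reference_id else tuples[sid]
        row = []
        for col in range(length):
            if gap_free or sid == reference_id:
                ch = str(rng.choice(list(AMINO_ACIDS)))
            else:
                ch = ("-" if rng.random() < gap_prob
                      else str(rng.choice(list(AMINO_ACIDS))))
            row.append(ch)
        for col, letter in zip(target_cols, planted):
            row[col] = letter
        rows[sid] = "".join(row)

    ref_row = rows[reference_id]
    positions = tuple(int(col) - ref_row[:int(col)].count("-") + 1
                      for col in target_cols)
    return SyntheticAlignment(
        ids=ids, rows=rows, reference_id=reference_id,
        reference_positions=positions,
        tuples=dict(tuples),
        ungapped={sid: rows[sid].replace("-", "") for sid in ids})


# ---------------------------------------------------------------------------
# Assay data
# ---------------------------------------------------------------------------

@dataclass
class AssayData:
    """A generated assay table plus its generating parameters."""

    table: pd.DataFrame
    truth: dict

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")


def gen_isotherm(kd: float, bmax: float,
                 free_conc: Sequence[float] = ISOTHERM_GRID_UM,
                 noise_sd: float = 0.0,
                 replicates: int = 3,
                 seed: int = DEFAULT_SEED) -> AssayData:
    """One-site isotherm: bound = B_max·F/(K_d+F) + N(0, noise_sd).

    ``noise_sd`` is in the bound units (μmol/g); for the 2%-of-B_max
    convention pass ``0.02 * bmax``.
    """
    if kd <= 0 or bmax <= 0:
        raise ValidationError("K_d and B_max must be positive")
    rng = _rng(seed)
    f = np.asarray(free_conc, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        bound = bmax * f / (kd + f) + rng.normal(0.0, noise_sd, size=f.size)
        for fi, bi in zip(f, bound):
            rows.append((fi, bi, rep))
    table = pd.DataFrame(rows, columns=["free_uM", "bound_umol_g",
                                        "replicate"])
    return AssayData(table=table, truth={
        "kd": kd, "bmax": bmax, "noise_sd": noise_sd,
        "replicates": replicates, "seed": seed})


def gen_stopped_flow(k_app: float,
                     concentrations_uM: Sequence[float],
                     a: float = 0.0, b: float = 1.0, c: float = 0.5,
                     noise_sd_frac: float = 0.01,
                     replicates: int = 3,
                     n_points: int = 200,
                     seed: int = DEFAULT_SEED) -> AssayData:
    """Pseudo-first-order traces y = a·t + b + c·e^(−k_app·C·t) + noise.

    ``k_app`` is in M⁻¹ s⁻¹ and concentrations in μM; each trace spans
    about six half-lives of its own k_obs. Pass a negative ``c`` for rise
    (reduction) traces; noise SD is ``noise_sd_frac·|c|``.
    """
    if k_app <= 0:
        raise ValidationError("k_app must be positive")
    rng = _rng(seed)
    rows = []
    for conc in concentrations_uM:
        k_obs = k_app * conc * 1e-6
        t = np.linspace(0.0, 6.0 / k_obs, n_points)
        for rep in range(1, replicates + 1):
            y = (a * t + b + c * np.exp(-k_obs * t)
                 + rng.normal(0.0, noise_sd_frac * abs(c), size=t.size))
            for ti, yi in zip(t, y):
                rows.append((ti, yi, conc, rep))
    table = pd.DataFrame(rows, columns=["time_s", "signal", "conc_uM",
                                        "replicate"])
    return AssayData(table=table, truth={
        "k_app": k_app, "a": a, "b": b, "c": c,
        "noise_sd_frac": noise_sd_frac, "replicates": replicates,
        "concentrations_uM": list(concentrations_uM), "seed": seed})


def gen_calibration(slope: float, intercept: float,
                    concentrations: Sequence[float] = (0, 2, 4, 6, 8),
                    noise_sd: float = 0.0,
                    replicates: int = 1,
                    seed: int = DEFAULT_SEED) -> AssayData:
    """Linear standards: response = slope·conc + intercept + N(0, σ)."""
    rng = _rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        resp = slope * conc + intercept + rng.normal(0, noise_sd, conc.size)
        for ci, ri in zip(conc, resp):
            rows.append((ci, ri, rep))
    table = pd.DataFrame(rows, columns=["conc_uM", "response", "replicate"])
    return AssayData(table=table, truth={
        "slope": slope, "intercept": intercept, "noise_sd": noise_sd,
        "replicates": replicates, "seed": seed})


def gen_depletion(initial_uM: float = 1000.0,
                  rate_per_h: float = 1.0,
                  t_max_h: float = 19.0,
                  dt_h: float = 0.05,
                  noise_sd: float = 0.0,
                  threshold_fraction: float = 0.05,
                  seed: int = DEFAULT_SEED) -> AssayData:
    """Exponentially decaying reductant series, c(t) = c₀·e^(−rate·t).

    The truth carries the closed-form threshold-crossing time
    ln(1/threshold)/rate (infinite, i.e. absent, when rate is 0 — the
    no-enzyme control trace stays flat at 100%).
    """
    rng = _rng(seed)
    t = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    conc = initial_uM * np.exp(-rate_per_h * t)
    conc = conc + rng.normal(0.0, noise_sd, size=t.size)
    table = pd.DataFrame({"time_h": t, "conc_uM": conc})
    crossing = (np.log(1.0 / threshold_fraction) / rate_per_h
                if rate_per_h > 0 else None)
    return AssayData(table=table, truth={
        "initial_uM": initial_uM, "rate_per_h": rate_per_h,
        "threshold_fraction": threshold_fraction,
        "crossing_time_h": crossing, "noise_sd": noise_sd, "seed": seed})
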