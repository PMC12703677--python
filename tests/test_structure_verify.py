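"""Geometric verification of Met/Met/His triplets on Cα coordinates."""

import itertools

import numpy as np
import pytest

import cbmscreen as cs
from cbmscreen.errors import ValidationError


def model_from(triples, protein_id="p"):
    """Build a StructureModel from (index, resname, xyz) triples."""
    return cs.StructureModel(
        protein_id=protein_id,
        residues={i: (name, np.asarray(xyz, float))
                  for i, name, xyz in triples})


def brute_force_verdict(model, start, end, threshold):
    """Oracle: enumerate all triplets with direct Euclidean distances."""
    mets = [i for i, (n, _) in model.residues.items()
            if n == "MET" and start <= i <= end]
    hises = [i for i, (n, _) in model.residues.items()
             if n == "HIS" and start <= i <= end]
    best = None
    for m1, m2 in itertools.combinations(sorted(mets), 2):
        for h in sorted(hises):
            a, b, c = (model.residues[i][1] for i in (m1, m2, h))
            dmax = max(np.linalg.norm(a - b), np.linalg.norm(a - c),
                       np.linalg.norm(b - c))
            if best is None or dmax < best:
                best = dmax
    if best is None:
        return None
    return bool(best <= threshold)


class TestReadStructure:
    def test_three_residue_file(self, tmp_path):
        text = cs.structure_to_pdb("p", "MAH",
                                   np.array([[0, 0, 0], [3.8, 0, 0],
                                             [7.6, 0, 0.0]]))
        p = tmp_path / "p.pdb"
        p.write_text(text)
        model = cs.read_structure(p)
        assert sorted(model.residues) == [1, 2, 3]
        assert model.residues[1][0] == "MET"
        assert model.residues[3][0] == "HIS"

    def test_residue_without_ca_is_absent(self, tmp_path):
        text = ("ATOM      1  CA  MET A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n"
                "ATOM      2  CB  ALA A   2       1.000   0.000   0.000"
                "  1.00  0.00           C\n"
                "END\n")
        p = tmp_path / "p.pdb"
        p.write_text(text)
        model = cs.read_structure(p)
        assert sorted(model.residues) == [1]

    def test_generator_pdb_round_trips_to_3_decimals(self, tmp_path):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=20, size=(10, 3))
        seq = "MAHWMKLHRC"
        p = tmp_path / "p.pdb"
        p.write_text(cs.structure_to_pdb("p", seq, coords))
        model = cs.read_structure(p)
        for i in range(10):
            assert np.allclose(model.residues[i + 1][1],
                               np.round(coords[i], 3), atol=5e-4)

    def test_insertion_code_rejected(self, tmp_path):
        line = ("ATOM      1  CA  MET A   1A      0.000   0.000   0.000"
                "  1.00  0.00           C\n")
        p = tmp_path / "p.pdb"
        p.write_text(line)
        with pytest.raises(ValidationError, match="insertion"):
            cs.read_structure(p)

    def test_truncated_atom_line_names_line_number(self, tmp_path):
        p = tmp_path / "p.pdb"
        p.write_text("ATOM      1  CA  MET A   1     0.0\n")
        with pytest.raises(cs.ParseError, match=":1"):
            cs.read_structure(p)


class TestVerifyMotifGeometry:
    def test_all_distances_below_threshold_passes(self):
        model = model_from([(1, "MET", (0, 0, 0)), (2, "MET", (5, 0, 0)),
                            (3, "HIS", (2.5, 5.45, 0))])  # ~5/6/6 Å
        ver = cs.verify_motif_geometry(model, 1, 3)
        assert ver.passed and ver.status == "confirmed"
        assert max(ver.distances) <= 8.5

    def test_single_long_distance_fails_all_pairs_rule(self):
        model = model_from([(1, "MET", (0, 0, 0)), (2, "MET", (8.6, 0, 0)),
                            (3, "HIS", (4.3, 1.5, 0))])
        ver = cs.verify_motif_geometry(model, 1, 3)
        assert not ver.passed
        assert ver.distances[0] == pytest.approx(8.6)

    def test_pair_to_his_mode_ignores_met_met_distance(self):
        model = model_from([(1, "MET", (0, 0, 0)), (2, "MET", (9.0, 0, 0)),
                            (3, "HIS", (4.5, 2.0, 0))])
        strict = cs.verify_motif_geometry(model, 1, 3)
        loose = cs.verify_motif_geometry(model, 1, 3,
                                         geometry_mode="pair_to_his")
        assert not strict.passed and loose.passed

    def test_no_met_or_his_reports_no_candidates(self):
        model = model_from([(1, "ALA", (0, 0, 0)), (2, "MET", (1, 0, 0))])
        ver = cs.verify_motif_geometry(model, 1, 2)
        assert ver.status == "no_candidates" and ver.triplet is None

    def test_matches_exhaustive_enumeration_with_many_candidates(self):
        rng = np.random.default_rng(3)
        names = ["MET"] * 3 + ["HIS"] * 2 + ["ALA"] * 5
        rng.shuffle(names)
        model = model_from([(i + 1, n, rng.uniform(0, 12, 3))
                            for i, n in enumerate(names)])
        ver = cs.verify_motif_geometry(model, 1, 10)
        assert ver.passed == brute_force_verdict(model, 1, 10, 8.5)

    def test_equals_brute_force_on_random_structures(self):
        for seed in range(60):
            seq, coords = cs.gen_random_structure(50, seed=seed)
            model = model_from([(i + 1, {"M": "MET", "H": "HIS"}.get(a, "ALA"),
                                 coords[i]) for i, a in enumerate(seq)])
            ver = cs.verify_motif_geometry(model, 1, 50)
            oracle = brute_force_verdict(model, 1, 50, 8.5)
            assert ver.passed == (oracle or False)
            if oracle is None:
                assert ver.status == "no_candidates"

    def test_invariant_under_rigid_body_motion(self):
        from scipy.spatial.transform import Rotation
        seq, coords = cs.gen_random_structure(40, seed=9)
        resname = {"M": "MET", "H": "HIS"}
        trips = [(i + 1, resname.get(a, "ALA"), coords[i])
                 for i, a in enumerate(seq)]
        ver0 = cs.verify_motif_geometry(model_from(trips), 1, 40)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = [(i, n, R @ xyz + np.array([10., -5., 3.]))
                 for i, n, xyz in trips]
        ver1 = cs.verify_motif_geometry(model_from(moved), 1, 40)
        assert ver0.passed == ver1.passed
        assert np.allclose(ver0.distances, ver1.distances, atol=1e-6)

    def test_monotone_in_threshold(self):
        for seed in range(20):
            seq, coords = cs.gen_random_structure(40, seed=seed)
            resname = {"M": "MET", "H": "HIS"}
            model = model_from([(i + 1, resname.get(a, "ALA"), coords[i])
                                for i, a in enumerate(seq)])
            passed = [cs.verify_motif_geometry(model, 1, 40, threshold=t).passed
                      for t in (6.0, 8.5, 12.0, 20.0)]
            assert passed == sorted(passed)  # once true, stays true


class TestConfirmHits:
    def _screen(self, dataset, models_txt, tmp_path, threshold=8.5):
        doms = cs.extract_domains(dataset.records, dataset.annotations)
        hits = cs.scan_dataset(doms)
        models = {}
        for pid, text in models_txt.items():
            p = tmp_path / f"{pid}.pdb"
            p.write_text(text)
            models[pid] = cs.read_structure(p, pid)
        return hits, cs.confirm_hits(hits, models, dataset.annotations,
                                     threshold=threshold)

    def test_confirms_exactly_the_geometry_consistent_positives(
            self, screen_dataset, screen_models, tmp_path):
        _, results = self._screen(screen_dataset, screen_models, tmp_path)
        truth_ok = {p for p, v in screen_dataset.truth.proteins.items()
                    if v["geometry_ok"]}
        assert cs.confirmed_ids(results) == truth_ok

    def test_violators_pass_at_20_angstrom(self, screen_dataset,
                                           screen_models, tmp_path):
        _, results = self._screen(screen_dataset, screen_models, tmp_path,
                                  threshold=20.0)
        planted = {p for p, v in screen_dataset.truth.proteins.items()
                   if v["has_mmh"]}
        assert cs.confirmed_ids(results) == planted

    def test_missing_model_is_unverified_and_listed(self):
        hit = cs.MotifHit("p", "CBM2", "MMH", (1, 4, 6), ("M", "M", "H"))
        results = cs.confirm_hits({"p": [hit]}, {}, [
            cs.DomainAnnotation("p", "CBM2", 1, 10)])
        assert results["p"].status == "unverified"
        assert cs.confirmed_ids(results) == set()
        assert cs.review_list(results) == ["p"]

    def test_infinite_threshold_reduces_to_candidate_presence(
            self, screen_dataset, screen_models, tmp_path):
        hits, results = self._screen(screen_dataset, screen_models, tmp_path,
                                     threshold=float("inf"))
        with_candidates = {pid for pid, v in results.items()
                          if v.status != "no_candidates"}
        assert cs.confirmed_ids(results) == with_candidates
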