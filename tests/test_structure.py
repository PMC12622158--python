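"""Contact labeling, residue distances, PDB round trip and the RDF."""

import numpy as np
import pytest

from cysligand import structure as st
from cysligand.errors import CysligandError
from cysligand.metrics import PredictionSet
from cysligand.structure import (LigandPose, Residue, StructureModel,
                                 compute_rdf, label_binding_residues,
                                 ligand_mw_filter, min_residue_distance,
                                 read_complex, top_k_binding, write_complex)
from cysligand.synthgen import GeneratorConfig, gen_complexes, gen_proteome


def simple_structure(residues):
    """residues: {pos: [(element, (x, y, z)), ...]}"""
    model = StructureModel(uid="P1")
    for pos, atoms in residues.items():
        model.residues[pos] = Residue(
            position=pos, name="ALA",
            atoms=[(el, np.asarray(xyz, dtype=float)) for el, xyz in atoms])
    return model


class TestMWFilter:
    @pytest.mark.parametrize("mw,accepted", [(149, False), (150, True),
                                             (300, True), (600, True),
                                             (601, False)])
    def test_inclusive_band(self, mw, accepted):
        pose = LigandPose("LIG", np.zeros((1, 3)), mw=mw)
        assert ligand_mw_filter(pose) is accepted


class TestContactLabeling:
    def test_heavy_pair_inside_cutoff_labeled(self):
        model = simple_structure({1: [("C", (4.4, 0, 0))],
                                  2: [("C", (5.0, 0, 0))]})
        pose = LigandPose("LIG", [[0, 0, 0]], mw=300)
        assert label_binding_residues(model, pose) == {1}

    def test_hydrogen_contacts_ignored(self):
        model = simple_structure({1: [("H", (3.0, 0, 0)), ("C", (5.0, 0, 0))]})
        pose = LigandPose("LIG", [[0, 0, 0]], mw=300)
        assert label_binding_residues(model, pose) == set()

    def test_residue_without_heavy_atoms_is_error(self):
        model = simple_structure({1: [("H", (1.0, 0, 0))]})
        pose = LigandPose("LIG", [[0, 0, 0]], mw=300)
        with pytest.raises(CysligandError):
            label_binding_residues(model, pose)

    def test_cutoff_nesting(self, rng):
        atoms = {p: [("C", rng.uniform(-8, 8, 3))] for p in range(1, 40)}
        model = simple_structure(atoms)
        pose = LigandPose("LIG", rng.uniform(-2, 2, (5, 3)), mw=300)
        s40 = label_binding_residues(model, pose, 4.0)
        s45 = label_binding_residues(model, pose, 4.5)
        s50 = label_binding_residues(model, pose, 5.0)
        assert s40 <= s45 <= s50

    def test_against_brute_force_on_50_toy_complexes(self):
        # short proteins sometimes carry zero cysteines, so over-generate
        cfg = GeneratorConfig(n_proteins=80, length_range=(40, 80), seed=21)
        proteins, gt = gen_proteome(cfg)
        structures, poses = gen_complexes(gt, cfg, proteins, n_complexes=50)
        assert len(structures) == 50
        for uid, model in structures.items():
            pose = poses[uid]
            got = label_binding_residues(model, pose)
            brute = set()
            for pos, res in model.residues.items():
                best = min(
                    float(np.linalg.norm(np.asarray(xyz) - lig))
                    for el, xyz in res.atoms if el != "H"
                    for lig in pose.heavy_coords)
                if best <= 4.5:
                    brute.add(pos)
            assert got == brute
            assert got == gt.binding[uid]   # generator margin guarantee


class TestResidueDistance:
    def test_self_distance_zero(self):
        model = simple_structure({1: [("C", (1, 2, 3))]})
        assert min_residue_distance(model, 1, 1) == 0.0

    def test_three_four_five(self):
        model = simple_structure({1: [("C", (0, 0, 0))],
                                  2: [("C", (3, 4, 0))]})
        assert min_residue_distance(model, 1, 2) == pytest.approx(5.0)

    def test_includes_hydrogens(self):
        model = simple_structure({1: [("C", (0, 0, 0))],
                                  2: [("H", (1, 0, 0)), ("C", (9, 0, 0))]})
        assert min_residue_distance(model, 1, 2) == pytest.approx(1.0)

    def test_missing_residue_is_lookup_error(self):
        model = simple_structure({1: [("C", (0, 0, 0))]})
        with pytest.raises(CysligandError):
            min_residue_distance(model, 1, 99)

    def test_random_multiatom_brute_force(self, rng):
        for _ in range(50):
            a = [("C", rng.uniform(-5, 5, 3)) for _ in range(4)]
            b = [("O", rng.uniform(-5, 5, 3)) for _ in range(3)]
            model = simple_structure({1: a, 2: b})
            brute = min(np.linalg.norm(x[1] - y[1]) for x in a for y in b)
            assert min_residue_distance(model, 1, 2) == pytest.approx(brute)


class TestPDBRoundTrip:
    def test_write_read_preserves_contacts(self, tmp_path):
        cfg = GeneratorConfig(n_proteins=3, length_range=(40, 60), seed=5)
        proteins, gt = gen_proteome(cfg)
        structures, poses = gen_complexes(gt, cfg, proteins, n_complexes=3)
        for uid in structures:
            path = tmp_path / f"{uid}.pdb"
            write_complex(path, structures[uid], poses[uid])
            model, pose = read_complex(path, uid=uid)
            assert pose is not None
            assert label_binding_residues(model, pose) == gt.binding[uid]
            # PDB has 3-decimal coordinates; MW is element-exact
            assert pose.mw == pytest.approx(poses[uid].mw)


def rigid_transform(rng):
    q = rng.standard_normal((3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    shift = rng.uniform(-30, 30, 3)
    return rot, shift


class TestRDF:
    def test_uniform_null_tail_is_one(self):
        """10,000 residues uniform in a ball around the cysteine: shell
        density is flat, so tail-normalized g(r) ~ 1 everywhere, tail included."""
        rng = np.random.default_rng(0)
        r_max = 20.0
        pts = rng.standard_normal((10_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r_max * rng.random((10_000, 1)) ** (1 / 3)
        residues = {1: [("S", (0.0, 0.0, 0.0))]}
        for i, p in enumerate(pts):
            residues[i + 2] = [("C", p)]
        model = simple_structure(residues)
        result = compute_rdf({("P1", 1): "TP"},
                             {"P1": set(range(2, 10_002))},
                             {"P1": model}, bin_width=0.5, r_max=r_max)
        tail = result.r_mid >= 0.8 * r_max
        assert result.g["TP"][tail].mean() == pytest.approx(1.0, abs=0.1)

    def test_zero_predictions_flagged_not_zeroed(self):
        model = simple_structure({1: [("S", (0, 0, 0))]})
        result = compute_rdf({("P1", 1): "TP"}, {"P1": set()}, {"P1": model})
        assert "TP" in result.skipped and "TP" not in result.g

    def test_planted_contacts_peak_in_4_to_6_band(self):
        """Generated complexes put binding residues 4-6 A from the focal
        cysteine; with far residues padding the tail, the TP peak must fall
        in the 4-6 A bins."""
        cfg = GeneratorConfig(n_proteins=12, length_range=(60, 90), seed=9)
        proteins, gt = gen_proteome(cfg)
        structures, _ = gen_complexes(gt, cfg, proteins, n_complexes=12)
        classes = {(uid, gt.focus_cys[uid]): "TP" for uid in structures}
        predicted = {uid: set(gt.binding[uid]) for uid in structures}
        # a realistic predictor also emits distant false positives: take some
        # non-binding residues to populate the tail region
        for uid, model in structures.items():
            far = sorted(set(model.residues) - predicted[uid]
                         - {gt.focus_cys[uid]})[:30]
            predicted[uid] |= set(far)
        result = compute_rdf(classes, predicted, structures,
                             bin_width=0.5, r_max=20.0)
        peak_r = result.r_mid[int(np.argmax(result.g["TP"]))]
        assert 4.0 <= peak_r <= 6.0

    def test_rigid_motion_invariance(self, rng):
        cfg = GeneratorConfig(n_proteins=2, length_range=(40, 60), seed=13)
        proteins, gt = gen_proteome(cfg)
        structures, poses = gen_complexes(gt, cfg, proteins, n_complexes=2)
        for uid, model in structures.items():
            rot, shift = rigid_transform(rng)
            moved = StructureModel(uid=uid)
            for pos, res in model.residues.items():
                moved.residues[pos] = Residue(
                    position=pos, name=res.name,
                    atoms=[(el, rot @ xyz + shift) for el, xyz in res.atoms])
            moved_pose = LigandPose(
                "LIG", (rot @ poses[uid].heavy_coords.T).T + shift,
                mw=poses[uid].mw)
            assert (label_binding_residues(moved, moved_pose)
                    == label_binding_residues(model, poses[uid]))
            classes = {(uid, gt.focus_cys[uid]): "TP"}
            predicted = {uid: set(model.residues) - {gt.focus_cys[uid]}}
            g1 = compute_rdf(classes, predicted, {uid: model})
            g2 = compute_rdf(classes, predicted, {uid: moved})
            assert np.allclose(g1.g["TP"], g2.g["TP"], atol=1e-9)


def test_top_k_and_threshold_binding_sets():
    scores = {("P1", i): s for i, s in enumerate([0.9, 0.8, 0.3, 0.6], start=1)}
    pred = PredictionSet(scores)
    assert top_k_binding(pred, k=2)["P1"] == {1, 2}
    assert st.thresholded_binding(pred, 0.5)["P1"] == {1, 2, 4}
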