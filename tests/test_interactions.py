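import dataclasses
import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caifp import (
    AtomRecord,
    BindingSite,
    GeometryConfig,
    INTERACTION_TYPES,
    InteractionProfile,
    ResidueKey,
    Structure,
    detect_interactions,
    find_aromatic_rings,
    find_charged_centers,
    interactions_report,
    make_interaction_fixture,
    profile_from_json,
)
from caifp.errors import MissingResidueError
from caifp.synth import _make_structure, _sidechain

from .conftest import assert_profiles_equal
from .oracle import detect_profile


def _mol(atom_tuples, kind="ligand", hetero=True, key=None):
    key = key or ResidueKey("L", 1, "", "LIG")
    atoms = [AtomRecord(i + 1, n, e, np.asarray(xyz, float), key, is_hetero=hetero)
             for i, (n, e, xyz) in enumerate(atom_tuples)]
    return Structure(atoms=atoms, kind=kind)


def _hexagon_atoms(radius=1.39, z=0.0, element="C"):
    out = []
    for k, ang in enumerate(range(0, 360, 60)):
        a = np.radians(ang)
        out.append((f"{element}{k+1}", element,
                    (radius * np.cos(a), radius * np.sin(a), z)))
    return out


class TestRingPerception:
    def test_ideal_benzene(self):
        mol = _mol(_hexagon_atoms())
        rings = find_aromatic_rings(mol)
        assert len(rings) == 1
        assert len(rings[0].member_atoms) == 6
        assert np.linalg.norm(rings[0].normal) == pytest.approx(1.0)
        np.testing.assert_allclose(rings[0].centroid, [0, 0, 0], atol=1e-12)

    def test_puckered_ring_rejected(self):
        # strongly puckered chair: +-0.45 A out of plane, beyond the 0.35 tolerance
        atoms = []
        r = np.sqrt(1.53 ** 2 - 0.9 ** 2)
        for k, ang in enumerate(range(0, 360, 60)):
            a = np.radians(ang)
            atoms.append((f"C{k+1}", "C",
                          (r * np.cos(a), r * np.sin(a), 0.45 * (-1) ** k)))
        assert find_aromatic_rings(_mol(atoms)) == []

    def test_phe_template(self):
        res = _mol(_sidechain("PHE"), kind="receptor", hetero=False,
                   key=ResidueKey("A", 1, "", "PHE"))
        rings = find_aromatic_rings(res)
        assert len(rings) == 1
        names = {a.name for a in res.atoms if a.serial in rings[0].member_atoms}
        assert names == {"CG", "CD1", "CE1", "CZ", "CE2", "CD2"}


class TestChargedCenters:
    def test_arg_guanidinium(self):
        res = _mol(_sidechain("ARG"), kind="receptor", hetero=False,
                   key=ResidueKey("A", 1, "", "ARG"))
        centers = find_charged_centers(res, "receptor")
        assert len(centers) == 1
        assert centers[0].sign == +1
        names = {a.name for a in res.atoms if a.serial in centers[0].member_atoms}
        assert names == {"CZ", "NE", "NH1", "NH2"}

    def test_acetate_ligand(self):
        mol = _mol([("C1", "C", (0, 0, 0)), ("O1", "O", (0.61, 1.10, 0)),
                    ("O2", "O", (0.61, -1.10, 0)), ("C2", "C", (-1.53, 0, 0))])
        centers = find_charged_centers(mol, "ligand")
        assert len(centers) == 1
        assert centers[0].sign == -1
        np.testing.assert_allclose(centers[0].center, [0.61, 0, 0], atol=1e-12)

    def test_benzene_neutral(self):
        assert find_charged_centers(_mol(_hexagon_atoms()), "ligand") == []

    def test_protonated_his_is_cationic(self):
        key = ResidueKey("A", 1, "", "HIS")
        base = _sidechain("HIS")
        names = {n: np.asarray(x) for n, e, x in base}
        protons = []
        for n, hn in (("ND1", "HD1"), ("NE2", "HE2")):
            center = np.array([4.36, 0, 0])
            out = names[n] - center
            protons.append((hn, "H", tuple(names[n] + out / np.linalg.norm(out))))
        res = _mol(base + protons, kind="receptor", hetero=False, key=key)
        centers = find_charged_centers(res, "receptor")
        assert [c.sign for c in centers] == [1]
        neutral = _mol(base + protons[:1], kind="receptor", hetero=False, key=key)
        assert find_charged_centers(neutral, "receptor") == []


class TestDetectInteractions:
    def test_hbond_distance_cutoff(self):
        """Carbonyl O at 2.9 A / 15 deg from SER OG-HG -> acceptor flag only;
        pushing the acceptor past 3.5 A clears it."""
        from caifp.synth import _probe_carbonyl
        key = ResidueKey("A", 1, "", "SER")
        rec = _mol(_sidechain("SER"), kind="receptor", hetero=False, key=key)
        site = BindingSite(residues=[key])
        near = _mol(_probe_carbonyl(2.9, 15.0))
        prof = detect_interactions(rec, near, site)
        assert prof.residue_flags[key].tolist() == [True] + [False] * 6
        far = _mol(_probe_carbonyl(3.6, 15.0))
        prof = detect_interactions(rec, far, site)
        assert not prof.flag(key, "hbond_acceptor")

    def test_parallel_stack_is_pipi_not_tstack(self):
        from caifp.synth import _probe_benzene
        key = ResidueKey("A", 1, "", "PHE")
        rec = _mol(_sidechain("PHE"), kind="receptor", hetero=False, key=key)
        site = BindingSite(residues=[key])
        lig = _mol(_probe_benzene(3.8, 5.0))
        prof = detect_interactions(rec, lig, site)
        assert prof.flag(key, "pi_pi")
        assert not prof.flag(key, "t_stack")

    def test_missing_site_residue(self):
        key = ResidueKey("A", 1, "", "SER")
        rec = _mol(_sidechain("SER"), kind="receptor", hetero=False, key=key)
        ghost = ResidueKey("A", 9, "", "GLY")
        with pytest.raises(MissingResidueError, match="9"):
            detect_interactions(rec, _mol(_hexagon_atoms()),
                                BindingSite(residues=[key, ghost]))

    @pytest.mark.parametrize("kind", INTERACTION_TYPES)
    def test_oracle_equivalence(self, kind, geo):
        """Detector flags equal a brute-force all-pairs scan on randomized
        planted fixtures, satisfy and violate alike."""
        for seed in range(15):
            for satisfy in (True, False):
                fx = make_interaction_fixture(kind, satisfy, seed=seed)
                site = BindingSite(residues=[fx.residue_key])
                prof = detect_interactions(fx.receptor, fx.ligand, site, geo)
                assert_profiles_equal(prof, detect_profile(fx.receptor, fx.ligand, site, geo))
                assert prof.flag(fx.residue_key, kind) is satisfy

    def test_cutoff_monotonicity(self, geo):
        """Enlarging every distance cutoff never clears a set flag."""
        wide = GeometryConfig(
            hbond_max_da_dist=4.5, hydrophobic_max_cc_dist=5.0,
            pipi_max_centroid_dist=8.5, tstack_max_centroid_dist=6.0,
            catpi_max_dist=7.0, saltbridge_max_dist=6.5)
        for kind in INTERACTION_TYPES:
            for seed in range(5):
                fx = make_interaction_fixture(kind, True, seed=seed)
                site = BindingSite(residues=[fx.residue_key])
                f0 = detect_interactions(fx.receptor, fx.ligand, site, geo)
                f1 = detect_interactions(fx.receptor, fx.ligand, site, wide)
                narrow = f0.residue_flags[fx.residue_key]
                broad = f1.residue_flags[fx.residue_key]
                assert np.all(broad[narrow])  # set stays set

    def test_salt_bridge_role_symmetry(self):
        """Salt-bridge fires regardless of which side carries the cation."""
        asp_key = ResidueKey("A", 1, "", "ASP")
        lys_key = ResidueKey("A", 1, "", "LYS")
        from caifp.synth import _probe_ammonium, _probe_acetate, _ASP_ANION
        rec1 = _mol(_sidechain("ASP"), kind="receptor", hetero=False, key=asp_key)
        lig1 = _mol(_probe_ammonium(_ASP_ANION + np.array([4.5, 0, 0])))
        p1 = detect_interactions(rec1, lig1, BindingSite(residues=[asp_key]))
        rec2 = _mol(_sidechain("LYS"), kind="receptor", hetero=False, key=lys_key)
        lig2 = _mol(_probe_acetate(np.array([3.0, 0, 0]) + np.array([4.5, 0, 0])))
        p2 = detect_interactions(rec2, lig2, BindingSite(residues=[lys_key]))
        assert p1.flag(asp_key, "salt_bridge") and p2.flag(lys_key, "salt_bridge")

    def test_rigid_motion_invariance(self):
        fx = make_interaction_fixture("pi_pi", True, seed=7)
        site = BindingSite(residues=[fx.residue_key])
        before = detect_interactions(fx.receptor, fx.ligand, site)
        rng = np.random.default_rng(1)
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        t = np.array([17.0, -4.0, 2.5])
        for s in (fx.receptor, fx.ligand):
            for a in s.atoms:
                a.coords = R @ a.coords + t
        after = detect_interactions(fx.receptor, fx.ligand, site)
        assert before == after

    def test_determinism(self):
        fx = make_interaction_fixture("cation_pi", True, seed=9)
        site = BindingSite(residues=[fx.residue_key])
        p1 = detect_interactions(fx.receptor, fx.ligand, site)
        p2 = detect_interactions(fx.receptor, fx.ligand, site)
        assert p1 == p2


class TestReport:
    def test_empty_profile(self):
        text, doc = interactions_report(InteractionProfile(residue_flags={}))
        assert text.splitlines() == ["residue\t" + "\t".join(INTERACTION_TYPES)]
        assert json.loads(doc)["residues"] == {}

    def test_single_donor_row(self):
        key = ResidueKey("A", 5, "", "SER")
        flags = np.zeros(7, bool)
        flags[1] = True
        text, doc = interactions_report(InteractionProfile(residue_flags={key: flags}))
        assert text.splitlines()[1].split("\t")[1:] == list("0100000")
        assert json.loads(doc)["residues"]["A/5/SER"] == [0, 1, 0, 0, 0, 0, 0]

    def test_json_round_trip(self):
        fx = make_interaction_fixture("hbond_acceptor", True, seed=0)
        site = BindingSite(residues=[fx.residue_key])
        prof = detect_interactions(fx.receptor, fx.ligand, site)
        _, doc = interactions_report(prof)
        assert profile_from_json(doc) == prof
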