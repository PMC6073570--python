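import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caifp import (
    AtomRecord,
    BindingSite,
    FixtureSpec,
    ResidueKey,
    Structure,
    Transform,
    derive_binding_site,
    make_training_set,
    read_site,
    read_structure,
    split_complex,
    superpose_calpha,
    write_site,
    write_structure,
)
from caifp.errors import AmbiguityError, AlignmentError, FormatError, ParseError, UsageError

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
HETATM    3 ZN    ZN A  99       0.000   0.000   0.000  1.00  0.00          ZN
"""

PDB_WATER = PDB_3ATOMS + """\
HETATM    4  O   HOH A 200       5.000   5.000   5.000  1.00  0.00           O
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C
ATOM      3  CB AALA A   1       3.000   0.000   0.000  0.50  0.00           C
ATOM      4  CB BALA A   1       4.000   0.000   0.000  0.50  0.00           C
"""

MOL2_ETHANOL = """\
@<TRIPOS>MOLECULE
ethanol
 3 2 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3     1  LIG         0.0000
      2 C2          1.5300    0.0000    0.0000 C.3     1  LIG         0.0000
      3 O1          2.2000    1.2000    0.0000 O.3     1  LIG         0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
"""

PDB_ETHANOL = """\
HETATM    1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  C2  LIG L   1       1.530   0.000   0.000  1.00  0.00           C
HETATM    3  O1  LIG L   1       2.200   1.200   0.000  1.00  0.00           O
"""

PDBQT_LINE = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00     0.123 A
HETATM    2  O1  LIG L   1       4.000   5.000   6.000  1.00  0.00    -0.400 OA
"""


def _ala(chain, num, x):
    """Two-atom residue at x along the axis (CA + CB)."""
    key = ResidueKey(chain, num, "", "ALA")
    return [AtomRecord(1000 * num + 1, "CA", "C", np.array([x, 0, 0]), key),
            AtomRecord(1000 * num + 2, "CB", "C", np.array([x + 1.53, 0, 0]), key)]


def _complex_with_residue_at(distance):
    """Complex: one ALA residue whose nearest atom is `distance` from a
    one-heavy-atom hetero ligand placed at the origin."""
    lig_key = ResidueKey("L", 1, "", "LIG")
    atoms = _ala("A", 1, distance)  # CA at `distance` is the nearest atom
    atoms += [
        AtomRecord(9001, "C1", "C", np.array([0.0, 0, 0]), lig_key, is_hetero=True),
        AtomRecord(9002, "O1", "O", np.array([-1.2, 0, 0]), lig_key, is_hetero=True),
    ]
    return Structure(atoms=atoms, kind="complex", identifier=f"d{distance}")


class TestReadStructure:
    def test_pdb_elements_from_columns(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_3ATOMS)
        s = read_structure(p)
        assert len(s) == 3
        assert s.elements == ["N", "C", "Zn"]
        assert s.atoms[2].is_hetero
        np.testing.assert_allclose(s.atoms[0].coords, [11.104, 6.134, -6.504])

    def test_strip_waters(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(PDB_WATER)
        assert len(read_structure(p)) == 4
        s = read_structure(p, strip_waters=True)
        assert len(s) == 3
        assert all(a.residue_key.resname != "HOH" for a in s.atoms)

    def test_altloc_highest_occupancy_tie_to_a(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        s = read_structure(p)
        assert len(s) == 2
        coords = {a.name: a.coords[0] for a in s.atoms}
        assert coords["CA"] == 2.0   # occupancy 0.70 wins
        assert coords["CB"] == 3.0   # tie at 0.50 -> altLoc 'A'

    def test_pdbqt_types_mapped_to_elements(self, tmp_path):
        p = tmp_path / "x.pdbqt"
        p.write_text(PDBQT_LINE)
        s = read_structure(p)
        assert s.elements == ["C", "O"]  # A -> aromatic carbon, OA -> acceptor oxygen

    def test_pdb_and_mol2_agree_on_heavy_coordinates(self, tmp_path):
        p1 = tmp_path / "e.pdb"
        p1.write_text(PDB_ETHANOL)
        p2 = tmp_path / "e.mol2"
        p2.write_text(MOL2_ETHANOL)
        s1, s2 = read_structure(p1), read_structure(p2)
        c1 = sorted(map(tuple, np.round(s1.coords[s1.heavy_indices()], 3)))
        c2 = sorted(map(tuple, np.round(s2.coords[s2.heavy_indices()], 3)))
        assert c1 == c2

    def test_unreadable_and_unsupported(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM      1  CA  ALA A   X       1.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_structure(bad)
        xyz = tmp_path / "m.xyz"
        xyz.write_text("3\n")
        with pytest.raises(FormatError):
            read_structure(xyz)
        with pytest.raises(ParseError):
            read_structure(tmp_path / "absent.pdb")

    def test_write_read_roundtrip(self, tmp_path, small_training_set):
        ts = small_training_set
        p = tmp_path / "cplx.pdb"
        write_structure(ts.complexes[0], p)
        again = read_structure(p)
        orig = ts.complexes[0]
        assert len(again) == len(orig)
        assert again.elements == orig.elements
        np.testing.assert_allclose(again.coords, orig.coords, atol=1.5e-3)


class TestSplitComplex:
    def test_single_hetero_residue(self, small_training_set):
        receptor, ligand = split_complex(small_training_set.complexes[0], "LIG")
        assert all(a.residue_key.resname == "LIG" for a in ligand.atoms)
        assert len(receptor) + len(ligand) == len(small_training_set.complexes[0])

    def test_zinc_stays_with_receptor(self):
        zn_key = ResidueKey("A", 99, "", "ZN")
        lig_key = ResidueKey("L", 1, "", "LIG")
        atoms = _ala("A", 1, 3.0) + [
            AtomRecord(500, "ZN", "Zn", np.array([8.0, 0, 0]), zn_key, is_hetero=True),
            AtomRecord(600, "C1", "C", np.array([0.0, 0, 0]), lig_key, is_hetero=True),
            AtomRecord(601, "C2", "C", np.array([1.4, 0, 0]), lig_key, is_hetero=True),
        ]
        cplx = Structure(atoms=atoms, kind="complex")
        receptor, ligand = split_complex(cplx, "LIG")
        assert any(a.element == "Zn" for a in receptor.atoms)
        assert all(a.residue_key.resname == "LIG" for a in ligand.atoms)

    def test_ambiguous_selector(self):
        k1, k2 = ResidueKey("L", 1, "", "LIG"), ResidueKey("L", 2, "", "LIG")
        atoms = _ala("A", 1, 3.0)
        atoms += [AtomRecord(700 + i, f"C{i}", "C", np.array([20.0 + i, 0, 0]), k1,
                             is_hetero=True) for i in range(2)]
        atoms += [AtomRecord(800 + i, f"C{i}", "C", np.array([40.0 + i, 0, 0]), k2,
                             is_hetero=True) for i in range(2)]
        with pytest.raises(AmbiguityError, match="matched 2"):
            split_complex(Structure(atoms=atoms), "LIG")


class TestDeriveBindingSite:
    def test_inclusion_by_distance(self):
        inside = _complex_with_residue_at(5.0)
        outside = _complex_with_residue_at(7.2)
        assert len(derive_binding_site([inside], 7.0)) == 1
        assert len(derive_binding_site([outside], 7.0)) == 0

    def test_union_over_complexes(self):
        c1 = _complex_with_residue_at(5.0)   # residue A/1
        c2 = _complex_with_residue_at(6.0)
        # move c2's residue to a different number so the union has two entries
        for a in c2.atoms:
            if not a.is_hetero:
                a.residue_key = ResidueKey("A", 2, "", "ALA")
        site = derive_binding_site([c1, c2], 7.0)
        assert [r.resnum for r in site.residues] == [1, 2]
        singles = [derive_binding_site([c], 7.0).residues for c in (c1, c2)]
        assert set(site.residues) == set(singles[0]) | set(singles[1])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        complexes = [_complex_with_residue_at(float(d))
                     for d in rng.uniform(3.0, 12.0, 8)]
        for c1, c2 in [(4.0, 7.0), (7.0, 10.0)]:
            s1 = set(derive_binding_site(complexes, c1).residues)
            s2 = set(derive_binding_site(complexes, c2).residues)
            assert s1 <= s2

    def test_empty_list_and_site_io(self, tmp_path):
        with pytest.raises(UsageError):
            derive_binding_site([])
        site = derive_binding_site([_complex_with_residue_at(4.0)], 7.0)
        p = tmp_path / "site.tsv"
        write_site(site, p)
        again = read_site(p)
        assert again.residues == site.residues
        assert again.site_tag == site.site_tag
        # bit-exact round trip
        write_site(again, tmp_path / "site2.tsv")
        assert p.read_text() == (tmp_path / "site2.tsv").read_text()


def _helix_like(n=12, chain="A"):
    atoms = []
    for i in range(n):
        key = ResidueKey(chain, i + 1, "", "GLY")
        xyz = np.array([np.cos(i * 0.6) * 2.3, np.sin(i * 0.6) * 2.3, 1.5 * i])
        atoms.append(AtomRecord(i + 1, "CA", "C", xyz, key))
    return Structure(atoms=atoms, kind="receptor", identifier="helix")


class TestSuperposeCalpha:
    def test_identity(self):
        ref = _helix_like()
        transform, rmsd = superpose_calpha(ref, ref.copy())
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self):
        ref = _helix_like()
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        mobile = ref.transformed(Transform(R, t))
        transform, rmsd = superpose_calpha(ref, mobile)
        assert rmsd < 1e-6
        aligned = mobile.transformed(transform)
        np.testing.assert_allclose(aligned.coords, ref.coords, atol=1e-6)

    def test_noise_level_recovered(self):
        ref = _helix_like(n=40)
        sigma = 0.1
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mobile = ref.copy()
            for a in mobile.atoms:
                a.coords = a.coords + rng.normal(0, sigma, 3)
            _, rmsd = superpose_calpha(ref, mobile)
            fits.append(rmsd)
        # E[RMSD^2] ~ 3 sigma^2 before fitting; the fit removes ~6 DoF
        assert np.mean(fits) == pytest.approx(np.sqrt(3) * sigma, rel=0.25)

    def test_fit_invariant_under_rigid_premotion(self):
        ref = _helix_like(n=20)
        mobile = ref.copy()
        rng = np.random.default_rng(3)
        for a in mobile.atoms:
            a.coords = a.coords + rng.normal(0, 0.3, 3)
        _, rmsd0 = superpose_calpha(ref, mobile)
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        premoved = mobile.transformed(Transform(R, np.array([4.0, -2.0, 9.0])))
        _, rmsd1 = superpose_calpha(ref, premoved)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-6)

    def test_too_few_pairs(self):
        ref = _helix_like(n=2)
        with pytest.raises(AlignmentError):
            superpose_calpha(ref, ref.copy())
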