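"""Molecular structures, binding sites, pose ensembles and receptor
superposition.

The container types here are deliberately minimal: an :class:`AtomRecord`
holds one atom, a :class:`Structure` is a flat atom list with optional
connectivity, and a :class:`BindingSite` is an ordered list of residue keys
that fixes the fingerprint bit axis. PDB and PDBQT files are read with a
fixed-width column parser (element from columns 77-78 with an atom-name
fallback; for altLoc groups the highest-occupancy conformer is kept, ties
resolved toward 'A'). SDF and MOL2 go through RDKit, which also supplies
formal charges and bonds.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chem import perceive_bonds
from .errors import (
    AlignmentError,
    AmbiguityError,
    FormatError,
    ParseError,
    UsageError,
)

WATER_NAMES = {"HOH", "WAT", "DOD", "TIP", "SOL", "H2O"}

TWO_LETTER_ELEMENTS = {
    "ZN", "CL", "BR", "FE", "MG", "NA", "CA", "MN", "CU", "NI", "SE", "CO", "K",
}

# AutoDock atom types -> element (PDBQT dialect)
_PDBQT_TYPES = {
    "H": "H", "HD": "H", "HS": "H", "C": "C", "A": "C", "N": "N", "NA": "N",
    "NS": "N", "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "ZN": "Zn", "MG": "Mg",
    "MN": "Mn", "FE": "Fe", "CA": "Ca",
}


class ResidueKey(NamedTuple):
    """Unique residue identity within a structure."""

    chain: str
    resnum: int
    icode: str
    resname: str


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_key: ResidueKey
    is_hetero: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")


@dataclass
class Structure:
    """A flat list of atoms with optional connectivity.

    ``kind`` is one of ``receptor``, ``ligand``, ``complex``. ``bonds`` holds
    atom-index pairs when the source format provides them (SDF/MOL2); when
    absent, consumers fall back to distance-based perception.
    """

    atoms: list[AtomRecord]
    kind: str = "complex"
    identifier: str = ""
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("duplicate atom serial numbers")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        out: dict[ResidueKey, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def get_bonds(self) -> list[tuple[int, int]]:
        if self.bonds is not None:
            return self.bonds
        return perceive_bonds(self.elements, self.coords)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            kind=self.kind,
            identifier=self.identifier,
            bonds=list(self.bonds) if self.bonds is not None else None,
        )

    def transformed(self, transform: "Transform") -> "Structure":
        new = self.copy()
        moved = transform.apply(self.coords)
        for a, xyz in zip(new.atoms, moved):
            a.coords = xyz
        return new


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


@dataclass
class BindingSite:
    """Ordered residue axis of the fingerprint.

    Deterministic ordering (chain, residue number, insertion code) makes the
    bit layout reproducible across runs and machines.
    """

    residues: list[ResidueKey]
    ordering_rule: str = "chain_resnum_icode"
    distance_cutoff: float = 7.0

    def __post_init__(self) -> None:
        if len(self.residues) != len(set(self.residues)):
            raise ValueError("binding site contains duplicate residues")

    def __len__(self) -> int:
        return len(self.residues)

    def index(self, key: ResidueKey) -> int:
        return self.residues.index(key)

    @property
    def site_tag(self) -> str:
        h = hashlib.sha1()
        for r in self.residues:
            h.update(f"{r.chain}|{r.resnum}|{r.icode}|{r.resname}\n".encode())
        return h.hexdigest()[:12]


@dataclass
class PoseSet:
    """Docking pose ensemble for one ligand against one receptor."""

    ligand_id: str
    receptor_id: str
    poses: list[Structure]
    engine_scores: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.poses:
            raise UsageError("pose set must contain at least one pose")
        ref = sorted(a.name for a in self.poses[0].atoms if a.element != "H")
        nheavy = len(self.poses[0].heavy_indices())
        for k, p in enumerate(self.poses[1:], start=1):
            names = sorted(a.name for a in p.atoms if a.element != "H")
            if len(p.heavy_indices()) != nheavy or names != ref:
                raise ValueError(f"pose {k} differs in heavy-atom composition")

    def __len__(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# parsing


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in TWO_LETTER_ELEMENTS and len(name.strip()) > 1:
        return two.capitalize()
    return stripped[0].upper()


def _parse_pdb_like(text: str, identifier: str, pdbqt: bool,
                    strip_waters: bool, strip_ions: bool) -> Structure:
    raw: list[tuple[str, float, AtomRecord]] = []  # (altloc, occupancy, atom)
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16:17]
            resname = line[17:20].strip()
            chain = line[21:22].strip()
            resnum = int(line[22:26])
            icode = line[26:27].strip()
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{identifier}: unparsable {rec.strip()} record at line {lineno}: {exc}") from None
        if pdbqt:
            ad_type = line[77:79].strip() or line[76:79].strip()
            element = _PDBQT_TYPES.get(ad_type.upper(), _element_from_name(name))
        else:
            element = line[76:78].strip()
            element = element.capitalize() if element else _element_from_name(name)
        atom = AtomRecord(
            serial=serial, name=name, element=element, coords=xyz,
            residue_key=ResidueKey(chain, resnum, icode, resname),
            is_hetero=(rec == "HETATM"),
        )
        raw.append((altloc.strip(), occupancy, atom))

    # altLoc resolution: keep highest occupancy per (residue, atom name); tie -> 'A'
    chosen: dict[tuple[ResidueKey, str], tuple[float, str, AtomRecord]] = {}
    order: list[tuple[ResidueKey, str]] = []
    for altloc, occ, atom in raw:
        key = (atom.residue_key, atom.name)
        if key not in chosen:
            chosen[key] = (occ, altloc, atom)
            order.append(key)
        else:
            occ0, alt0, _ = chosen[key]
            if occ > occ0 or (occ == occ0 and altloc < alt0):
                chosen[key] = (occ, altloc, atom)

    atoms = [chosen[k][2] for k in order]
    if strip_waters:
        atoms = [a for a in atoms if a.residue_key.resname not in WATER_NAMES]
    if strip_ions:
        counts: dict[ResidueKey, int] = {}
        for a in atoms:
            counts[a.residue_key] = counts.get(a.residue_key, 0) + 1
        atoms = [
            a for a in atoms
            if not (a.is_hetero and counts[a.residue_key] == 1
                    and a.residue_key.resname != "ZN")
        ]
    return Structure(atoms=atoms, kind="complex", identifier=identifier)


def _structure_from_rdkit(mol, identifier: str) -> Structure:
    conf = mol.GetConformer()
    atoms: list[AtomRecord] = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        info = atom.GetPDBResidueInfo()
        if info is not None:
            key = ResidueKey(info.GetChainId().strip(), info.GetResidueNumber(),
                             info.GetInsertionCode().strip(), info.GetResidueName().strip())
            name = info.GetName().strip()
        else:
            key = ResidueKey("L", 1, "", "LIG")
            name = f"{atom.GetSymbol()}{idx + 1}"
        atoms.append(AtomRecord(
            serial=idx + 1, name=name, element=atom.GetSymbol(),
            coords=np.array([pos.x, pos.y, pos.z]), residue_key=key,
            is_hetero=True, formal_charge=atom.GetFormalCharge(),
        ))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return Structure(atoms=atoms, kind="ligand", identifier=identifier, bonds=bonds)


def read_structure(path: str | Path, format_hint: str | None = None, *,
                   strip_waters: bool = False, strip_ions: bool = False) -> Structure:
    """Read a molecular structure from PDB, PDBQT, SDF or MOL2.

    The format is auto-detected from the file extension unless ``format_hint``
    is given. ``strip_waters`` removes water residues; ``strip_ions`` removes
    single-atom hetero residues other than zinc (the catalytic ion is kept).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _parse_pdb_like(path.read_text(), path.stem, False, strip_waters, strip_ions)
    if fmt == "pdbqt":
        return _parse_pdb_like(path.read_text(), path.stem, True, strip_waters, strip_ions)
    if fmt in ("sdf", "sd", "mol"):
        from rdkit import Chem
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise ParseError(f"{path}: no molecule records found")
        return _structure_from_rdkit(mols[0], path.stem)
    if fmt == "mol2":
        from rdkit import Chem
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ParseError(f"{path}: unreadable MOL2 file")
        return _structure_from_rdkit(mol, path.stem)
    raise FormatError(f"unsupported format '{fmt}' for {path}")


def read_pose_set(path: str | Path, ligand_id: str = "", receptor_id: str = "",
                  format_hint: str | None = None) -> PoseSet:
    """Read a multi-record pose file (multi-molecule SDF or multi-MODEL PDB)."""
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    poses: list[Structure] = []
    if fmt in ("sdf", "sd"):
        from rdkit import Chem
        for k, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)):
            if mol is None:
                continue
            s = _structure_from_rdkit(mol, f"{path.stem}:{k}")
            poses.append(s)
    elif fmt in ("pdb", "pdbqt"):
        text = path.read_text()
        blocks: list[str] = []
        if "MODEL" in text:
            current: list[str] = []
            for line in text.splitlines():
                if line.startswith("MODEL"):
                    current = []
                elif line.startswith("ENDMDL"):
                    blocks.append("\n".join(current))
                else:
                    current.append(line)
        else:
            blocks = [text]
        for k, block in enumerate(blocks):
            s = _parse_pdb_like(block, f"{path.stem}:{k}", fmt == "pdbqt", False, False)
            s.kind = "ligand"
            poses.append(s)
    else:
        raise FormatError(f"unsupported pose format '{fmt}'")
    if not poses:
        raise ParseError(f"{path}: no poses found")
    return PoseSet(ligand_id=ligand_id or path.stem, receptor_id=receptor_id, poses=poses)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as fixed-width PDB v3.3."""
    lines = []
    for a in structure.atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name
        if len(name) < 4 and len(a.element) == 1:
            name = f" {name}"
        r = a.residue_key
        x, y, z = a.coords
        lines.append(
            f"{rec}{a.serial:>5} {name:<4} {r.resname:>3} {r.chain:1}"
            f"{r.resnum:>4}{r.icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# complex handling


def _ligand_candidates(cplx: Structure) -> dict[ResidueKey, list[AtomRecord]]:
    """Hetero residues that could be the ligand: not water, not single-atom ions."""
    out: dict[ResidueKey, list[AtomRecord]] = {}
    for key, atoms in cplx.residues().items():
        if not any(a.is_hetero for a in atoms):
            continue
        if key.resname in WATER_NAMES:
            continue
        if len(atoms) == 1:  # single-atom ion (zinc included) stays with receptor
            continue
        out[key] = atoms
    return out


def split_complex(cplx: Structure, ligand_selector: str | None = None
                  ) -> tuple[Structure, Structure]:
    """Partition a complex into (receptor, ligand).

    ``ligand_selector`` is a hetero residue name (e.g. ``"LIG"``) or
    ``"chain/resnum"``. Zinc and other single-atom ions always remain with the
    receptor. With no selector, exactly one candidate hetero residue must
    exist.
    """
    candidates = _ligand_candidates(cplx)
    if ligand_selector:
        if "/" in ligand_selector:
            chain, num = ligand_selector.split("/", 1)
            matches = [k for k in candidates if k.chain == chain and k.resnum == int(num)]
        else:
            matches = [k for k in candidates if k.resname == ligand_selector]
    else:
        matches = list(candidates)
    if len(matches) != 1:
        raise AmbiguityError(
            f"ligand selector {ligand_selector!r} matched {len(matches)} residues: "
            f"{sorted(matches)}"
        )
    lig_key = matches[0]
    lig_atoms = [a for a in cplx.atoms if a.residue_key == lig_key]
    rec_atoms = [a for a in cplx.atoms if a.residue_key != lig_key]
    receptor = Structure(atoms=rec_atoms, kind="receptor", identifier=cplx.identifier)
    ligand = Structure(atoms=lig_atoms, kind="ligand", identifier=f"{cplx.identifier}:{lig_key.resname}")
    return receptor, ligand


def derive_binding_site(complexes: Sequence[Structure], cutoff: float = 7.0, *,
                        heavy_only: bool = False, include_ion_residues: bool = False,
                        ligand_selector: str | None = None) -> BindingSite:
    """Union of receptor residues with any atom within ``cutoff`` of any ligand
    atom, over all complexes, in deterministic (chain, resnum, icode) order.

    Hydrogens participate by default (the structures are assumed prepared with
    hydrogens); ``heavy_only`` restricts the distance test to heavy atoms.
    Single-atom ion residues (e.g. the catalytic zinc) are excluded unless
    ``include_ion_residues`` is set.
    """
    if not complexes:
        raise UsageError("derive_binding_site requires at least one complex")
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    selected: set[ResidueKey] = set()
    for cplx in complexes:
        receptor, ligand = split_complex(cplx, ligand_selector)
        lig_atoms = [a for a in ligand.atoms if not (heavy_only and a.element == "H")]
        lig_xyz = np.array([a.coords for a in lig_atoms])
        for key, atoms in receptor.residues().items():
            if len(atoms) == 1 and not include_ion_residues:
                continue
            res_atoms = [a for a in atoms if not (heavy_only and a.element == "H")]
            if not res_atoms:
                continue
            res_xyz = np.array([a.coords for a in res_atoms])
            if cdist(res_xyz, lig_xyz).min() <= cutoff:
                selected.add(key)
    ordered = sorted(selected, key=lambda r: (r.chain, r.resnum, r.icode))
    return BindingSite(residues=ordered, distance_cutoff=cutoff)


def write_site(site: BindingSite, path: str | Path) -> None:
    lines = [f"# cutoff={site.distance_cutoff}\tordering={site.ordering_rule}",
             "chain\tresnum\ticode\tresname"]
    for r in site.residues:
        lines.append(f"{r.chain}\t{r.resnum}\t{r.icode}\t{r.resname}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_site(path: str | Path) -> BindingSite:
    cutoff = 7.0
    ordering = "chain_resnum_icode"
    residues: list[ResidueKey] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line[1:].split("\t"):
                k, _, v = tok.strip().partition("=")
                if k == "cutoff":
                    cutoff = float(v)
                elif k == "ordering":
                    ordering = v
            continue
        if line.startswith("chain\t") or not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"malformed site line: {line!r}")
        residues.append(ResidueKey(parts[0], int(parts[1]), parts[2], parts[3]))
    return BindingSite(residues=residues, ordering_rule=ordering, distance_cutoff=cutoff)


# ---------------------------------------------------------------------------
# superposition


def superpose_calpha(reference: Structure, mobile: Structure
                     ) -> tuple[Transform, float]:
    """Kabsch least-squares superposition over paired C-alpha atoms.

    Pairing is by (chain, residue number, insertion code); the receptors are
    assumed to be the same protein, so no sequence alignment is attempted.
    Returns the rigid transform carrying ``mobile`` onto ``reference`` and the
    fit RMSD over the paired C-alphas.
    """
    def ca_map(s: Structure) -> dict[tuple[str, int, str], np.ndarray]:
        return {
            (a.residue_key.chain, a.residue_key.resnum, a.residue_key.icode): a.coords
            for a in s.atoms if a.name == "CA" and a.element == "C"
        }

    ref_ca = ca_map(reference)
    mob_ca = ca_map(mobile)
    common = sorted(set(ref_ca) & set(mob_ca))
    if len(common) < 3:
        raise AlignmentError(f"only {len(common)} paired C-alpha atoms (need >= 3)")
    P = np.array([ref_ca[k] for k in common])
    Q = np.array([mob_ca[k] for k in common])
    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(P - p_mean, Q - q_mean)
    R = rot.as_matrix()
    t = p_mean - R @ q_mean
    rmsd = rssd / np.sqrt(len(common))
    return Transform(R, t), float(rmsd)
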