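"""Synthetic ground-truth fixtures: minimal receptor/ligand systems with
planted interactions, perturbed pose ensembles, and whole training sets.

Every generator is seed-deterministic. Receptor fragments use idealized
amino-acid side-chain templates (SER, LEU, PHE, ASP, plus ARG/LYS/HIS/ALA);
ligands are small probe fragments (carbonyl, hydroxyl, methane, benzene,
triazine, ammonium, acetate) placed to satisfy — or violate, by a stated
margin — exactly one interaction's geometric criteria. Probe placement
windows keep "satisfy" geometries at least ~0.1 angstrom / 5 degrees inside
the default cutoffs and "violate" geometries at least 0.3 angstrom /
10 degrees outside, and are additionally chosen so that no *other*
interaction type fires incidentally; a planted training complex therefore
has an exactly known fingerprint.

These fixtures are geometric probes, not physically realistic molecules: a
"ligand" may consist of several disconnected fragments and carries no
energetics. They exercise the detector, the fingerprint pipeline, the
rescoring statistics and the clustering with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .fingerprints import Fingerprint, ReferenceFingerprint, build_reference
from .interactions import INTERACTION_TYPES, N_INTERACTIONS
from .structures import AtomRecord, BindingSite, PoseSet, ResidueKey, Structure

Atom = tuple[str, str, tuple[float, float, float]]  # (name, element, xyz)

_HEX = [(np.cos(np.radians(a)), np.sin(np.radians(a))) for a in range(180, -180, -60)]
_PENT_ANGLES = (180.0, 108.0, 36.0, -36.0, -108.0)
_TET = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / np.sqrt(3)


def _hexagon(center: np.ndarray, radius: float, u: np.ndarray, v: np.ndarray
             ) -> list[np.ndarray]:
    """Six vertices of a regular hexagon in the plane spanned by u, v."""
    out = []
    for ang in range(0, 360, 60):
        a = np.radians(ang)
        out.append(center + radius * (np.cos(a) * u + np.sin(a) * v))
    return out


def _sidechain(resname: str, hg_axis: str = "x") -> list[Atom]:
    """Idealized side-chain template in a local frame: the chain extends
    along +x from CA at the origin; ring planes lie in z=0."""
    x = np.array([1.0, 0, 0])
    if resname == "SER":
        hg = (3.92, 0.0, 0.0) if hg_axis == "x" else (2.96, 0.96, 0.0)
        return [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0)),
                ("OG", "O", (2.96, 0, 0)), ("HG", "H", hg)]
    if resname == "ALA":
        return [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0))]
    if resname == "LEU":
        return [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0)),
                ("CG", "C", (3.06, 0, 0)), ("CD1", "C", (4.59, 0, 0))]
    if resname == "ASP":
        return [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0)),
                ("CG", "C", (3.04, 0, 0)), ("OD1", "O", (3.65, 1.10, 0)),
                ("OD2", "O", (3.65, -1.10, 0))]
    if resname == "PHE":
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        center = np.array([4.43, 0, 0])
        verts = [center + 1.39 * np.array([c, s, 0]) for c, s in _HEX]
        atoms: list[Atom] = [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0))]
        atoms += [(n, "C", tuple(v)) for n, v in zip(names, verts)]
        return atoms
    if resname == "ARG":
        return [("CD", "C", (0, 0, 0)), ("NE", "N", (1.46, 0, 0)),
                ("CZ", "C", (2.79, 0, 0)), ("NH1", "N", (3.46, 1.15, 0)),
                ("NH2", "N", (3.46, -1.15, 0))]
    if resname == "LYS":
        return [("CD", "C", (0, 0, 0)), ("CE", "C", (1.53, 0, 0)),
                ("NZ", "N", (3.00, 0, 0)), ("HZ1", "H", (3.52, 0.82, 0)),
                ("HZ2", "H", (3.52, -0.82, 0)), ("HZ3", "H", (3.26, 0, 0.93))]
    if resname == "HIS":
        center = np.array([4.36, 0, 0])
        names = ("CG", "ND1", "CE1", "NE2", "CD2")
        elems = ("C", "N", "C", "N", "C")
        atoms = [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0))]
        for n, e, ang in zip(names, elems, _PENT_ANGLES):
            a = np.radians(ang)
            atoms.append((n, e, tuple(center + 1.166 * np.array([np.cos(a), np.sin(a), 0]))))
        return atoms
    raise GenerationError(f"no side-chain template for {resname}")


_SER_OG = np.array([2.96, 0.0, 0.0])
_SER_HG = np.array([3.92, 0.0, 0.0])
_LEU_CD1 = np.array([4.59, 0.0, 0.0])
_PHE_CENTROID = np.array([4.43, 0.0, 0.0])
_ASP_ANION = np.array([3.65, 0.0, 0.0])


# ---------------------------------------------------------------------------
# probes (ligand fragments in the residue's local frame)


def _probe_carbonyl(da_dist: float, deviation_deg: float) -> list[Atom]:
    """Carbonyl acceptor: O placed at donor-acceptor distance ``da_dist``
    from SER OG with the stated D-H...A deviation from linearity."""
    dev = np.radians(deviation_deg)
    # acceptor along direction `dev` off the OG-HG axis, measured at HG
    oh = 0.96
    disc = oh ** 2 * np.cos(dev) ** 2 - oh ** 2 + da_dist ** 2
    rho = -oh * np.cos(dev) + np.sqrt(disc)
    a = _SER_HG + rho * np.array([np.cos(dev), np.sin(dev), 0.0])
    direction = (a - _SER_HG) / np.linalg.norm(a - _SER_HG)
    c = a + 1.23 * direction
    perp = np.array([-direction[1], direction[0], 0.0])
    h1 = c + 0.55 * direction + 0.93 * perp
    h2 = c + 0.55 * direction - 0.93 * perp
    return [("O", "O", tuple(a)), ("C", "C", tuple(c)),
            ("H1", "H", tuple(h1)), ("H2", "H", tuple(h2))]


def _probe_hydroxyl(da_dist: float, tilt_deg: float) -> list[Atom]:
    """Hydroxyl donor: ligand O at ``da_dist`` from SER OG (the acceptor),
    O-H tilted off the O->OG axis by ``tilt_deg``."""
    o = _SER_OG + np.array([da_dist, 0, 0])
    t = np.radians(tilt_deg)
    h = o + 0.96 * np.array([-np.cos(t), np.sin(t), 0])
    c = o + 1.43 * np.array([1.0, 0, 0])
    return [("O", "O", tuple(o)), ("H", "H", tuple(h)), ("C", "C", tuple(c))]


def _probe_methane(cc_dist: float) -> list[Atom]:
    c = _LEU_CD1 + np.array([cc_dist, 0, 0])
    atoms: list[Atom] = [("C", "C", tuple(c))]
    for k, v in enumerate(_TET):
        atoms.append((f"H{k + 1}", "H", tuple(c + 1.09 * v)))
    return atoms


def _probe_benzene(height: float, tilt_deg: float, lateral: float = 0.0) -> list[Atom]:
    """Benzene parallel (up to ``tilt_deg``) above the PHE ring at centroid
    separation ``height``."""
    t = np.radians(tilt_deg)
    u = np.array([1.0, 0, 0])
    v = np.array([0, np.cos(t), np.sin(t)])
    center = _PHE_CENTROID + np.array([lateral, 0, height])
    verts = _hexagon(center, 1.39, u, v)
    return [(f"C{k + 1}", "C", tuple(p)) for k, p in enumerate(verts)]


def _probe_triazine(height: float, angle_deg: float = 90.0) -> list[Atom]:
    """1,3,5-triazine edge-on to the PHE ring (plane angle ``angle_deg``),
    centroid ``height`` above (positive) or below (negative) along z.
    The alternation is chosen so a nitrogen sits at the vertex nearest the
    PHE ring — no carbon comes close enough for a hydrophobic contact."""
    t = np.radians(angle_deg)
    u = np.array([1.0, 0, 0])
    v = np.array([0, np.cos(t), np.sin(t)])  # plane angle vs the xy ring = angle_deg
    center = _PHE_CENTROID + np.array([0, 0, height])
    # vertex with sin=-1 is nearest the PHE plane when height > 0; sin=+1 when below
    n_angles = (150, 270, 30) if height > 0 else (90, 210, 330)
    atoms: list[Atom] = []
    for ang in (90, 150, 210, 270, 330, 30):
        a = np.radians(ang)
        p = center + 1.33 * (np.cos(a) * u + np.sin(a) * v)
        elem = "N" if ang in n_angles else "C"
        atoms.append((f"{elem}{len(atoms) + 1}", elem, tuple(p)))
    return atoms


def _probe_ammonium(position: np.ndarray) -> list[Atom]:
    atoms: list[Atom] = [("N", "N", tuple(position))]
    for k, v in enumerate(_TET):
        atoms.append((f"H{k + 1}", "H", tuple(position + 1.00 * v)))
    return atoms


def _probe_acetate(center: np.ndarray) -> list[Atom]:
    """Acetate with its carboxylate O-midpoint at ``center``."""
    c = center - np.array([0.61, 0, 0])
    return [("C1", "C", tuple(c)), ("O1", "O", tuple(c + np.array([0.61, 1.10, 0]))),
            ("O2", "O", tuple(c + np.array([0.61, -1.10, 0]))),
            ("C2", "C", tuple(c - np.array([1.53, 0, 0])))]


# ---------------------------------------------------------------------------
# assembly helpers


def _make_structure(parts: list[tuple[ResidueKey, list[Atom], bool]],
                    kind: str, identifier: str,
                    offset: np.ndarray | None = None,
                    serial_start: int = 1) -> Structure:
    atoms: list[AtomRecord] = []
    serial = serial_start
    shift = offset if offset is not None else np.zeros(3)
    for key, part, hetero in parts:
        for name, element, xyz in part:
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element,
                coords=np.asarray(xyz) + shift, residue_key=key, is_hetero=hetero))
            serial += 1
    return Structure(atoms=atoms, kind=kind, identifier=identifier)


def _random_rigid(rng: np.random.Generator, translation_scale: float = 5.0):
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q))
    t = rng.uniform(-translation_scale, translation_scale, 3)
    return rot.as_matrix(), t


def _apply_rigid(structure: Structure, R: np.ndarray, t: np.ndarray) -> None:
    for a in structure.atoms:
        a.coords = R @ a.coords + t


def _probe_for(kind: str, satisfy: bool, rng: np.random.Generator,
               salt_partner: str = "asp_ammonium") -> tuple[str, str, list[Atom]]:
    """Returns (residue template, HG axis variant, probe atoms)."""
    if kind == "hbond_acceptor":
        if satisfy:
            probe = _probe_carbonyl(rng.uniform(2.7, 3.3), rng.uniform(0, 40))
        else:
            probe = _probe_carbonyl(rng.uniform(3.9, 4.6), rng.uniform(0, 40))
        return "SER", "x", probe
    if kind == "hbond_donor":
        if satisfy:
            probe = _probe_hydroxyl(rng.uniform(2.7, 3.3), rng.uniform(0, 25))
        else:
            probe = _probe_hydroxyl(rng.uniform(3.9, 4.6), rng.uniform(0, 25))
        return "SER", "y", probe
    if kind == "hydrophobic":
        d = rng.uniform(3.2, 3.9) if satisfy else rng.uniform(4.4, 5.2)
        return "LEU", "x", _probe_methane(d)
    if kind == "pi_pi":
        if satisfy:
            probe = _probe_benzene(rng.uniform(4.6, 5.5), rng.uniform(0, 10),
                                   rng.uniform(0, 0.5))
        else:  # violate by centroid distance, well beyond cutoff
            probe = _probe_benzene(rng.uniform(8.0, 9.0), rng.uniform(0, 10))
        return "PHE", "x", probe
    if kind == "t_stack":
        if satisfy:
            probe = _probe_triazine(rng.uniform(4.78, 4.90),
                                    90 + rng.uniform(-15, 15))
        else:
            probe = _probe_triazine(rng.uniform(5.5, 6.5),
                                    90 + rng.uniform(-15, 15))
        return "PHE", "x", probe
    if kind == "cation_pi":
        dist = rng.uniform(4.0, 5.5) if satisfy else rng.uniform(6.5, 7.5)
        phi = np.radians(rng.uniform(0, 30))
        pos = _PHE_CENTROID + dist * np.array([0, np.sin(phi), np.cos(phi)])
        return "PHE", "x", _probe_ammonium(pos)
    if kind == "salt_bridge":
        dist = rng.uniform(3.8, 5.0) if satisfy else rng.uniform(5.9, 7.0)
        if salt_partner == "arg_acetate":
            arg_center = np.array([(2.79 + 1.46 + 3.46 + 3.46) / 4, 0, 0])
            return "ARG", "x", _probe_acetate(arg_center + np.array([dist, 0, 0]))
        return "ASP", "x", _probe_ammonium(_ASP_ANION + np.array([dist, 0, 0]))
    raise GenerationError(f"unknown interaction type {kind!r}")


@dataclass
class InteractionFixture:
    receptor: Structure
    ligand: Structure
    residue_key: ResidueKey
    kind: str
    expected: bool


def make_interaction_fixture(kind: str, satisfy: bool, seed: int,
                             salt_partner: str = "asp_ammonium",
                             randomize_frame: bool = True) -> InteractionFixture:
    """Minimal two-fragment system planted to satisfy or violate exactly the
    requested interaction's criteria. Ground truth is the requested flag."""
    if kind not in INTERACTION_TYPES:
        raise GenerationError(f"unknown interaction type {kind!r}")
    rng = np.random.default_rng(seed)
    resname, hg_axis, probe = _probe_for(kind, satisfy, rng, salt_partner)
    res_key = ResidueKey("A", 1, "", resname)
    lig_key = ResidueKey("L", 1, "", "LIG")
    receptor = _make_structure([(res_key, _sidechain(resname, hg_axis), False)],
                               "receptor", f"{kind}-{'sat' if satisfy else 'vio'}")
    ligand = _make_structure([(lig_key, probe, True)], "ligand", "probe",
                             serial_start=1000)
    if randomize_frame:
        R, t = _random_rigid(rng)
        _apply_rigid(receptor, R, t)
        _apply_rigid(ligand, R, t)
    return InteractionFixture(receptor, ligand, res_key, kind, satisfy)


# ---------------------------------------------------------------------------
# pose ensembles


def make_pose_ensemble(native: Structure, n: int, perturbation_scale: float,
                       seed: int, include_native: bool = False,
                       ligand_id: str = "lig", receptor_id: str = "rec"
                       ) -> tuple[PoseSet, list[float]]:
    """Rigid-body jitters of a native pose: random rotation (angle growing
    with the scale) about the heavy-atom centroid plus an isotropic Gaussian
    translation of standard deviation ``perturbation_scale`` per axis.
    Returns the ensemble and each pose's naive RMSD to the native."""
    if n < 1:
        raise GenerationError("need at least one pose")
    rng = np.random.default_rng(seed)
    heavy = native.heavy_indices()
    centroid = native.coords[heavy].mean(axis=0)
    poses: list[Structure] = []
    rmsds: list[float] = []
    for k in range(n):
        pose = native.copy()
        pose.identifier = f"{ligand_id}:pose{k}"
        if not (include_native and k == 0):
            max_angle = min(90.0, 25.0 * perturbation_scale)
            angle = np.radians(rng.uniform(0, max_angle)) if max_angle > 0 else 0.0
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(angle * axis).as_matrix()
            t = rng.normal(0, perturbation_scale, 3) if perturbation_scale > 0 else np.zeros(3)
            for a in pose.atoms:
                a.coords = R @ (a.coords - centroid) + centroid + t
        X = pose.coords[heavy]
        Y = native.coords[heavy]
        rmsds.append(float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1)))))
        poses.append(pose)
    return PoseSet(ligand_id=ligand_id, receptor_id=receptor_id, poses=poses), rmsds


# ---------------------------------------------------------------------------
# training sets


@dataclass
class FixtureSpec:
    """Recipe for a synthetic training family.

    ``planted_interactions`` is one list of (residue index, interaction type)
    per complex; a flat list of pairs is broadcast to ``n_complexes``
    identical complexes. ``group_structure`` optionally appends planted
    clusters: a list of (member count, core planting) pairs whose members all
    share the core planting (and hence the fingerprint).
    """

    seed: int = 0
    site_size: int = 8
    planted_interactions: Sequence = ()
    n_complexes: int | None = None
    pose_count: int = 20
    perturbation_scale: float = 1.0
    group_structure: list[tuple[int, list[tuple[int, str]]]] | None = None


@dataclass
class TrainingSet:
    receptor: Structure
    ligands: list[Structure]
    complexes: list[Structure]
    site: BindingSite
    expected_fingerprints: list[Fingerprint]
    expected_reference: ReferenceFingerprint
    labels: list[str]
    group_ids: list[int] | None = None


_TEMPLATE_FOR_TYPE = {
    "hbond_acceptor": "SER", "hbond_donor": "SER", "hydrophobic": "LEU",
    "pi_pi": "PHE", "t_stack": "PHE", "cation_pi": "PHE", "salt_bridge": "ASP",
}

_SLOT_SPACING = 15.0  # angstrom between residue slots; larger than any cutoff


def _normalise_plantings(spec: FixtureSpec) -> tuple[list[list[tuple[int, str]]], list[int] | None]:
    plantings: list[list[tuple[int, str]]]
    raw = list(spec.planted_interactions)
    flat = bool(raw) and len(raw[0]) == 2 and isinstance(raw[0][1], str)
    if flat:
        n = spec.n_complexes or 1
        plantings = [[tuple(p) for p in raw]] * n
    else:
        plantings = [[tuple(q) for q in p] for p in raw]
    group_ids: list[int] | None = None
    if spec.group_structure:
        group_ids = [0] * len(plantings)
        for gid, (size, core) in enumerate(spec.group_structure, start=1):
            plantings.extend([list(core)] * size)
            group_ids.extend([gid] * size)
    for plist in plantings:
        for idx, kind in plist:
            if not 0 <= idx < spec.site_size:
                raise GenerationError(f"residue index {idx} outside site of {spec.site_size}")
            if kind not in INTERACTION_TYPES:
                raise GenerationError(f"unknown interaction type {kind!r}")
    if not plantings:
        raise GenerationError("no complexes requested")
    return plantings, group_ids


def _slot_probes(types: list[str], rng: np.random.Generator
                 ) -> list[Atom]:
    """Probe fragments realising ``types`` at one residue slot, placed to
    avoid each other and any incidental interaction."""
    probes: list[Atom] = []
    for kind in types:
        if kind == "hbond_acceptor":
            probes += _probe_carbonyl(rng.uniform(2.7, 3.3), rng.uniform(0, 30))
        elif kind == "hbond_donor":
            if "hbond_acceptor" in types:  # second approach axis, along +y
                o = _SER_OG + np.array([0, rng.uniform(2.7, 3.3), 0])
                probes += [("O", "O", tuple(o)),
                           ("H", "H", tuple(o + np.array([0, -0.96, 0]))),
                           ("C", "C", tuple(o + np.array([0, 1.43, 0])))]
            else:
                probes += _probe_hydroxyl(rng.uniform(2.7, 3.3), rng.uniform(0, 25))
        elif kind == "hydrophobic":
            probes += _probe_methane(rng.uniform(3.2, 3.9))
        elif kind == "pi_pi":
            probes += _probe_benzene(rng.uniform(4.6, 5.5), rng.uniform(0, 10),
                                     rng.uniform(0, 0.5))
        elif kind == "t_stack":
            probes += _probe_triazine(-rng.uniform(4.78, 4.90),
                                      90 + rng.uniform(-15, 15))
        elif kind == "cation_pi":
            dist = rng.uniform(4.5, 5.5)
            phi = np.radians(rng.uniform(35, 50))
            pos = _PHE_CENTROID + dist * np.array([0, np.sin(phi), np.cos(phi)])
            probes += _probe_ammonium(pos)
        elif kind == "salt_bridge":
            dist = rng.uniform(3.8, 5.0)
            probes += _probe_ammonium(_ASP_ANION + np.array([dist, 0, 0]))
    return probes


def make_training_set(spec: FixtureSpec, min_support: int = 3) -> TrainingSet:
    """A family of synthetic complexes whose planted interactions are realised
    geometrically, with the exactly expected per-complex fingerprints and the
    expected consensus reference."""
    rng = np.random.default_rng(spec.seed)
    plantings, group_ids = _normalise_plantings(spec)

    # one residue template per slot, consistent across the whole family
    slot_types: list[set[str]] = [set() for _ in range(spec.site_size)]
    for plist in plantings:
        for idx, kind in plist:
            slot_types[idx].add(kind)
    slot_template: list[str] = []
    for idx, types in enumerate(slot_types):
        templates = {_TEMPLATE_FOR_TYPE[t] for t in types}
        if len(templates) > 1:
            raise GenerationError(
                f"residue slot {idx} requires contradictory templates {sorted(templates)} "
                f"for types {sorted(types)}")
        slot_template.append(templates.pop() if templates else "ALA")

    def slot_key(idx: int) -> ResidueKey:
        return ResidueKey("A", idx + 1, "", slot_template[idx])

    def slot_offset(idx: int) -> np.ndarray:
        return np.array([0.0, _SLOT_SPACING * idx, 0.0])

    # receptor shared by all complexes
    rec_parts = []
    for idx in range(spec.site_size):
        types = slot_types[idx]
        hg_axis = "y" if (slot_template[idx] == "SER"
                          and types == {"hbond_donor"}) else "x"
        atoms = [(n, e, tuple(np.asarray(xyz) + slot_offset(idx)))
                 for n, e, xyz in _sidechain(slot_template[idx], hg_axis)]
        rec_parts.append((slot_key(idx), atoms, False))
    receptor = _make_structure(rec_parts, "receptor", "synthetic-receptor")

    site = BindingSite(residues=[slot_key(i) for i in range(spec.site_size)],
                       distance_cutoff=7.0)

    ligands: list[Structure] = []
    complexes: list[Structure] = []
    expected_fps: list[Fingerprint] = []
    labels: list[str] = []
    type_index = {t: j for j, t in enumerate(INTERACTION_TYPES)}
    for k, plist in enumerate(plantings):
        by_slot: dict[int, list[str]] = {}
        for idx, kind in plist:
            by_slot.setdefault(idx, []).append(kind)
        lig_key = ResidueKey("L", 1, "", "LIG")
        lig_atoms: list[Atom] = []
        for idx, types in sorted(by_slot.items()):
            placed = _slot_probes(sorted(set(types)), rng)
            off = slot_offset(idx)
            for _, e, xyz in placed:
                lig_atoms.append((f"{e}{len(lig_atoms) + 1}", e,
                                  tuple(np.asarray(xyz) + off)))
        label = f"cplx{k:03d}"
        ligand = _make_structure([(lig_key, lig_atoms, True)], "ligand", label,
                                 serial_start=len(receptor.atoms) + 1)
        bits = np.zeros(N_INTERACTIONS * spec.site_size, dtype=bool)
        for idx, kind in plist:
            bits[N_INTERACTIONS * idx + type_index[kind]] = True
        expected_fps.append(Fingerprint(bits=bits, site_tag=site.site_tag, label=label))
        ligands.append(ligand)
        labels.append(label)
        cplx = Structure(atoms=[a for a in receptor.copy().atoms] + ligand.copy().atoms,
                         kind="complex", identifier=label)
        complexes.append(cplx)

    expected_ref = build_reference(expected_fps, min_support=min_support)
    return TrainingSet(receptor=receptor, ligands=ligands, complexes=complexes,
                       site=site, expected_fingerprints=expected_fps,
                       expected_reference=expected_ref, labels=labels,
                       group_ids=group_ids)
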