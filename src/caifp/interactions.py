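"""Geometric detection of the seven ligand-protein interaction types.

For each binding-site residue the detector evaluates, against one ligand
pose, the presence or absence of: H-bond with the ligand as acceptor, H-bond
with the ligand as donor, hydrophobic contact, parallel pi-pi stacking,
T-stacking, cation-pi interaction, and salt bridge. Multiple qualifying atom
pairs collapse to a single per-residue flag per type — the result is strictly
binary.

Typing rules (kept simple and auditable):

* donors are N/O heavy atoms with at least one bound hydrogen; the H-bond
  angle criterion is the deviation of the D-H...A angle from linearity;
* acceptors are N and O (S optionally, off by default);
* hydrophobic carbons are carbons whose heavy neighbours are only C or S
  (carbonyl/carboxyl carbons do not count);
* receptor aromatic rings come from residue templates (PHE, TYR, HIS, two in
  TRP); ligand rings are 5-6-membered cycles of the bond graph passing a
  0.35 angstrom coplanarity test;
* charged centers come from residue templates on the receptor side (ARG, LYS,
  doubly protonated HIS, ASP, GLU, termini, optionally zinc) and from
  substructure rules plus recorded formal charges on the ligand side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .chem import adjacency, perceive_bonds
from .config import GeometryConfig
from .errors import MissingResidueError
from .structures import BindingSite, ResidueKey, Structure

INTERACTION_TYPES: tuple[str, ...] = (
    "hbond_acceptor",
    "hbond_donor",
    "hydrophobic",
    "pi_pi",
    "t_stack",
    "cation_pi",
    "salt_bridge",
)

N_INTERACTIONS = len(INTERACTION_TYPES)

RING_PLANARITY_TOL = 0.35  # max out-of-plane deviation, angstrom

RESIDUE_RING_TEMPLATES: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}

# residue -> (sign, heteroatom names averaged for the center)
RESIDUE_CHARGE_TEMPLATES: dict[str, tuple[int, tuple[str, ...]]] = {
    "ARG": (+1, ("CZ", "NE", "NH1", "NH2")),
    "LYS": (+1, ("NZ",)),
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
}


@dataclass
class AromaticRing:
    member_atoms: list[int]        # atom serials
    centroid: np.ndarray
    normal: np.ndarray
    radius: float
    residue_key: ResidueKey


@dataclass
class ChargedCenter:
    sign: int                      # +1 or -1
    center: np.ndarray
    member_atoms: list[int]        # atom serials
    source: str                    # residue-template | ligand-rule | formal-charge | ion
    residue_key: ResidueKey


@dataclass
class InteractionProfile:
    """Per-residue 7-flag interaction table for one ligand pose."""

    residue_flags: dict[ResidueKey, np.ndarray]

    def flag(self, key: ResidueKey, interaction: str) -> bool:
        return bool(self.residue_flags[key][INTERACTION_TYPES.index(interaction)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionProfile):
            return NotImplemented
        if set(self.residue_flags) != set(other.residue_flags):
            return False
        return all(
            np.array_equal(self.residue_flags[k], other.residue_flags[k])
            for k in self.residue_flags
        )


# ---------------------------------------------------------------------------
# feature extraction


def _best_fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Returns (centroid, unit normal, max out-of-plane deviation)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    deviation = float(np.abs(centered @ normal).max())
    return centroid, normal / np.linalg.norm(normal), deviation


def _ring_from_atoms(atoms, key: ResidueKey) -> AromaticRing | None:
    coords = np.array([a.coords for a in atoms])
    centroid, normal, deviation = _best_fit_plane(coords)
    if deviation > RING_PLANARITY_TOL:
        return None
    radius = float(np.linalg.norm(coords - centroid, axis=1).max())
    return AromaticRing([a.serial for a in atoms], centroid, normal, radius, key)


def find_aromatic_rings(mol: Structure) -> list[AromaticRing]:
    """Aromatic rings: residue templates for the standard aromatic amino
    acids, graph cycles of size 5-6 (with a planarity test) elsewhere."""
    rings: list[AromaticRing] = []
    template_atoms: set[int] = set()
    by_res = mol.residues()
    for key, atoms in by_res.items():
        templates = RESIDUE_RING_TEMPLATES.get(key.resname)
        if templates is None:
            continue
        names = {a.name: a for a in atoms}
        for template in templates:
            if all(n in names for n in template):
                ring = _ring_from_atoms([names[n] for n in template], key)
                if ring is not None:
                    rings.append(ring)
                template_atoms.update(names[n].serial for n in template)

    # graph-based perception for everything outside the templates
    heavy = [i for i in mol.heavy_indices()
             if mol.atoms[i].residue_key.resname not in RESIDUE_RING_TEMPLATES]
    if heavy:
        idx_map = {i: k for k, i in enumerate(heavy)}
        bonds = mol.get_bonds()
        g = nx.Graph()
        g.add_nodes_from(range(len(heavy)))
        for i, j in bonds:
            if i in idx_map and j in idx_map:
                g.add_edge(idx_map[i], idx_map[j])
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) not in (5, 6):
                continue
            members = [mol.atoms[heavy[c]] for c in cycle]
            ring = _ring_from_atoms(members, members[0].residue_key)
            if ring is not None:
                rings.append(ring)
    return rings


def _donors_acceptors(mol: Structure, cfg: GeometryConfig
                      ) -> tuple[list[tuple[int, int]], list[int]]:
    """Donor (heavy, hydrogen) index pairs and acceptor heavy-atom indices."""
    adj = adjacency(len(mol.atoms), mol.get_bonds())
    acceptor_elements = {"N", "O"} | ({"S"} if cfg.sulfur_acceptors else set())
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i, a in enumerate(mol.atoms):
        if a.element in ("N", "O"):
            for j in adj[i]:
                if mol.atoms[j].element == "H":
                    donors.append((i, j))
        if a.element in acceptor_elements:
            acceptors.append(i)
    return donors, acceptors


def _hydrophobic_carbons(mol: Structure) -> list[int]:
    adj = adjacency(len(mol.atoms), mol.get_bonds())
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        heavy_nb = {mol.atoms[j].element for j in adj[i] if mol.atoms[j].element != "H"}
        if heavy_nb <= {"C", "S"}:
            out.append(i)
    return out


def find_charged_centers(mol: Structure, role: str) -> list[ChargedCenter]:
    """Charged centers for salt-bridge and cation-pi detection.

    ``role`` is ``"receptor"`` (residue templates, termini, zinc) or
    ``"ligand"`` (substructure rules plus recorded formal charges).
    """
    centers: list[ChargedCenter] = []
    adj = adjacency(len(mol.atoms), mol.get_bonds())
    index_of = {a.serial: i for i, a in enumerate(mol.atoms)}

    def n_hydrogens(i: int) -> int:
        return sum(1 for j in adj[i] if mol.atoms[j].element == "H")

    if role == "receptor":
        for key, atoms in mol.residues().items():
            names = {a.name: a for a in atoms}
            tpl = RESIDUE_CHARGE_TEMPLATES.get(key.resname)
            if tpl is not None:
                sign, needed = tpl
                if all(n in names for n in needed):
                    group = [names[n] for n in needed]
                    centers.append(ChargedCenter(
                        sign, np.mean([a.coords for a in group], axis=0),
                        [a.serial for a in group], "residue-template", key))
            if key.resname == "HIS":
                ring_n = [names[n] for n in ("ND1", "NE2") if n in names]
                if len(ring_n) == 2 and all(
                        n_hydrogens(index_of[a.serial]) >= 1 for a in ring_n):
                    centers.append(ChargedCenter(
                        +1, np.mean([a.coords for a in ring_n], axis=0),
                        [a.serial for a in ring_n], "residue-template", key))
            if key.resname == "ZN" and len(atoms) == 1:
                centers.append(ChargedCenter(
                    +1, atoms[0].coords.copy(), [atoms[0].serial], "ion", key))
            # chain termini: free amine / carboxylate terminus
            if "N" in names and n_hydrogens(index_of[names["N"].serial]) >= 2:
                centers.append(ChargedCenter(
                    +1, names["N"].coords.copy(), [names["N"].serial],
                    "residue-template", key))
            if "OXT" in names and "O" in names:
                group = [names["O"], names["OXT"]]
                centers.append(ChargedCenter(
                    -1, np.mean([a.coords for a in group], axis=0),
                    [a.serial for a in group], "residue-template", key))
        return centers

    # ligand rules
    claimed: set[int] = set()
    for i, a in enumerate(mol.atoms):
        if a.element == "C":
            heavy_nb = [j for j in adj[i] if mol.atoms[j].element != "H"]
            term_o = [j for j in heavy_nb
                      if mol.atoms[j].element == "O"
                      and len([k for k in adj[j] if mol.atoms[k].element != "H"]) == 1]
            n_nb = [j for j in heavy_nb if mol.atoms[j].element == "N"]
            if len(term_o) == 2:  # carboxylate
                centers.append(ChargedCenter(
                    -1, np.mean([mol.atoms[j].coords for j in term_o], axis=0),
                    [mol.atoms[j].serial for j in term_o], "ligand-rule",
                    a.residue_key))
                claimed.update(term_o)
            elif len(n_nb) == 3:  # guanidinium-like
                group = [i] + n_nb
                centers.append(ChargedCenter(
                    +1, np.mean([mol.atoms[j].coords for j in group], axis=0),
                    [mol.atoms[j].serial for j in group], "ligand-rule",
                    a.residue_key))
                claimed.update(group)
        elif a.element in ("S", "P"):
            term_o = [j for j in adj[i]
                      if mol.atoms[j].element == "O"
                      and len([k for k in adj[j] if mol.atoms[k].element != "H"]) == 1]
            if len(term_o) >= 2:  # sulfonate / phosphate
                centers.append(ChargedCenter(
                    -1, np.mean([mol.atoms[j].coords for j in term_o], axis=0),
                    [mol.atoms[j].serial for j in term_o], "ligand-rule",
                    a.residue_key))
                claimed.update(term_o)
        elif a.element == "N" and len(adj[i]) == 4:  # sp3 ammonium
            centers.append(ChargedCenter(
                +1, a.coords.copy(), [a.serial], "ligand-rule", a.residue_key))
            claimed.add(i)
    for i, a in enumerate(mol.atoms):
        if a.formal_charge != 0 and i not in claimed:
            centers.append(ChargedCenter(
                +1 if a.formal_charge > 0 else -1, a.coords.copy(), [a.serial],
                "formal-charge", a.residue_key))
    return centers


# ---------------------------------------------------------------------------
# detection


@dataclass
class ReceptorFeatures:
    """Receptor-side features precomputed once per (receptor, site, config)."""

    residue_atoms: dict[ResidueKey, list[int]]
    donors: dict[ResidueKey, list[tuple[int, int]]]
    acceptors: dict[ResidueKey, list[int]]
    hydrophobic: dict[ResidueKey, list[int]]
    rings: dict[ResidueKey, list[AromaticRing]]
    cations: dict[ResidueKey, list[ChargedCenter]]
    anions: dict[ResidueKey, list[ChargedCenter]]


def prepare_receptor(receptor: Structure, site: BindingSite,
                     cfg: GeometryConfig) -> ReceptorFeatures:
    by_res = receptor.residues()
    for key in site.residues:
        if key not in by_res:
            raise MissingResidueError(f"site residue {key} not found in receptor")
    site_set = set(site.residues)
    residue_atoms = {
        key: [i for i, a in enumerate(receptor.atoms) if a.residue_key == key]
        for key in site.residues
    }
    donors_all, acceptors_all = _donors_acceptors(receptor, cfg)
    hydro_all = _hydrophobic_carbons(receptor)

    def by_key(indices: Iterable, keyfn) -> dict[ResidueKey, list]:
        out: dict[ResidueKey, list] = {k: [] for k in site.residues}
        for item in indices:
            k = keyfn(item)
            if k in out:
                out[k].append(item)
        return out

    feats = ReceptorFeatures(
        residue_atoms=residue_atoms,
        donors=by_key(donors_all, lambda p: receptor.atoms[p[0]].residue_key),
        acceptors=by_key(acceptors_all, lambda i: receptor.atoms[i].residue_key),
        hydrophobic=by_key(hydro_all, lambda i: receptor.atoms[i].residue_key),
        rings=by_key(find_aromatic_rings(receptor), lambda r: r.residue_key),
        cations={k: [] for k in site.residues},
        anions={k: [] for k in site.residues},
    )
    for c in find_charged_centers(receptor, "receptor"):
        if c.residue_key not in site_set:
            continue
        if c.source == "ion" and not cfg.zinc_cation:
            continue
        (feats.cations if c.sign > 0 else feats.anions)[c.residue_key].append(c)
    return feats


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes in [0, 90] degrees."""
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def _hbond_deviation(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation of the D-H...A angle from linearity (degrees)."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return 180.0 - float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _projection_overlap(r1: AromaticRing, r2: AromaticRing, padding: float) -> bool:
    """True when either ring centroid projects inside the other ring's
    perimeter extended by ``padding``."""
    for a, b in ((r1, r2), (r2, r1)):
        delta = b.centroid - a.centroid
        proj = delta - np.dot(delta, a.normal) * a.normal
        if np.linalg.norm(proj) <= a.radius + padding:
            return True
    return False


def detect_interactions(receptor: Structure, ligand_pose: Structure,
                        site: BindingSite, cfg: GeometryConfig | None = None,
                        features: ReceptorFeatures | None = None
                        ) -> InteractionProfile:
    """Seven-type interaction profile of one ligand pose against the binding
    site. ``features`` may carry receptor-side features precomputed with
    :func:`prepare_receptor` to amortise the cost over a pose ensemble."""
    cfg = cfg or GeometryConfig()
    feats = features or prepare_receptor(receptor, site, cfg)

    lig_donors, lig_acceptors = _donors_acceptors(ligand_pose, cfg)
    lig_hydro = _hydrophobic_carbons(ligand_pose)
    lig_rings = find_aromatic_rings(ligand_pose)
    lig_centers = find_charged_centers(ligand_pose, "ligand")
    lig_cations = [c for c in lig_centers if c.sign > 0]
    lig_anions = [c for c in lig_centers if c.sign < 0]
    lxyz = ligand_pose.coords
    rxyz = receptor.coords

    flags = {key: np.zeros(N_INTERACTIONS, dtype=bool) for key in site.residues}

    for key in site.residues:
        f = flags[key]
        # (1) ligand as H-bond acceptor vs residue donors
        for d_i, h_i in feats.donors[key]:
            for a_i in lig_acceptors:
                if np.linalg.norm(rxyz[d_i] - lxyz[a_i]) <= cfg.hbond_max_da_dist and \
                   _hbond_deviation(rxyz[d_i], rxyz[h_i], lxyz[a_i]) <= cfg.hbond_max_deviation:
                    f[0] = True
                    break
            if f[0]:
                break
        # (2) ligand as H-bond donor vs residue acceptors
        for d_i, h_i in lig_donors:
            for a_i in feats.acceptors[key]:
                if np.linalg.norm(lxyz[d_i] - rxyz[a_i]) <= cfg.hbond_max_da_dist and \
                   _hbond_deviation(lxyz[d_i], lxyz[h_i], rxyz[a_i]) <= cfg.hbond_max_deviation:
                    f[1] = True
                    break
            if f[1]:
                break
        # (3) hydrophobic carbon-carbon contact
        res_c = feats.hydrophobic[key]
        if res_c and lig_hydro:
            d = np.linalg.norm(
                rxyz[np.asarray(res_c)][:, None, :] - lxyz[np.asarray(lig_hydro)][None, :, :],
                axis=-1)
            if d.min() <= cfg.hydrophobic_max_cc_dist:
                f[2] = True
        # (4, 5) ring stacking
        for rring in feats.rings[key]:
            for lring in lig_rings:
                cd = float(np.linalg.norm(rring.centroid - lring.centroid))
                ang = _plane_angle(rring.normal, lring.normal)
                if (cd <= cfg.pipi_max_centroid_dist
                        and ang <= cfg.pipi_max_plane_angle
                        and _projection_overlap(rring, lring, cfg.pipi_projection_padding)):
                    f[3] = True
                if (cd <= cfg.tstack_max_centroid_dist
                        and abs(ang - 90.0) <= cfg.tstack_plane_angle_window):
                    f[4] = True
        # (6) cation-pi, both directions
        for rring in feats.rings[key]:
            for cat in lig_cations:
                if np.linalg.norm(rring.centroid - cat.center) <= cfg.catpi_max_dist:
                    f[5] = True
        for cat in feats.cations[key]:
            for lring in lig_rings:
                if np.linalg.norm(cat.center - lring.centroid) <= cfg.catpi_max_dist:
                    f[5] = True
        # (7) salt bridge
        for rc in feats.cations[key]:
            for lc in lig_anions:
                if np.linalg.norm(rc.center - lc.center) <= cfg.saltbridge_max_dist:
                    f[6] = True
        for rc in feats.anions[key]:
            for lc in lig_cations:
                if np.linalg.norm(rc.center - lc.center) <= cfg.saltbridge_max_dist:
                    f[6] = True

    return InteractionProfile(residue_flags=flags)


# ---------------------------------------------------------------------------
# reporting


def _key_str(key: ResidueKey) -> str:
    return f"{key.chain}/{key.resnum}{key.icode}/{key.resname}"


def _key_from_str(s: str) -> ResidueKey:
    chain, mid, resname = s.split("/")
    num = mid.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    icode = mid[len(num):]
    return ResidueKey(chain, int(num), icode, resname)


def interactions_report(profile: InteractionProfile) -> tuple[str, str]:
    """Render a profile as a text table and a stable-sorted JSON document.

    Columns follow the fixed flag order (acceptor, donor, hydrophobic, pi-pi,
    T-stack, cation-pi, salt bridge).
    """
    header = "residue\t" + "\t".join(INTERACTION_TYPES)
    rows = [header]
    payload = {}
    for key in sorted(profile.residue_flags, key=lambda r: (r.chain, r.resnum, r.icode)):
        bits = profile.residue_flags[key].astype(int)
        rows.append(_key_str(key) + "\t" + "\t".join(str(b) for b in bits))
        payload[_key_str(key)] = [int(b) for b in bits]
    text = "\n".join(rows)
    doc = json.dumps({"flag_order": list(INTERACTION_TYPES), "residues": payload},
                     sort_keys=True, indent=1)
    return text, doc


def profile_from_json(doc: str) -> InteractionProfile:
    data = json.loads(doc)
    flags = {
        _key_from_str(k): np.array(v, dtype=bool)
        for k, v in data["residues"].items()
    }
    return InteractionProfile(residue_flags=flags)
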