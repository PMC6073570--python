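"""Independent brute-force interaction detector used as a test oracle.

Deliberately naive: plain double/triple loops over all atom pairs, no spatial
indexing, no shared code with the package's detector beyond the structure
containers. Ring perception enumerates 5- and 6-atom subsets that form a
single cycle. Kept slow and obvious on purpose.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
         "S": 1.05, "Cl": 1.02, "Zn": 1.22, "Br": 1.20, "I": 1.39}

FLAGS = ("hbond_acceptor", "hbond_donor", "hydrophobic", "pi_pi", "t_stack",
         "cation_pi", "salt_bridge")


def _dist(a, b):
    return math.dist(tuple(a), tuple(b))


def _bonds(structure):
    atoms = structure.atoms
    out = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cut = 1.3 * (RADII.get(atoms[i].element, 0.76) + RADII.get(atoms[j].element, 0.76))
            if _dist(atoms[i].coords, atoms[j].coords) <= cut:
                out.add((i, j))
    return out


def _neighbors(structure, bonds):
    nb = {i: set() for i in range(len(structure.atoms))}
    for i, j in bonds:
        nb[i].add(j)
        nb[j].add(i)
    return nb


def _plane(coords):
    centroid = coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1] / np.linalg.norm(vt[-1])
    dev = max(abs(float((c - centroid) @ normal)) for c in coords)
    return centroid, normal, dev


def _rings(structure, bonds):
    """All planar 5/6-membered cycles among heavy atoms."""
    nb = _neighbors(structure, bonds)
    heavy = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    cyclic = [i for i in heavy if len(nb[i] & set(heavy)) >= 2]
    rings = []
    seen = set()
    for size in (5, 6):
        for combo in combinations(cyclic, size):
            sub = set(combo)
            degs = [len(nb[i] & sub) for i in combo]
            if any(d != 2 for d in degs):
                continue
            # connected single cycle?
            start = combo[0]
            visited = {start}
            frontier = [start]
            while frontier:
                cur = frontier.pop()
                for nxt in nb[cur] & sub:
                    if nxt not in visited:
                        visited.add(nxt)
                        frontier.append(nxt)
            if visited != sub or frozenset(sub) in seen:
                continue
            coords = np.array([structure.atoms[i].coords for i in combo])
            centroid, normal, dev = _plane(coords)
            if dev <= 0.35:
                seen.add(frozenset(sub))
                radius = max(_dist(c, centroid) for c in coords)
                rings.append((frozenset(sub), centroid, normal, radius))
    return rings


def _donors(structure, nb):
    out = []
    for i, a in enumerate(structure.atoms):
        if a.element in ("N", "O"):
            for j in nb[i]:
                if structure.atoms[j].element == "H":
                    out.append((i, j))
    return out


def _acceptors(structure):
    return [i for i, a in enumerate(structure.atoms) if a.element in ("N", "O")]


def _greasy_carbons(structure, nb):
    out = []
    for i, a in enumerate(structure.atoms):
        if a.element != "C":
            continue
        if all(structure.atoms[j].element in ("C", "H", "S") for j in nb[i]):
            out.append(i)
    return out


_RES_CHARGES = {"ARG": (+1, ("CZ", "NE", "NH1", "NH2")), "LYS": (+1, ("NZ",)),
                "ASP": (-1, ("OD1", "OD2")), "GLU": (-1, ("OE1", "OE2"))}


def _receptor_charges(structure, nb):
    centers = []
    by_res = {}
    for i, a in enumerate(structure.atoms):
        by_res.setdefault(a.residue_key, []).append(i)
    for key, idxs in by_res.items():
        names = {structure.atoms[i].name: i for i in idxs}
        if key.resname in _RES_CHARGES:
            sign, need = _RES_CHARGES[key.resname]
            if all(n in names for n in need):
                pts = np.array([structure.atoms[names[n]].coords for n in need])
                centers.append((key, sign, pts.mean(axis=0)))
        if key.resname == "HIS" and "ND1" in names and "NE2" in names:
            hs = [any(structure.atoms[j].element == "H" for j in nb[names[n]])
                  for n in ("ND1", "NE2")]
            if all(hs):
                pts = np.array([structure.atoms[names[n]].coords for n in ("ND1", "NE2")])
                centers.append((key, +1, pts.mean(axis=0)))
        if key.resname == "ZN" and len(idxs) == 1:
            centers.append((key, +1, structure.atoms[idxs[0]].coords))
        if "N" in names and sum(
                1 for j in nb[names["N"]] if structure.atoms[j].element == "H") >= 2:
            centers.append((key, +1, structure.atoms[names["N"]].coords))
        if "OXT" in names and "O" in names:
            pts = np.array([structure.atoms[names[n]].coords for n in ("O", "OXT")])
            centers.append((key, -1, pts.mean(axis=0)))
    return centers


def _ligand_charges(structure, nb):
    centers = []
    claimed = set()
    atoms = structure.atoms
    for i, a in enumerate(atoms):
        heavy_nb = [j for j in nb[i] if atoms[j].element != "H"]
        if a.element == "C":
            term_o = [j for j in heavy_nb if atoms[j].element == "O"
                      and len([k for k in nb[j] if atoms[k].element != "H"]) == 1]
            n_nb = [j for j in heavy_nb if atoms[j].element == "N"]
            if len(term_o) == 2:
                centers.append((-1, np.mean([atoms[j].coords for j in term_o], axis=0)))
                claimed.update(term_o)
            elif len(n_nb) == 3:
                grp = [i] + n_nb
                centers.append((+1, np.mean([atoms[j].coords for j in grp], axis=0)))
                claimed.update(grp)
        elif a.element in ("S", "P"):
            term_o = [j for j in nb[i] if atoms[j].element == "O"
                      and len([k for k in nb[j] if atoms[k].element != "H"]) == 1]
            if len(term_o) >= 2:
                centers.append((-1, np.mean([atoms[j].coords for j in term_o], axis=0)))
                claimed.update(term_o)
        elif a.element == "N" and len(nb[i]) == 4:
            centers.append((+1, a.coords))
            claimed.add(i)
    for i, a in enumerate(atoms):
        if a.formal_charge != 0 and i not in claimed:
            centers.append((+1 if a.formal_charge > 0 else -1, a.coords))
    return centers


def _deviation(d, h, a):
    v1 = np.asarray(d) - np.asarray(h)
    v2 = np.asarray(a) - np.asarray(h)
    cos = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def _plane_angle(n1, n2):
    cos = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, cos)))


def detect_profile(receptor, ligand, site, cfg):
    """Brute-force reference profile: dict residue_key -> 7 bools."""
    rb = _bonds(receptor)
    lb = _bonds(ligand)
    rnb = _neighbors(receptor, rb)
    lnb = _neighbors(ligand, lb)
    r_donors = _donors(receptor, rnb)
    r_acceptors = _acceptors(receptor)
    if cfg.sulfur_acceptors:
        r_acceptors += [i for i, a in enumerate(receptor.atoms) if a.element == "S"]
    r_greasy = _greasy_carbons(receptor, rnb)
    r_rings = _rings(receptor, rb)
    r_charges = _receptor_charges(receptor, rnb)
    if not cfg.zinc_cation:
        r_charges = [(k, s, c) for k, s, c in r_charges if k.resname != "ZN"]
    l_donors = _donors(ligand, lnb)
    l_acceptors = _acceptors(ligand)
    if cfg.sulfur_acceptors:
        l_acceptors += [i for i, a in enumerate(ligand.atoms) if a.element == "S"]
    l_greasy = _greasy_carbons(ligand, lnb)
    l_rings = _rings(ligand, lb)
    l_charges = _ligand_charges(ligand, lnb)

    ratoms = receptor.atoms
    latoms = ligand.atoms
    out = {}
    for key in site.residues:
        f = [False] * 7
        mine = lambda i: ratoms[i].residue_key == key
        for d, h in r_donors:
            if not mine(d):
                continue
            for a in l_acceptors:
                if _dist(ratoms[d].coords, latoms[a].coords) <= cfg.hbond_max_da_dist \
                        and _deviation(ratoms[d].coords, ratoms[h].coords,
                                       latoms[a].coords) <= cfg.hbond_max_deviation:
                    f[0] = True
        for d, h in l_donors:
            for a in r_acceptors:
                if not mine(a):
                    continue
                if _dist(latoms[d].coords, ratoms[a].coords) <= cfg.hbond_max_da_dist \
                        and _deviation(latoms[d].coords, latoms[h].coords,
                                       ratoms[a].coords) <= cfg.hbond_max_deviation:
                    f[1] = True
        for i in r_greasy:
            if not mine(i):
                continue
            for j in l_greasy:
                if _dist(ratoms[i].coords, latoms[j].coords) <= cfg.hydrophobic_max_cc_dist:
                    f[2] = True
        for members, c1, n1, rad1 in r_rings:
            if not all(mine(i) for i in members):
                continue
            for _, c2, n2, rad2 in l_rings:
                cd = _dist(c1, c2)
                ang = _plane_angle(n1, n2)
                if cd <= cfg.pipi_max_centroid_dist and ang <= cfg.pipi_max_plane_angle:
                    ok = False
                    for (ca, na, ra), (cb, _, _) in (((c1, n1, rad1), (c2, n2, rad2)),
                                                     ((c2, n2, rad2), (c1, n1, rad1))):
                        delta = np.asarray(cb) - np.asarray(ca)
                        proj = delta - float(delta @ na) * np.asarray(na)
                        if np.linalg.norm(proj) <= ra + cfg.pipi_projection_padding:
                            ok = True
                    if ok:
                        f[3] = True
                if cd <= cfg.tstack_max_centroid_dist and abs(ang - 90.0) <= cfg.tstack_plane_angle_window:
                    f[4] = True
            for sign, center in l_charges:
                if sign > 0 and _dist(c1, center) <= cfg.catpi_max_dist:
                    f[5] = True
        for k, sign, center in r_charges:
            if k != key:
                continue
            if sign > 0:
                for _, c2, _, _ in l_rings:
                    if _dist(center, c2) <= cfg.catpi_max_dist:
                        f[5] = True
            for lsign, lcenter in l_charges:
                if lsign == -sign and _dist(center, lcenter) <= cfg.saltbridge_max_dist:
                    f[6] = True
        out[key] = f
    return out
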