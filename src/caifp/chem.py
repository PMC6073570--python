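"""Light-weight chemistry helpers: covalent radii and distance-based bond
perception used whenever an input format carries no connectivity."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# Pyykko & Atsumi single-bond covalent radii (angstrom), the usual set for
# distance-based bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "P": 1.07, "S": 1.05, "Cl": 1.02, "K": 2.03,
    "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32,
    "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}

BOND_TOLERANCE = 1.3  # pair bonded when d <= tol * (r_a + r_b)


def perceive_bonds(elements: list[str], coords: np.ndarray) -> list[tuple[int, int]]:
    """Distance-based bond perception.

    Returns index pairs (i < j) whose separation is at most
    ``BOND_TOLERANCE * (r_i + r_j)``. Unknown elements default to the carbon
    radius.
    """
    if len(elements) == 0:
        return []
    radii = np.array([COVALENT_RADII.get(e, 0.76) for e in elements])
    coords = np.asarray(coords, dtype=float)
    rmax = BOND_TOLERANCE * 2.0 * radii.max()
    tree = cKDTree(coords)
    bonds: list[tuple[int, int]] = []
    for i, j in sorted(tree.query_pairs(rmax)):
        cutoff = BOND_TOLERANCE * (radii[i] + radii[j])
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
            bonds.append((i, j))
    return bonds


def adjacency(n_atoms: int, bonds: list[tuple[int, int]]) -> list[set[int]]:
    """Adjacency sets (by atom index) from a bond list."""
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj
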