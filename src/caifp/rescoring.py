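"""Pose-ensemble rescoring by Tanimoto similarity to the reference
fingerprint, plus the evaluation statistics: symmetry-aware heavy-atom RMSD,
aRMSD (mean selected-pose RMSD) and NLRD (fraction of ligands whose selected
pose lies strictly below an RMSD threshold, 2.0 angstrom by default)."""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import GeometryConfig
from .errors import InputError, UsageError
from .fingerprints import Fingerprint, ReferenceFingerprint, encode_fingerprint, tanimoto
from .interactions import detect_interactions, prepare_receptor
from .structures import BindingSite, PoseSet, Structure

log = logging.getLogger(__name__)

MAX_AUTOMORPHISMS = 10_000


@dataclass
class RescoreResult:
    ligand_id: str
    receptor_id: str
    scores: list[float]              # Tc-IFP per pose, in pose order
    best_pose_index: int
    ranking: list[int]               # pose indices, best first
    fingerprints: list[Fingerprint] = field(default_factory=list)
    engine_scores: list[float] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rank_of = {p: r + 1 for r, p in enumerate(self.ranking)}
        rows = {
            "pose_index": list(range(len(self.scores))),
            "tc_ifp": self.scores,
            "rank": [rank_of[i] for i in range(len(self.scores))],
        }
        if self.engine_scores is not None:
            rows["engine_score"] = self.engine_scores
        return pd.DataFrame(rows)


@dataclass
class EvalStats:
    rmsds: list[float]
    arms_d: float                    # aRMSD, angstrom
    nlrd_fraction: float             # in [0, 1]
    rmsd_threshold: float = 2.0

    @property
    def nlrd_percent(self) -> float:
        return 100.0 * self.nlrd_fraction


# ---------------------------------------------------------------------------
# RMSD


def _heavy_graph(structure: Structure) -> tuple[list[int], nx.Graph]:
    heavy = structure.heavy_indices()
    pos = {atom_idx: k for k, atom_idx in enumerate(heavy)}
    g = nx.Graph()
    for k, atom_idx in enumerate(heavy):
        g.add_node(k, element=structure.atoms[atom_idx].element)
    for i, j in structure.get_bonds():
        if i in pos and j in pos:
            g.add_edge(pos[i], pos[j])
    return heavy, g


def _automorphisms(g: nx.Graph, limit: int = MAX_AUTOMORPHISMS):
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    return list(itertools.islice(matcher.isomorphisms_iter(), limit + 1))


def ligand_rmsd(pose_a: Structure, pose_b: Structure,
                symmetry_aware: bool = True) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, compared in
    the shared receptor frame (no refitting).

    With ``symmetry_aware`` the minimum over element-labelled automorphisms of
    the heavy-atom bond graph is returned, so that e.g. a flipped benzene ring
    scores 0. Beyond 10^4 automorphisms the identity mapping is used with a
    warning.
    """
    heavy_a = pose_a.heavy_indices()
    heavy_b = pose_b.heavy_indices()
    ea = [pose_a.atoms[i].element for i in heavy_a]
    eb = [pose_b.atoms[i].element for i in heavy_b]
    if ea != eb:
        raise InputError("poses differ in heavy-atom composition or ordering")
    A = pose_a.coords[heavy_a]
    B = pose_b.coords[heavy_b]
    identity = float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
    if not symmetry_aware:
        return identity
    _, g = _heavy_graph(pose_a)
    autos = _automorphisms(g)
    if len(autos) > MAX_AUTOMORPHISMS:
        warnings.warn(
            f"more than {MAX_AUTOMORPHISMS} automorphisms; falling back to the "
            "identity atom mapping", stacklevel=2)
        return identity
    best = identity
    n = len(heavy_a)
    for mapping in autos:
        perm = np.array([mapping[k] for k in range(n)])
        rmsd = float(np.sqrt(np.mean(np.sum((A - B[perm]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def best_attainable(ps: PoseSet, native: Structure,
                    symmetry_aware: bool = True) -> tuple[float, int]:
    """Minimum RMSD to the native pose over the ensemble and its index —
    the ideal-scoring-function baseline."""
    rmsds = [ligand_rmsd(p, native, symmetry_aware=symmetry_aware) for p in ps.poses]
    idx = int(np.argmin(rmsds))
    return float(rmsds[idx]), idx


# ---------------------------------------------------------------------------
# rescoring


def rescore_pose_set(ps: PoseSet, receptor: Structure, site: BindingSite,
                     ref: ReferenceFingerprint, cfg: GeometryConfig | None = None
                     ) -> RescoreResult:
    """Score every pose by Tc-IFP against the reference and rank descending.

    Ties are broken toward the lower pose index (the docking engine's own
    ordering) and logged.
    """
    if not ps.poses:
        raise UsageError("empty pose set")
    cfg = cfg or GeometryConfig()
    feats = prepare_receptor(receptor, site, cfg)
    scores: list[float] = []
    fps: list[Fingerprint] = []
    for k, pose in enumerate(ps.poses):
        profile = detect_interactions(receptor, pose, site, cfg, features=feats)
        fp = encode_fingerprint(profile, site, label=f"{ps.ligand_id}:pose{k}")
        fps.append(fp)
        scores.append(tanimoto(fp, ref))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    best = order[0]
    ties = [i for i in order[1:] if scores[i] == scores[best]]
    if ties:
        log.info("Tc-IFP tie at %.4f between poses %s; keeping pose %d",
                 scores[best], [best] + ties, best)
    result = RescoreResult(
        ligand_id=ps.ligand_id, receptor_id=ps.receptor_id, scores=scores,
        best_pose_index=best, ranking=order, fingerprints=fps,
        engine_scores=ps.engine_scores)
    assert all(scores[best] >= s for s in scores)
    return result


def evaluate(selected_rmsds: Sequence[float], threshold: float = 2.0) -> EvalStats:
    """aRMSD (arithmetic mean) and NLRD (fraction strictly below threshold)."""
    if len(selected_rmsds) == 0:
        raise UsageError("evaluate requires at least one RMSD value")
    vals = np.asarray(selected_rmsds, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise UsageError("RMSD values must be finite")
    return EvalStats(
        rmsds=[float(v) for v in vals],
        arms_d=float(vals.mean()),
        nlrd_fraction=float(np.mean(vals < threshold)),
        rmsd_threshold=threshold,
    )


def cross_docking_plan(ligand_ids: Sequence[str], receptor_ids: Sequence[str]
                       ) -> pd.DataFrame:
    """Full cross-docking task table: one row per (ligand, receptor) pair."""
    if not ligand_ids or not receptor_ids:
        raise UsageError("ligand and receptor id lists must be non-empty")

    def dedupe(ids: Sequence[str], what: str) -> list[str]:
        seen: list[str] = []
        for i in ids:
            if i in seen:
                warnings.warn(f"duplicate {what} id {i!r} removed", stacklevel=3)
            else:
                seen.append(i)
        return seen

    ligands = dedupe(ligand_ids, "ligand")
    receptors = dedupe(receptor_ids, "receptor")
    rows = [(l, r) for l in ligands for r in receptors]
    return pd.DataFrame(rows, columns=["ligand_id", "receptor_id"])
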