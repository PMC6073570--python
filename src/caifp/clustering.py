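"""Complete-linkage clustering of ligands by fingerprint similarity.

Ligands are merged agglomeratively on the distance d = 1 - Tc with complete
linkage (cluster distance = maximum pairwise member distance), so every
emitted cluster is guaranteed a minimum within-cluster pairwise Tanimoto.
Merging requires strictly Tc > threshold for all cross pairs (a boundary pair
at exactly the threshold does not merge); ``inclusive=True`` switches to >=.
Equal minimum distances are broken toward the lexicographically smallest
member-label pair, which makes the output independent of input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InconsistencyError, UsageError
from .fingerprints import Fingerprint, tanimoto


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray     # symmetric, unit diagonal for non-empty fingerprints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise UsageError("similarity matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise UsageError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise UsageError("similarity values must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy())


@dataclass
class ClusterSet:
    clusters: list[list[str]]        # each sorted; partition of the labels
    threshold: float
    singletons: list[str]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def similarity_matrix(fps: Sequence[Fingerprint]) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix over a fingerprint collection."""
    if len(fps) < 2:
        raise UsageError("need at least two fingerprints")
    tags = {fp.site_tag for fp in fps}
    if len(tags) != 1:
        raise InconsistencyError(f"mixed site tags: {sorted(tags)}")
    n = len(fps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    labels = [fp.label or f"fp{i}" for i, fp in enumerate(fps)]
    return SimilarityMatrix(labels=labels, values=m)


def complete_linkage_cluster(sm: SimilarityMatrix, tc_threshold: float = 0.40,
                             inclusive: bool = False) -> ClusterSet:
    """Agglomerative complete-linkage clustering cut at the Tc threshold."""
    if not 0 < tc_threshold <= 1:
        raise UsageError("tc_threshold must be in (0, 1]")
    d = 1.0 - sm.values
    dmax = 1.0 - tc_threshold
    clusters: list[list[int]] = [[i] for i in range(len(sm.labels))]

    def link(a: list[int], b: list[int]) -> float:
        return max(d[i, j] for i in a for j in b)

    def labelkey(c: list[int]) -> tuple[str, ...]:
        return tuple(sorted(sm.labels[i] for i in c))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                la, lb = sorted([labelkey(clusters[x]), labelkey(clusters[y])])
                cand = (link(clusters[x], clusters[y]), la, lb, x, y)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dist, _, _, x, y = best
        mergeable = dist < dmax or (inclusive and dist <= dmax)
        if not mergeable:
            break
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]

    out = sorted((sorted(sm.labels[i] for i in c) for c in clusters),
                 key=lambda c: (-len(c), c))
    singletons = [c[0] for c in out if len(c) == 1]
    return ClusterSet(clusters=out, threshold=tc_threshold, singletons=singletons)


def cluster_report(cs: ClusterSet, fps: Sequence[Fingerprint] | None = None) -> dict:
    """Census of the clustering: sizes, members, singleton fraction and, when
    fingerprints are supplied, per-cluster consensus bits (bits shared by all
    members)."""
    by_label = {fp.label: fp for fp in (fps or [])}
    n_total = sum(len(c) for c in cs.clusters)
    report: dict = {
        "threshold": cs.threshold,
        "n_ligands": n_total,
        "n_clusters": sum(1 for c in cs.clusters if len(c) > 1),
        "n_singletons": len(cs.singletons),
        "singleton_fraction": len(cs.singletons) / n_total if n_total else 0.0,
        "clusters": [],
    }
    for cid, members in enumerate(cs.clusters, start=1):
        entry: dict = {"cluster_id": cid, "size": len(members), "members": members}
        if by_label and all(m in by_label for m in members):
            consensus = np.logical_and.reduce([by_label[m].bits for m in members])
            entry["consensus_bits"] = [int(i) for i in np.flatnonzero(consensus)]
        report["clusters"].append(entry)
    return report


def write_clusters(cs: ClusterSet, csv_path: str | Path,
                   json_path: str | Path | None = None,
                   fps: Sequence[Fingerprint] | None = None) -> None:
    rows = [(label, cid) for cid, members in enumerate(cs.clusters, start=1)
            for label in members]
    pd.DataFrame(rows, columns=["label", "cluster_id"]).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(cluster_report(cs, fps), indent=1))
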