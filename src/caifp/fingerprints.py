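"""Binary interaction fingerprints, the consensus reference, and Tanimoto
similarity.

A fingerprint has ``7 * n_residues`` bits; bit ``7*i + j`` encodes interaction
type ``j`` (fixed flag order) at binding-site residue ``i``. For the 44-residue
carbonic anhydrase II site this gives 308 bits. The consensus reference keeps
only bits supported by at least ``min_support`` training complexes (default 3)
— interactions shown by fewer ligands are treated as noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, InconsistencyError, UsageError
from .interactions import INTERACTION_TYPES, N_INTERACTIONS, InteractionProfile
from .structures import BindingSite

log = logging.getLogger(__name__)


@dataclass
class Fingerprint:
    bits: np.ndarray               # bool vector, length 7 * |site|
    site_tag: str
    label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass
class ReferenceFingerprint(Fingerprint):
    min_support: int = 3
    training_labels: list[str] = field(default_factory=list)
    support_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def encode_fingerprint(profile: InteractionProfile, site: BindingSite,
                       label: str = "") -> Fingerprint:
    """Lay the per-residue flags out as a fixed bit string.

    Residues in the site but absent from the profile contribute an all-zero
    7-bit block; a profile residue outside the site is an inconsistency.
    """
    site_set = set(site.residues)
    extra = set(profile.residue_flags) - site_set
    if extra:
        raise InconsistencyError(f"profile residues not in site: {sorted(extra)}")
    bits = np.zeros(N_INTERACTIONS * len(site), dtype=bool)
    for i, key in enumerate(site.residues):
        flags = profile.residue_flags.get(key)
        if flags is not None:
            bits[N_INTERACTIONS * i:N_INTERACTIONS * (i + 1)] = flags
    return Fingerprint(bits=bits, site_tag=site.site_tag, label=label)


def build_reference(fps: Sequence[Fingerprint], min_support: int = 3,
                    label: str = "reference") -> ReferenceFingerprint:
    """Consensus fingerprint: a bit is on iff at least ``min_support`` input
    fingerprints have it on."""
    if not fps:
        raise UsageError("build_reference requires at least one fingerprint")
    if min_support < 1:
        raise UsageError("min_support must be >= 1")
    tags = {fp.site_tag for fp in fps}
    if len(tags) != 1:
        raise InconsistencyError(f"mixed site tags: {sorted(tags)}")
    counts = np.sum([fp.bits for fp in fps], axis=0).astype(int)
    return ReferenceFingerprint(
        bits=counts >= min_support,
        site_tag=fps[0].site_tag,
        label=label,
        min_support=min_support,
        training_labels=[fp.label for fp in fps],
        support_counts=counts,
    )


def tanimoto(a: Fingerprint, b: Fingerprint, denominator: str = "union") -> float:
    """Tanimoto coefficient of two binary fingerprints.

    ``denominator="union"`` is the standard |A&B| / (|A| + |B| - |A&B|);
    ``"sum"`` divides by |A| + |B| instead (a literal reading of the score's
    prose definition, kept for comparison — it caps identity at 0.5).
    Two all-zero fingerprints score 0.0 by convention.
    """
    if len(a) != len(b):
        raise InconsistencyError(f"fingerprint lengths differ: {len(a)} vs {len(b)}")
    if a.site_tag != b.site_tag:
        raise InconsistencyError(f"site tags differ: {a.site_tag} vs {b.site_tag}")
    na, nb = a.n_on, b.n_on
    if na + nb == 0:
        log.debug("tanimoto of two empty fingerprints (%s, %s) -> 0.0", a.label, b.label)
        return 0.0
    common = int(np.sum(a.bits & b.bits))
    if denominator == "sum":
        return common / (na + nb)
    if denominator != "union":
        raise UsageError(f"unknown denominator rule {denominator!r}")
    return common / (na + nb - common)


# ---------------------------------------------------------------------------
# I/O: TSV of label <TAB> bitstring, site checksum in a header comment


def _check_bits(bitstring: str, site: BindingSite) -> np.ndarray:
    if set(bitstring) - {"0", "1"}:
        raise FormatError(f"bit string contains non-binary characters: {bitstring[:20]}...")
    expected = N_INTERACTIONS * len(site)
    if len(bitstring) != expected:
        raise FormatError(
            f"bit string length {len(bitstring)} != {expected} (7 x {len(site)} residues)")
    return np.array([c == "1" for c in bitstring])


def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    if not fps:
        raise UsageError("nothing to write")
    lines = [f"# site_tag={fps[0].site_tag}"]
    for fp in fps:
        lines.append(f"{fp.label}\t{fp.to_string()}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fingerprints(path: str | Path, site: BindingSite) -> list[Fingerprint]:
    tag = None
    fps: list[Fingerprint] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            if k == "site_tag":
                tag = v
            continue
        if not line.strip():
            continue
        label, _, bitstring = line.partition("\t")
        fps.append(Fingerprint(bits=_check_bits(bitstring, site),
                               site_tag=site.site_tag, label=label))
    if tag is not None and tag != site.site_tag:
        raise InconsistencyError(
            f"fingerprint file site tag {tag} does not match site {site.site_tag}")
    return fps


def write_reference(ref: ReferenceFingerprint, path: str | Path) -> None:
    lines = [
        f"# site_tag={ref.site_tag}",
        f"# min_support={ref.min_support}",
        f"{ref.label}\t{ref.to_string()}",
        "#counts\t" + ",".join(str(c) for c in ref.support_counts),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(path: str | Path, site: BindingSite) -> ReferenceFingerprint:
    tag, min_support, label, bits, counts = None, 3, "reference", None, None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#counts\t"):
            counts = np.array([int(c) for c in line.split("\t", 1)[1].split(",")])
        elif line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            if k == "site_tag":
                tag = v
            elif k == "min_support":
                min_support = int(v)
        elif line.strip():
            label, _, bitstring = line.partition("\t")
            bits = _check_bits(bitstring, site)
    if bits is None:
        raise FormatError(f"{path}: no reference fingerprint line found")
    if tag is not None and tag != site.site_tag:
        raise InconsistencyError(
            f"reference site tag {tag} does not match site {site.site_tag}")
    if counts is None:
        counts = bits.astype(int) * min_support
    return ReferenceFingerprint(
        bits=bits, site_tag=site.site_tag, label=label,
        min_support=min_support, support_counts=counts)
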