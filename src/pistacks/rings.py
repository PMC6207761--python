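"""Aromatic ring centroids and face-normal vectors.

The constructive definitions used throughout the package:

* Phe/Tyr ring centre: arithmetic mean of the six ring atoms CG, CD1, CD2,
  CE1, CE2, CZ.
* Trp ring centre: midpoint of CD2 and CE2 (a single fused-ring proxy; the
  five- and six-membered rings are not treated separately).
* Face normal: normalized cross product of the centre->CG and centre->CD1
  vectors for Phe/Tyr, and of centre->CD1 and centre->CD2 for Trp. The sign
  of the normal is arbitrary; every consumer must be sign-invariant.

Histidine is excluded by default — the definitions above cover only
Phe/Tyr/Trp. Planarity is never enforced: the definitions are purely
constructive and apply to distorted rings as written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pistacks.structure import Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "AromaticRing", "RING_ATOMS", "AROMATIC_RESIDUES",
    "MissingRingAtomsError", "DegenerateRingError",
    "ring_centroid", "face_normal", "centroid_distance",
    "extract_rings", "ring_report",
]

#: atoms whose mean defines the ring centre, per residue type
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2"),
}

#: atoms whose centre->atom vectors are crossed to give the face normal
_NORMAL_ATOMS: dict[str, tuple[str, str]] = {
    "PHE": ("CG", "CD1"),
    "TYR": ("CG", "CD1"),
    "TRP": ("CD1", "CD2"),
}

AROMATIC_RESIDUES = frozenset(RING_ATOMS)

#: cross products below this magnitude (A^2) are treated as degenerate
DEGENERACY_TOL = 1e-6


class MissingRingAtomsError(ValueError):
    """A ring-defining atom is absent from the residue."""


class DegenerateRingError(ValueError):
    """The two centre-to-atom vectors are (near-)collinear."""


@dataclass(frozen=True)
class AromaticRing:
    """One aromatic ring: identity, centroid (A) and unit face normal.

    The normal's sign is reported as computed and carries no meaning.
    """

    chain_id: str
    residue_seq: int
    residue_name: str
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]
    source_atoms: tuple[str, ...]

    def __post_init__(self):
        n = np.asarray(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError("centroid must be finite")

    @property
    def centroid_array(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)

    @property
    def normal_array(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}:{self.residue_seq}"


def _ring_coords(residue: Residue) -> dict[str, np.ndarray]:
    name = residue.name.upper()
    if name not in RING_ATOMS:
        raise MissingRingAtomsError(
            f"{residue.chain_id}:{residue.name}:{residue.seq} is not Phe/Tyr/Trp")
    needed = set(RING_ATOMS[name]) | set(_NORMAL_ATOMS[name])
    coords = {}
    for atom_name in needed:
        atom = residue.atom(atom_name)
        if atom is None:
            raise MissingRingAtomsError(
                f"{residue.chain_id}:{residue.name}:{residue.seq} "
                f"lacks ring atom {atom_name}")
        coords[atom_name] = atom.coords
    return coords


def ring_centroid(residue: Residue) -> np.ndarray:
    """Ring centre of a Phe/Tyr/Trp residue, in Angstrom.

    Phe/Tyr: mean of the six ring atoms; Trp: midpoint of CD2 and CE2.
    Raises :class:`MissingRingAtomsError` if a defining atom is absent.
    """
    coords = _ring_coords(residue)
    ring = RING_ATOMS[residue.name.upper()]
    return np.mean([coords[a] for a in ring], axis=0)


def face_normal(residue: Residue) -> np.ndarray:
    """Unit face normal of an aromatic ring (sign arbitrary).

    Cross product of centre->CG and centre->CD1 (Phe/Tyr) or centre->CD1
    and centre->CD2 (Trp), normalized. Raises :class:`DegenerateRingError`
    when the cross product magnitude falls below 1e-6 A^2.
    """
    coords = _ring_coords(residue)
    centre = ring_centroid(residue)
    a1, a2 = _NORMAL_ATOMS[residue.name.upper()]
    cross = np.cross(coords[a1] - centre, coords[a2] - centre)
    norm = np.linalg.norm(cross)
    if norm < DEGENERACY_TOL:
        raise DegenerateRingError(
            f"{residue.chain_id}:{residue.name}:{residue.seq}: "
            f"cross product magnitude {norm:.2e} A^2 below {DEGENERACY_TOL:g}")
    return cross / norm


def centroid_distance(a: AromaticRing, b: AromaticRing) -> float:
    """Euclidean centroid-centroid distance in Angstrom (symmetric)."""
    return float(np.linalg.norm(a.centroid_array - b.centroid_array))


def make_ring(residue: Residue) -> AromaticRing:
    """Build an :class:`AromaticRing` from a residue (may raise)."""
    centroid = ring_centroid(residue)
    normal = face_normal(residue)
    return AromaticRing(
        chain_id=residue.chain_id,
        residue_seq=residue.seq,
        residue_name=residue.name.upper(),
        centroid=tuple(float(x) for x in centroid),
        normal=tuple(float(x) for x in normal),
        source_atoms=RING_ATOMS[residue.name.upper()],
    )


def extract_rings(model: StructureModel) -> list[AromaticRing]:
    """All well-formed aromatic rings in a model.

    Residues with missing ring atoms or degenerate geometry are skipped
    with a logged warning, never a hard error: deposited structures
    routinely truncate side chains.
    """
    rings = []
    for residue in model.iter_residues():
        if residue.name.upper() not in AROMATIC_RESIDUES:
            continue
        try:
            rings.append(make_ring(residue))
        except (MissingRingAtomsError, DegenerateRingError) as exc:
            logger.warning("skipping ring: %s", exc)
    return rings


def ring_report(rings: list[AromaticRing], path: str | Path | None = None) -> pd.DataFrame:
    """Debug table of ring geometry; optionally written as TSV."""
    df = pd.DataFrame([
        {
            "chain": r.chain_id,
            "residue_name": r.residue_name,
            "residue_seq": r.residue_seq,
            "cx": r.centroid[0], "cy": r.centroid[1], "cz": r.centroid[2],
            "nx": r.normal[0], "ny": r.normal[1], "nz": r.normal[2],
        }
        for r in rings
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return df
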