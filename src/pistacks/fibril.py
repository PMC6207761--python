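"""Helical fibril geometry: building multi-layer fibrils and the closed
forms for crossover distance, handedness and mass-per-length.

Conventions
-----------
The fibril axis is the z-axis through the origin; the caller aligns the
subunit to this frame (a least-squares axis fit helper is provided).
Layer k is the subunit rotated by k*twist about +z (right-hand rule) and
translated by k*rise along +z. Under this convention a NEGATIVE twist
produces a LEFT-handed helix — matching the refined beta-2-microglobulin
fibril parameters (rise 4.83 A, twist -0.608 degrees per layer, C2).

With C2 symmetry a second protofilament is added as the 180-degree rotation
of every layer about the axis, so each layer holds two subunits.

The crossover distance — the axial spacing of the apparent narrow points of
a twisted fibril, half the true helical pitch — is rise * 180 / |twist|.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np

from pistacks.structure import AtomSite, Chain, Residue, StructureModel

__all__ = [
    "HelicalParams", "build_fibril", "crossover_distance", "pitch",
    "mass_per_length", "handedness", "two_start_screw_equivalent",
    "fit_axis", "measure_layer_transform",
]


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry parameters of a fibril.

    rise : A per layer (> 0).
    twist : degrees per layer, signed; negative = left-handed here.
    symmetry : "C1" or "C2" (C2 adds a second protofilament).
    """

    rise: float
    twist: float
    symmetry: str = "C1"

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if abs(self.twist) > 180:
            raise ValueError("twist must lie in [-180, 180] degrees")
        if self.symmetry not in ("C1", "C2"):
            raise ValueError("symmetry must be C1 or C2")

    @property
    def subunits_per_layer(self) -> int:
        return 2 if self.symmetry == "C2" else 1


def _rot_z(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# chain-ID pool for remapped subunit copies (PDB one-character field)
_CHAIN_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


def build_fibril(
    subunit: StructureModel, params: HelicalParams, n_layers: int
) -> StructureModel:
    """Stack ``n_layers`` copies of an axis-aligned subunit into a fibril.

    Layer k is rotated by k*twist about z and translated by k*rise along z;
    with C2 symmetry every layer gains a second, 180-degree-rotated copy
    (x, y, z) -> (-x, -y, z). Chain IDs are remapped uniquely per subunit
    copy, and the copy layout (layer, protofilament, chains) is recorded in
    the result's ``meta["copies"]``.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    n_copies = n_layers * params.subunits_per_layer * len(subunit.chains)
    if n_copies > len(_CHAIN_POOL):
        raise ValueError(
            f"{n_copies} chain copies exceed the {len(_CHAIN_POOL)} "
            "single-character PDB chain IDs")

    out = StructureModel(identifier=f"{subunit.identifier}_fibril")
    pool = iter(_CHAIN_POOL)
    copies = []
    for k in range(n_layers):
        for proto in range(params.subunits_per_layer):
            rot = _rot_z(k * params.twist + proto * 180.0)
            shift = np.array([0.0, 0.0, k * params.rise])
            chain_ids = []
            for chain in subunit.chains:
                new_id = next(pool)
                chain_ids.append(new_id)
                new_chain = Chain(chain_id=new_id)
                for res in chain.residues:
                    new_res = Residue(chain_id=new_id, seq=res.seq, name=res.name)
                    for a in res.atoms:
                        new_res.atoms.append(AtomSite(
                            atom_name=a.atom_name,
                            residue_name=a.residue_name,
                            residue_seq=a.residue_seq,
                            chain_id=new_id,
                            coords=rot @ a.coords + shift,
                            occupancy=a.occupancy,
                            altloc=a.altloc,
                            element=a.element,
                        ))
                    new_chain.residues.append(new_res)
                out.chains.append(new_chain)
            copies.append({"layer": k, "protofilament": proto, "chains": chain_ids})
    out.meta["copies"] = copies
    out.meta["params"] = params
    return out


def crossover_distance(params: HelicalParams) -> float:
    """Crossover distance in Angstrom: rise * 180 / |twist|.

    The crossover distance is the axial spacing between the narrow points
    visible along a twisted fibril and equals half the true helical pitch.
    Undefined for an untwisted fibril.
    """
    if params.twist == 0:
        raise ValueError("crossover distance undefined for an untwisted fibril")
    return params.rise * 180.0 / abs(params.twist)


def pitch(params: HelicalParams) -> float:
    """Full helical pitch in Angstrom (twice the crossover distance)."""
    return 2.0 * crossover_distance(params)


def mass_per_length(
    subunit_mass: float, subunits_per_layer: int, rise: float
) -> float:
    """Fibril mass per unit length in kDa/nm.

    subunits_per_layer * subunit_mass / rise, with the rise converted from
    Angstrom to nm. For the two-protofilament beta-2-microglobulin fibril
    (11.731 kDa monomer, 2 per layer, rise 4.83 A) this gives ~48.6 kDa/nm.
    """
    if subunit_mass <= 0 or subunits_per_layer <= 0 or rise <= 0:
        raise ValueError("all arguments must be positive")
    return subunits_per_layer * subunit_mass / (rise / 10.0)


def handedness(params: HelicalParams) -> str:
    """"left" or "right"; negative twist is left-handed here."""
    if params.twist == 0:
        raise ValueError("handedness undefined for an untwisted fibril")
    return "left" if params.twist < 0 else "right"


def two_start_screw_equivalent(params: HelicalParams) -> HelicalParams:
    """The 2_1-screw hypothesis matching a C2 fibril's layer spacing.

    A pseudo-2_1 helix relates successive subunits by half the C2 rise and
    half the twist plus 180 degrees, with no in-layer symmetry. Building
    both and comparing coordinates is how the two symmetry hypotheses are
    distinguished.
    """
    twist = params.twist / 2.0 + 180.0
    if twist > 180.0:
        twist -= 360.0
    return HelicalParams(rise=params.rise / 2.0, twist=twist, symmetry="C1")


def fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helical-axis estimate (centroid, unit direction).

    Plumbing helper: the principal component of the point cloud, for
    pre-aligning a subunit stack to the z-axis convention. Not a
    refinement of helical parameters.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if direction[2] < 0:
        direction = -direction
    return centroid, direction


def measure_layer_transform(
    fibril: StructureModel, atom_name: str | None = None
) -> tuple[float, float]:
    """Measure (rise_A, signed_twist_deg) between layers 0 and 1 of a
    built fibril, from coordinates alone.

    Uses the first atom (or the named atom) of the first chain of each of
    the two layers' protofilament-0 copies; the signed azimuthal rotation
    is taken from the xy-projections with the right-hand rule about +z.
    """
    copies = fibril.meta.get("copies")
    if not copies:
        raise ValueError("model lacks copy metadata; build it with build_fibril")

    def first_atom(copy_info):
        chain = fibril.chain(copy_info["chains"][0])
        for res in chain.residues:
            for a in res.atoms:
                if atom_name is None or a.atom_name == atom_name:
                    return a.coords
        raise ValueError(f"atom {atom_name!r} not found in layer copy")

    layer0 = next(c for c in copies if c["layer"] == 0 and c["protofilament"] == 0)
    layer1 = next(c for c in copies if c["layer"] == 1 and c["protofilament"] == 0)
    p0, p1 = first_atom(layer0), first_atom(layer1)
    rise = float(p1[2] - p0[2])
    a, b = p0[:2], p1[:2]
    twist = math.degrees(math.atan2(a[0] * b[1] - a[1] * b[0], float(a @ b)))
    return rise, twist
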