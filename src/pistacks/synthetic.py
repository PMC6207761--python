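"""Synthetic structures and contact tables with known ground truth.

Fixtures emulate the geometry that motivates the detector: parallel
in-register aromatic ladders stacked along a fibril axis at ~4.8 A spacing,
optionally a second C2-related chain across a ~7.6 A protofilament
interface, tilt on the ring normals, and seeded Gaussian coordinate jitter.
Residues are written as standard PHE/TYR so the production reader and ring
extractor are exercised, never bypassed.

Ground truths (expected pair set and stack sizes) are computed analytically
from the recipe BEFORE jitter, by direct arithmetic on the constructed
centres and normals — not by running the detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pistacks.contacts import Contact
from pistacks.structure import AtomSite, Chain, Residue, StructureModel

__all__ = [
    "FibrilRecipe", "StackGroundTruth",
    "make_ring_residue", "make_fibril_fixture", "make_contact_table",
    "contacts_from_structure",
]

#: aromatic C-C bond length, A; for a regular hexagon this equals the
#: circumradius, so ring atoms sit 1.39 A from the centre.
CC_BOND = 1.39

# hexagon vertex order chosen so that centre->CG x centre->CD1 = +normal
_RING_ORDER = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``normal``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def make_ring_residue(
    center,
    normal,
    residue_name: str = "TYR",
    chain_id: str = "A",
    residue_seq: int = 1,
) -> Residue:
    """An idealized six-membered aromatic ring as a PHE or TYR residue.

    The six ring atoms (CG, CD1, CD2, CE1, CE2, CZ) form a regular hexagon
    of C-C bond length 1.39 A in the plane perpendicular to ``normal``,
    centred at ``center``. By construction the ring-geometry definitions
    recover (center, +/-normal) exactly.
    """
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
        raise ValueError("normal must be a unit vector")
    if residue_name not in ("PHE", "TYR"):
        raise ValueError("ring fixtures are written as PHE or TYR")
    u, v = _orthonormal_frame(normal)
    res = Residue(chain_id=chain_id, seq=residue_seq, name=residue_name)
    for k, atom_name in enumerate(_RING_ORDER):
        # counter-clockwise about +normal puts CD1 at +60 deg from CG
        theta = math.radians(60.0 * k)
        pos = center + CC_BOND * (math.cos(theta) * u + math.sin(theta) * v)
        res.atoms.append(AtomSite(
            atom_name=atom_name,
            residue_name=residue_name,
            residue_seq=residue_seq,
            chain_id=chain_id,
            coords=pos,
            element="C",
        ))
    return res


@dataclass(frozen=True)
class FibrilRecipe:
    """Recipe for a synthetic ring-ladder fibril fixture.

    n_layers rings per chain stacked at ``rise`` A with ``twist`` degrees
    per layer; with two chains the second is the C2 copy and the ring
    centroids sit ``interface_gap`` A apart across the axis in layer 0.
    ``ring_tilt`` tips every ring normal away from the axis; ``jitter_sd``
    adds seeded Gaussian noise to every atom coordinate.
    """

    n_layers: int
    rise: float = 4.8
    twist: float = 0.0
    n_chains: int = 1
    interface_gap: float = 7.6
    ring_tilt: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0
    residue_name: str = "TYR"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.rise <= 0 or self.interface_gap <= 0:
            raise ValueError("rise and interface_gap must be positive")
        if self.n_chains not in (1, 2):
            raise ValueError("n_chains must be 1 or 2")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


@dataclass
class StackGroundTruth:
    """Analytic expectation for a recipe at jitter_sd = 0.

    rings : (chain_id, residue_seq) of every constructed ring.
    pairs : unordered (ring, ring) keys accepted by the 6 A / 20 deg rule.
    stacks : per connected component, dict with size/chains/interchain.
    """

    rings: list[tuple[str, int]] = field(default_factory=list)
    pairs: set[frozenset] = field(default_factory=set)
    stacks: list[dict] = field(default_factory=list)


def _rot_z(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _recipe_geometry(recipe: FibrilRecipe):
    """(chain_id, seq, centre, normal) for every ring, before jitter."""
    base_center = np.array([recipe.interface_gap / 2.0, 0.0, 0.0])
    base_normal = _rot_x(recipe.ring_tilt) @ np.array([0.0, 0.0, 1.0])
    out = []
    for chain_idx in range(recipe.n_chains):
        chain_id = "AB"[chain_idx]
        c2 = _rot_z(180.0 * chain_idx)
        for k in range(recipe.n_layers):
            rot = _rot_z(k * recipe.twist)
            centre = c2 @ rot @ base_center + np.array([0.0, 0.0, k * recipe.rise])
            normal = c2 @ rot @ base_normal
            out.append((chain_id, k + 1, centre, normal))
    return out


def _ground_truth(geometry, distance_threshold=6.0, angle_threshold=20.0):
    """Threshold rule + union-find on the analytic geometry."""
    truth = StackGroundTruth(rings=[(c, s) for c, s, _, _ in geometry])
    n = len(geometry)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        ci, si, pi, ni = geometry[i]
        for j in range(i + 1, n):
            cj, sj, pj, nj = geometry[j]
            dist = math.dist(pi, pj)
            cos = min(1.0, abs(float(ni @ nj)))
            angle = math.degrees(math.acos(cos))
            if dist < distance_threshold and angle <= angle_threshold:
                truth.pairs.add(frozenset(((ci, si), (cj, sj))))
                parent[find(i)] = find(j)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    for members in components.values():
        if len(members) < 2:
            continue
        chains = {geometry[i][0] for i in members}
        truth.stacks.append({
            "size": len(members),
            "chains": chains,
            "interchain": len(chains) >= 2,
        })
    truth.stacks.sort(key=lambda s: (-s["size"], sorted(s["chains"])))
    return truth


def make_fibril_fixture(
    recipe: FibrilRecipe,
) -> tuple[StructureModel, StackGroundTruth]:
    """Build a ring-ladder fixture and its analytic detection ground truth.

    With ``jitter_sd = 0`` the detector's output on the returned model must
    match the ground truth exactly; under jitter, differences can occur
    only for pairs within ~3 sigma of a threshold boundary.
    """
    geometry = _recipe_geometry(recipe)
    truth = _ground_truth(geometry)
    model = StructureModel(identifier=f"synth_fibril_seed{recipe.seed}")
    chains: dict[str, Chain] = {}
    for chain_id, seq, centre, normal in geometry:
        chain = chains.setdefault(chain_id, Chain(chain_id=chain_id))
        chain.residues.append(make_ring_residue(
            centre, normal, residue_name=recipe.residue_name,
            chain_id=chain_id, residue_seq=seq,
        ))
    model.chains = [chains[c] for c in sorted(chains)]
    if recipe.jitter_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        for atom in model.iter_atoms():
            atom.coords = atom.coords + rng.normal(0.0, recipe.jitter_sd, 3)
    return model, truth


# separation ranges per contact class, inclusive, for a chain of n residues
def _class_sep_range(cls: str, n_residues: int) -> tuple[int, int]:
    return {
        "intra": (0, 0),
        "sequential": (1, 1),
        "medium": (2, 4),
        "long": (5, n_residues - 1),
    }[cls]


def make_contact_table(
    class_counts: tuple[int, int, int, int],
    seed: int,
    n_residues: int = 100,
) -> list[Contact]:
    """A contact list realizing exact per-class counts.

    ``class_counts`` is (intra, sequential, medium, long) over residues
    0..n_residues-1. Pairs are drawn with a seeded generator; duplicate
    residue pairs are allowed (records stand for distinct cross-peaks).
    Raises if a class count is negative or its separation range does not
    fit in ``n_residues`` residues.
    """
    if len(class_counts) != 4:
        raise ValueError("class_counts must be (intra, sequential, medium, long)")
    rng = np.random.default_rng(seed)
    contacts: list[Contact] = []
    for cls, count in zip(("intra", "sequential", "medium", "long"), class_counts):
        if count < 0:
            raise ValueError(f"negative count for class {cls!r}")
        if count == 0:
            continue
        lo, hi = _class_sep_range(cls, n_residues)
        if hi < lo or lo > n_residues - 1:
            raise ValueError(
                f"class {cls!r} infeasible with {n_residues} residues")
        for _ in range(count):
            sep = int(rng.integers(lo, hi + 1))
            i = int(rng.integers(0, n_residues - sep))
            contacts.append(Contact(residue_i=i, residue_j=i + sep))
    return contacts


def contacts_from_structure(
    model: StructureModel,
    cutoff: float,
    params=None,
) -> list[Contact]:
    """Contacts synthesized from a fibril model's own distances.

    Every residue pair of the reference subunit whose evaluated distance
    (minimum over intra and adjacent-layer arrangements) is within
    ``cutoff`` becomes a contact — so by construction every returned
    contact is satisfied at any cutoff >= the generating one.
    """
    from pistacks.contacts import check_model_against_contacts

    seqs = sorted({r.seq for r in model.iter_residues()})
    candidates = [
        Contact(residue_i=i, residue_j=j)
        for a, i in enumerate(seqs) for j in seqs[a:]
    ]
    report = check_model_against_contacts(model, candidates, cutoff, params)
    kept = report[report["satisfied"]]
    return [Contact(residue_i=int(r.i), residue_j=int(r.j))
            for r in kept.itertuples(index=False)]
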