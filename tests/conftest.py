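"""Shared fixtures: hand-built residues and raw PDB text helpers.

The PDB-line formatter here is deliberately independent of the package's
writer so that parser tests exercise real fixed-column text, not a
round-trip through the same library.
"""

from __future__ import annotations

import numpy as np
import pytest

from pistacks.structure import AtomSite, Chain, Residue, StructureModel


def format_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.00,
    altloc: str = " ",
    element: str = "C",
) -> str:
    """One fixed-column PDB v3.3 ATOM record."""
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2s}"
    )


def hexagon_residue(
    center=(0.0, 0.0, 0.0),
    radius: float = 1.39,
    resname: str = "PHE",
    chain: str = "A",
    seq: int = 1,
    plane: str = "xy",
) -> Residue:
    """A regular hexagonal ring built from explicit trigonometry.

    Vertex order follows the ring bond path CG-CD1-CE1-CZ-CE2-CD2 so the
    face normal is well defined; ``plane`` picks the pair of axes the ring
    lies in.
    """
    axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    center = np.asarray(center, dtype=float)
    res = Residue(chain_id=chain, seq=seq, name=resname)
    for k, atom in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
        theta = np.radians(60.0 * k)
        pos = center.copy()
        pos[axes[0]] += radius * np.cos(theta)
        pos[axes[1]] += radius * np.sin(theta)
        res.atoms.append(AtomSite(
            atom_name=atom, residue_name=resname, residue_seq=seq,
            chain_id=chain, coords=pos, element="C",
        ))
    return res


def single_residue_model(residue: Residue, identifier: str = "fixture") -> StructureModel:
    return StructureModel(
        identifier=identifier,
        chains=[Chain(chain_id=residue.chain_id, residues=[residue])],
    )


@pytest.fixture
def phe_model() -> StructureModel:
    return single_residue_model(hexagon_residue())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
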