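"""Read/write macromolecular structures behind a small uniform model.

Parsing is delegated to gemmi (PDB v3.3 fixed-column and mmCIF). Only the
first model of multi-model files is exposed; alternate locations are
collapsed to the highest-occupancy conformer (ties broken by altloc
identifier). Hydrogens are kept in the model but every downstream consumer
selects atoms by name or filters them out, so their presence never changes a
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSite", "Residue", "Chain", "StructureModel",
    "StructureParseError", "EmptyStructureError",
    "read_structure", "write_structure",
]


class StructureParseError(ValueError):
    """The file could not be parsed under the named standard."""


class EmptyStructureError(ValueError):
    """The file parsed but contains no atoms."""


@dataclass
class AtomSite:
    """One atom site, PDB v3 atom naming, coordinates in Angstrom."""

    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""
    model_number: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"coords must be a finite 3-vector, got {self.coords!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() in ("H", "D")
        return self.atom_name.lstrip("0123456789").startswith(("H", "D"))


@dataclass
class Residue:
    chain_id: str
    seq: int
    name: str
    atoms: list[AtomSite] = field(default_factory=list)

    def atom(self, name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """One model's worth of chains/residues/atoms.

    ``meta`` carries optional provenance (e.g. the copy layout written by
    :func:`pistacks.fibril.build_fibril`); it is never required for IO.
    """

    identifier: str
    chains: list[Chain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one site per atom name: highest occupancy, tie -> first altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for atoms in by_name.values():
        if len(atoms) == 1:
            kept.append(atoms[0])
        else:
            kept.append(min(atoms, key=lambda a: (-a.occ, a.altloc or "~")))
    return kept


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Multi-model files contribute model 1 only; altloc-duplicated atoms are
    collapsed to the highest-occupancy conformer. Hydrogens are retained.

    Parameters
    ----------
    path : path to the structure file.
    format : ``"pdb"``, ``"mmcif"`` or ``"auto"`` (extension/content sniffing).

    Raises
    ------
    StructureParseError
        If the file cannot be parsed; the underlying parser message names
        the offending line or CIF category.
    EmptyStructureError
        If the file parses but holds zero atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models in file")

    gmodel = st[0]  # first model only
    model = StructureModel(identifier=st.name or path.stem)
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(chain_id=gchain.name, seq=gres.seqid.num, name=gres.name)
            for atom in _collapse_altlocs(gres):
                res.atoms.append(AtomSite(
                    atom_name=atom.name,
                    residue_name=gres.name,
                    residue_seq=gres.seqid.num,
                    chain_id=gchain.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc or "",
                    element=atom.element.name,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if model.n_atoms == 0:
        raise EmptyStructureError(f"{path.name}: zero atoms after parsing")
    return model


# PDB resSeq is a fixed 4-column field
_PDB_SEQ_MIN, _PDB_SEQ_MAX = -999, 9999


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        if len(chain.chain_id) != 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} does not fit the 1-character PDB field")
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            if not _PDB_SEQ_MIN <= res.seq <= _PDB_SEQ_MAX:
                raise ValueError(
                    f"residue_seq {res.seq} outside the PDB 4-column field "
                    f"[{_PDB_SEQ_MIN}, {_PDB_SEQ_MAX}]")
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq, " ")
            for a in res.atoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = a.occupancy
                atom.altloc = a.altloc[:1] if a.altloc else "\0"
                if a.element:
                    atom.element = gemmi.Element(a.element)
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as a standard-conformant PDB file.

    Round-trips through :func:`read_structure` preserve the atom count
    exactly and coordinates to the PDB precision of 1e-3 Angstrom.
    """
    if model.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty model")
    st = _to_gemmi(model)
    st.write_pdb(str(Path(path)))
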