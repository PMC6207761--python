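"""MAS-NMR distance-constraint classification and model checking.

Constraints are residue-pair records classified by sequence separation
|i - j|: 0 intra-residue, 1 sequential, 2-4 medium-range, >=5 long-range.
The published class boundaries leave |i - j| = 5 unhoused ("2-4" vs ">5");
it is assigned to long-range so the four classes partition all separations.

Checking a constraint table against a fibril model must respect the
intra-/inter-molecular ambiguity of cross-peaks in a parallel in-register
fibril: a contact is evaluated as the MINIMUM over the intra-subunit
residue-pair distance and the same pair measured between a reference
subunit and the subunit copies in the axially adjacent layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pistacks.fibril import HelicalParams
from pistacks.structure import Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "Contact", "ContactTally", "CONTACT_CLASSES",
    "classify_contact", "tally_contacts",
    "read_contact_table", "write_contact_table",
    "check_model_against_contacts",
]

CONTACT_CLASSES = ("intra", "sequential", "medium", "long")

#: default satisfaction cutoff, A — a typical upper bound for the
#: 13C-13C mixing experiments these constraints come from; configurable,
#: never silently applied elsewhere.
DEFAULT_CUTOFF = 8.0


def classify_contact(i: int, j: int) -> str:
    """Sequence-separation class of a residue pair.

    |i-j| = 0 -> intra, 1 -> sequential, 2-4 -> medium, >=5 -> long.
    """
    sep = abs(i - j)
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


@dataclass(frozen=True)
class Contact:
    """A residue-pair distance constraint (optionally atom-specific)."""

    residue_i: int
    residue_j: int
    atom_i: str | None = None
    atom_j: str | None = None

    @property
    def separation(self) -> int:
        return abs(self.residue_i - self.residue_j)

    @property
    def contact_class(self) -> str:
        return classify_contact(self.residue_i, self.residue_j)


@dataclass(frozen=True)
class ContactTally:
    intra: int
    sequential: int
    medium: int
    long: int

    @property
    def total(self) -> int:
        return self.intra + self.sequential + self.medium + self.long

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CONTACT_CLASSES} | {"total": self.total}


def tally_contacts(contacts: list[Contact]) -> ContactTally:
    """Count contacts per sequence-separation class.

    Records are counted as given — duplicate residue pairs (e.g. distinct
    atom pairs of the same residues) each count once.
    """
    counts = dict.fromkeys(CONTACT_CLASSES, 0)
    for c in contacts:
        counts[c.contact_class] += 1
    return ContactTally(**counts)


def read_contact_table(path: str | Path) -> list[Contact]:
    """Read a headered TSV of contacts (columns i, j; optional atom_i, atom_j)."""
    df = pd.read_csv(path, sep="\t", dtype={"i": int, "j": int})
    missing = {"i", "j"} - set(df.columns)
    if missing:
        raise ValueError(f"contact table lacks required column(s): {sorted(missing)}")
    contacts = []
    for row in df.itertuples(index=False):
        atom_i = getattr(row, "atom_i", None)
        atom_j = getattr(row, "atom_j", None)
        contacts.append(Contact(
            residue_i=int(row.i),
            residue_j=int(row.j),
            atom_i=None if pd.isna(atom_i) or atom_i == "" else str(atom_i),
            atom_j=None if pd.isna(atom_j) or atom_j == "" else str(atom_j),
        ))
    return contacts


def write_contact_table(contacts: list[Contact], path: str | Path) -> None:
    df = pd.DataFrame([
        {"i": c.residue_i, "j": c.residue_j,
         "atom_i": c.atom_i or "", "atom_j": c.atom_j or ""}
        for c in contacts
    ], columns=["i", "j", "atom_i", "atom_j"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model checking


def _copy_groups(model: StructureModel, params: HelicalParams) -> list[dict]:
    """Copy layout of a fibril: from build metadata, else inferred by the
    per-chain mean z offset against the rise."""
    if "copies" in model.meta:
        return model.meta["copies"]
    groups = []
    # chains whose mean z differs by ~k*rise belong to layer k
    z0 = min(
        float(np.mean([a.coords[2] for r in c.residues for a in r.atoms]))
        for c in model.chains
    )
    for c in model.chains:
        zc = float(np.mean([a.coords[2] for r in c.residues for a in r.atoms]))
        layer = int(round((zc - z0) / params.rise))
        groups.append({"layer": layer, "protofilament": 0, "chains": [c.chain_id]})
    return groups


def _residue_map(model: StructureModel, chain_ids: list[str]) -> dict[int, Residue]:
    """seq -> residue over a subunit copy's chains (first occurrence wins)."""
    out: dict[int, Residue] = {}
    for cid in chain_ids:
        chain = model.chain(cid)
        if chain is None:
            continue
        for res in chain.residues:
            out.setdefault(res.seq, res)
    return out


def _pair_distance(res_a: Residue, res_b: Residue,
                   atom_a: str | None, atom_b: str | None) -> float | None:
    """Min heavy-atom distance, or the named atom pair distance if both
    names are given. None when the required atoms are absent."""
    if atom_a and atom_b:
        a, b = res_a.atom(atom_a), res_b.atom(atom_b)
        if a is None or b is None:
            return None
        return float(np.linalg.norm(a.coords - b.coords))
    ha = res_a.heavy_atoms()
    hb = res_b.heavy_atoms()
    if not ha or not hb:
        return None
    xa = np.array([a.coords for a in ha])
    xb = np.array([b.coords for b in hb])
    return float(np.min(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)))


def check_model_against_contacts(
    model: StructureModel,
    contacts: list[Contact],
    cutoff: float = DEFAULT_CUTOFF,
    params: HelicalParams | None = None,
) -> pd.DataFrame:
    """Per-contact satisfaction report of a fibril model.

    The model must contain at least three stacked layers built with
    ``params`` (so a middle subunit has axial neighbours on both sides).
    For each contact the evaluated distance is the minimum over the
    intra-subunit arrangement and the inter-layer arrangements against the
    adjacent layers; a contact is satisfied when that distance is at or
    below ``cutoff``. Contacts whose residues are missing from the ordered
    core are flagged unmappable rather than raising.

    Returns a DataFrame with columns i, j, contact_class, distance_A,
    arrangement (intra/inter-layer/unmappable), satisfied.
    """
    if params is None:
        params = model.meta.get("params")
    if params is None:
        raise ValueError("helical params required (pass params= or build the "
                         "model with build_fibril)")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    groups = _copy_groups(model, params)
    layers = sorted({g["layer"] for g in groups})
    if len(layers) < 3:
        raise ValueError("model must contain at least three stacked layers")
    mid = layers[len(layers) // 2]
    ref = next(g for g in groups if g["layer"] == mid)
    ref_map = _residue_map(model, ref["chains"])
    neighbour_maps = [
        _residue_map(model, g["chains"])
        for g in groups if abs(g["layer"] - mid) == 1
    ]

    rows = []
    for c in contacts:
        res_i = ref_map.get(c.residue_i)
        res_j = ref_map.get(c.residue_j)
        if res_i is None or res_j is None:
            rows.append((c.residue_i, c.residue_j, c.contact_class,
                         np.nan, "unmappable", False))
            continue
        best = _pair_distance(res_i, res_j, c.atom_i, c.atom_j)
        arrangement = "intra"
        for nmap in neighbour_maps:
            other_j = nmap.get(c.residue_j)
            if other_j is not None:
                d = _pair_distance(res_i, other_j, c.atom_i, c.atom_j)
                if d is not None and (best is None or d < best):
                    best, arrangement = d, "inter-layer"
            other_i = nmap.get(c.residue_i)
            if other_i is not None:
                d = _pair_distance(other_i, res_j, c.atom_i, c.atom_j)
                if d is not None and (best is None or d < best):
                    best, arrangement = d, "inter-layer"
        if best is None:
            rows.append((c.residue_i, c.residue_j, c.contact_class,
                         np.nan, "unmappable", False))
        else:
            rows.append((c.residue_i, c.residue_j, c.contact_class,
                         best, arrangement, best <= cutoff))
    return pd.DataFrame(
        rows,
        columns=["i", "j", "contact_class", "distance_A", "arrangement",
                 "satisfied"],
    )
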