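"""In-memory coordinate model plus mmCIF/PDB readers and writers (via gemmi).

``StructureModel`` is a flat atom table: (entity/chain id, residue index,
residue code, atom name, element, xyz, confidence).  The confidence column is
the B-factor-equivalent field, which AlphaFold 3 uses for pLDDT; it is passed
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

from .errors import StructureError

#: Single-bond covalent radii (Angstrom) used for distance-based bond inference.
COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
                   "S": 1.05, "P": 1.07, "F": 0.57, "CA": 1.76, "MN": 1.39}

#: Slack added to the sum of covalent radii when inferring bonds.
BOND_TOLERANCE = 0.4


@dataclass
class Atom:
    entity: str
    residue_index: int
    residue_code: str
    name: str
    element: str
    pos: np.ndarray
    confidence: Optional[float] = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class StructureModel:
    """Atom list with helpers; (entity, residue_index, atom name) is unique."""

    atoms: list = field(default_factory=list)
    name: str = "model"

    def add_atom(self, entity, residue_index, residue_code, name, element,
                 pos, confidence=None):
        self.atoms.append(Atom(entity, int(residue_index), residue_code, name,
                               element, np.asarray(pos, dtype=float), confidence))

    # -- lookups -------------------------------------------------------

    def residues(self):
        """Ordered unique (entity, residue_index, residue_code) triples."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.entity, a.residue_index)
            if key not in seen:
                seen.add(key)
                out.append((a.entity, a.residue_index, a.residue_code))
        return out

    def residue_atoms(self, entity, residue_index, heavy_only=True):
        return [a for a in self.atoms
                if a.entity == entity and a.residue_index == residue_index
                and not (heavy_only and a.is_hydrogen)]

    def find_atom(self, entity, residue_index, name) -> Optional[Atom]:
        for a in self.atoms:
            if a.entity == entity and a.residue_index == residue_index and a.name == name:
                return a
        return None

    def coords(self, atoms=None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.vstack([a.pos for a in atoms])

    def transformed(self, rotation, translation) -> "StructureModel":
        out = StructureModel(name=self.name)
        rotation = np.asarray(rotation)
        translation = np.asarray(translation)
        for a in self.atoms:
            out.add_atom(a.entity, a.residue_index, a.residue_code, a.name,
                         a.element, rotation @ a.pos + translation, a.confidence)
        return out

    # -- bond inference ------------------------------------------------

    def infer_bonds(self, heavy_only=True) -> list:
        """Distance-based heavy-atom bonds: d < r_cov(a) + r_cov(b) + 0.4 A.

        Returns a symmetric-free list of index pairs (i < j) into ``self.atoms``.
        """
        idx = [i for i, a in enumerate(self.atoms)
               if not (heavy_only and a.is_hydrogen)]
        if not idx:
            return []
        pos = np.vstack([self.atoms[i].pos for i in idx])
        radii = np.array([COVALENT_RADIUS.get(self.atoms[i].element.upper(), 0.77)
                          for i in idx])
        bonds = []
        for k in range(len(idx)):
            d = np.linalg.norm(pos[k + 1:] - pos[k], axis=1)
            cut = radii[k] + radii[k + 1:] + BOND_TOLERANCE
            for off in np.nonzero(d < cut)[0]:
                bonds.append((idx[k], idx[k + 1 + off]))
        return bonds

    def neighbor_map(self, bonds=None) -> dict:
        """atom index -> sorted list of bonded atom indices."""
        if bonds is None:
            bonds = self.infer_bonds()
        nbr: dict[int, list] = {}
        for i, j in bonds:
            nbr.setdefault(i, []).append(j)
            nbr.setdefault(j, []).append(i)
        return {k: sorted(v) for k, v in nbr.items()}

    # -- confidence ----------------------------------------------------

    def extract_confidence(self, entity=None, residue_indices=None):
        """Per-atom confidence values for a selection plus (mean, min) summary.

        Returns ``(values, summary)``; empty selection or an absent
        confidence column yields ``([], None)``.
        """
        values = []
        for a in self.atoms:
            if entity is not None and a.entity != entity:
                continue
            if residue_indices is not None and a.residue_index not in residue_indices:
                continue
            if a.confidence is not None:
                values.append(a.confidence)
        if not values:
            return [], None
        arr = np.asarray(values, dtype=float)
        return values, {"mean": float(arr.mean()), "min": float(arr.min()),
                        "n": len(values)}


# ---------------------------------------------------------------------------
# gemmi-backed serialization
# ---------------------------------------------------------------------------

def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        if a.entity not in chains:
            chains[a.entity] = gemmi.Chain(a.entity)
        key = (a.entity, a.residue_index)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.residue_code
            res.seqid = gemmi.SeqId(a.residue_index, " ")
            res.het_flag = "H"
            chains[a.entity].add_residue(res)
            residues[key] = chains[a.entity][-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = 1.0
        at.b_iso = float(a.confidence) if a.confidence is not None else 0.0
        residues[key].add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def _from_gemmi(st: gemmi.Structure, confidence_present=True) -> StructureModel:
    model = StructureModel(name=st.name or "model")
    if len(st) == 0:
        raise StructureError("structure contains no models")
    for chain in st[0]:
        for res in chain:
            for at in res:
                conf = float(at.b_iso) if confidence_present else None
                model.add_atom(chain.name, res.seqid.num, res.name, at.name,
                               at.element.name.upper(), [at.pos.x, at.pos.y, at.pos.z],
                               conf)
    return model


def read_structure(text: str, fmt: str = "mmcif") -> StructureModel:
    """Parse an mmCIF or PDB document into a :class:`StructureModel`.

    ``fmt`` is ``"mmcif"`` or ``"pdb"``.  The B-factor column is read as the
    confidence value (pLDDT for AlphaFold 3 outputs).
    """
    fmt = fmt.lower()
    try:
        if fmt in ("mmcif", "cif"):
            block = gemmi.cif.read_string(text)[0]
            st = gemmi.make_structure_from_block(block)
        elif fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureError(f"could not parse {fmt} input: {exc}") from exc
    return _from_gemmi(st)


def read_structure_file(path: str) -> StructureModel:
    """Read a structure file, dispatching on extension (.cif/.mmcif vs .pdb)."""
    text = open(path).read()
    fmt = "pdb" if str(path).lower().endswith(".pdb") else "mmcif"
    return read_structure(text, fmt)


def write_structure(model: StructureModel, fmt: str = "mmcif") -> str:
    """Serialize to mmCIF or PDB text."""
    st = _to_gemmi(model)
    fmt = fmt.lower()
    if fmt in ("mmcif", "cif"):
        return st.make_mmcif_document().as_string()
    if fmt == "pdb":
        return st.make_pdb_string()
    raise StructureError(f"unknown format {fmt!r}")
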