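"""Chemical components (mmCIF ``chem_comp`` dialect) and leaving-atom edits.

AlphaFold 3 removes an aldose donor's O1 automatically during glycosidic bond
formation (guided by ``pdbx_leaving_atom_flag``), but it does not remove the
O2 of ketose donors such as sialic acid, nor the leaving oxygens of
modification blocks (sulfate, phosphate, ...).  Jobs using those donors need
an edited component — the original entry minus the leaving oxygen and its
hydroxyl hydrogen — supplied through the ``userCCD`` field under a new code.

Components can be loaded from real PDBeChem ``chem_comp`` files or generated
synthetically from the registry's ideal reference builds; the two are
drop-in compatible, which keeps the test suite download-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import ComponentError
from .registry import (MODIFICATIONS, definition_for_code, lookup_definition,
                       registry_codes)


@dataclass(frozen=True)
class ComponentAtom:
    name: str
    element: str
    x: float
    y: float
    z: float
    leaving: bool = False


@dataclass(frozen=True)
class ComponentBond:
    atom1: str
    atom2: str
    order: str = "SING"


@dataclass
class CCDComponent:
    code: str
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)

    def atom_names(self):
        return [a.name for a in self.atoms]

    def heavy_atom_count(self):
        return sum(1 for a in self.atoms if a.element != "H")

    def has_atom(self, name):
        return any(a.name == name for a in self.atoms)

    def neighbors(self, name):
        out = []
        for b in self.bonds:
            if b.atom1 == name:
                out.append(b.atom2)
            elif b.atom2 == name:
                out.append(b.atom1)
        return out

    def ring_atoms(self) -> set:
        """Atoms lying on any cycle (DFS back-edge fundamental cycles)."""
        adj = {a.name: set() for a in self.atoms}
        for b in self.bonds:
            adj[b.atom1].add(b.atom2)
            adj[b.atom2].add(b.atom1)
        in_ring: set = set()
        parent: dict = {}
        depth: dict = {}
        for start in adj:
            if start in depth:
                continue
            stack = [(start, None)]
            while stack:
                node, par = stack.pop()
                if node in depth:
                    continue
                depth[node] = depth.get(par, -1) + 1
                parent[node] = par
                for nxt in adj[node]:
                    if nxt == par:
                        continue
                    if nxt in depth:  # back edge: walk up to close the cycle
                        lo, hi = (node, nxt) if depth[node] > depth[nxt] else (nxt, node)
                        cyc = [lo]
                        while lo != hi and parent[lo] is not None:
                            lo = parent[lo]
                            cyc.append(lo)
                        in_ring.update(cyc)
                    else:
                        stack.append((nxt, node))
        return in_ring

    def __eq__(self, other):
        return (isinstance(other, CCDComponent) and self.code == other.code
                and self.atoms == other.atoms and sorted(
                    (b.atom1, b.atom2, b.order) for b in self.bonds) == sorted(
                    (b.atom1, b.atom2, b.order) for b in other.bonds))


# ---------------------------------------------------------------------------
# mmCIF chem_comp IO
# ---------------------------------------------------------------------------

_ATOM_TAGS = ["comp_id", "atom_id", "type_symbol", "charge",
              "pdbx_leaving_atom_flag", "pdbx_model_Cartn_x_ideal",
              "pdbx_model_Cartn_y_ideal", "pdbx_model_Cartn_z_ideal"]
_BOND_TAGS = ["comp_id", "atom_id_1", "atom_id_2", "value_order"]


def load_component_cif(text: str) -> CCDComponent:
    """Parse a ``chem_comp`` mmCIF block (``_chem_comp_atom`` + ``_chem_comp_bond``)."""
    try:
        doc = gemmi.cif.read_string(text)
        block = doc[0]
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ComponentError(f"could not parse chem_comp mmCIF: {exc}") from exc
    code = block.find_value("_chem_comp.id") or block.name
    atoms = []
    names = set()
    atom_loop = block.find("_chem_comp_atom.",
                           ["atom_id", "type_symbol", "pdbx_leaving_atom_flag"])
    coords = block.find("_chem_comp_atom.",
                        ["pdbx_model_Cartn_x_ideal", "pdbx_model_Cartn_y_ideal",
                         "pdbx_model_Cartn_z_ideal"])
    if len(atom_loop) == 0:
        # tolerate the PDBeChem variant with model (non-ideal) coordinates
        coords = block.find("_chem_comp_atom.",
                            ["model_Cartn_x", "model_Cartn_y", "model_Cartn_z"])
        atom_loop = block.find("_chem_comp_atom.",
                               ["atom_id", "type_symbol", "pdbx_leaving_atom_flag"])
    if len(atom_loop) == 0 or len(coords) != len(atom_loop):
        raise ComponentError("missing or inconsistent _chem_comp_atom loop")
    for row, crow in zip(atom_loop, coords):
        name = gemmi.cif.as_string(row[0])
        if name in names:
            raise ComponentError(f"duplicate atom name {name}")
        names.add(name)
        atoms.append(ComponentAtom(
            name, gemmi.cif.as_string(row[1]).upper(),
            float(crow[0]), float(crow[1]), float(crow[2]),
            gemmi.cif.as_string(row[2]).upper() == "Y"))
    bonds = []
    bond_loop = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"])
    for row in bond_loop:
        a1 = gemmi.cif.as_string(row[0])
        a2 = gemmi.cif.as_string(row[1])
        if a1 not in names or a2 not in names:
            raise ComponentError(f"bond references unknown atom {a1}-{a2}")
        bonds.append(ComponentBond(a1, a2, gemmi.cif.as_string(row[2]).upper()))
    return CCDComponent(str(code), atoms, bonds)


def write_component_cif(component: CCDComponent) -> str:
    """Serialize to the ``chem_comp`` dialect accepted by the userCCD field.

    Field order is fixed so output is byte-stable; ``load(write(c)) == c``.
    """
    lines = [f"data_{component.code}",
             "#",
             f"_chem_comp.id {component.code}",
             "_chem_comp.pdbx_type HETAIN",
             "#"]
    if component.atoms:
        lines.append("loop_")
        lines += [f"_chem_comp_atom.{t}" for t in _ATOM_TAGS]
        for a in component.atoms:
            lines.append(f"{component.code} {a.name} {a.element} 0 "
                         f"{'Y' if a.leaving else 'N'} "
                         f"{a.x:.3f} {a.y:.3f} {a.z:.3f}")
        lines.append("#")
    if component.bonds:
        lines.append("loop_")
        lines += [f"_chem_comp_bond.{t}" for t in _BOND_TAGS]
        for b in component.bonds:
            lines.append(f"{component.code} {b.atom1} {b.atom2} {b.order}")
        lines.append("#")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# leaving-atom remediation
# ---------------------------------------------------------------------------

def next_edited_code(base_code: str, taken=None) -> str:
    """Deterministic collision-free code for an edited component: base + 'X',
    then 'X2', 'X3', ... (checked against the whole registry)."""
    taken = set(taken or ()) | registry_codes()
    cand = base_code + "X"
    k = 2
    while cand in taken:
        cand = f"{base_code}X{k}"
        k += 1
    return cand


def strip_leaving_atoms(component: CCDComponent, atom_names,
                        taken_codes=None) -> CCDComponent:
    """Remove the named atoms (plus hydrogens bonded only to them) and all
    their bonds; returns a new component under a deterministic new code.

    Stripping with an empty set returns an identical component under the same
    code.  Removing a ring atom is refused.
    """
    atom_names = list(atom_names)
    if not atom_names:
        return CCDComponent(component.code, list(component.atoms), list(component.bonds))
    have = set(component.atom_names())
    missing = [n for n in atom_names if n not in have]
    if missing:
        raise ComponentError(f"cannot strip missing atoms: {missing}")
    rings = component.ring_atoms()
    bad = [n for n in atom_names if n in rings]
    if bad:
        raise ComponentError(f"refusing to strip ring atoms: {bad}")
    doomed = set(atom_names)
    for a in component.atoms:
        if a.element == "H":
            nbrs = component.neighbors(a.name)
            if nbrs and all(n in doomed for n in nbrs):
                doomed.add(a.name)
    new_code = next_edited_code(component.code, taken_codes)
    atoms = [a for a in component.atoms if a.name not in doomed]
    bonds = [b for b in component.bonds
             if b.atom1 not in doomed and b.atom2 not in doomed]
    return CCDComponent(new_code, atoms, bonds)


def plan_modification_bond(residue, position: int, mod_name: str):
    """Bond plan for decorating ``residue`` at ``position`` with ``mod_name``.

    Returns ``(bond_spec, edits)`` where ``bond_spec`` is
    ``(sugar_atom, mod_code, mod_atom)`` — the sugar's bridging oxygen is
    retained and pairs with the modification's bonding atom — and ``edits``
    lists the leaving atoms to strip from the modification component.
    """
    definition = lookup_definition(residue.sugar_name)
    if definition is None:
        raise ComponentError(f"unknown sugar {residue.sugar_name!r}")
    if position not in definition.substitutable_positions:
        raise ComponentError(
            f"{residue.sugar_name} position {position} cannot carry a modification")
    for pos, existing in residue.modifications:
        if pos == position and existing != mod_name:
            raise ComponentError(f"position {position} already carries {existing}")
    mod = MODIFICATIONS.get(mod_name)
    if mod is None:
        raise ComponentError(f"unknown modification {mod_name!r}")
    bond_spec = (definition.position_atom(position), mod.ccd_code, mod.bond_atom_on_mod)
    return bond_spec, {"strip": list(mod.leaving_atoms_on_mod), "code": mod.ccd_code}


# ---------------------------------------------------------------------------
# synthetic component generation
# ---------------------------------------------------------------------------

def _round3(p):
    return float(round(p[0], 3)), float(round(p[1], 3)), float(round(p[2], 3))


def _mod_component(code: str) -> CCDComponent:
    if code == "SO4":
        center, cel = "S", "S"
    elif code == "PO4":
        center, cel = "P", "P"
    elif code == "ACY":
        atoms = [ComponentAtom("C", "C", 0.0, 0.0, 0.0),
                 ComponentAtom("O", "O", 0.59, 1.06, 0.0),
                 ComponentAtom("OXT", "O", 0.59, -1.2, 0.0, leaving=True),
                 ComponentAtom("CH3", "C", -1.5, 0.0, 0.0)]
        bonds = [ComponentBond("C", "O", "DOUB"), ComponentBond("C", "OXT"),
                 ComponentBond("C", "CH3")]
        return CCDComponent("ACY", atoms, bonds)
    elif code == "MOH":
        return CCDComponent("MOH",
                            [ComponentAtom("C", "C", 0.0, 0.0, 0.0),
                             ComponentAtom("O", "O", 1.41, 0.0, 0.0, leaving=True)],
                            [ComponentBond("C", "O")])
    else:
        raise ComponentError(f"no synthetic build for component {code!r}")
    # tetrahedral XO4
    d = 1.50
    t = d / math.sqrt(3.0)
    verts = [(t, t, t), (t, -t, -t), (-t, t, -t), (-t, -t, t)]
    atoms = [ComponentAtom(center, cel, 0.0, 0.0, 0.0)]
    bonds = []
    for i, (x, y, z) in enumerate(verts):
        name = f"O{i + 1}"
        atoms.append(ComponentAtom(name, "O", round(x, 3), round(y, 3), round(z, 3),
                                   leaving=(i == 0)))
        bonds.append(ComponentBond(center, name))
    return CCDComponent(code, atoms, bonds)


def build_component(code: str) -> CCDComponent:
    """Synthetic ``chem_comp`` entry for a registry CCD code.

    Sugars are built from their ideal reference-chair coordinates with
    hydroxyl hydrogens; the leaving oxygen (O1 aldoses / O2 ketoses) and its
    hydrogen carry the leaving flag.  Modification blocks (SO4, PO4, ACY,
    MOH) get idealized small-molecule geometry.  Coordinates are rounded to
    3 decimals so that write/load round-trips are exact.
    """
    if code in ("SO4", "PO4", "ACY", "MOH"):
        return _mod_component(code)
    hit = definition_for_code(code)
    if hit is None:
        raise ComponentError(f"code {code!r} is not in the registry")
    definition, config, _ring, anomer = hit
    from .synthetic import build_residue

    build = build_residue(definition, anomer, config=config, with_hydrogens=True)
    leaving = {definition.leaving_atom, "H" + definition.leaving_atom}
    atoms = []
    for name, pos in build.atoms.items():
        x, y, z = _round3(pos)
        atoms.append(ComponentAtom(name, build.elements[name], x, y, z,
                                   leaving=name in leaving))
    bonds = [ComponentBond(a, b) for a, b in build.bonds]
    return CCDComponent(code, atoms, bonds)
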