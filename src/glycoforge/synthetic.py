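"""Synthetic coordinate generator.

Builds ideal rings at a requested Cremer-Pople pucker, full monosaccharides
from the registry's axial/equatorial substitution patterns, assembled toy
glycans, and stereochemically corrupted variants for detector tests.

The generated geometry makes no claim of energetic realism: ring radii, bond
lengths and default glycosidic torsions (phi = -60, psi = 120 degrees) are
chosen only to produce clean, clash-free reference structures whose forward
pucker analysis and chirality signs are exactly reproducible.  D-sugars are
built in the 4C1 chair; L-sugars are built as the mirror image of their
D-configured pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GeometryError, UnsupportedSugarError
from .geometry import dihedral, exo_directions, normalize, rotation_about_axis
from .graph import GlycanGraph
from .pucker import synthesize_displacements
from .registry import (MODIFICATIONS, MonosaccharideDefinition, lookup_definition,
                       resolve_ccd)

BOND_C_O = 1.43
BOND_C_N = 1.47
BOND_C_C = 1.53
BOND_O_H = 0.97
GLYCOSIDIC_ANGLE = 117.0  # C_x - O_x - C_anomeric, degrees

#: Default chair / envelope build targets (Q Angstrom, theta deg, phi deg).
DEFAULT_PUCKER_6 = (0.57, 0.0, 0.0)
DEFAULT_PUCKER_5 = (0.38, None, 270.0)

#: Default toy glycosidic torsions; chosen only to avoid clashes.
DEFAULT_PHI = -60.0
DEFAULT_PSI = 120.0
DEFAULT_OMEGA = 60.0


@dataclass
class RingBuildSpec:
    ring_size: int = 6
    q_total: float = 0.57
    theta: Optional[float] = 0.0
    phi: float = 0.0
    ring_radius: Optional[float] = None  # default 1.45 (6-ring) / 1.25 (5-ring)


def build_ring(spec: RingBuildSpec) -> np.ndarray:
    """Coordinates of an N-ring whose forward pucker analysis returns the target.

    Atoms are placed clockwise (viewed from +z) on a circle, displaced
    out-of-plane by the inverse Cremer-Pople synthesis, so the mean-plane
    normal of the forward analysis is +z and (Q, theta, phi) are recovered
    exactly (to rounding) by :func:`glycoforge.pucker.cremer_pople`.
    """
    n = spec.ring_size
    if n not in (5, 6):
        raise GeometryError(f"ring size {n} not supported")
    radius = spec.ring_radius or (1.45 if n == 6 else 1.25)
    if spec.q_total < 0 or spec.q_total > radius:
        raise GeometryError(
            f"puckering amplitude Q={spec.q_total} infeasible for radius {radius}")
    z = synthesize_displacements(n, spec.q_total, spec.theta, spec.phi)
    j = np.arange(n)
    ang = 2 * np.pi * j / n
    coords = np.stack([radius * np.cos(ang), -radius * np.sin(ang), z], axis=1)
    return coords


@dataclass
class ResidueBuild:
    """Heavy-atom (plus optional polar-H) build of one monosaccharide."""

    definition: MonosaccharideDefinition
    anomer: str
    mirrored: bool
    atoms: dict = field(default_factory=dict)   # name -> np.ndarray
    elements: dict = field(default_factory=dict)
    bonds: list = field(default_factory=list)   # (name, name)
    ring_atoms: tuple = ()
    leaving_atom: str = "O1"

    def heavy_atoms(self):
        return {n: p for n, p in self.atoms.items() if self.elements[n] != "H"}

    def copy(self):
        out = ResidueBuild(self.definition, self.anomer, self.mirrored,
                           {n: p.copy() for n, p in self.atoms.items()},
                           dict(self.elements), list(self.bonds),
                           self.ring_atoms, self.leaving_atom)
        return out


def _element_of(name: str) -> str:
    return {"O": "O", "N": "N", "C": "C", "H": "H", "S": "S", "P": "P"}[name[0]]


def _bond_length(el_a: str, el_b: str) -> float:
    pair = {el_a, el_b}
    if pair == {"C"}:
        return BOND_C_C
    if "H" in pair:
        return BOND_O_H
    if "N" in pair:
        return BOND_C_N
    return BOND_C_O


def _chain_dir(parent: np.ndarray, anchor: np.ndarray, k: int,
               gamma_offset: float = 0.0) -> np.ndarray:
    """Direction for the k-th chain substituent on ``parent`` anchored away
    from ``anchor``, tilted tetrahedrally and fanned by 120 degrees per k."""
    e1 = normalize(parent - anchor)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(e1 @ ref) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = normalize(np.cross(e1, ref))
    e3 = np.cross(e1, e2)
    gamma = math.radians(120.0 * k + 60.0 + gamma_offset)
    # 70.5 deg from the extension axis = tetrahedral (109.5 deg) bond angle
    # at the parent, and 109.5 deg between fanned siblings
    tilt = math.radians(70.5)
    return normalize(e1 * math.cos(tilt)
                     + (e2 * math.cos(gamma) + e3 * math.sin(gamma)) * math.sin(tilt))


def build_residue(definition: MonosaccharideDefinition, anomer: str,
                  conformer: Optional[tuple] = None,
                  config: Optional[str] = None,
                  with_hydrogens: bool = False) -> ResidueBuild:
    """Ideal heavy-atom coordinates for one residue of the registry.

    ``conformer`` is a (Q, theta, phi) target; the default is the reference
    chair (or a reference envelope for furanoses).  ``with_hydrogens`` adds
    hydroxyl hydrogens (used for chemical-component generation).  L-sugars
    are mirrored after the D-pattern build.
    """
    config = config or definition.default_config
    if definition.default_ring == "open-chain":
        return _build_open_chain(definition, with_hydrogens)
    n = len(definition.ring_atom_names)
    if conformer is None:
        conformer = DEFAULT_PUCKER_6 if n == 6 else DEFAULT_PUCKER_5
    q_total, theta, phi = conformer
    if n == 5 and theta is not None:
        raise GeometryError("furanose conformers have no polar angle; pass theta=None")
    ring = build_ring(RingBuildSpec(n, q_total, theta, phi))

    build = ResidueBuild(definition, anomer, mirrored=(config == "L"),
                         ring_atoms=definition.ring_atom_names,
                         leaving_atom=definition.leaving_atom)
    names = definition.ring_atom_names
    for i, name in enumerate(names):
        build.atoms[name] = ring[i]
        build.elements[name] = _element_of(name)
        build.bonds.append((name, names[(i + 1) % n]))

    def place_sub(ring_atom, sub_name, orient):
        i = names.index(ring_atom)
        p = build.atoms[ring_atom]
        a = build.atoms[names[(i - 1) % n]]
        b = build.atoms[names[(i + 1) % n]]
        d1, d2 = exo_directions(p, a, b)
        # the more nearly vertical direction is axial
        ax, eq = (d1, d2) if abs(d1[2]) >= abs(d2[2]) else (d2, d1)
        d = ax if orient == "ax" else eq
        el = _element_of(sub_name)
        build.atoms[sub_name] = p + d * _bond_length("C", el)
        build.elements[sub_name] = el
        build.bonds.append((ring_atom, sub_name))

    # anomeric substituent(s)
    ac = definition.anomeric_carbon
    if anomer not in ("alpha", "beta"):
        raise UnsupportedSugarError(f"{definition.sugar_name}: anomer {anomer!r}")
    anomeric_orient = "ax" if anomer == "alpha" else "eq"
    place_sub(ac, definition.leaving_atom, anomeric_orient)
    if definition.anomeric_partner:  # ketoses: carboxylate C1 takes the other slot
        place_sub(ac, definition.anomeric_partner,
                  "eq" if anomeric_orient == "ax" else "ax")
        for i, tail_atom in enumerate(("O1A", "O1B")):
            anchor = build.atoms[ac]
            parent = build.atoms[definition.anomeric_partner]
            build.atoms[tail_atom] = parent + _chain_dir(parent, anchor, i) * 1.25
            build.elements[tail_atom] = "O"
            build.bonds.append((definition.anomeric_partner, tail_atom))

    for ring_atom, sub, orient in definition.ring_subs:
        place_sub(ring_atom, sub, orient)
    # second-shell chain atoms (O6, glycerol tail, carboxylate oxygens)
    parent_children: dict[str, int] = {}
    ring_index = {nm: i for i, nm in enumerate(names)}
    parent_of = {}
    for a, b in build.bonds:
        if b not in names:
            parent_of[b] = a
    for parent, atom in definition.tails:
        if parent not in build.atoms:
            continue
        anchor_name = parent_of.get(parent)
        if anchor_name is None:  # parent is a ring atom
            i = ring_index[parent]
            anchor_name = names[(i - 1) % n]
        used = parent_children.setdefault(parent, [])
        el = _element_of(atom)
        length = _bond_length("C", el)
        existing = np.vstack(list(build.atoms.values()))
        best, best_clearance = None, -1.0
        for k in range(3):  # pick the tetrahedral slot with most clearance
            if k in used:
                continue
            d = _chain_dir(build.atoms[parent], build.atoms[anchor_name], k)
            cand = build.atoms[parent] + d * length
            clearance = np.linalg.norm(existing - cand, axis=1)
            clearance = np.sort(clearance)[1]  # ignore the bonded parent
            if clearance > best_clearance:
                best, best_clearance, best_k = cand, clearance, k
        used.append(best_k)
        build.atoms[atom] = best
        build.elements[atom] = el
        build.bonds.append((parent, atom))
        parent_of[atom] = parent

    if with_hydrogens:
        _add_hydroxyl_hydrogens(build)
    if build.mirrored:
        for name in build.atoms:
            build.atoms[name] = build.atoms[name] * np.array([-1.0, 1.0, 1.0])
    return build


def _add_hydroxyl_hydrogens(build: ResidueBuild):
    parents = {}
    for a, b in build.bonds:
        parents.setdefault(b, a)
    for name in list(build.atoms):
        if build.elements[name] != "O":
            continue
        heavy_nbrs = [x for (x, y) in build.bonds if y == name] + \
                     [y for (x, y) in build.bonds if x == name]
        heavy_nbrs = [x for x in heavy_nbrs if build.elements[x] != "H"]
        if len(heavy_nbrs) != 1:
            continue  # bridging or carboxylate-like oxygen: no OH hydrogen
        parent = heavy_nbrs[0]
        d = normalize(build.atoms[name] - build.atoms[parent])
        h_name = "H" + name
        build.atoms[h_name] = build.atoms[name] + d * BOND_O_H
        build.elements[h_name] = "H"
        build.bonds.append((name, h_name))


def _build_open_chain(definition, with_hydrogens=False) -> ResidueBuild:
    """Extended zig-zag build for open-chain polyols (ribitol)."""
    build = ResidueBuild(definition, "none", mirrored=False, ring_atoms=(),
                         leaving_atom=definition.leaving_atom)
    n_carbons = 5
    for i in range(n_carbons):
        name = f"C{i + 1}"
        build.atoms[name] = np.array([1.29 * i, 0.45 * ((-1) ** i), 0.0])
        build.elements[name] = "C"
        if i:
            build.bonds.append((f"C{i}", name))
    subs = {ring_atom: orient for ring_atom, _s, orient in definition.ring_subs}
    for i in range(n_carbons):
        cname = f"C{i + 1}"
        oname = f"O{i + 1}"
        if i in (0, n_carbons - 1):  # terminal hydroxyls extend the chain
            d = normalize(build.atoms[cname] - build.atoms[f"C{2 if i == 0 else n_carbons - 1}"])
            build.atoms[oname] = build.atoms[cname] + d * BOND_C_O
        else:
            side = 1.0 if subs.get(cname, "eq") == "eq" else -1.0
            # tilt away from the chain axis so lateral oxygens stay apart
            d = normalize(np.array([0.0, 0.9 * ((-1) ** i), side * 1.43]))
            build.atoms[oname] = build.atoms[cname] + d * BOND_C_O
        build.elements[oname] = "O"
        build.bonds.append((cname, oname))
    if with_hydrogens:
        _add_hydroxyl_hydrogens(build)
    return build

# ---------------------------------------------------------------------------
# glycan assembly
# ---------------------------------------------------------------------------

def _mod_geometry(mod_name: str, bridge_pos: np.ndarray, anchor_pos: np.ndarray,
                  existing: Optional[np.ndarray] = None):
    """Atoms of a modification block grafted onto a bridge oxygen.

    Returns (atoms, elements, code) with the block's leaving oxygen already
    absent, mirroring the edited component used in the emitted job.  The
    central atom is placed in the clearest of the bridge oxygen's tetrahedral
    slots, and pendant atoms fan away from the densest surroundings.
    """
    mod = MODIFICATIONS[mod_name]
    if existing is None or len(existing) == 0:
        existing = np.asarray([anchor_pos])

    def clearest(candidates):
        best, best_c = None, -1.0
        for cand in candidates:
            c = np.sort(np.linalg.norm(existing - cand, axis=1))[1] \
                if len(existing) > 1 else 10.0
            if c > best_c:
                best, best_c = cand, c
        return best

    center_len = {"sulfate": 1.60, "phosphate": 1.60,
                  "acetyl": 1.36, "methyl": 1.43}[mod_name]
    c_pos = clearest([bridge_pos + _chain_dir(bridge_pos, anchor_pos, k) * center_len
                      for k in range(3)])
    atoms, elements = {}, {}
    if mod_name in ("sulfate", "phosphate"):
        center = "S" if mod_name == "sulfate" else "P"
        atoms[center] = c_pos
        elements[center] = center
        # rotate the oxygen fan to the clearest orientation
        best_off, best_c = 0.0, -1.0
        for off in range(0, 120, 10):
            pts = [c_pos + _chain_dir(c_pos, bridge_pos, i, float(off)) * 1.47
                   for i in range(3)]
            c = min(np.linalg.norm(existing - pt, axis=1).min() for pt in pts)
            if c > best_c:
                best_off, best_c = float(off), c
        for i, name in enumerate(("O2", "O3", "O4")):
            atoms[name] = c_pos + _chain_dir(c_pos, bridge_pos, i, best_off) * 1.47
            elements[name] = "O"
    elif mod_name == "acetyl":
        atoms["C"] = c_pos
        elements["C"] = "C"
        atoms["O"] = c_pos + _chain_dir(c_pos, bridge_pos, 0) * 1.22
        elements["O"] = "O"
        atoms["CH3"] = c_pos + _chain_dir(c_pos, bridge_pos, 1) * 1.50
        elements["CH3"] = "C"
    else:  # methyl
        atoms["C"] = c_pos
        elements["C"] = "C"
    return atoms, elements, mod.ccd_code


def build_glycan_coords(graph: GlycanGraph, entity_id: str = "NG",
                        phi: float = DEFAULT_PHI, psi: float = DEFAULT_PSI,
                        max_retries: int = 200):
    """Assemble a clean structural model of a glycan graph.

    Residues are placed breadth-first with ideal reference-chair builds,
    joined by glycosidic bonds of length 1.43 A at the requested phi/psi
    torsions.  Donor leaving oxygens are omitted (as in a remediated job).
    Returns a :class:`glycoforge.structure.StructureModel` whose residue
    indices follow the canonical numbering.
    """
    from .graph import modification_slots
    from .structure import StructureModel

    g = graph.canonicalized()
    model = StructureModel(name=f"synthetic-{entity_id}")
    builds = {}
    placed: dict[int, dict] = {}

    def residue_def(num):
        return lookup_definition(g.residues[num].sugar_name)

    order = g.residue_numbering()
    for num in order:
        res = g.residues[num]
        definition = residue_def(num)
        build = build_residue(definition, res.anomer if res.anomer != "none" else "none",
                              config=res.absolute_config) \
            if res.anomer != "none" else _build_open_chain(definition)
        builds[num] = build
        if num == g.root_index:
            placed[num] = {n: p.copy() for n, p in build.heavy_atoms().items()}
            continue
        lk = g.parent_linkage(num)
        acc_atoms = placed[lk.acceptor_index]
        pos = lk.acceptor_position
        o_name = f"O{pos}"
        if o_name not in acc_atoms:
            raise GeometryError(
                f"acceptor residue {lk.acceptor_index} has no atom {o_name}")
        c_name = f"C{pos}"
        prev_name = f"C{pos - 1}" if f"C{pos - 1}" in acc_atoms else "C2"
        o_x, c_x, prev = acc_atoms[o_name], acc_atoms[c_name], acc_atoms[prev_name]

        local = build.heavy_atoms()
        an_c = build.definition.anomeric_carbon
        leaving = build.leaving_atom
        c_loc, o_loc = local[an_c], local[leaving]

        # deterministic torsion scan: default first, then widening offsets
        deltas = [(0, 0)]
        for dphi in (0, 30, -30, 60, -60, 90, -90, 120, -120, 150, 180):
            for dpsi in (0, 20, -20, 40, -40, 60, -60, 80, -80, 100, -100,
                         120, -120, 140, -140, 160, 180):
                if (dpsi, dphi) != (0, 0):
                    deltas.append((dpsi, dphi))
        success = False
        for attempt in range(min(max_retries, len(deltas))):
            dpsi, dphi = deltas[attempt]
            psi_t = psi + dpsi
            phi_t = phi + dphi
            d = normalize(o_x - c_x)
            ref = np.array([0.0, 0.0, 1.0])
            if abs(d @ ref) > 0.95:
                ref = np.array([1.0, 0.0, 0.0])
            k = normalize(np.cross(d, ref))
            v = rotation_about_axis(k, 180.0 - GLYCOSIDIC_ANGLE) @ d
            q = o_x + v * BOND_C_O
            cur_psi = dihedral(q, o_x, c_x, prev)
            # rotation sense vs dihedral sign depends on geometry; try both
            best = None
            for sgn in (1.0, -1.0):
                v_try = rotation_about_axis(d, sgn * (psi_t - cur_psi)) @ v
                q_try = o_x + v_try * BOND_C_O
                err = abs((dihedral(q_try, o_x, c_x, prev) - psi_t + 180) % 360 - 180)
                if best is None or err < best[0]:
                    best = (err, v_try, q_try)
            _err, v, q = best

            u = normalize(o_loc - c_loc)
            w = normalize(o_x - q)
            axis = np.cross(u, w)
            if np.linalg.norm(axis) < 1e-9:
                rot1 = np.eye(3) if u @ w > 0 else rotation_about_axis(
                    np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0]),
                    180.0)
            else:
                ang = math.degrees(math.acos(max(-1.0, min(1.0, float(u @ w)))))
                rot1 = rotation_about_axis(axis, ang)
            pos_new = {n: rot1 @ (p - c_loc) + q for n, p in local.items()}
            ring_o = build.ring_atoms[0] if build.ring_atoms else "C2"
            cur_phi = dihedral(pos_new[ring_o], q, o_x, c_x)
            best = None
            for sgn in (1.0, -1.0):
                rot2 = rotation_about_axis(o_x - q, sgn * (phi_t - cur_phi))
                probe = rot2 @ (pos_new[ring_o] - q) + q
                err = abs((dihedral(probe, q, o_x, c_x) - phi_t + 180) % 360 - 180)
                if best is None or err < best[0]:
                    best = (err, rot2)
            pos_new = {n: best[1] @ (p - q) + q for n, p in pos_new.items()}
            del pos_new[leaving]  # displaced on bond formation

            # non-bonded contacts below 2.0 A would read as spurious bonds
            clash = False
            existing = np.vstack([p for atoms in placed.values() for p in atoms.values()])
            bridge_row = np.linalg.norm(existing - o_x, axis=1).argmin()
            for n, p in pos_new.items():
                dists = np.linalg.norm(existing - p, axis=1)
                if n == an_c:  # bonded to the bridge oxygen; that contact is fine
                    dists[bridge_row] = 10.0
                if dists.min() < 2.0:
                    clash = True
                    break
            if not clash:
                placed[num] = pos_new
                success = True
                break
        if not success:
            raise GeometryError(f"steric collapse placing residue {num}")

    canon_code = {}
    for num in order:
        code, _ac, _leave = resolve_ccd(g.residues[num])
        canon_code[num] = code
        for name, p in placed[num].items():
            model.add_atom(entity_id, num, code, name, _element_of(name), p, 90.0)

    for slot, host, pos, mod_name in modification_slots(g):
        bridge = placed[host][f"O{pos}"]
        anchor = placed[host][f"C{pos}"]
        existing = np.vstack([a.pos for a in model.atoms])
        atoms, elements, code = _mod_geometry(mod_name, bridge, anchor, existing)
        for name, p in atoms.items():
            model.add_atom(entity_id, slot, code, name, elements[name], p, 90.0)
    return model


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

@dataclass
class CorruptionSpec:
    """One named stereochemical defect to inject.

    error_class: ``epimer-flip`` | ``anomer-flip`` | ``retain-leaving-oxygen``
    | ``ring-flatten``.  ``center`` names the stereocenter for epimer flips;
    anomer flips and leaving-oxygen retention act at the anomeric carbon.
    """

    entity: str
    residue_index: int
    error_class: str
    center: Optional[str] = None


def _residue_definition_of(model, entity, residue_index):
    from .registry import definition_for_code

    atoms = model.residue_atoms(entity, residue_index)
    if not atoms:
        raise GeometryError(f"no residue {residue_index} in entity {entity}")
    hit = definition_for_code(atoms[0].residue_code)
    if hit is None:
        raise GeometryError(f"unknown residue code {atoms[0].residue_code}")
    return hit[0]


def _exo_dirs_at(model, entity, residue_index, center, definition):
    names = definition.ring_atom_names
    p = model.find_atom(entity, residue_index, center).pos
    if names:
        i = names.index(center)
        a = model.find_atom(entity, residue_index, names[(i - 1) % len(names)]).pos
        b = model.find_atom(entity, residue_index, names[(i + 1) % len(names)]).pos
    else:  # open chain: flanking carbons are the backbone
        i = int(center[1:])
        a = model.find_atom(entity, residue_index, f"C{i - 1}").pos
        b = model.find_atom(entity, residue_index, f"C{i + 1}").pos
    return p, exo_directions(p, a, b)


def corrupt(model, spec: CorruptionSpec, graph: Optional[GlycanGraph] = None):
    """Return a copy of ``model`` with exactly the requested defect injected."""
    import copy

    out = copy.deepcopy(model)
    definition = _residue_definition_of(out, spec.entity, spec.residue_index)
    cls = spec.error_class

    if cls == "ring-flatten":
        from .pucker import ring_displacements
        atoms = [out.find_atom(spec.entity, spec.residue_index, n)
                 for n in definition.ring_atom_names]
        if not definition.ring_atom_names or any(a is None for a in atoms):
            raise GeometryError("ring-flatten requires a cyclic residue")
        coords = np.vstack([a.pos for a in atoms])
        z = ring_displacements(coords)
        center = coords.mean(axis=0)
        rel = coords - center
        # remove the out-of-plane component along the mean-plane normal
        j = np.arange(len(coords))
        rp = (rel * np.sin(2 * np.pi * j / len(coords))[:, None]).sum(axis=0)
        rpp = (rel * np.cos(2 * np.pi * j / len(coords))[:, None]).sum(axis=0)
        normal = normalize(np.cross(rp, rpp))
        for a, zi in zip(atoms, z):
            a.pos = a.pos - normal * zi
        return out

    if cls == "epimer-flip":
        if spec.center is None:
            raise GeometryError("epimer-flip requires a center")
        sub = definition.substituent_of(spec.center)
        if sub is None:
            raise GeometryError(f"{spec.center} has no defined substituent")
        sub_name, _orient = sub
        p, (d1, d2) = _exo_dirs_at(out, spec.entity, spec.residue_index,
                                   spec.center, definition)
        at = out.find_atom(spec.entity, spec.residue_index, sub_name)
        if at is None:
            raise GeometryError(f"substituent {sub_name} missing")
        length = float(np.linalg.norm(at.pos - p))
        cur = normalize(at.pos - p)
        other = d2 if abs(cur @ d1) >= abs(cur @ d2) else d1
        at.pos = p + other * length
        # re-place chain atoms hanging off the flipped substituent so the
        # flip does not manufacture spurious close contacts
        _replace_subtree(out, spec.entity, spec.residue_index, definition,
                         sub_name, spec.center)
        return out

    ac = definition.anomeric_carbon
    if cls == "retain-leaving-oxygen":
        p, (d1, d2) = _exo_dirs_at(out, spec.entity, spec.residue_index, ac,
                                   definition)
        partner = (out.find_atom(spec.entity, spec.residue_index,
                                 definition.anomeric_partner)
                   if definition.anomeric_partner else None)
        occupied = []
        for a in out.atoms:
            if a.is_hydrogen:
                continue
            d = np.linalg.norm(a.pos - p)
            if 0.1 < d < 1.9:
                occupied.append(normalize(a.pos - p))
        if partner is not None and len(occupied) >= 4:
            # ketose junction: all four tetrahedral slots are taken, so the
            # retained oxygen crowds the face opposite the carboxylate
            free = -normalize(partner.pos - p)
        else:
            free = d1
            if any(float(free @ o) > 0.8 for o in occupied):
                free = d2
        out.add_atom(spec.entity, spec.residue_index,
                     out.residue_atoms(spec.entity, spec.residue_index)[0].residue_code,
                     definition.leaving_atom, "O", p + free * BOND_C_O, 90.0)
        return out

    if cls == "anomer-flip":
        return _flip_anomer(out, spec, definition, graph)
    raise GeometryError(f"unknown corruption class {cls!r}")


def _replace_subtree(model, entity, residue_index, definition, root_sub,
                     root_anchor):
    """Re-place the chain atoms below ``root_sub`` (breadth-first), choosing
    for each the tetrahedral slot with the most clearance."""
    bonds = _definition_bonds(definition)
    children_of: dict[str, list] = {}
    parent_of: dict[str, str] = {}
    for a, b in bonds:
        children_of.setdefault(a, []).append(b)
        parent_of[b] = a
    parent_of[root_sub] = root_anchor
    queue = list(children_of.get(root_sub, []))
    order = []
    while queue:
        child = queue.pop(0)
        order.append(child)
        queue.extend(children_of.get(child, []))
    placed_slots: dict[str, list] = {}
    for child in order:
        at = model.find_atom(entity, residue_index, child)
        if at is None:
            continue
        parent = model.find_atom(entity, residue_index, parent_of[child])
        anchor = model.find_atom(entity, residue_index, parent_of[parent_of[child]])
        if parent is None or anchor is None:
            continue
        length = float(np.linalg.norm(at.pos - parent.pos))
        existing = np.vstack([a.pos for a in model.atoms if a is not at])
        used = placed_slots.setdefault(parent_of[child], [])
        best, best_c, best_k = at.pos, -1.0, None
        for k in range(3):
            if k in used:
                continue
            cand = parent.pos + _chain_dir(parent.pos, anchor.pos, k) * length
            c = np.sort(np.linalg.norm(existing - cand, axis=1))[1]
            if c > best_c:
                best, best_c, best_k = cand, c, k
        if best_k is not None:
            used.append(best_k)
            at.pos = best


def _definition_bonds(definition):
    bonds = []
    names = definition.ring_atom_names
    for ring_atom, sub, _o in definition.ring_subs:
        bonds.append((ring_atom, sub))
    for parent, atom in definition.tails:
        bonds.append((parent, atom))
    return bonds


def _flip_anomer(model, spec, definition, graph):
    ac = definition.anomeric_carbon
    entity, num = spec.entity, spec.residue_index
    p, (d1, d2) = _exo_dirs_at(model, entity, num, ac, definition)
    leaving = model.find_atom(entity, num, definition.leaving_atom)
    partner = (model.find_atom(entity, num, definition.anomeric_partner)
               if definition.anomeric_partner else None)

    glyco_o = None
    if graph is not None:
        g = graph.canonicalized()
        lk = g.parent_linkage(num)
        if lk is not None:
            glyco_o = model.find_atom(entity, lk.acceptor_index,
                                      f"O{lk.acceptor_position}")
    if glyco_o is not None:
        # linked donor: rotate the donor subtree 180 deg about the exterior
        # bisector axis at the anomeric carbon; this swaps the two exocyclic
        # slots (inverting C1 chirality) while leaving the acceptor untouched
        axis = d1 + d2
        rot = rotation_about_axis(axis, 180.0)
        subtree = {num}
        if graph is not None:
            order = g.residue_numbering()
            for cand in order:
                node = cand
                while node is not None and node not in subtree:
                    lk2 = g.parent_linkage(node)
                    node = lk2.acceptor_index if lk2 else None
                if node in subtree:
                    subtree.add(cand)
        moving = [a for a in model.atoms
                  if a.entity == entity and a.residue_index in subtree]
        for a in moving:
            a.pos = rot @ (a.pos - p) + p
        # spin about the glycosidic bond (chirality-preserving) for clearance
        anomeric = model.find_atom(entity, num, ac)
        bond_axis = glyco_o.pos - anomeric.pos
        moving_set = set(id(a) for a in moving)
        others_atoms = [a for a in model.atoms if id(a) not in moving_set]
        others = np.vstack([a.pos for a in others_atoms])
        anom_row = next(i for i, a in enumerate(moving) if a is anomeric)
        glyco_col = next(i for i, a in enumerate(others_atoms) if a is glyco_o)
        best_spin, best_c = 0.0, -1.0
        for spin in range(0, 360, 30):
            rspin = rotation_about_axis(bond_axis, float(spin))
            pts = np.vstack([rspin @ (a.pos - anomeric.pos) + anomeric.pos
                             for a in moving])
            dmat = np.linalg.norm(pts[:, None, :] - others[None, :, :], axis=2)
            dmat[anom_row, glyco_col] = 10.0  # the glycosidic bond itself
            c = dmat.min()
            if c > best_c:
                best_spin, best_c = float(spin), c
        rspin = rotation_about_axis(bond_axis, best_spin)
        for a in moving:
            a.pos = rspin @ (a.pos - anomeric.pos) + anomeric.pos
        return model
    # free residue: swap the exocyclic slots of the leaving O (and carboxylate
    # partner for ketoses)
    if leaving is None:
        raise GeometryError("anomer-flip target has no anomeric substituent")
    cur = normalize(leaving.pos - p)
    other = d2 if abs(cur @ d1) >= abs(cur @ d2) else d1
    same = d1 if other is d2 else d2
    new_o = p + other * float(np.linalg.norm(leaving.pos - p))
    if partner is not None:
        partner.pos = p + same * float(np.linalg.norm(partner.pos - p))
        anomeric = model.find_atom(entity, num, ac)
        used = []
        for name in ("O1A", "O1B"):  # re-fan the carboxylate oxygens
            at = model.find_atom(entity, num, name)
            if at is None:
                continue
            length = float(np.linalg.norm(at.pos - partner.pos)) or 1.25
            existing = np.vstack([a.pos for a in model.atoms if a is not at])
            best, best_c, best_k = at.pos, -1.0, None
            for k in range(3):
                if k in used:
                    continue
                cand = partner.pos + _chain_dir(partner.pos, anomeric.pos, k) * length
                c = np.sort(np.linalg.norm(existing - cand, axis=1))[1]
                if c > best_c:
                    best, best_c, best_k = cand, c, k
            used.append(best_k)
            at.pos = best
    leaving.pos = new_o
    return model
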