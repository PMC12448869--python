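"""Stereochemistry validation of predicted glycan structures.

Given a structural model and the glycan topology it was supposed to realize,
the validator checks, per residue:

* the anomeric configuration (alpha/beta), by comparing the signed volume of
  the three edge vectors at the anomeric carbon (ring O, next ring C,
  glycosidic/anomeric O, in that fixed role order) against the same
  determinant computed on the registry's ideal build of the expected residue;
* every other ring stereocenter (epimer check, axial vs equatorial), by the
  same signed-volume comparison against the reference build — deliberately
  avoiding CIP priority rules, which keeps the test total, fast and exact;
* valence sanity: any oxygen with more than two heavy-atom neighbours, and
  any carbon bonded to three oxygens (the signature of a retained leaving
  oxygen at a glycosidic junction);
* ring puckering: Cremer-Pople (Q, theta, phi) plus the nearest canonical
  conformer label, on the geometrically perceived ring.

All verdicts are derived from heavy atoms only; hydrogens are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import GlycanGraph
from .pucker import classify_pucker_detail, cremer_pople
from .registry import lookup_definition, resolve_ccd
from .structure import StructureModel
from .synthetic import build_residue
from .geometry import dihedral


@dataclass
class PuckerReport:
    entity: str
    residue_index: int
    q_total: float
    theta: Optional[float]
    phi: float
    conformer: str
    margin: float   # angular distance (deg) to the runner-up label

    @property
    def borderline(self) -> bool:
        return self.margin < 10.0


@dataclass
class ResidueVerdict:
    residue_index: int
    expected_code: str
    anomeric_verdict: str = "ok"            # ok | flipped | indeterminate
    epimer_mismatches: list = field(default_factory=list)
    indeterminate_centers: list = field(default_factory=list)
    pucker: Optional[PuckerReport] = None

    @property
    def clean(self) -> bool:
        return self.anomeric_verdict == "ok" and not self.epimer_mismatches


@dataclass
class StereoReport:
    entity: str
    residues: list = field(default_factory=list)
    valence_flags: list = field(default_factory=list)

    def findings(self) -> list:
        out = []
        for r in self.residues:
            if r.anomeric_verdict == "flipped":
                out.append({"category": "anomer-flip", "residue": r.residue_index})
            for center in r.epimer_mismatches:
                out.append({"category": "epimer-flip", "residue": r.residue_index,
                            "center": center})
        for f in self.valence_flags:
            out.append(dict(f, category=f.get("category", "valence")))
        return out

    @property
    def clean(self) -> bool:
        return not self.findings()

    def to_dict(self) -> dict:
        return {
            "entity": self.entity,
            "clean": self.clean,
            "findings": self.findings(),
            "residues": [{
                "residue_index": r.residue_index,
                "expected_code": r.expected_code,
                "anomeric_verdict": r.anomeric_verdict,
                "epimer_mismatches": r.epimer_mismatches,
                "indeterminate_centers": r.indeterminate_centers,
                "pucker": None if r.pucker is None else {
                    "Q": round(r.pucker.q_total, 4),
                    "theta": None if r.pucker.theta is None else round(r.pucker.theta, 2),
                    "phi": round(r.pucker.phi, 2),
                    "conformer": r.pucker.conformer,
                    "borderline": r.pucker.borderline,
                },
            } for r in self.residues],
        }

    def format_table(self) -> str:
        lines = [f"{'res':>4} {'code':<5} {'anomer':<13} {'epimers':<18} {'pucker':<8} Q"]
        for r in self.residues:
            puck = r.pucker.conformer if r.pucker else "-"
            q = f"{r.pucker.q_total:.2f}" if r.pucker else "-"
            eps = ",".join(r.epimer_mismatches) or "-"
            lines.append(f"{r.residue_index:>4} {r.expected_code:<5} "
                         f"{r.anomeric_verdict:<13} {eps:<18} {puck:<8} {q}")
        if self.valence_flags:
            lines.append("valence flags:")
            for f in self.valence_flags:
                lines.append(f"  {f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ring perception
# ---------------------------------------------------------------------------

def perceive_ring(model: StructureModel, entity: str, residue_index: int,
                  bonds=None):
    """Ordered ring atoms of a residue: ring O first, then toward the
    anomeric carbon.  Returns a list of Atom objects, or None when the
    residue has no single 5/6-cycle with exactly one oxygen (open chains)."""
    atoms = model.residue_atoms(entity, residue_index)
    index_of = {}
    for i, a in enumerate(model.atoms):
        if a.entity == entity and a.residue_index == residue_index and not a.is_hydrogen:
            index_of[i] = a
    if bonds is None:
        bonds = model.infer_bonds()
    adj: dict[int, list] = {i: [] for i in index_of}
    for i, j in bonds:
        if i in index_of and j in index_of:
            adj[i].append(j)
            adj[j].append(i)

    cycles = []
    def dfs(path, target, limit):
        node = path[-1]
        for nxt in adj[node]:
            if nxt == target and len(path) >= 5:
                cycles.append(list(path))
            elif nxt not in path and len(path) < limit:
                dfs(path + [nxt], target, limit)

    for start in adj:
        dfs([start], start, 6)
    uniq = {}
    for cyc in cycles:
        uniq[frozenset(cyc)] = cyc
    candidates = [c for c in uniq.values()
                  if len(c) in (5, 6)
                  and sum(1 for i in c if index_of[i].element == "O") == 1]
    if len(candidates) != 1:
        return None
    cyc = candidates[0]
    o_pos = next(k for k, i in enumerate(cyc) if index_of[i].element == "O")
    cyc = cyc[o_pos:] + cyc[:o_pos]
    # orient toward the anomeric carbon: the ring-O neighbour with more
    # oxygen neighbours (the anomeric C carries an extra O); ties break on name
    nxt, prv = cyc[1], cyc[-1]
    def rank(i):
        other_o = sum(1 for j in adj[i] if index_of[j].element == "O")
        return (-other_o, index_of[i].name)
    if rank(prv) < rank(nxt):
        cyc = [cyc[0]] + cyc[1:][::-1]
    return [index_of[i] for i in cyc]


# ---------------------------------------------------------------------------
# valence
# ---------------------------------------------------------------------------

def check_valence(model: StructureModel, bonds=None) -> list:
    """Flag over-coordinated oxygens and anomeric carbons with 3 O neighbours."""
    if bonds is None:
        bonds = model.infer_bonds()
    nbr = model.neighbor_map(bonds)
    flags = []
    flagged_carbons = set()
    oxy_flags = []
    for i, a in enumerate(model.atoms):
        if a.is_hydrogen:
            continue
        heavy = [j for j in nbr.get(i, []) if not model.atoms[j].is_hydrogen]
        if a.element == "O" and len(heavy) > 2:
            oxy_flags.append((i, heavy,
                              {"category": "oxygen-overcoordination",
                               "entity": a.entity, "residue": a.residue_index,
                               "atom": a.name, "n_heavy": len(heavy)}))
        if a.element == "C":
            n_o = sum(1 for j in heavy if model.atoms[j].element == "O")
            if n_o >= 3:
                flagged_carbons.add(i)
                flags.append({"category": "retained-leaving-oxygen",
                              "entity": a.entity, "residue": a.residue_index,
                              "atom": a.name, "n_oxygen": n_o})
    # an over-coordinated oxygen bonded to a retained-leaving-oxygen carbon
    # is the same junction defect, not an independent finding
    for _i, heavy, flag in oxy_flags:
        if not any(j in flagged_carbons for j in heavy):
            flags.append(flag)
    return flags


# ---------------------------------------------------------------------------
# stereocenters
# ---------------------------------------------------------------------------

def _signed_volume(center, p1, p2, p3) -> float:
    m = np.stack([p1 - center, p2 - center, p3 - center])
    return float(np.linalg.det(m))


def _reference_signs(definition, anomer, config):
    """Chirality reference signs on the ideal build of the expected residue."""
    build = build_residue(definition, anomer, config=config)
    names = definition.ring_atom_names
    signs = {}
    if not names:
        # open chain: centers defined against chain neighbours
        for center in definition.stereocenters():
            if center == definition.anomeric_carbon:
                continue
            i = int(center[1:])
            sub = definition.substituent_of(center)[0]
            v = _signed_volume(build.atoms[center], build.atoms[f"C{i - 1}"],
                               build.atoms[f"C{i + 1}"], build.atoms[sub])
            signs[center] = np.sign(v)
        return signs
    n = len(names)
    for center in definition.stereocenters():
        i = names.index(center)
        prev_a, next_a = names[(i - 1) % n], names[(i + 1) % n]
        if center == definition.anomeric_carbon:
            sub = definition.leaving_atom
        else:
            sub = definition.substituent_of(center)[0]
        v = _signed_volume(build.atoms[center], build.atoms[prev_a],
                           build.atoms[next_a], build.atoms[sub])
        signs[center] = np.sign(v)
    return signs


_REF_CACHE: dict = {}


def reference_signs(definition, anomer, config):
    key = (definition.sugar_name, anomer, config)
    if key not in _REF_CACHE:
        _REF_CACHE[key] = _reference_signs(definition, anomer, config)
    return _REF_CACHE[key]


def check_stereocenters(model: StructureModel, graph: GlycanGraph,
                        entity: str = "NG") -> StereoReport:
    """Compare every ring stereocenter of ``model`` against the intended
    topology; model residues map to graph residues by canonical numbering."""
    g = graph.canonicalized()
    bonds = model.infer_bonds()
    report = StereoReport(entity=entity)
    numbering = g.residue_numbering()
    for num in numbering:
        res = g.residues[num]
        definition = lookup_definition(res.sugar_name)
        code, _ac, _leave = resolve_ccd(res)
        verdict = ResidueVerdict(residue_index=num, expected_code=code)
        anomer = res.anomer if res.anomer != "none" else None

        # locate the exo oxygen filling the anomeric slot in the model
        lk = g.parent_linkage(num)
        names = definition.ring_atom_names
        if anomer is not None and names:
            refs = reference_signs(definition, anomer, res.absolute_config)
            n = len(names)
            for center in definition.stereocenters():
                i = names.index(center)
                prev_a = model.find_atom(entity, num, names[(i - 1) % n])
                next_a = model.find_atom(entity, num, names[(i + 1) % n])
                c_at = model.find_atom(entity, num, center)
                if center == definition.anomeric_carbon:
                    if lk is not None:
                        exo = model.find_atom(entity, lk.acceptor_index,
                                              f"O{lk.acceptor_position}")
                    else:
                        exo = model.find_atom(entity, num, definition.leaving_atom)
                else:
                    exo = model.find_atom(entity, num,
                                          definition.substituent_of(center)[0])
                if any(x is None for x in (c_at, prev_a, next_a, exo)):
                    if center == definition.anomeric_carbon:
                        verdict.anomeric_verdict = "indeterminate"
                    else:
                        verdict.indeterminate_centers.append(center)
                    continue
                sign = np.sign(_signed_volume(c_at.pos, prev_a.pos, next_a.pos,
                                              exo.pos))
                if center == definition.anomeric_carbon:
                    verdict.anomeric_verdict = (
                        "ok" if sign == refs[center] else "flipped")
                elif sign != refs[center]:
                    verdict.epimer_mismatches.append(center)
        elif anomer is None:
            # open-chain residue: epimer checks against chain neighbours
            refs = reference_signs(definition, "none", res.absolute_config)
            for center, ref_sign in refs.items():
                i = int(center[1:])
                c_at = model.find_atom(entity, num, center)
                p1 = model.find_atom(entity, num, f"C{i - 1}")
                p2 = model.find_atom(entity, num, f"C{i + 1}")
                exo = model.find_atom(entity, num,
                                      definition.substituent_of(center)[0])
                if any(x is None for x in (c_at, p1, p2, exo)):
                    verdict.indeterminate_centers.append(center)
                    continue
                sign = np.sign(_signed_volume(c_at.pos, p1.pos, p2.pos, exo.pos))
                if sign != ref_sign:
                    verdict.epimer_mismatches.append(center)
            verdict.anomeric_verdict = "ok"

        ring = perceive_ring(model, entity, num, bonds=bonds)
        if ring is not None:
            coords = np.vstack([a.pos for a in ring])
            q_total, theta, phi = cremer_pople(coords)
            label, margin = classify_pucker_detail(
                q_total, theta, phi, [a.name for a in ring])
            verdict.pucker = PuckerReport(entity, num, q_total, theta, phi,
                                          label, margin)
        report.residues.append(verdict)
    report.valence_flags = [
        f for f in check_valence(model, bonds) if f["entity"] == entity]
    return report


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def glycosidic_torsions(model: StructureModel, graph: GlycanGraph,
                        donor_index: int, entity: str = "NG") -> dict:
    """phi/psi (and omega for 1->6 links) of the linkage donated by a residue.

    phi = O_ring - C_anomeric - O_x - C_x; psi = C_anomeric - O_x - C_x -
    C_(x-1); omega = O_x - C6 - C5 - O_ring(acceptor), 1->6 links only.
    Missing atoms yield absent keys.
    """
    g = graph.canonicalized()
    lk = g.parent_linkage(donor_index)
    if lk is None:
        return {}
    donor = g.residues[donor_index]
    don_def = lookup_definition(donor.sugar_name)
    acc = g.residues[lk.acceptor_index]
    acc_def = lookup_definition(acc.sugar_name)
    pos = lk.acceptor_position
    out = {}
    ring_o = don_def.ring_atom_names[0] if don_def.ring_atom_names else None
    a_ring_o = model.find_atom(entity, donor_index, ring_o) if ring_o else None
    c_an = model.find_atom(entity, donor_index, don_def.anomeric_carbon)
    o_x = model.find_atom(entity, lk.acceptor_index, f"O{pos}")
    c_x = model.find_atom(entity, lk.acceptor_index, f"C{pos}")
    c_prev = model.find_atom(entity, lk.acceptor_index, f"C{pos - 1}")
    if all(x is not None for x in (a_ring_o, c_an, o_x, c_x)):
        out["phi"] = dihedral(a_ring_o.pos, c_an.pos, o_x.pos, c_x.pos)
    if all(x is not None for x in (c_an, o_x, c_x, c_prev)):
        out["psi"] = dihedral(c_an.pos, o_x.pos, c_x.pos, c_prev.pos)
    if pos == 6 and acc_def.ring_atom_names:
        acc_ring_o = model.find_atom(entity, lk.acceptor_index,
                                     acc_def.ring_atom_names[0])
        c5 = model.find_atom(entity, lk.acceptor_index, "C5")
        if all(x is not None for x in (o_x, c_x, c5, acc_ring_o)):
            out["omega"] = dihedral(o_x.pos, c_x.pos, c5.pos, acc_ring_o.pos)
    return out
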