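"""AlphaFold 3 input-job assembly and JSON (v2 dialect) serialization.

A job is a set of entities (proteins, ligand chains built from CCD codes,
ions) plus an explicit covalent-bond list (``bondedAtomPairs``) and any
user-edited chemical components (``userCCD``).  Glycans enter as ligand
chains whose ``ccdCodes`` order equals the canonical residue numbering; each
glycosidic linkage becomes one bonded pair, ordered acceptor oxygen first,
donor anomeric carbon second.

Ketose donors (sialic acids) and modification blocks need edited components:
AlphaFold 3 does not remove their leaving oxygens automatically, which would
otherwise leave an extra oxygen on the glycosidic junction (an invalid
valence state).  The job builder plans those edits automatically and records
base-code -> edited-code assignments in the job manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .components import (build_component, next_edited_code, strip_leaving_atoms,
                         write_component_cif)
from .errors import JobError
from .graph import AttachmentSpec, GlycanGraph, modification_slots
from .registry import (LIPID_BLOCKS, MODIFICATIONS, lookup_definition,
                       resolve_ccd)

#: Protein atoms accepted as covalent attachment points.
_PROTEIN_ATOMS = {"N", "CA", "C", "O", "OXT", "CB", "ND2", "OG", "OG1", "SG",
                  "NZ", "NE2", "OD1", "OE1", "OH"}


@dataclass
class BondedAtomPair:
    first: tuple    # (entity id, residue index 1-based, atom name)
    second: tuple

    def as_json(self):
        return [list(self.first), list(self.second)]


@dataclass
class EntitySpec:
    id: str
    kind: str                       # protein | ligand-chain | ion
    sequence: Optional[str] = None
    ccd_codes: Optional[list] = None
    protein_modifications: list = field(default_factory=list)  # (ptmType, position)
    glycan: Optional[GlycanGraph] = None


@dataclass
class AF3Job:
    name: str
    model_seeds: list = field(default_factory=lambda: [1])
    entities: list = field(default_factory=list)
    bonded_atom_pairs: list = field(default_factory=list)
    user_ccd_blocks: dict = field(default_factory=dict)   # code -> mmCIF text
    manifest: dict = field(default_factory=dict)          # base code -> edited code

    def entity(self, entity_id) -> Optional[EntitySpec]:
        for e in self.entities:
            if e.id == entity_id:
                return e
        return None

    def next_glycan_id(self, mnemonic: str = "NG") -> str:
        existing = {e.id for e in self.entities}
        if mnemonic not in existing:
            return mnemonic
        k = 2
        while f"{mnemonic}{k}" in existing:
            k += 1
        return f"{mnemonic}{k}"


# ---------------------------------------------------------------------------
# glycan -> entity + bonds
# ---------------------------------------------------------------------------

def _edited_code_for(base_code: str, job: AF3Job) -> str:
    if base_code in job.manifest:
        return job.manifest[base_code]
    code = next_edited_code(base_code, taken=job.manifest.values())
    job.manifest[base_code] = code
    return code


def _ensure_user_ccd(job: AF3Job, base_code: str, strip: list) -> str:
    """Attach an edited component (base minus ``strip``) and return its code."""
    edited = _edited_code_for(base_code, job)
    if edited not in job.user_ccd_blocks:
        component = build_component(base_code)
        stripped = strip_leaving_atoms(component, strip,
                                       taken_codes=job.manifest.values())
        stripped.code = edited
        job.user_ccd_blocks[edited] = write_component_cif(stripped)
    return edited


def glycan_ccd_codes(job: AF3Job, graph: GlycanGraph) -> list:
    """ccdCodes in canonical numbering order, with modification blocks
    appended; donor ketoses and modifications get edited codes (planned into
    the job's userCCD)."""
    g = graph.canonicalized()
    codes = []
    for num in g.residue_numbering():
        res = g.residues[num]
        code, _ac, (leaving_atom, auto_removed) = resolve_ccd(res)
        if g.parent_linkage(num) is not None and not auto_removed:
            code = _ensure_user_ccd(job, code, [leaving_atom])
        codes.append(code)
    for _slot, _host, _pos, mod_name in modification_slots(g):
        mod = MODIFICATIONS[mod_name]
        codes.append(_ensure_user_ccd(job, mod.ccd_code,
                                      list(mod.leaving_atoms_on_mod)))
    return codes


def emit_glycan_bonds(graph: GlycanGraph, entity_id: str) -> list:
    """Bonded pairs for all glycosidic linkages and modifications of a glycan.

    Exactly ``len(residues) - 1 + len(modifications)`` pairs; each glycosidic
    pair is ordered (acceptor O_x, donor anomeric C), indices follow the
    canonical numbering.
    """
    g = graph.canonicalized()
    pairs = []
    for num in g.residue_numbering():
        lk = g.parent_linkage(num)
        if lk is None:
            continue
        res = g.residues[num]
        _code, anomeric_carbon, _leave = resolve_ccd(res)
        pairs.append(BondedAtomPair(
            (entity_id, lk.acceptor_index, f"O{lk.acceptor_position}"),
            (entity_id, num, anomeric_carbon)))
    for slot, host, pos, mod_name in modification_slots(g):
        mod = MODIFICATIONS[mod_name]
        pairs.append(BondedAtomPair(
            (entity_id, host, f"O{pos}"),
            (entity_id, slot, mod.bond_atom_on_mod)))
    return pairs


def add_glycan(job: AF3Job, graph: GlycanGraph, entity_id: Optional[str] = None,
               attachment: Optional[AttachmentSpec] = None) -> str:
    """Add a glycan ligand entity (codes, internal bonds, userCCD edits) to a
    job; optionally bond its reducing end to a partner entity."""
    issues = graph.validate_graph()
    if issues:
        raise JobError(f"invalid glycan graph: {issues}")
    entity_id = entity_id or job.next_glycan_id()
    if job.entity(entity_id) is not None:
        raise JobError(f"duplicate entity id {entity_id!r}")
    codes = glycan_ccd_codes(job, graph)
    attachment = attachment or graph.attachment
    stored = graph.canonicalized()
    if attachment is not None:
        stored.attachment = attachment
    job.entities.append(EntitySpec(entity_id, "ligand-chain", ccd_codes=codes,
                                   glycan=stored))
    job.bonded_atom_pairs.extend(emit_glycan_bonds(graph, entity_id))
    if attachment is not None and attachment.kind != "free":
        job.bonded_atom_pairs.append(attach_glycan(job, entity_id, attachment))
    return entity_id


def attach_glycan(job: AF3Job, glycan_entity: str,
                  attachment: AttachmentSpec) -> BondedAtomPair:
    """Bond a glycan's reducing end to its protein/lipid partner.

    Returns the pair ((partner, residue, ND2|OG|OG1|custom),
    (glycan, 1, anomeric C of the root)).
    """
    if attachment.kind == "free":
        raise JobError("free reducing end: nothing to attach")
    entity = job.entity(glycan_entity)
    if entity is None or entity.glycan is None:
        raise JobError(f"no glycan entity {glycan_entity!r}")
    partner = job.entity(attachment.partner_entity)
    if partner is None:
        raise JobError(f"partner entity {attachment.partner_entity!r} not in job")
    if partner.kind == "protein":
        if not (1 <= (attachment.partner_residue or 0) <= len(partner.sequence)):
            raise JobError(
                f"partner residue {attachment.partner_residue} outside sequence")
    atom = attachment.resolved_atom()
    if atom is None:
        raise JobError(f"attachment kind {attachment.kind!r} needs an explicit atom")
    g = entity.glycan
    root = g.residues[g.root_index]
    definition = lookup_definition(root.sugar_name)
    return BondedAtomPair(
        (attachment.partner_entity, attachment.partner_residue, atom),
        (glycan_entity, 1, definition.anomeric_carbon))


# ---------------------------------------------------------------------------
# job assembly
# ---------------------------------------------------------------------------

def build_job(name: str, proteins=(), glycans=(), ions=(), ligand_blocks=(),
              extra_bonds=(), seeds=(1,), user_ccd_strips=()) -> AF3Job:
    """Assemble a complete job.

    Parameters
    ----------
    proteins : iterable of (id, sequence) or (id, sequence, [(ptmType, pos)])
    glycans : iterable of (entity_id, GlycanGraph, AttachmentSpec-or-None)
    ions : iterable of (id, ccd_code)
    ligand_blocks : iterable of (id, [ccd_codes]) — lipid and linker chains
    extra_bonds : iterable of ((eid, res, atom), (eid, res, atom))
    user_ccd_strips : iterable of (base_code, [atoms]) — extra planned edits
        (e.g. a phosphate bridging two partners loses two oxygens)
    """
    job = AF3Job(name=name, model_seeds=list(seeds))
    for spec in proteins:
        pid, seq = spec[0], spec[1]
        ptms = list(spec[2]) if len(spec) > 2 else []
        if job.entity(pid):
            raise JobError(f"duplicate entity id {pid!r}")
        job.entities.append(EntitySpec(pid, "protein", sequence=seq,
                                       protein_modifications=ptms))
    for iid, code in ions:
        job.entities.append(EntitySpec(iid, "ion", ccd_codes=[code]))
    for base_code, strip in user_ccd_strips:
        _ensure_user_ccd(job, base_code, list(strip))
    for lid, codes in ligand_blocks:
        edited = [job.manifest.get(c, c) for c in codes]
        job.entities.append(EntitySpec(lid, "ligand-chain", ccd_codes=edited))
    for entity_id, graph, attachment in glycans:
        add_glycan(job, graph, entity_id, attachment)
    for first, second in extra_bonds:
        job.bonded_atom_pairs.append(BondedAtomPair(tuple(first), tuple(second)))
    issues = validate_job(job)
    if issues:
        raise JobError(f"job failed validation: {issues}")
    return job


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _known_atoms_for_code(code: str) -> Optional[set]:
    """Atom names of a component when they are knowable offline."""
    if code in LIPID_BLOCKS:
        return None  # external CCD entry; atom list not shipped
    try:
        return set(build_component(code).atom_names())
    except Exception:
        return None


def validate_job(job: AF3Job) -> list:
    """Invariant check; empty list iff the job is valid.

    Categories: duplicate-id, dangling-pair, bad-atom-name, missing-userCCD.
    """
    issues = []
    seen = set()
    for e in job.entities:
        if e.id in seen:
            issues.append({"category": "duplicate-id", "entity": e.id})
        seen.add(e.id)

    atom_cache: dict = {}
    def atoms_of(code):
        if code not in atom_cache:
            if code in job.user_ccd_blocks:
                from .components import load_component_cif
                atom_cache[code] = set(
                    load_component_cif(job.user_ccd_blocks[code]).atom_names())
            else:
                atom_cache[code] = _known_atoms_for_code(code)
        return atom_cache[code]

    for pair in job.bonded_atom_pairs:
        if pair.first == pair.second:
            issues.append({"category": "dangling-pair", "pair": pair.as_json(),
                           "reason": "self-bond"})
            continue
        for ref in (pair.first, pair.second):
            eid, residue, atom = ref
            entity = job.entity(eid)
            if entity is None:
                issues.append({"category": "dangling-pair", "pair": pair.as_json(),
                               "reason": f"no entity {eid!r}"})
                continue
            if entity.kind == "protein":
                if not (1 <= residue <= len(entity.sequence)):
                    issues.append({"category": "dangling-pair",
                                   "pair": pair.as_json(),
                                   "reason": f"residue {residue} outside {eid}"})
                elif atom not in _PROTEIN_ATOMS:
                    issues.append({"category": "bad-atom-name",
                                   "pair": pair.as_json(), "atom": atom})
            else:
                codes = entity.ccd_codes or []
                if not (1 <= residue <= len(codes)):
                    issues.append({"category": "dangling-pair",
                                   "pair": pair.as_json(),
                                   "reason": f"residue {residue} outside {eid}"})
                    continue
                known = atoms_of(codes[residue - 1])
                if known is not None and atom not in known:
                    issues.append({"category": "bad-atom-name",
                                   "pair": pair.as_json(), "atom": atom,
                                   "code": codes[residue - 1]})

    # ketose donors and modification blocks must use edited components
    for e in job.entities:
        if e.glycan is None:
            continue
        g = e.glycan
        codes = e.ccd_codes
        for num in g.residue_numbering():
            res = g.residues[num]
            base, _ac, (leaving_atom, auto_removed) = resolve_ccd(res)
            if g.parent_linkage(num) is None or auto_removed:
                continue
            code = codes[num - 1]
            if code == base or code not in job.user_ccd_blocks:
                issues.append({"category": "missing-userCCD", "entity": e.id,
                               "residue": num, "code": base,
                               "reason": f"{leaving_atom} of {base} is not "
                                         "removed automatically"})
    return issues


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_json(job: AF3Job) -> str:
    """Canonical v2-dialect JSON; byte-stable across runs."""
    sequences = []
    for e in job.entities:
        if e.kind == "protein":
            block = {"id": e.id, "sequence": e.sequence}
            if e.protein_modifications:
                block["modifications"] = [
                    {"ptmType": t, "ptmPosition": p}
                    for t, p in e.protein_modifications]
            sequences.append({"protein": block})
        else:
            sequences.append({"ligand": {"id": e.id, "ccdCodes": list(e.ccd_codes)}})
    doc = {
        "dialect": "alphafold3",
        "version": 2,
        "name": job.name,
        "modelSeeds": list(job.model_seeds),
        "sequences": sequences,
        "bondedAtomPairs": [p.as_json() for p in job.bonded_atom_pairs],
    }
    if job.user_ccd_blocks:
        doc["userCCD"] = "\n".join(job.user_ccd_blocks[c]
                                   for c in sorted(job.user_ccd_blocks))
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def read_json(text: str) -> dict:
    """Generic JSON read-back (round-trip check helper)."""
    return json.loads(text)
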