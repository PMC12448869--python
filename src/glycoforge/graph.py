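"""Rooted-tree data model for glycan topologies.

A glycan is represented as a rooted directed acyclic graph (in practice a
tree) of monosaccharide residues joined by glycosidic linkages.  The root is
the reducing-end residue, whose anomeric carbon is either free or bonded to
the aglycone (protein side chain, lipid block, ...).  All residue indices are
1-based, matching AlphaFold 3 JSON residue indexing.

The canonical residue numbering used throughout the package (and in emitted
JSON) is breadth-first from the root, visiting the children of a branch point
in ascending acceptor-position order (O2 < O3 < O4 < O6).  This convention
uniquely reproduces the published numbering of the common N-glycans: the two
terminal galactoses of the biantennary G2 glycan land on indices 8 and 9, and
the 3-arm mannoses of M9 land on 4, 6 and 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque
from typing import Optional

from .errors import TopologyError, UnsupportedSugarError

#: Modification tokens understood by the model layer.
MOD_NAMES = ("sulfate", "phosphate", "acetyl", "methyl")

#: Default protein attachment atoms by attachment kind.
ATTACHMENT_DEFAULT_ATOM = {
    "N-linked": "ND2",
    "O-Ser": "OG",
    "O-Thr": "OG1",
}


@dataclass
class MonosaccharideResidue:
    """One monosaccharide (or open-chain polyol) node.

    Parameters
    ----------
    sugar_name : str
        Registry token, e.g. ``Glc``, ``GlcNAc``, ``Neu5Ac``, ``Rbo-ol``.
    absolute_config : str
        ``"D"`` or ``"L"``.
    ring_form : str
        ``"pyranose"``, ``"furanose"`` or ``"open-chain"``.
    anomer : str
        ``"alpha"``, ``"beta"``, or ``"none"`` (open-chain residues only).
    modifications : list of (int, str)
        Ring position plus modification token (``sulfate``, ``phosphate``,
        ``acetyl``, ``methyl``).
    """

    sugar_name: str
    absolute_config: str = "D"
    ring_form: str = "pyranose"
    anomer: str = "beta"
    modifications: list = field(default_factory=list)

    def key(self):
        return (self.sugar_name, self.absolute_config, self.ring_form, self.anomer)


@dataclass
class GlycosidicLinkage:
    """Directed glycosidic bond: donor anomeric carbon -> acceptor hydroxyl O."""

    donor_index: int
    acceptor_index: int
    acceptor_position: int
    donor_anomeric_carbon: str = "C1"


@dataclass
class AttachmentSpec:
    """How the reducing end is attached to a partner entity.

    ``kind`` determines a default ``partner_atom`` (N-linked -> ND2,
    O-Ser -> OG, O-Thr -> OG1) which may be overridden explicitly.
    """

    kind: str = "free"
    partner_entity: Optional[str] = None
    partner_residue: Optional[int] = None
    partner_atom: Optional[str] = None

    def resolved_atom(self) -> Optional[str]:
        if self.partner_atom is not None:
            return self.partner_atom
        return ATTACHMENT_DEFAULT_ATOM.get(self.kind)


class GlycanGraph:
    """Rooted tree of monosaccharide residues.

    Residues are stored 1-based; the first residue added becomes the root
    unless ``root_index`` is reassigned before linkages exist.
    """

    def __init__(self, attachment: Optional[AttachmentSpec] = None):
        self.residues: dict[int, MonosaccharideResidue] = {}
        self.linkages: list[GlycosidicLinkage] = []
        self.root_index: Optional[int] = None
        self.attachment = attachment or AttachmentSpec()
        self._next = 1

    # -- construction -------------------------------------------------

    def add_residue(self, residue: MonosaccharideResidue) -> int:
        """Append a residue; returns its stable 1-based index."""
        from .registry import lookup_definition  # deferred: avoid cycle

        definition = lookup_definition(residue.sugar_name)
        if definition is None:
            raise UnsupportedSugarError(f"unknown sugar name {residue.sugar_name!r}")
        for pos, mod in residue.modifications:
            if mod not in MOD_NAMES:
                raise UnsupportedSugarError(f"unknown modification {mod!r}")
            if pos not in definition.substitutable_positions:
                raise TopologyError(
                    f"{residue.sugar_name}: position {pos} cannot carry a "
                    f"{mod} modification (valid: {sorted(definition.substitutable_positions)})"
                )
        idx = self._next
        self.residues[idx] = residue
        self._next += 1
        if self.root_index is None:
            self.root_index = idx
        return idx

    def add_linkage(self, donor_index: int, acceptor_index: int,
                    acceptor_position: int) -> GlycosidicLinkage:
        """Record donor --(anomeric C)--> acceptor O<position>; keeps the tree a tree."""
        from .registry import lookup_definition

        for idx in (donor_index, acceptor_index):
            if idx not in self.residues:
                raise TopologyError(f"residue index {idx} does not exist")
        if donor_index == acceptor_index:
            raise TopologyError("self-linkage is not allowed")
        for lk in self.linkages:
            if lk.acceptor_index == acceptor_index and lk.acceptor_position == acceptor_position:
                raise TopologyError(
                    f"position {acceptor_position} of residue {acceptor_index} is occupied")
            if lk.donor_index == donor_index:
                raise TopologyError(f"residue {donor_index} is already a donor")
        acceptor = self.residues[acceptor_index]
        for pos, mod in acceptor.modifications:
            if pos == acceptor_position:
                raise TopologyError(
                    f"position {acceptor_position} of residue {acceptor_index} "
                    f"carries a {mod} modification")
        acc_def = lookup_definition(acceptor.sugar_name)
        if acceptor_position not in acc_def.substitutable_positions:
            raise TopologyError(
                f"{acceptor.sugar_name} has no linkable position {acceptor_position}")
        if self._would_cycle(donor_index, acceptor_index):
            raise TopologyError("linkage would create a cycle")
        donor = self.residues[donor_index]
        don_def = lookup_definition(donor.sugar_name)
        lk = GlycosidicLinkage(donor_index, acceptor_index, acceptor_position,
                               don_def.anomeric_carbon)
        self.linkages.append(lk)
        # the deepest residue on the acceptor path is the reducing end
        if donor_index == self.root_index:
            self.root_index = self._find_root()
        return lk

    def _would_cycle(self, donor, acceptor) -> bool:
        # walk from acceptor toward the reducing end; hitting donor = cycle
        parent = {lk.donor_index: lk.acceptor_index for lk in self.linkages}
        node = acceptor
        seen = set()
        while node in parent:
            if node in seen:  # pre-existing corruption; treat as cycle
                return True
            seen.add(node)
            node = parent[node]
            if node == donor:
                return True
        return False

    def _find_root(self):
        donors = {lk.donor_index for lk in self.linkages}
        candidates = [i for i in self.residues if i not in donors]
        if candidates:
            return min(candidates)
        return self.root_index

    # -- queries -------------------------------------------------------

    def children(self, index: int) -> list[GlycosidicLinkage]:
        """Linkages whose acceptor is ``index``, ascending acceptor position."""
        out = [lk for lk in self.linkages if lk.acceptor_index == index]
        out.sort(key=lambda lk: lk.acceptor_position)
        return out

    def parent_linkage(self, index: int) -> Optional[GlycosidicLinkage]:
        for lk in self.linkages:
            if lk.donor_index == index:
                return lk
        return None

    def residue_numbering(self) -> list[int]:
        """Breadth-first order from the root, children by ascending acceptor position.

        Returns the residue indices in canonical (published) numbering order;
        position ``k`` of the returned list is canonical residue ``k+1``.
        """
        if self.root_index is None:
            return []
        order = []
        queue = deque([self.root_index])
        while queue:
            node = queue.popleft()
            order.append(node)
            for lk in self.children(node):
                queue.append(lk.donor_index)
        return order

    def canonical_index(self) -> dict[int, int]:
        """Map internal residue index -> canonical 1-based number."""
        return {idx: n + 1 for n, idx in enumerate(self.residue_numbering())}

    def validate_graph(self) -> list[dict]:
        """Return a list of invariant violations; empty means the graph is valid."""
        from .registry import lookup_definition

        issues = []
        donors = {}
        for lk in self.linkages:
            if lk.donor_index not in self.residues or lk.acceptor_index not in self.residues:
                issues.append({"category": "dangling-linkage", "linkage": lk})
                continue
            donors.setdefault(lk.donor_index, 0)
            donors[lk.donor_index] += 1
            don_def = lookup_definition(self.residues[lk.donor_index].sugar_name)
            if don_def and lk.donor_anomeric_carbon != don_def.anomeric_carbon:
                issues.append({"category": "anomeric-carbon-mismatch",
                               "residue": lk.donor_index,
                               "expected": don_def.anomeric_carbon,
                               "found": lk.donor_anomeric_carbon})
        for idx, count in donors.items():
            if count > 1:
                issues.append({"category": "donor-reuse", "residue": idx})
        reachable = set(self.residue_numbering())
        for idx, res in self.residues.items():
            if idx not in reachable:
                issues.append({"category": "orphan-residue", "residue": idx})
            if res.anomer == "none" and res.ring_form != "open-chain":
                issues.append({"category": "anomer-missing", "residue": idx})
            if res.ring_form == "open-chain" and res.anomer != "none":
                issues.append({"category": "anomer-on-open-chain", "residue": idx})
        occupied = set()
        for lk in self.linkages:
            key = (lk.acceptor_index, lk.acceptor_position)
            if key in occupied:
                issues.append({"category": "occupied-position", "linkage": lk})
            occupied.add(key)
        return issues

    def canonicalized(self) -> "GlycanGraph":
        """Return an equivalent graph whose internal indices equal canonical numbering."""
        mapping = self.canonical_index()
        out = GlycanGraph(attachment=self.attachment)
        for old in sorted(mapping, key=mapping.get):
            out.residues[mapping[old]] = self.residues[old]
            out._next = max(out._next, mapping[old] + 1)
        out.root_index = mapping[self.root_index]
        for lk in sorted(self.linkages, key=lambda l: mapping[l.donor_index]):
            out.linkages.append(GlycosidicLinkage(
                mapping[lk.donor_index], mapping[lk.acceptor_index],
                lk.acceptor_position, lk.donor_anomeric_carbon))
        return out

    def __len__(self):
        return len(self.residues)


def modification_slots(graph: GlycanGraph) -> list:
    """Ordered modification slots of a glycan, as emitted in AF3 jobs.

    Modifications become extra residues appended after the sugars, ordered by
    (host canonical number, position).  Returns a list of
    ``(slot_number, host_number, position, mod_name)`` with 1-based slot
    numbers continuing the residue numbering.
    """
    canon = graph.canonical_index()
    mods = []
    for idx, res in graph.residues.items():
        for pos, mod_name in res.modifications:
            mods.append((canon[idx], pos, mod_name))
    mods.sort()
    n = len(graph.residues)
    return [(n + i + 1, host, pos, mod) for i, (host, pos, mod) in enumerate(mods)]
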