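"""Monosaccharide / lipid-block / modification registry.

Maps the package's sugar tokens to Chemical Component Dictionary (CCD) codes
per (absolute configuration, ring form, anomer), and records the chemistry
needed everywhere else:

* the anomeric carbon (C1 for aldoses, C2 for ketoses such as sialic acids),
* the leaving atom displaced on glycosidic bond formation (O1 for aldoses,
  O2 for ketoses) and whether AlphaFold 3 removes it automatically (it does
  for aldoses via the ``pdbx_leaving_atom_flag``, but not for ketoses — the
  reason sialic-acid donors need an edited component),
* the reference axial/equatorial substitution pattern of each stereocenter in
  the reference chair, from which ideal coordinates and chirality reference
  signs are derived.

Reference-build conventions: D-pyranoses are built in the 4C1 chair; L-sugars
are built as the mirror image of their D-configured pattern (which places them
in 1C4, their usual chair).  Orientation entries are therefore given for the
D-parent pattern.  For ketoses the anomeric C2 carries two exocyclic heavy
atoms (the carboxylate C1 and the glycosidic O2); the alpha anomer is built
with O2 axial, beta with O2 equatorial — a fixed package convention that the
validator applies consistently on both reference and model sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import UnsupportedSugarError


@dataclass(frozen=True)
class MonosaccharideDefinition:
    sugar_name: str
    default_config: str                      # "D" or "L"
    default_ring: str                        # "pyranose" / "furanose" / "open-chain"
    anomeric_carbon: str                     # "C1" or "C2"
    leaving_atom: str                        # "O1" or "O2"
    auto_removed: bool                       # AF3 strips it without a userCCD edit
    codes: dict                              # (config, ring, anomer) -> CCD code
    ring_atom_names: tuple                   # ring O first, then carbons (empty: open chain)
    ring_subs: tuple                         # ((ring_atom, sub_atom, "ax"|"eq"), ...)
    tails: tuple = ()                        # ((parent_atom, atom), ...) second shell, chain-extended
    substitutable_positions: frozenset = frozenset()
    anomeric_partner: Optional[str] = None   # second exocyclic heavy atom on a ketose C2
    mirror_for_L: bool = True                # L entries built as mirror of the D pattern

    def stereocenters(self) -> list:
        """Ring stereocenters with a defined heavy substituent, anomeric center first."""
        out = [self.anomeric_carbon]
        out += [ring_atom for ring_atom, _sub, _o in self.ring_subs
                if ring_atom != self.anomeric_carbon]
        return out

    def substituent_of(self, center: str):
        for ring_atom, sub, orient in self.ring_subs:
            if ring_atom == center:
                return sub, orient
        return None

    def position_atom(self, position: int) -> str:
        """Hydroxyl oxygen name for a linkage/modification position."""
        return f"O{position}"


def _hexose(name, codes, o2="eq", o3="eq", o4="eq", nitrogen2=False,
            deoxy6=False, uronic=False, config="D", positions=None):
    sub2 = ("N2" if nitrogen2 else "O2")
    ring_subs = [("C2", sub2, o2), ("C3", "O3", o3), ("C4", "O4", o4), ("C5", "C6", "eq")]
    tails = ()
    if uronic:
        tails = (("C6", "O6A"), ("C6", "O6B"))
        default_positions = {2, 3, 4}
    elif deoxy6:
        default_positions = {2, 3, 4}
    else:
        tails = (("C6", "O6"),)
        default_positions = {2, 3, 4, 6}
    if nitrogen2:
        default_positions.discard(2)
    return MonosaccharideDefinition(
        sugar_name=name, default_config=config, default_ring="pyranose",
        anomeric_carbon="C1", leaving_atom="O1", auto_removed=True,
        codes=codes, ring_atom_names=("O5", "C1", "C2", "C3", "C4", "C5"),
        ring_subs=tuple(ring_subs), tails=tails,
        substitutable_positions=frozenset(positions or default_positions))


def _pentose(name, codes, o2="eq", o3="eq", o4="eq", config="D"):
    return MonosaccharideDefinition(
        sugar_name=name, default_config=config, default_ring="pyranose",
        anomeric_carbon="C1", leaving_atom="O1", auto_removed=True,
        codes=codes, ring_atom_names=("O5", "C1", "C2", "C3", "C4", "C5"),
        ring_subs=(("C2", "O2", o2), ("C3", "O3", o3), ("C4", "O4", o4)),
        substitutable_positions=frozenset({2, 3, 4}))


def _sialic(name, codes, n5=True, deoxy3=True, positions=None):
    # nonulosonic acid: ring O6, anomeric C2, carboxylate C1, glycerol tail C7-C9
    ring_subs = [("C4", "O4", "eq"),
                 ("C5", "N5" if n5 else "O5", "eq"),
                 ("C6", "C7", "eq")]
    tails = (("C7", "O7"), ("C7", "C8"), ("C8", "O8"), ("C8", "C9"), ("C9", "O9"))
    return MonosaccharideDefinition(
        sugar_name=name, default_config="D", default_ring="pyranose",
        anomeric_carbon="C2", leaving_atom="O2", auto_removed=False,
        codes=codes, ring_atom_names=("O6", "C2", "C3", "C4", "C5", "C6"),
        ring_subs=tuple(ring_subs), tails=tails,
        substitutable_positions=frozenset(positions or {4, 7, 8, 9}),
        anomeric_partner="C1")


_DEFS = [
    _hexose("Glc", {("D", "pyranose", "alpha"): "GLC", ("D", "pyranose", "beta"): "BGC"}),
    _hexose("Gal", {("D", "pyranose", "alpha"): "GLA", ("D", "pyranose", "beta"): "GAL"},
            o4="ax"),
    _hexose("Man", {("D", "pyranose", "alpha"): "MAN", ("D", "pyranose", "beta"): "BMA"},
            o2="ax"),
    _hexose("GlcNAc", {("D", "pyranose", "alpha"): "NDG", ("D", "pyranose", "beta"): "NAG"},
            nitrogen2=True),
    _hexose("GalNAc", {("D", "pyranose", "alpha"): "A2G", ("D", "pyranose", "beta"): "NGA"},
            o4="ax", nitrogen2=True),
    _hexose("GlcN", {("D", "pyranose", "alpha"): "PA1", ("D", "pyranose", "beta"): "GCS"},
            nitrogen2=True),
    # 6-deoxy-L-galactose; built as the mirror of the D pattern below
    _hexose("Fuc", {("L", "pyranose", "alpha"): "FUC", ("L", "pyranose", "beta"): "FUL"},
            o4="ax", deoxy6=True, config="L"),
    # 6-deoxy-L-mannose
    _hexose("Rha", {("L", "pyranose", "alpha"): "RAM", ("L", "pyranose", "beta"): "RM4"},
            o2="ax", deoxy6=True, config="L"),
    _pentose("Xyl", {("D", "pyranose", "alpha"): "XYS", ("D", "pyranose", "beta"): "XYP"}),
    _pentose("Ara", {("L", "pyranose", "alpha"): "ARA", ("L", "pyranose", "beta"): "ARB"},
             o2="ax", o3="ax", config="L"),
    _hexose("GlcA", {("D", "pyranose", "alpha"): "GCU", ("D", "pyranose", "beta"): "BDP"},
            uronic=True),
    _hexose("GalA", {("D", "pyranose", "alpha"): "ADA", ("D", "pyranose", "beta"): "GTR"},
            o4="ax", uronic=True),
    _hexose("ManA", {("D", "pyranose", "alpha"): "MAV", ("D", "pyranose", "beta"): "BEM"},
            o2="ax", uronic=True),
    # L-iduronic acid: D-ido pattern (O2/O3/O4 axial in 4C1) mirrored
    _hexose("IdoA", {("L", "pyranose", "alpha"): "IDR"},
            o2="ax", o3="ax", o4="ax", uronic=True, config="L"),
    _sialic("Neu5Ac", {("D", "pyranose", "alpha"): "SIA", ("D", "pyranose", "beta"): "SLB"}),
    _sialic("Neu5Gc", {("D", "pyranose", "alpha"): "NGC", ("D", "pyranose", "beta"): "NGE"}),
    _sialic("Kdn", {("D", "pyranose", "alpha"): "KDN"}, n5=False,
            positions={4, 5, 7, 8, 9}),
    _sialic("Kdo", {("D", "pyranose", "alpha"): "KDO"}, n5=False,
            positions={4, 5, 7, 8}),
    # beta-D-ribofuranose; ring O4, anomeric C1
    MonosaccharideDefinition(
        sugar_name="Rib", default_config="D", default_ring="furanose",
        anomeric_carbon="C1", leaving_atom="O1", auto_removed=True,
        codes={("D", "furanose", "beta"): "BDR", ("D", "furanose", "alpha"): "RIB"},
        ring_atom_names=("O4", "C1", "C2", "C3", "C4"),
        ring_subs=(("C2", "O2", "ax"), ("C3", "O3", "ax"), ("C4", "C5", "eq")),
        tails=(("C5", "O5"),),
        substitutable_positions=frozenset({2, 3, 5})),
    # ribitol (open-chain pentitol); participates with positional linkage semantics
    MonosaccharideDefinition(
        sugar_name="Rbo-ol", default_config="D", default_ring="open-chain",
        anomeric_carbon="C1", leaving_atom="O1", auto_removed=True,
        codes={("D", "open-chain", "none"): "RBL"},
        ring_atom_names=(),
        ring_subs=(("C2", "O2", "eq"), ("C3", "O3", "eq"), ("C4", "O4", "eq")),
        tails=(),
        substitutable_positions=frozenset({1, 2, 3, 4, 5})),
]

REGISTRY: dict[str, MonosaccharideDefinition] = {d.sugar_name: d for d in _DEFS}


@dataclass(frozen=True)
class ModificationDefinition:
    """A small covalent decoration grafted onto a sugar hydroxyl.

    The sugar's bridging oxygen is retained; the modification component loses
    one of its own oxygens (plus that oxygen's hydrogen) so that the bridge O
    ends up with exactly two heavy-atom neighbours.
    """

    mod_name: str
    ccd_code: str
    bond_atom_on_mod: str
    leaving_atoms_on_mod: tuple


MODIFICATIONS: dict[str, ModificationDefinition] = {
    "sulfate": ModificationDefinition("sulfate", "SO4", "S", ("O1",)),
    "phosphate": ModificationDefinition("phosphate", "PO4", "P", ("O1",)),
    "acetyl": ModificationDefinition("acetyl", "ACY", "C", ("OXT",)),
    "methyl": ModificationDefinition("methyl", "MOH", "C", ("O",)),
}

#: Short-token forms used in the text notation ("6S", "2P", "9Ac", "3Me").
MOD_TOKEN = {"S": "sulfate", "P": "phosphate", "Ac": "acetyl", "Me": "methyl"}
MOD_TOKEN_INV = {v: k for k, v in MOD_TOKEN.items()}


@dataclass(frozen=True)
class LipidBlock:
    """Non-sugar building block used in glycolipid / GPI assemblies."""

    code: str
    name: str
    bond_atoms: tuple   # atoms this block is typically bonded through


LIPID_BLOCKS: dict[str, LipidBlock] = {
    "SPH": LipidBlock("SPH", "sphingosine", ("N", "O1", "O3")),
    "STE": LipidBlock("STE", "stearic acid", ("C1", "O1", "O2")),
    "OTP": LipidBlock("OTP", "octaprenyl pyrophosphate (dolichol-PP analog)",
                      ("O1", "O3B")),
    "GOL": LipidBlock("GOL", "glycerol", ("O1", "O2", "O3")),
    "PL3": LipidBlock("PL3", "palmityl alcohol", ("O1", "C1")),
    "IPD": LipidBlock("IPD", "inositol-1-phosphate", ("O2", "O6", "P1")),
    "ETA": LipidBlock("ETA", "ethanolamine", ("N", "O")),
    "PO4": LipidBlock("PO4", "phosphate", ("P", "O1", "O2", "O3", "O4")),
}


def lookup_definition(sugar_name: str) -> Optional[MonosaccharideDefinition]:
    return REGISTRY.get(sugar_name)


def resolve_ccd(residue) -> tuple:
    """Resolve a residue to ``(ccd_code, anomeric_carbon, (leaving_atom, auto_removed))``.

    The anomer is encoded purely by the code choice, never by geometry: the
    alpha and beta anomers of one sugar map to distinct CCD entries.
    """
    definition = lookup_definition(residue.sugar_name)
    if definition is None:
        raise UnsupportedSugarError(f"unknown sugar name {residue.sugar_name!r}")
    key = (residue.absolute_config, residue.ring_form, residue.anomer)
    code = definition.codes.get(key)
    if code is None:
        alternatives = ", ".join(
            f"{c}-{r}-{a} -> {code}" for (c, r, a), code in sorted(definition.codes.items()))
        raise UnsupportedSugarError(
            f"{residue.sugar_name} has no CCD code for {key}; supported: {alternatives}")
    return code, definition.anomeric_carbon, (definition.leaving_atom, definition.auto_removed)


def registry_codes() -> set:
    """Every CCD code the registry can emit (sugars, lipid blocks, modifications)."""
    codes = set()
    for d in REGISTRY.values():
        codes.update(d.codes.values())
    codes.update(LIPID_BLOCKS)
    codes.update(m.ccd_code for m in MODIFICATIONS.values())
    return codes


def definition_for_code(code: str):
    """Reverse lookup: CCD code -> (definition, config, ring, anomer) or None.

    Edited-component codes (base + 'X' suffix) resolve to their base entry.
    """
    for d in REGISTRY.values():
        for key, c in d.codes.items():
            if c == code:
                return (d, *key)
    if len(code) > 1 and code[-1] == "X" or (len(code) > 2 and code[-2] == "X"):
        base = code.rstrip("0123456789")
        if base.endswith("X"):
            return definition_for_code(base[:-1])
    return None


def resolvable_forms():
    """Iterate (definition, config, ring, anomer, code) over every registry tuple."""
    for d in REGISTRY.values():
        for (config, ring, anomer), code in sorted(d.codes.items()):
            yield d, config, ring, anomer, code
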