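"""IUPAC-condensed text grammar for glycan topologies.

Residue token grammar (read left to right; donors precede their acceptors)::

    [D-|L-] SugarName [<pos><Mod>...] [p|f] [a|b] [<d>-<a>]

* config prefix only when it differs from the sugar's SNFG default
  (Fuc, Rha, Ara, IdoA default L; everything else D);
* modification suffixes: ``6S`` (sulfate), ``2P`` (phosphate), ``9Ac``
  (acetyl), ``3Me`` (methyl);
* ring marker ``p``/``f`` only when it differs from the default ring form;
* anomer letter ``a``/``b``; the reducing-end residue may omit it (default
  beta); open-chain residues (``Rbo-ol``) carry no anomer letter;
* the trailing ``<d>-<a>`` linkage (e.g. ``1-4``, ``2-6``) names the donor
  anomeric position and the acceptor hydroxyl position; the reducing-end
  token has none;
* branches in square brackets attach to the residue written directly after
  the closing bracket, e.g. ``Mana1-6[Mana1-3]Manb1-4...``.

Examples: ``Galb1-4GlcNAcb1-3Galb1-4Glc`` (LNnT);
``Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6[Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3]Manb1-4GlcNAcb1-4GlcNAc``
(the disialylated biantennary N-glycan G2S2).

The grammar is unambiguous: ``parse(write(g)) == g`` for every supported
graph, and the serializer emits no whitespace while the parser ignores it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import NotationError
from .graph import GlycanGraph, MonosaccharideResidue
from .registry import MOD_TOKEN, MOD_TOKEN_INV, REGISTRY, lookup_definition

_NAMES = sorted(REGISTRY, key=len, reverse=True)
_TOKEN_RE = re.compile(
    r"(?P<config>[DL]-)?"
    r"(?P<name>" + "|".join(re.escape(n) for n in _NAMES) + r")"
    r"(?P<mods>(?:\d+(?:Ac|Me|S|P))*)"
    r"(?P<ring>[pf])?"
    r"(?P<anomer>[ab])?"
    r"(?:(?P<dpos>\d+)-(?P<apos>\d+))?")
_MOD_RE = re.compile(r"(\d+)(Ac|Me|S|P)")

_RING_NAME = {"p": "pyranose", "f": "furanose"}
_RING_MARK = {"pyranose": "p", "furanose": "f"}


@dataclass
class _Token:
    name: str
    config: Optional[str]
    ring: Optional[str]
    anomer: Optional[str]
    mods: list
    linkage: Optional[tuple]   # (donor_pos, acceptor_pos)
    offset: int


def _tokenize(text: str) -> list:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "[]":
            out.append(((ch, i), i))
            i += 1
            continue
        m = _TOKEN_RE.match(text, i)
        if not m or not m.group("name"):
            raise NotationError(f"syntax error at offset {i}: {text[i:i + 12]!r}",
                                offset=i)
        mods = [(int(p), MOD_TOKEN[c]) for p, c in _MOD_RE.findall(m.group("mods") or "")]
        linkage = None
        if m.group("dpos"):
            linkage = (int(m.group("dpos")), int(m.group("apos")))
        out.append((_Token(m.group("name"),
                           m.group("config")[0] if m.group("config") else None,
                           m.group("ring"), m.group("anomer"), mods, linkage, i), i))
        i = m.end()
    return [t for t, _ in out]


def _make_residue(tok: _Token) -> MonosaccharideResidue:
    definition = lookup_definition(tok.name)
    config = tok.config or definition.default_config
    ring = _RING_NAME.get(tok.ring, definition.default_ring)
    if definition.default_ring == "open-chain":
        if tok.anomer:
            raise NotationError(
                f"open-chain residue {tok.name} takes no anomer letter",
                offset=tok.offset)
        anomer = "none"
    else:
        anomer = {"a": "alpha", "b": "beta"}.get(tok.anomer, "beta")
    return MonosaccharideResidue(tok.name, config, ring, anomer, list(tok.mods))


def parse_iupac_condensed(text: str) -> GlycanGraph:
    """Parse IUPAC-condensed text into a canonical :class:`GlycanGraph`.

    Whitespace-insensitive.  Raises :class:`NotationError` with a character
    offset on syntax errors and :class:`UnsupportedSugarError` for unknown
    sugar tokens.
    """
    compact = "".join(text.split())
    if not compact:
        raise NotationError("empty glycan string", offset=0)
    tokens = _tokenize(compact)
    graph = GlycanGraph()
    _build_chain(tokens, graph, outer_acceptor=None)
    issues = graph.validate_graph()
    if issues:
        raise NotationError(f"inconsistent glycan topology: {issues}")
    return graph.canonicalized()


def _build_chain(tokens: list, graph: GlycanGraph, outer_acceptor) -> int:
    if not tokens:
        raise NotationError("empty (sub)chain", offset=0)
    tail = tokens.pop()
    if not isinstance(tail, _Token):
        raise NotationError("chain may not end with a bracket", offset=tail[1])
    rid = graph.add_residue(_make_residue(tail))
    if outer_acceptor is not None:
        if tail.linkage is None:
            raise NotationError("branch is missing its linkage", offset=tail.offset)
        _check_donor_position(tail, rid, graph)
        graph.add_linkage(rid, outer_acceptor, tail.linkage[1])
    elif tail.linkage is not None:
        raise NotationError("reducing-end residue cannot carry a linkage",
                            offset=tail.offset)
    acceptor = rid
    while tokens:
        top = tokens[-1]
        if isinstance(top, tuple) and top[0] == "]":
            depth = 0
            start = None
            for i in range(len(tokens) - 1, -1, -1):
                t = tokens[i]
                if isinstance(t, tuple):
                    depth += 1 if t[0] == "]" else -1
                    if depth == 0:
                        start = i
                        break
            if start is None:
                raise NotationError("unbalanced brackets", offset=top[1])
            group = tokens[start + 1:-1]
            del tokens[start:]
            _build_chain(group, graph, outer_acceptor=acceptor)
        elif isinstance(top, tuple):
            raise NotationError("unexpected '['", offset=top[1])
        else:
            tok = tokens.pop()
            if tok.linkage is None:
                raise NotationError("interior residue is missing its linkage",
                                    offset=tok.offset)
            donor = graph.add_residue(_make_residue(tok))
            _check_donor_position(tok, donor, graph)
            graph.add_linkage(donor, acceptor, tok.linkage[1])
            acceptor = donor
    return rid


def _check_donor_position(tok: _Token, rid: int, graph: GlycanGraph):
    definition = lookup_definition(tok.name)
    expected = int(definition.anomeric_carbon[1:])
    if tok.linkage[0] != expected:
        raise NotationError(
            f"{tok.name} links through C{expected}, not C{tok.linkage[0]}",
            offset=tok.offset)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_iupac_condensed(graph: GlycanGraph) -> str:
    """Canonical IUPAC-condensed text of a glycan graph.

    At branch points the highest-position arm is written in line and the
    remaining arms in brackets, ascending by position (the deepest-written
    chain is the leftmost).  ``parse(write(g)) == g``.
    """
    g = graph.canonicalized()
    if not g.residues:
        raise NotationError("cannot serialize an empty graph")

    def token(num: int) -> str:
        res = g.residues[num]
        definition = lookup_definition(res.sugar_name)
        parts = []
        if res.absolute_config != definition.default_config:
            parts.append(res.absolute_config + "-")
        parts.append(res.sugar_name)
        for pos, mod in sorted(res.modifications):
            parts.append(f"{pos}{MOD_TOKEN_INV[mod]}")
        if res.ring_form != definition.default_ring:
            parts.append(_RING_MARK[res.ring_form])
        lk = g.parent_linkage(num)
        is_root = num == g.root_index
        if res.anomer == "alpha":
            parts.append("a")
        elif res.anomer == "beta" and not is_root:
            parts.append("b")
        if lk is not None:
            parts.append(f"{int(definition.anomeric_carbon[1:])}-{lk.acceptor_position}")
        return "".join(parts)

    def subtree(num: int) -> str:
        children = g.children(num)
        parts = []
        if children:
            inline = children[-1]
            parts.append(subtree(inline.donor_index))
            for lk in children[:-1]:
                parts.append("[" + subtree(lk.donor_index) + "]")
        parts.append(token(num))
        return "".join(parts)

    return subtree(g.root_index)
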