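"""Parsing, canonical serialization and structural descriptors for milk
oligosaccharides written in IUPAC-condensed nomenclature.

Milk oligosaccharides (MOs) are free glycans built by elaborating a lactose
core (Galβ1-4Glc) at the reducing end.  IUPAC-condensed strings are written
from the non-reducing end towards the reducing end, with side branches in
parentheses bound to the residue immediately to their right, e.g.
``Fucα1-2(Neu5Acα2-6)Galβ1-4GlcNAc``.  A residue token may carry a sulfate
modification written as a position + ``S`` suffix (``Gal6S`` or ``Gal(6S)``).

The in-memory representation is a rooted tree: the root is the reducing-end
residue (the Glc of the lactose core when present); every other node points
to its parent through a :class:`Linkage`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Monosaccharide",
    "Linkage",
    "GlycanStructure",
    "GlycanComposition",
    "StructuralFeatures",
    "GlycanParseError",
    "parse_iupac",
    "write_iupac",
    "parse_composition",
    "composition_of",
    "structural_features",
    "is_isomorphic",
    "novelty_percentage",
]

#: Residue vocabulary. ``Hex``/``HexNAc`` are generic classes used in motif
#: patterns; concrete residues map onto them for class-level matching.
RESIDUE_VOCABULARY = ("Neu5Ac", "GlcNAc", "GalNAc", "HexNAc", "Hex", "Glc", "Gal", "Fuc")

#: Monosaccharide class of each residue (Hex / HexNAc / Fuc / Neu5Ac).
RESIDUE_CLASS = {
    "Glc": "Hex",
    "Gal": "Hex",
    "Hex": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "HexNAc": "HexNAc",
    "Fuc": "Fuc",
    "Neu5Ac": "Neu5Ac",
}


class GlycanParseError(ValueError):
    """Raised when an IUPAC-condensed string cannot be parsed."""


@dataclass(frozen=True)
class Monosaccharide:
    """A single residue: a base token plus optional carbon modifications.

    ``modifications`` is a frozenset of ``(carbon_position, kind)`` pairs;
    the only supported kind is ``"S"`` (sulfate).
    """

    base: str
    modifications: frozenset = frozenset()

    def __post_init__(self):
        if self.base not in RESIDUE_CLASS:
            raise GlycanParseError(f"unknown residue token {self.base!r}")
        positions = [p for p, _ in self.modifications]
        if len(positions) != len(set(positions)):
            raise GlycanParseError(
                f"residue {self.base} carries more than one modification on a carbon"
            )
        for p, kind in self.modifications:
            if not (1 <= p <= 9):
                raise GlycanParseError(f"modification position {p} out of range 1-9")
            if kind != "S":
                raise GlycanParseError(f"unsupported modification kind {kind!r}")

    @property
    def residue_class(self) -> str:
        return RESIDUE_CLASS[self.base]

    @property
    def token(self) -> str:
        mods = "".join(f"{p}{k}" for p, k in sorted(self.modifications))
        return f"{self.base}{mods}"


@dataclass(frozen=True)
class Linkage:
    """Glycosidic linkage of a child residue to its parent.

    ``anomeric`` is α, β or ``?``; carbons are integers or ``None`` for
    unknown.  Neu5Ac links through its anomeric carbon 2, hexoses and
    HexNAc through carbon 1.
    """

    anomeric: str = "?"
    child_carbon: Optional[int] = None
    parent_carbon: Optional[int] = None

    def __post_init__(self):
        if self.anomeric not in ("α", "β", "?"):
            raise GlycanParseError(f"bad anomeric configuration {self.anomeric!r}")

    def __str__(self) -> str:
        cc = "?" if self.child_carbon is None else str(self.child_carbon)
        pc = "?" if self.parent_carbon is None else str(self.parent_carbon)
        return f"{self.anomeric}{cc}-{pc}"


class GlycanStructure:
    """Rooted tree of monosaccharides.

    Node identifiers are integers assigned in parse order (left to right in
    the serialized string); identity of identifiers is an artifact of
    serialization — structural equality is tree isomorphism, tested through
    the canonical string (see :func:`write_iupac`).
    """

    def __init__(self):
        self.nodes: dict[int, Monosaccharide] = {}
        self.parent: dict[int, tuple[int, Linkage]] = {}
        self.children: dict[int, list[int]] = {}
        self.root: Optional[int] = None
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add_node(self, residue: Monosaccharide) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = residue
        self.children[nid] = []
        return nid

    def add_edge(self, child: int, parent: int, linkage: Linkage) -> None:
        if child in self.parent:
            raise GlycanParseError("node already has a parent")
        if self.nodes[child].base == "Neu5Ac" and linkage.child_carbon not in (None, 2):
            raise GlycanParseError("Neu5Ac links through carbon 2")
        for sib in self.children[parent]:
            sib_pc = self.parent[sib][1].parent_carbon
            if sib_pc is not None and sib_pc == linkage.parent_carbon:
                raise GlycanParseError(
                    f"two children of a residue share parent carbon {sib_pc}"
                )
        self.parent[child] = (parent, linkage)
        self.children[parent].append(child)

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self.nodes)

    def linkage(self, child: int) -> Linkage:
        return self.parent[child][1]

    def leaves(self) -> list[int]:
        return [n for n in self.nodes if not self.children[n]]

    def subtree_size(self, node: int) -> int:
        return 1 + sum(self.subtree_size(c) for c in self.children[node])

    def __repr__(self) -> str:
        return f"GlycanStructure({write_iupac(self)!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return write_iupac(self) == write_iupac(other)

    def __hash__(self) -> int:
        return hash(write_iupac(self))


# ---------------------------------------------------------------------------
# parsing

_RESIDUE_RE = re.compile("|".join(RESIDUE_VOCABULARY))
_MOD_RE = re.compile(r"(\d)S|\((\d)S\)")
_LINKAGE_RE = re.compile(r"([αβab?])([\d?])-([\d?])")


def _parse_linkage(m: re.Match) -> Linkage:
    ano = {"a": "α", "b": "β"}.get(m.group(1), m.group(1))
    cc = None if m.group(2) == "?" else int(m.group(2))
    pc = None if m.group(3) == "?" else int(m.group(3))
    return Linkage(ano, cc, pc)


def parse_iupac(text: str) -> GlycanStructure:
    """Parse an IUPAC-condensed glycan string into a rooted tree.

    The rightmost residue becomes the root (reducing end).  Whitespace is
    ignored; branch nesting is supported to arbitrary depth; both Greek α/β
    and ASCII a/b anomeric letters and both ``Gal6S`` and ``Gal(6S)``
    sulfate spellings are accepted.  ``?`` marks unknown anomericity or
    carbon positions.

    Raises :class:`GlycanParseError` (naming the offset or token) on
    unbalanced parentheses, unknown residues or malformed linkages.
    """
    s = re.sub(r"\s+", "", text)
    if not s:
        raise GlycanParseError("empty glycan string")
    g = GlycanStructure()
    root, trailing, pos = _parse_chain(g, s, 0)
    if trailing is not None:
        raise GlycanParseError("dangling linkage at end of string")
    if pos != len(s):
        raise GlycanParseError(f"unexpected {s[pos]!r} at offset {pos}")
    g.root = root
    return g


def _parse_chain(g: GlycanStructure, s: str, pos: int):
    """Parse one chain; returns (chain root id, trailing linkage, new pos).

    A trailing linkage is present when the chain is a parenthesized branch
    (the linkage that binds the branch to the residue right of the parens).
    """
    carry: list[tuple[int, Linkage]] = []  # subtrees awaiting their parent
    while True:
        if pos >= len(s):
            raise GlycanParseError(f"unexpected end of string at offset {pos}")
        if s[pos] == "(":
            # sulfate spelled "(6S)" belongs to the preceding residue and is
            # consumed by the residue tokenizer; here "(" always opens a branch
            branch_root, branch_link, pos = _parse_chain(g, s, pos + 1)
            if pos >= len(s) or s[pos] != ")":
                raise GlycanParseError(f"unbalanced parenthesis at offset {pos}")
            if branch_link is None:
                raise GlycanParseError(f"branch without linkage before offset {pos}")
            pos += 1
            carry.append((branch_root, branch_link))
            continue
        if s[pos] == ")":
            raise GlycanParseError(f"unbalanced parenthesis at offset {pos}")

        m = _RESIDUE_RE.match(s, pos)
        if m is None:
            bad = re.match(r"[A-Za-z0-9']+", s[pos:])
            tok = bad.group(0) if bad else s[pos]
            raise GlycanParseError(f"unknown residue token {tok!r} at offset {pos}")
        base = m.group(0)
        pos = m.end()
        mods = set()
        while True:
            mm = _MOD_RE.match(s, pos)
            if mm is None:
                break
            p = int(mm.group(1) or mm.group(2))
            mods.add((p, "S"))
            pos = mm.end()
        node = g.add_node(Monosaccharide(base, frozenset(mods)))
        for child, link in carry:
            g.add_edge(child, node, link)
        carry = []

        if pos >= len(s) or s[pos] == ")":
            return node, None, pos
        lm = _LINKAGE_RE.match(s, pos)
        if lm is None:
            raise GlycanParseError(f"malformed linkage at offset {pos}")
        link = _parse_linkage(lm)
        pos = lm.end()
        if pos >= len(s) or s[pos] == ")":
            return node, link, pos
        carry.append((node, link))


# ---------------------------------------------------------------------------
# canonical serialization


def write_iupac(g: GlycanStructure) -> str:
    """Serialize to the canonical IUPAC-condensed string.

    Canonical branch order: at every residue the child subtree with the most
    residues stays on the main chain (outside parentheses); ties break by
    smaller parent carbon outside.  ``parse_iupac(write_iupac(g))`` is
    isomorphic to ``g``.
    """
    if g.root is None:
        raise ValueError("structure has no root")
    return _write_node(g, g.root)


def _write_node(g: GlycanStructure, node: int) -> str:
    kids = g.children[node]
    tok = g.nodes[node].token
    if not kids:
        return tok

    def sort_key(c):
        link = g.linkage(c)
        pc = link.parent_carbon if link.parent_carbon is not None else 10
        return (-g.subtree_size(c), pc, _write_node(g, c), str(link))

    ordered = sorted(kids, key=sort_key)
    main, rest = ordered[0], ordered[1:]
    out = _write_node(g, main) + str(g.linkage(main))
    for c in rest:
        out += f"({_write_node(g, c)}{g.linkage(c)})"
    return out + tok


def is_isomorphic(a: GlycanStructure, b: GlycanStructure) -> bool:
    """Label- and linkage-preserving tree isomorphism."""
    return write_iupac(a) == write_iupac(b)


# ---------------------------------------------------------------------------
# compositions


@dataclass
class GlycanComposition:
    """Residue-class counts of a glycan; structure-free.

    Compositions stand in for partially characterized glycans measured by
    mass only (e.g. ``Neu5Ac6Hex12HexNAc10``); they can appear in abundance
    tables but not in motif matching.
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neu5ac: int = 0
    sulfate_count: int = 0

    @property
    def size(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neu5ac

    def __post_init__(self):
        if min(self.hex, self.hexnac, self.fuc, self.neu5ac, self.sulfate_count) < 0:
            raise ValueError("composition counts must be non-negative")


_COMP_FIELD = {"Hex": "hex", "HexNAc": "hexnac", "Fuc": "fuc", "Neu5Ac": "neu5ac", "S": "sulfate_count"}
_COMP_RE = re.compile(r"(Neu5Ac|HexNAc|Hex|Fuc|S)_?(\d+)_?")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``Neu5Ac6Hex12HexNAc10``.

    Underscore-delimited spellings (``Neu5Ac_6_Hex_12_``) are accepted.
    """
    s = re.sub(r"\s+", "", text)
    comp = GlycanComposition()
    pos = 0
    while pos < len(s):
        m = _COMP_RE.match(s, pos)
        if m is None:
            bad = re.match(r"[A-Za-z05']+", s[pos:])
            raise GlycanParseError(
                f"unknown composition token {bad.group(0) if bad else s[pos]!r}"
            )
        setattr(comp, _COMP_FIELD[m.group(1)], int(m.group(2)))
        pos = m.end()
    return comp


def composition_of(g: GlycanStructure) -> GlycanComposition:
    """Project a structure onto residue-class counts (Glc/Gal → Hex etc.)."""
    comp = GlycanComposition()
    for nid, res in g.nodes.items():
        attr = _COMP_FIELD[res.residue_class]
        setattr(comp, attr, getattr(comp, attr) + 1)
        comp.sulfate_count += sum(1 for _, k in res.modifications if k == "S")
    return comp


# ---------------------------------------------------------------------------
# structural descriptors


@dataclass
class StructuralFeatures:
    size: int
    branch_points: int
    max_depth: int
    terminal_residues: list


def structural_features(g: GlycanStructure, backbone_only: bool = False) -> StructuralFeatures:
    """Size, branching and depth descriptors of a structure.

    ``branch_points`` counts residues with at least two children; with
    ``backbone_only`` decorations (Fuc, Neu5Ac children) are excluded from
    the child count so that only backbone (Hex/HexNAc) bifurcations count.
    ``max_depth`` is the longest root-to-leaf path in edges;
    ``terminal_residues`` are the non-reducing-end leaves.
    """
    branch_points = 0
    for n in g.nodes:
        kids = g.children[n]
        if backbone_only:
            kids = [c for c in kids if g.nodes[c].residue_class in ("Hex", "HexNAc")]
        if len(kids) >= 2:
            branch_points += 1

    def depth(n):
        return 0 if not g.children[n] else 1 + max(depth(c) for c in g.children[n])

    terminals = [n for n in g.leaves() if n != g.root]
    return StructuralFeatures(len(g), branch_points, depth(g.root), terminals)


def novelty_percentage(n_novel: int, n_characterized: int) -> int:
    """Share of characterized structures that are previously unreported,
    as an integer percent."""
    if n_characterized <= 0:
        raise ValueError("need at least one characterized structure")
    return round(100 * n_novel / n_characterized)
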