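"""Named glycan motifs and terminal-constrained subtree matching.

A motif is a small glycan pattern (possibly using the generic classes Hex /
HexNAc and unknown linkages as wildcards) searched for inside full
structures.  Matching is injective, child-to-parent-edge preserving subtree
embedding; every embedding is one occurrence and overlapping occurrences
all count.  Motif *quantities* per sample are the occurrence counts
weighted by glycan relative abundances.

The built-in library transcribes the classic milk-oligosaccharide epitopes
(Lewis X/Y, H/B/Galili antigens, I/i antigens, LacdiNAc, sialyl-H variants,
keratan-sulfate-like units) as standard immunochemical definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .structures import (
    GlycanComposition,
    GlycanStructure,
    Linkage,
    parse_iupac,
)

__all__ = [
    "MotifDefinition",
    "MotifLibrary",
    "MotifOccurrence",
    "ForbiddenChild",
    "match_motif",
    "annotate",
    "terminal_motifs",
    "quantify_motifs",
    "builtin_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForbiddenChild:
    """Negative constraint: the structure node matched by pattern node
    ``node_index`` (parse-order id in the first pattern variant) must have
    no child through a linkage with this parent carbon (and anomeric /
    base, when given) — used e.g. to keep the i antigen strictly linear."""

    node_index: int
    parent_carbon: int
    anomeric: Optional[str] = None
    base: Optional[str] = None


@dataclass
class MotifDefinition:
    """A named pattern with a terminal constraint.

    ``patterns`` may hold several variant strings (e.g. the type-2 H
    antigen accepts GlcNAc or Glc at the reducing position); occurrences
    are pooled over variants.  ``terminal_constraint``:

    * ``"terminal"`` — every pattern leaf must map to a non-reducing
      terminal residue of the structure;
    * ``"internal"`` — at least one pattern leaf maps to a non-terminal;
    * ``"anywhere"`` — no constraint.
    """

    name: str
    patterns: list
    terminal_constraint: str = "anywhere"
    reducing_end_open: bool = True
    forbidden: tuple = ()

    def __post_init__(self):
        if self.terminal_constraint not in ("terminal", "internal", "anywhere"):
            raise ValueError(f"bad terminal_constraint {self.terminal_constraint!r}")
        if isinstance(self.patterns, str):
            self.patterns = [self.patterns]
        self._trees = [parse_iupac(p) for p in self.patterns]


class MotifLibrary:
    """Ordered collection of uniquely named motif definitions."""

    def __init__(self, definitions):
        self.definitions = list(definitions)
        names = [d.name for d in self.definitions]
        if len(names) != len(set(names)):
            raise ValueError("duplicate motif names in library")

    def __iter__(self):
        return iter(self.definitions)

    def __len__(self):
        return len(self.definitions)

    def names(self):
        return [d.name for d in self.definitions]

    def __getitem__(self, name: str) -> MotifDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass
class MotifOccurrence:
    """One embedding of a pattern: pattern node id → structure node id."""

    motif: str
    mapping: dict


# ---------------------------------------------------------------------------
# matching

_HEX = {"Glc", "Gal", "Hex"}
_HEXNAC = {"GlcNAc", "GalNAc", "HexNAc"}


def _residue_matches(pattern_base, structure_base):
    if pattern_base == "Hex":
        return structure_base in _HEX
    if pattern_base == "HexNAc":
        return structure_base in _HEXNAC
    return pattern_base == structure_base


def _linkage_matches(pat: Linkage, struct: Linkage) -> bool:
    # unknown components of the *pattern* are wildcards; unknown components
    # of the structure match nothing but a wildcard
    if pat.anomeric != "?" and pat.anomeric != struct.anomeric:
        return False
    if pat.child_carbon is not None and pat.child_carbon != struct.child_carbon:
        return False
    if pat.parent_carbon is not None and pat.parent_carbon != struct.parent_carbon:
        return False
    return True


def _node_matches(pat_res, struct_res, mode):
    if not _residue_matches(pat_res.base, struct_res.base):
        return False
    if mode == "ignore_modifications":
        return True
    return pat_res.modifications == struct_res.modifications


def _embed(pattern, g, p_node, s_node, mapping, mode):
    """Extend ``mapping`` with p_node→s_node and all pattern descendants;
    yields every completed mapping."""
    if not _node_matches(pattern.nodes[p_node], g.nodes[s_node], mode):
        return
    mapping = dict(mapping)
    mapping[p_node] = s_node
    p_kids = pattern.children[p_node]
    if not p_kids:
        yield mapping
        return
    s_kids = g.children[s_node]

    def assign(i, current, used):
        if i == len(p_kids):
            yield current
            return
        pc = p_kids[i]
        for sc in s_kids:
            if sc in used:
                continue
            if not _linkage_matches(pattern.linkage(pc), g.linkage(sc)):
                continue
            for m2 in _embed(pattern, g, pc, sc, current, mode):
                yield from assign(i + 1, m2, used | {sc})

    yield from assign(0, mapping, frozenset())


def _forbidden_ok(g, mapping, forbidden):
    for fb in forbidden:
        s_node = mapping.get(fb.node_index)
        if s_node is None:
            continue
        for child in g.children[s_node]:
            link = g.linkage(child)
            if link.parent_carbon != fb.parent_carbon:
                continue
            if fb.anomeric is not None and link.anomeric != fb.anomeric:
                continue
            if fb.base is not None and g.nodes[child].base != fb.base:
                continue
            return False
    return True


def match_motif(
    g: GlycanStructure,
    motif: MotifDefinition,
    mode: str = "strict",
    terminal_constraint: Optional[str] = None,
) -> list:
    """All occurrences of ``motif`` in ``g``.

    ``mode`` is ``"strict"`` (a pattern residue without modifications only
    matches an unmodified residue) or ``"ignore_modifications"``.
    ``terminal_constraint`` overrides the definition's own constraint.
    """
    if isinstance(g, GlycanComposition):
        raise TypeError("composition-only records cannot be motif-matched")
    if mode not in ("strict", "ignore_modifications"):
        raise ValueError(f"bad mode {mode!r}")
    constraint = terminal_constraint or motif.terminal_constraint
    occurrences = []
    for variant_idx, pattern in enumerate(motif._trees):
        candidates = list(g.nodes) if motif.reducing_end_open else [g.root]
        for s_root in candidates:
            for mapping in _embed(pattern, g, pattern.root, s_root, {}, mode):
                leaf_images = [mapping[leaf] for leaf in pattern.leaves()]
                is_terminal = [not g.children[s] for s in leaf_images]
                if constraint == "terminal" and not all(is_terminal):
                    continue
                if constraint == "internal" and all(is_terminal):
                    continue
                if variant_idx == 0 and not _forbidden_ok(g, mapping, motif.forbidden):
                    continue
                occurrences.append(MotifOccurrence(motif.name, mapping))
    return occurrences


def annotate(g: GlycanStructure, library: MotifLibrary, mode: str = "strict") -> dict:
    """Occurrence count per motif name; zero-count motifs included."""
    return {d.name: len(match_motif(g, d, mode)) for d in library}


def terminal_motifs(g: GlycanStructure, library: MotifLibrary, mode: str = "strict") -> set:
    """Names of library motifs present with terminal-constrained matching."""
    return {
        d.name
        for d in library
        if match_motif(g, d, mode, terminal_constraint="terminal")
    }


# ---------------------------------------------------------------------------
# abundance-weighted quantification

_SIZE_BINS = (("size_S", 0, 5), ("size_M", 6, 12), ("size_L", 13, 10**9))


def quantify_motifs(
    table,
    structures: dict,
    library: MotifLibrary,
    mode: str = "strict",
    feature_sets=("known",),
    presence_only: bool = False,
):
    """Abundance-weighted motif quantities per sample.

    A motif's quantity in a sample is Σ over glycans of (occurrence count ×
    glycan relative abundance); with ``presence_only`` the count is capped
    at 1.  ``structures`` maps each glycan column of ``table`` to a
    :class:`GlycanStructure` or a :class:`GlycanComposition`
    (composition-only glycans are excluded from motif features with a
    logged warning).  Feature sets: ``"known"`` (the motif library) and
    ``"size_branch"`` (size-bin and branch-count columns).

    Returns an object of the same table type with motif columns and the
    original sample metadata.
    """
    from .tables import AbundanceTable

    glycans = list(table.data.columns)
    missing = [g for g in glycans if g not in structures]
    if missing:
        raise KeyError(f"no structure or composition for columns: {missing}")
    structured = [g for g in glycans if isinstance(structures[g], GlycanStructure)]
    comp_only = [g for g in glycans if not isinstance(structures[g], GlycanStructure)]
    if comp_only:
        logger.warning(
            "excluding %d composition-only glycans from motif quantification: %s",
            len(comp_only),
            comp_only,
        )

    blocks = []
    if "known" in feature_sets:
        counts = np.zeros((len(structured), len(library)))
        for i, g in enumerate(structured):
            ann = annotate(structures[g], library, mode)
            counts[i] = [ann[name] for name in library.names()]
        if presence_only:
            counts = np.minimum(counts, 1)
        known = pd.DataFrame(
            table.data[structured].to_numpy() @ counts,
            index=table.data.index,
            columns=library.names(),
        )
        blocks.append(known)
    if "size_branch" in feature_sets:
        from .structures import structural_features

        feats = {name: np.zeros(len(structured)) for name, _, _ in _SIZE_BINS}
        branches = {}
        for i, g in enumerate(structured):
            f = structural_features(structures[g])
            for name, lo, hi in _SIZE_BINS:
                if lo <= f.size <= hi:
                    feats[name][i] = 1
            branches.setdefault(f"branches_{min(f.branch_points, 2)}", np.zeros(len(structured)))[i] = 1
        cols = {**feats, **branches}
        sb = pd.DataFrame(
            table.data[structured].to_numpy() @ np.column_stack(list(cols.values())),
            index=table.data.index,
            columns=list(cols),
        )
        blocks.append(sb)
    if not blocks:
        raise ValueError("no feature set selected")
    return AbundanceTable(pd.concat(blocks, axis=1), table.meta.copy())


# ---------------------------------------------------------------------------
# built-in library


def builtin_library() -> MotifLibrary:
    """The standard milk-oligosaccharide epitope library."""
    L = Linkage
    defs = [
        MotifDefinition("Lewis X", "Galβ1-4(Fucα1-3)GlcNAc"),
        MotifDefinition("Sialyl-Lewis X", "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc"),
        MotifDefinition("Lewis Y", "Fucα1-2Galβ1-4(Fucα1-3)GlcNAc"),
        MotifDefinition(
            "type-2 H antigen",
            ["Fucα1-2Galβ1-4HexNAc", "Fucα1-2Galβ1-4Glc"],
            terminal_constraint="terminal",
        ),
        MotifDefinition("B antigen", "Galα1-3(Fucα1-2)Gal"),
        MotifDefinition(
            "Galili antigen",
            "Galα1-3Gal",
            terminal_constraint="terminal",
            # true Galili excludes the fucosylated (B-antigen) form
            forbidden=(ForbiddenChild(node_index=1, parent_carbon=2, base="Fuc"),),
        ),
        MotifDefinition("I antigen", "Galβ1-4GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)Gal"),
        MotifDefinition(
            "i antigen",
            "Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAc",
            # linear poly-LacNAc: no β1-6 branch on the internal Gal
            forbidden=(ForbiddenChild(node_index=2, parent_carbon=6),),
        ),
        MotifDefinition("terminal LacdiNAc", "GalNAcβ1-4GlcNAc", terminal_constraint="terminal"),
        MotifDefinition("internal LacdiNAc", "GalNAcβ1-4GlcNAc", terminal_constraint="internal"),
        MotifDefinition(
            "proximal type-2 sialyl-H",
            ["Fucα1-2(Neu5Acα2-6)Galβ1-4GlcNAc", "Fucα1-2(Neu5Acα2-6)Galβ1-4Glc"],
        ),
        MotifDefinition("distal type-2 sialyl-H", "Fucα1-2Galβ1-4(Neu5Acα2-6)GlcNAc"),
        MotifDefinition("keratan sulfate unit", "Galβ1-4GlcNAc6S"),
        MotifDefinition("poly-LacNAc", "Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAc"),
        MotifDefinition("Neu5Ac(a2-3)Gal", "Neu5Acα2-3Gal"),
        MotifDefinition("Neu5Ac(a2-6)Gal", "Neu5Acα2-6Gal"),
        MotifDefinition("Fuc(a1-2)Gal", "Fucα1-2Gal"),
        MotifDefinition("Fuc(a1-3)GlcNAc", "Fucα1-3GlcNAc"),
        MotifDefinition("Sda", "Neu5Acα2-3(GalNAcβ1-4)Gal"),
    ]
    return MotifLibrary(defs)
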