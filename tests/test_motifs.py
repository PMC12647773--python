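"""Motif matching against a brute-force embedding enumerator, plus
annotation and abundance-weighted quantification."""

import itertools

import numpy as np
import pandas as pd
import pytest

import glycolac as gl
from glycolac.motifs import MotifDefinition, _linkage_matches, _node_matches
from glycolac.structures import GlycanStructure, Linkage, Monosaccharide

from conftest import SEAL_STRUCTURE_STRINGS, random_structures


def brute_force_count(g, pattern, mode="strict", constraint="anywhere"):
    """Independent oracle: enumerate every injective node assignment and
    keep those that preserve edges, classes, linkages and modifications."""
    p_nodes = list(pattern.nodes)
    count = 0
    for combo in itertools.permutations(list(g.nodes), len(p_nodes)):
        mapping = dict(zip(p_nodes, combo))
        ok = all(
            _node_matches(pattern.nodes[p], g.nodes[mapping[p]], mode) for p in p_nodes
        )
        if ok:
            for child, (parent, link) in pattern.parent.items():
                sc, sp = mapping[child], mapping[parent]
                if sc not in g.parent or g.parent[sc][0] != sp:
                    ok = False
                    break
                if not _linkage_matches(link, g.linkage(sc)):
                    ok = False
                    break
        if ok:
            leaf_terminal = [not g.children[mapping[l]] for l in pattern.leaves()]
            if constraint == "terminal" and not all(leaf_terminal):
                ok = False
            elif constraint == "internal" and all(leaf_terminal):
                ok = False
        count += ok
    return count


def random_pattern(rng, max_nodes=4):
    bases = ["Glc", "Gal", "GlcNAc", "GalNAc", "Fuc", "Neu5Ac", "Hex", "HexNAc"]
    g = GlycanStructure()
    mods = frozenset({(6, "S")}) if rng.random() < 0.15 else frozenset()
    root = g.add_node(Monosaccharide(rng.choice(bases), mods))
    g.root = root
    for _ in range(rng.integers(0, max_nodes - 1)):
        parent = int(rng.choice(list(g.nodes)))
        base = rng.choice(bases)
        cc = 2 if base == "Neu5Ac" else 1
        link = Linkage(
            rng.choice(["α", "β", "?"]),
            None if rng.random() < 0.2 else cc,
            None if rng.random() < 0.2 else int(rng.integers(2, 7)),
        )
        try:
            node = g.add_node(Monosaccharide(base))
            g.add_edge(node, parent, link)
        except Exception:
            del g.nodes[node], g.children[node]
    return g


class TestMatchExamples:
    def test_pattern_equal_to_target(self):
        s = "Fucα1-2Galβ1-4(Neu5Acα2-6)GlcNAc"
        m = MotifDefinition("self", s)
        assert len(gl.match_motif(gl.parse_iupac(s), m)) == 1

    def test_modification_rule_strict_vs_ignore(self):
        g = gl.parse_iupac("Fucα1-2Gal6Sβ1-4Glc")
        m = MotifDefinition("fuc-gal", "Fucα1-2Gal", terminal_constraint="terminal")
        assert gl.match_motif(g, m, mode="strict") == []
        assert len(gl.match_motif(g, m, mode="ignore_modifications")) == 1

    def test_residue_mismatch(self):
        g = gl.parse_iupac("Galβ1-4GlcNAc")
        m = MotifDefinition("ldn", "GalNAcβ1-4GlcNAc")
        assert gl.match_motif(g, m) == []

    def test_generic_classes_match_concrete_residues(self):
        g = gl.parse_iupac("Galβ1-4GlcNAc")
        m = MotifDefinition("lacnac-generic", "Hexβ1-4HexNAc")
        assert len(gl.match_motif(g, m)) == 1

    def test_composition_only_input_rejected(self):
        comp = gl.parse_composition("Hex2")
        m = MotifDefinition("lac", "Galβ1-4Glc")
        with pytest.raises(TypeError):
            gl.match_motif(comp, m)


class TestOracleEquivalence:
    def test_matcher_equals_brute_force_enumeration(self):
        """Fuzz: occurrence counts equal exhaustive embedding enumeration
        on structures ≤8 residues and patterns ≤4 residues."""
        rng = np.random.default_rng(42)
        donors = random_structures(seed=7, n=120, max_size=7, p_sulf6_glcnac=0.3)
        donors = [g for g in donors if len(g) <= 8]
        mismatches = 0
        for i in range(300):
            g = donors[int(rng.integers(len(donors)))]
            pattern = random_pattern(rng)
            mode = rng.choice(["strict", "ignore_modifications"])
            constraint = rng.choice(["anywhere", "terminal", "internal"])
            m = MotifDefinition("fuzz", gl.write_iupac(pattern), constraint)
            m._trees = [pattern]  # keep exact pattern (incl. wildcards)
            got = len(gl.match_motif(g, m, mode=mode))
            want = brute_force_count(g, pattern, mode, constraint)
            mismatches += got != want
        assert mismatches == 0

    def test_monotonicity_under_extension(self):
        """Adding residues never removes unconstrained occurrences."""
        lib = gl.builtin_library()
        small = gl.parse_iupac("Fucα1-2Galβ1-4GlcNAc")
        big = gl.parse_iupac("Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4Glc")
        for d in lib:
            if d.terminal_constraint != "anywhere":
                continue
            assert len(gl.match_motif(big, d)) >= len(gl.match_motif(small, d))


class TestAnnotate:
    def test_lactose_has_no_epitopes(self, library):
        counts = gl.annotate(gl.parse_iupac("Galβ1-4Glc"), library)
        assert set(counts) == set(library.names())
        assert all(v == 0 for v in counts.values())

    def test_proximal_vs_distal_sialyl_h(self, library):
        prox = gl.annotate(gl.parse_iupac("Fucα1-2(Neu5Acα2-6)Galβ1-4GlcNAc"), library)
        assert prox["proximal type-2 sialyl-H"] == 1
        assert prox["distal type-2 sialyl-H"] == 0
        dist = gl.annotate(gl.parse_iupac("Fucα1-2Galβ1-4(Neu5Acα2-6)GlcNAc"), library)
        assert dist["proximal type-2 sialyl-H"] == 0
        assert dist["distal type-2 sialyl-H"] == 1

    def test_linear_polylacnac_is_i_not_I(self, library):
        counts = gl.annotate(gl.parse_iupac("Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAc"), library)
        assert counts["i antigen"] == 1
        assert counts["I antigen"] == 0

    def test_branched_polylacnac_is_I_not_i(self, library):
        s = "Galβ1-4GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)Galβ1-4Glc"
        counts = gl.annotate(gl.parse_iupac(s), library)
        assert counts["I antigen"] == 1
        assert counts["i antigen"] == 0

    @pytest.mark.parametrize(
        "s,motif",
        [
            ("Galβ1-4(Fucα1-3)GlcNAc", "Lewis X"),
            ("Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc", "Sialyl-Lewis X"),
            ("Fucα1-2Galβ1-4(Fucα1-3)GlcNAc", "Lewis Y"),
            ("Fucα1-2Galβ1-4GlcNAc", "type-2 H antigen"),
            ("Galα1-3(Fucα1-2)Gal", "B antigen"),
            ("Galα1-3Gal", "Galili antigen"),
            ("GalNAcβ1-4GlcNAc", "terminal LacdiNAc"),
            ("Galβ1-4GlcNAc6S", "keratan sulfate unit"),
            ("Neu5Acα2-3(GalNAcβ1-4)Gal", "Sda"),
        ],
    )
    def test_each_epitope_found_in_its_defining_structure(self, library, s, motif):
        assert gl.annotate(gl.parse_iupac(s), library)[motif] >= 1

    def test_b_antigen_is_not_galili(self, library):
        counts = gl.annotate(gl.parse_iupac("Galα1-3(Fucα1-2)Gal"), library)
        assert counts["Galili antigen"] == 0


class TestTerminalMotifs:
    def test_h_like_terminal_fucosylation(self, library):
        names = gl.terminal_motifs(gl.parse_iupac("Fucα1-2Galβ1-4Glc"), library)
        assert "Fuc(a1-2)Gal" in names

    def test_lactose_yields_empty_set(self, library):
        assert gl.terminal_motifs(gl.parse_iupac("Galβ1-4Glc"), library) == set()

    def test_idempotent_under_reparsing(self, library):
        for g in random_structures(seed=21, n=20):
            again = gl.parse_iupac(gl.write_iupac(g))
            assert gl.terminal_motifs(g, library) == gl.terminal_motifs(again, library)


class TestQuantifyMotifs:
    def _table(self, abundances, names):
        data = pd.DataFrame([abundances], index=["s1"], columns=names)
        meta = pd.DataFrame({"individual": ["A"], "day": [2]}, index=["s1"])
        return gl.AbundanceTable(data, meta)

    def test_single_glycan_conservation(self, library):
        s = "Fucα1-2Galβ1-4GlcNAc"
        t = self._table([100.0], [s])
        out = gl.quantify_motifs(t, {s: gl.parse_iupac(s)}, library)
        assert out.data.loc["s1", "type-2 H antigen"] == pytest.approx(100.0)

    def test_weighted_sum_over_occurrences(self, library):
        a = "Fucα1-2Galβ1-4GlcNAcβ1-3(Fucα1-2Galβ1-4GlcNAcβ1-6)Galβ1-4Glc"
        b = "Fucα1-2Galβ1-4GlcNAc"
        structures = {a: gl.parse_iupac(a), b: gl.parse_iupac(b)}
        t = self._table([60.0, 40.0], [a, b])
        out = gl.quantify_motifs(t, structures, library)
        # a carries the H epitope twice, b once: 2×60 + 1×40
        assert out.data.loc["s1", "type-2 H antigen"] == pytest.approx(160.0)
        presence = gl.quantify_motifs(t, structures, library, presence_only=True)
        assert presence.data.loc["s1", "type-2 H antigen"] == pytest.approx(100.0)

    def test_linearity_in_abundances(self, library):
        s = "Galβ1-4GlcNAcβ1-3Galβ1-4Glc"
        structures = {s: gl.parse_iupac(s)}
        one = gl.quantify_motifs(self._table([50.0], [s]), structures, library)
        two = gl.quantify_motifs(self._table([100.0], [s]), structures, library)
        assert np.allclose(2 * one.data.to_numpy(), two.data.to_numpy())

    def test_missing_structure_is_an_error(self, library):
        t = self._table([100.0], ["mystery"])
        with pytest.raises(KeyError, match="mystery"):
            gl.quantify_motifs(t, {}, library)

    def test_composition_only_columns_are_excluded_with_warning(self, library, caplog):
        s = "Galβ1-4Glc"
        t = self._table([60.0, 40.0], [s, "comp_only"])
        structures = {s: gl.parse_iupac(s), "comp_only": gl.parse_composition("Hex5HexNAc3")}
        with caplog.at_level("WARNING"):
            out = gl.quantify_motifs(t, structures, library)
        assert "comp_only" in caplog.text
        assert out.data.shape[1] == len(library)

    def test_size_branch_feature_set(self, library):
        s = "Galβ1-4GlcNAcβ1-6(Galβ1-3)Galβ1-4Glc"
        t = self._table([100.0], [s])
        out = gl.quantify_motifs(
            t, {s: gl.parse_iupac(s)}, library, feature_sets=("size_branch",)
        )
        assert out.data.loc["s1", "size_S"] == pytest.approx(100.0)
        assert out.data.loc["s1", "branches_1"] == pytest.approx(100.0)


def test_library_reproduces_motif_calls_on_all_printed_strings(library):
    """Every printed structure parses and annotates without error, and
    terminal-motif sets are stable under canonicalization."""
    for s in SEAL_STRUCTURE_STRINGS:
        g = gl.parse_iupac(s)
        counts = gl.annotate(g, library)
        assert all(v >= 0 for v in counts.values())
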