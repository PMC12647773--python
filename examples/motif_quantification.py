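"""Annotate glycans with named epitopes and weight them by abundance.

A motif's quantity in a sample is the sum over glycans of (occurrence
count × relative abundance), so a motif present twice in a glycan at 60 %
and once in a glycan at 40 % scores 160.
"""

import pandas as pd

import glycolac as gl

lib = gl.builtin_library()

a = "Fucα1-2Galβ1-4GlcNAcβ1-3(Fucα1-2Galβ1-4GlcNAcβ1-6)Galβ1-4Glc"
b = "Fucα1-2Galβ1-4GlcNAc"
structures = {a: gl.parse_iupac(a), b: gl.parse_iupac(b)}

print("epitopes in", b, "->",
      {k: v for k, v in gl.annotate(structures[b], lib).items() if v})

table = gl.AbundanceTable(
    pd.DataFrame([[60.0, 40.0]], index=["s1"], columns=[a, b]),
    pd.DataFrame({"individual": ["A"], "day": [2]}, index=["s1"]),
)
motifs = gl.quantify_motifs(table, structures, lib, feature_sets=("known", "size_branch"))
row = motifs.data.loc["s1"]
print("type-2 H antigen quantity:", row["type-2 H antigen"])  # 2*60 + 1*40 = 160
print("terminal motif set of", b, "->", sorted(gl.terminal_motifs(structures[b], lib)))
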