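"""Parse milk-oligosaccharide strings and inspect their structure.

Milk oligosaccharides elaborate a lactose core; the IUPAC-condensed string
is read right-to-left (reducing end last), with branches in parentheses.
"""

import glycolac as gl

strings = [
    "Galβ1-4Glc",  # lactose, the biosynthetic core
    "Fucα1-2Gal6Sβ1-4Glc",  # 6S-2'-fucosyllactose, a sulfated variant
    "Galβ1-4GlcNAcβ1-6(Galβ1-3)Galβ1-4Glc",  # branched pentasaccharide
    "Fucα1-2(Neu5Acα2-6)Galβ1-4GlcNAc",  # proximal type-2 sialyl-H antigen
]

for s in strings:
    g = gl.parse_iupac(s)
    f = gl.structural_features(g)
    c = gl.composition_of(g)
    print(f"{gl.write_iupac(g)}")
    print(
        f"  residues={f.size}  branch_points={f.branch_points}  depth={f.max_depth}"
        f"  composition=Hex{c.hex} HexNAc{c.hexnac} Fuc{c.fuc} Neu5Ac{c.neu5ac}"
        f"  sulfates={c.sulfate_count}"
    )

# The largest composition reported in seal milk: 28 monosaccharides.
print("giant MO size:", gl.parse_composition("Neu5Ac6Hex12HexNAc10").size)
# 166 of 240 characterized structures were previously unreported:
print("novel structures:", gl.novelty_percentage(166, 240), "%")
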