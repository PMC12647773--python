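"""Test whether 6-O-sulfation of GlcNAc suppresses chain extension.

Structures are drawn from the lactose-core grammar with a planted gap:
unmodified GlcNAc is capped (extended) with probability 0.8, sulfated
GlcNAc with probability 0.2.  The Wilcoxon signed-rank test over size
strata should report a negative direction (sulfated extended less).
"""

import glycolac as gl

params = gl.GrammarParams(
    p_extend=0.7, p_branch=0.3, p_sulf6_glcnac=0.4,
    p_cap=0.8, p_cap_sulfated=0.2, max_size=20, seed=3,
)
structures = gl.simulate_structures(250, params)
W, p, direction = gl.sulfation_branching_test(structures)
label = {-1: "sulfated GlcNAc extended LESS often", 0: "no effect",
         1: "sulfated GlcNAc extended MORE often"}[direction]
print(f"Wilcoxon signed-rank over size strata: W={W:.1f}  p={p:.2g}")
print("direction:", label)
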