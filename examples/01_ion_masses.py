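"""Exact ion masses and isotope patterns from molecular formulas.

Computes the m/z of the four lock-mass ions used for on-the-fly mass-axis
recalibration on a QTOF (tributylamine, the phosphazene calibrant in both
polarities, and trifluoroacetic acid), a bare fragment cation, and the
isotopologue envelope that fingerprints an elemental composition.
"""

import msderep as M

for formula_s, ion in [
    ("C12H27N", "[M+H]+"),
    ("C18H18F24N3O6P3", "[M+H]+"),
    ("C18H18F24N3O6P3", "[M+HCOO]-"),
    ("C2HF3O2", "[M-H]-"),
]:
    f = M.parse_formula(formula_s)
    print(f"{formula_s:>18s} {ion:>11s}  m/z {M.ion_mz(f, ion):.4f}")
# electron-mass-correct arithmetic: omitting it would miss by ~0.5 mDa

frag = M.parse_formula("C16H16NO")
print(f"\nbare fragment cation [C16H16NO]+  m/z {M.ion_mz(frag, '[M]+'):.3f}")

print("\nisotopologue envelope of C8H10Cl2 (two chlorines -> large A+2):")
for mz, ab in M.isotope_pattern(M.parse_formula("C8H10Cl2"), prune_below=0.1):
    print(f"  m {mz:9.4f}  {ab:6.2f} % of base")
# the A+2/A ratio (~65%) distinguishes this composition from any Cl-free
# formula at the same nominal mass
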