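"""Aggressive dereplication: full-scan screening against a formula list.

No fragment spectra are needed — each candidate formula is hunted by
extracted ion chromatograms of its expected adducts, an area cutoff
(10,000), accurate mass and an isotope-pattern score (>= 70). The dimer
trap is shown: one compound's [2M+H]+/[2M+Na]+ coincide exactly with the
[M+H]+/[M+Na]+ of a formula twice its mass, producing a false positive
that the adduct cross-check flags.
"""

import msderep as M

comps = M.fixture_compounds(0)
quin = comps["Quinolactacin-like"]
run, _ = M.simulate_run(
    M.RunRecipe(compounds=[quin], noise_level=150.0, dda=None, seed=4)
)

search_list = [
    M.SearchListEntry("Quinolactacin-like", quin.formula, quin.rt),
    M.SearchListEntry("Fellutanine-like", quin.formula * 2, quin.rt),
    M.SearchListEntry("absent compound", M.parse_formula("C30H46O4")),
]
hits = M.aggressive_derep(run, search_list, "positive")
M.annotate_adduct_flags(hits, run)

print(f"{'candidate':22s} {'ion':14s} {'rt':>6s} {'ppm':>7s} {'iso':>6s}  flags")
for h in hits:
    print(f"{h.entry.name:22s} {h.ion_species:14s} {h.rt:6.2f} "
          f"{h.mass_ppm:7.2f} {h.isotope_score:6.1f}  "
          f"{';'.join(sorted(h.flags))}")
# only the quinolactacin-like compound was in the run; the fellutanine-like
# "hit" is its dimer signal, flagged suspected_dimer_artifact; the absent
# compound produces no hit at all

features = M.feature_extract(run)
print("\nmolecular features (quality >= 99):")
for f in features:
    ions = ", ".join(lab for lab, _, _ in f.ions)
    print(f"  neutral mass {f.neutral_mass:.4f}  rt {f.rt:.2f}  "
          f"quality {f.quality:.1f}  ions: {ions}")
# the feature extractor groups [M+H]+, [M+Na]+ and the 2M dimers into one
# feature with the correct neutral monoisotopic mass
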