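"""Forward, reverse and similarity search against the MS/HRMS library.

Shows the isobar problem: seven fixture compounds share the composition
C7H6O4, so a precursor-mass search alone cannot separate them — the
forward score (which penalises query peaks the library spectrum does not
explain) picks the right one, while the reverse score is deliberately
tolerant of extra query content. Similarity search drops the precursor
constraint entirely to find structural analogues sharing fragment ions.
"""

import dataclasses

import msderep as M

lib = M.make_fixture_library(0)
print(f"library: {lib.stats()}")

patulin = lib.by_name("Patulin")
print(f"\nPatulin shares C7H6O4 with "
      f"{M.count_isobars(lib, patulin)} other library compounds")

query = dataclasses.replace(patulin.spectra[("[M-H]-", 10.0)])
print("\nprecursor-constrained search, 10 eV query (forward/reverse):")
for r in M.search(query, lib, min_forward=0, min_reverse=0)[:4]:
    print(f"  {r.entry.name:28s} {r.forward:5.1f} / {r.reverse:5.1f}")
# the self-match scores 100/100; isobars score lower on forward

analogue = M.fixture_compounds(0)["Asperphenamate +O analogue"]
frags = analogue.fragment_model[20.0]
q = M.Spectrum(
    [m for m, _ in frags], [i for _, i in frags], ms_level=2,
    precursor_mz=M.ion_mz(analogue.formula, "[M+H]+"),
)
print("\nsimilarity search with an analogue NOT in the library:")
for entry, score in M.similarity_search(q, lib, min_score=50):
    print(f"  {entry.name:28s} reverse-style score {score:5.1f}")
# the +O analogue shares the benzamide-side fragments (m/z 238.123,
# 256.133) with the parent compound, which is retrieved even though the
# parent masses differ by one oxygen
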