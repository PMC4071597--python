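# msderep

Dereplication of microbial secondary metabolites from LC-MS/MS data:
a multi-energy MS/HRMS spectral library with forward/reverse/similarity
search, plus full-scan "aggressive dereplication" by accurate mass,
isotope pattern and adduct logic — robust to detector saturation, and
exercised end-to-end on synthetic, ground-truthed runs.

**Who it is for.** Natural-products chemists screening microbial extracts
want to identify already-known compounds quickly so isolation effort goes
to novel chemistry. This package implements that workflow for QTOF-style
centroided data: reference spectra at three fixed collision energies
(10/20/40 eV), data-dependent acquisition simulation, and the adduct
cross-checks that catch the classic false positives (in-source fragments
masquerading as smaller molecules, 2M dimers matching another compound's
pseudomolecular ions, water-loss isomer confusion).

## The core quantities

Ion m/z is electron-mass-correct: `m/z = (n·M + Δadd − Δsub − z·mₑ)/|z|`,
so protonation adds 1.0072765 Da. Spectral matching uses a
square-root-intensity cosine,

```
forward = 100 · [Σ_pairs √(I_q·I_l)]² / (Σ_all I_q · Σ_all I_l)
```

where the **forward** score penalises query peaks the library spectrum
cannot explain, the **reverse** score first discards them (tolerant of
co-eluting noise), and **similarity** search applies the reverse score
without any precursor constraint to find analogues sharing fragment ions.
Full-scan hits are gated by an isotope-pattern score
`100·exp(−[(ΔA1/σ)² + (ΔA2/σ)²]/2)` (σ = 7 percentage points, threshold
70) and an area cutoff of 10,000. Default mass tolerance everywhere is
50 ppm + 2 mDa.

## Worked example

```python
import dataclasses, msderep as M

lib = M.make_fixture_library(0)
patulin = lib.by_name("Patulin")
print(M.count_isobars(lib, patulin))          # 6 other C7H6O4 compounds

query = dataclasses.replace(patulin.spectra[("[M-H]-", 10.0)])
for r in M.search(query, lib, min_forward=0, min_reverse=0)[:3]:
    print(f"{r.entry.name:28s} {r.forward:5.1f} / {r.reverse:5.1f}")
```

prints

```
6
Patulin                      100.0 / 100.0
Terreic acid                  12.3 /  52.3
2,4-dihydroxybenzoic acid      7.0 /  29.9
```

— the self-match scores 100/100 on both scales, while isobars (same
elemental composition C7H6O4, hence inside the precursor window) score
much higher on reverse than forward: exactly why both scores are needed
to avoid misidentification among small, sparsely fragmenting compounds.

The `examples/` directory holds one short script per capability — exact
ion masses and isotope envelopes, library search, auto-MS/MS screening
with adduct flags, aggressive dereplication with the dimer trap, and
saturation recovery — each printing the numbers it computes with a note
on what they mean. A thin CLI wraps the same functions:
`msderep simulate|search|screen|derep|features|lib`.

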