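# Methods

`msderep` implements an integrated dereplication workflow for microbial
secondary metabolites: a multi-energy MS/HRMS spectral library with
forward/reverse/similarity scoring, plus full-scan "aggressive
dereplication" against formula lists using accurate mass, isotope patterns
and adduct logic. This note documents the models, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Mass arithmetic

All masses derive from a single embedded IUPAC/CODATA table
(`docs/element_masses.csv`, also exported by `msderep lib constants`),
covering H, C, N, O, F, Na, Si, P, S, Cl, K, Br and I with their stable
isotopes. Ion m/z is computed as

    m/z = (n·M + Δadd − Δsub − z·mₑ) / |z|

with the electron mass mₑ = 0.000548580 Da included: protonation adds
m(H) − mₑ = 1.0072765 Da. This correction is required to reproduce
published QTOF lock-mass values (e.g. protonated tributylamine at
m/z 186.2216) at four decimal places; omitting it misses by ~0.5 mDa.
Only singly charged species are supported — the small-molecule ESI regime
this package targets — and the registered ion species cover the
pseudomolecular ions, in-source losses (water ×1–2, formic and acetic
acid), 2M multimers and bare (pre-charged) fragment compositions.

Isotopologue envelopes are computed by convolving per-element single-atom
isotope distributions (exponentiation by squaring), aggregating fine
structure by nominal mass shift with abundance-weighted centroid masses.
This matches how centroided QTOF spectra are read (one peak per A+k
isotopologue) and is verified in the test suite against an independent
brute-force multinomial enumeration to 1e-6.

Mass tolerances follow the two-component form used throughout:
`window(m) = m·ppm·1e-6 + mda/1000`, default **50 ppm + 2 mDa** for
precursor, product and full-scan matching.

## Chromatography, saturation, merging

EICs are per-MS1-scan intensity sums inside the tolerance window. Peaks
are local maxima whose boundaries extend to the surrounding minima below
5% of apex height; areas are trapezoid integrals in counts·min.

TOF detectors clip intense signals. Two symptoms are modelled and
detected: the monoisotopic intensity reaching a configurable ceiling, and
the measured A+1/A ratio deviating from the theoretical envelope by more
than 5 percentage points (the threshold is a package decision; vendors do
not publish theirs). Peak spectra are therefore merged only from scans at
or below 10% of the peak height (falling back to the two boundary scans),
after removing explicitly flagged scans; merged intensities are per-scan
averages so the background — the per-bin median of MS1 scans in a flanking
window of 2× the peak width on each side — can be subtracted on the same
scale, floored at zero. Centroids are binned across scans at
tolerance-window width with intensity-weighted centroid m/z.

## Library and scoring

A library entry stores one compound (name, CAS, formula, retention time)
with reference spectra at the three fixed collision energies 10/20/40 eV
per included ion species. Ion inclusion follows full-scan intensity rules:
positive mode always takes [M+H]+, adds [M+Na]+/[M+NH4]+ above 50% of
[M+H]+ and loss ions only when more intense than [M+H]+; negative mode
takes [M−H]− and adds [M+HCOO]− above 50%. Sodiated MS/MS spectra whose
only fragments are the precursor (or bare Na+) above 1% of base are
excluded from the searchable pool — they would match any ion at the right
m/z.

The score family is a square-root-intensity cosine:

    forward = 100 · [Σ_pairs √(I_q·I_l)]² / (Σ_all I_q · Σ_all I_l)

with greedy peak pairing (most intense library peaks claim the nearest
unassigned query peak in-window; ties to the more intense query peak).
The reverse score is the same statistic after discarding query peaks the
library spectrum cannot explain. Consequences, all property-tested:
self-match = 100, scale invariance, forward ≤ reverse for every pair, and
reverse = 100 whenever the query contains the library spectrum. Vendor
implementations of forward/reverse scoring are proprietary; this
definition reproduces their documented qualitative behaviour, not their
absolute values. Searches score each stored energy (nearest to the query's
if no exact match) and rank by forward score, ties by reverse then
|precursor ppm|. Similarity search applies the reverse score to every
library spectrum with no precursor constraint, to find analogues sharing
fragment ions. Default thresholds are forward ≥ 50 and reverse ≥ 50; a
`recommended` preset raises reverse to 70 for compounds with sparse
fragmentation.

## Aggressive dereplication and features

Full-scan screening hunts each search-list formula via the EICs of its
expected ions ([M+H]+/[M+Na]+ positive, [M−H]−/[M+HCOO]− negative, all
treated as singly charged), keeps peaks with area ≥ 10,000, and accepts a
hit when the merged-spectrum m/z is in tolerance and the isotope score
reaches 70. The isotope score is a Gaussian penalty on the A+1/A and
A+2/A deviations (percentage points):

    score = 100 · exp(−[(ΔA1/σ)² + (ΔA2/σ)²]/2),  σ = 7

σ was chosen so that a ±2-point deviation on both ratios — the instrument
accuracy achievable on non-saturated data — scores 92, while halving the
A+1 of a C20 compound scores ~30 and a missing A+1 on C30 scores ~0.

Adduct logic cross-validates identifications: a co-eluting EIC peak at the
identification's own [M+Na]+ m/z confirms it; its absence combined with a
retention time off the library value (> 0.3 min) marks a suspected
in-source fragment; and an ion fully explainable as the [2M+H]+/[2M+Na]+
of another co-eluting identification is flagged a suspected dimer
artifact. Water-loss isomer pairs (X matched through [M+H−H2O]+, Y through
[M+H]+, formula(Y) = formula(X) − H2O) are resolved by which sodiated EIC
co-elutes; with neither, both stay flagged ambiguous. The 3M trimer check
exists behind a config flag, off by default, as no trimer scenario is part
of the study conditions.

Molecular-feature extraction bins all MS1 centroids, detects peaks per
bin, discards isotopologue traces, and groups co-eluting ions whose
implied neutral masses agree in-window under the common species set. The
quality score is 0.5·mass coherence + 0.3·cross-ion isotope consistency
(A+1 ratios divided by multimer count) + 0.2·Gaussian peak-shape R², each
0–100, reported at ≥ 99 by default.

## The synthetic-data generator

The generator is first-class, seeded and ledgered: Gaussian elution
profiles, full isotope envelopes per ion, configurable adduct/dimer
ratios, in-source fragment ions with their own compositions, additive
Gaussian noise plus sparse chemical-noise peaks, and hard clipping at a
detector ceiling with two configurable saturation artefacts (A+1 relative
inflation, default 15%, and a centroid drift of 3 mDa in clipped scans).
DDA selects up to 3 precursors per 0.5 s cycle above 50,000 counts with a
0.04 min dynamic-exclusion window and emits MS2 at 10/20/40 eV from each
compound's seeded fragment model (uniform m/z over 50–95% of the
precursor, log-uniform intensities, family-shared cores for analogue
scenarios). The ledger records every emitted ion, clipped scan and
precursor selection, so downstream identifications are labelled true or
false mechanically.

What it does not emulate: m/z-domain profile shapes (peaks are ideal
centroids), retention drift, ion suppression, realistic fragmentation
chemistry, multiply charged species, and lock-mass dropout. Passing tests
therefore demonstrate the correctness of the pipeline logic under
controlled conditions, not instrument-level performance on real extracts.

The fixture library (15 entries, deterministic per seed) encodes the
scenario set the pipelines must handle: a seven-compound C7H6O4 isobar
panel with the retention times of the corresponding reference standards; a
benzamide-family parent whose +O analogue (absent from the library) shares
the fragment core at m/z 238.123/256.133; a water-loss isomer pair where
the hydrated compound's [M+H−H2O]+ coincides exactly with the dehydrated
compound's [M+H]+ (and the water-loss spectrum is itself stored, as
in-source dehydration makes it observable); an acetate-loss-dominated
compound whose base full-scan ion is a fragment, confirmed via [M+Na]+;
an in-source-fragment pair; and a dimer-coincidence pair whose formulas
satisfy M_B = 2·M_A exactly.

Deliberately separated study conditions worth knowing when reading test
results: co-eluting isobars whose auto-MS/MS events fuse into one
retention-contiguous group (elution windows overlapping at the shared
precursor m/z) yield a single mixed merged spectrum, so only one of them
can win the search — the known failure mode of integrating overlapping
isomer peaks. The recall checks therefore spike compounds with disjoint
elution windows; the overlapping case is exercised separately by the
water-loss disambiguation tests.

## Problem sizes and determinism

Synthetic runs in the tests and the acceptance script use 0.5 s scan
intervals over 2–14 min gradients (a few hundred to ~2000 scans), 1–21
compounds, responses of 10^5–2×10^6 counts and noise of 150–300 counts —
small enough to run in seconds while exercising every phenomenon. The
isotope-fidelity measurement uses a 21-compound C10–C50 panel
(`carbon_series_compounds`), detector ceiling above all apexes, noise 300
counts. All randomness flows from a single seed per recipe;
`scripts/acceptance.py --seed N` threads that seed through every
stochastic step.
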