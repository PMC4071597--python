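"""Seeded generator of synthetic LC-MS/MS runs and fixture libraries.

The generator emulates the phenomena the dereplication pipelines must
handle: Gaussian chromatographic elution, full isotopologue envelopes,
configurable adduct/dimer ratios, in-source fragment ions, additive detector
noise, hard intensity clipping at a detector ceiling (with the accompanying
relative inflation of the A+1 isotopologue seen on overloaded QTOF
detectors), and top-N data-dependent MS/MS selection with dynamic exclusion.
Every emitted ion, clipped scan and precursor selection is recorded in a
ground-truth ledger so downstream identifications can be labelled
true/false mechanically.

It does not attempt chemistry: fragment spectra are seeded pseudo-random
m/z sets (with family-shared cores for analogue scenarios), peaks are ideal
centroids, and retention is a fixed Gaussian per compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    MolecularFormula,
    get_ion_species,
    ion_mz,
    isotope_pattern,
    parse_formula,
)
from .config import DDAParams
from .speclib import LIBRARY_ENERGIES, LibraryEntry, SpectralLibrary
from .spectra import ScanSeries, Spectrum

__all__ = [
    "InsourceIon",
    "SyntheticCompound",
    "RunRecipe",
    "DDAEvent",
    "GroundTruth",
    "simulate_run",
    "simulate_dda",
    "make_fixture_library",
    "fixture_compounds",
]

FragmentModel = Dict[float, List[Tuple[float, float]]]


@dataclass(frozen=True)
class InsourceIon:
    """An extra ion a compound emits in the source (e.g. a fragment that
    mimics a smaller molecule's protonated ion), with its own composition
    and therefore its own isotope envelope."""

    formula: MolecularFormula
    ion_label: str
    ratio: float  # fraction of the compound's base-ion response
    fragment_model: Optional[FragmentModel] = None

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.ion_label)


@dataclass
class SyntheticCompound:
    name: str
    formula: MolecularFormula
    rt: float  # min
    peak_sigma: float = 0.05  # min
    response: float = 1e6  # counts at the apex of the base ion
    adduct_ratios: Dict[str, float] = field(default_factory=lambda: {"[M+H]+": 1.0})
    fragment_model: FragmentModel = field(default_factory=dict)
    insource: Tuple[InsourceIon, ...] = ()
    sodiated_specific: bool = True  # False: [M+Na]+ MS2 shows only the precursor

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.adduct_ratios.values()):
            raise ValueError("adduct ratios must be >= 0")
        for energy, frags in self.fragment_model.items():
            for mz, _ in frags:
                pmz = min(
                    ion_mz(self.formula, lab) for lab in self.adduct_ratios
                )
                if mz >= pmz:
                    raise ValueError(
                        f"{self.name}: fragment m/z {mz} not below precursor"
                    )


@dataclass
class RunRecipe:
    compounds: List[SyntheticCompound]
    scan_interval: float = 0.5  # s between MS1 scans (one acquisition cycle)
    run_length: Optional[float] = None  # min; default spans all compounds
    noise_level: float = 0.0  # counts (sd of additive noise)
    detector_ceiling: float = math.inf  # counts
    a1_inflation: float = 0.15  # relative A+1 inflation in clipped scans
    clip_mz_shift: float = 0.003  # Da centroid drift of clipped ions
    dda: Optional[DDAParams] = field(default_factory=DDAParams)
    polarity: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")


@dataclass
class DDAEvent:
    rt: float
    precursor_mz: float
    compound: str
    ion_label: str
    scan_indices: List[int]  # MS2 scans emitted for this selection


@dataclass
class GroundTruth:
    """Ledger of everything the generator emitted."""

    seed: int
    compounds: Dict[str, SyntheticCompound]
    ions: List[dict]  # name, ion_label, mz, apex_intensity, rt, insource_of
    clipped: Dict[Tuple[str, str], List[int]] = field(default_factory=dict)
    dda_events: List[DDAEvent] = field(default_factory=list)

    def ions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ions)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rt": e.rt,
                    "precursor_mz": e.precursor_mz,
                    "compound": e.compound,
                    "ion": e.ion_label,
                    "n_scans": len(e.scan_indices),
                }
                for e in self.dda_events
            ]
        )

    def compound_at(self, mz: float, rt: float, mz_tol: float = 0.01,
                    rt_tol: float = 0.2) -> Optional[str]:
        """Name of the compound whose emitted ion best explains (mz, rt)."""
        best, best_d = None, math.inf
        for rec in self.ions:
            if abs(rec["mz"] - mz) <= mz_tol and abs(rec["rt"] - rt) <= rt_tol:
                d = abs(rec["mz"] - mz)
                if d < best_d:
                    best, best_d = rec["name"], d
        return best


# ---------------------------------------------------------------------------
# fragment model generation
# ---------------------------------------------------------------------------

def _random_fragments(
    rng: np.random.Generator,
    precursor_mz: float,
    energies: Sequence[float] = LIBRARY_ENERGIES,
    core: Sequence[Tuple[float, float]] = (),
    n_range: Tuple[int, int] = (5, 10),
) -> FragmentModel:
    """Seeded pseudo-random fragment sets: uniform m/z over 50–95% of the
    precursor, log-uniform intensities, plus family-shared core peaks."""
    model: FragmentModel = {}
    for energy in energies:
        k = int(rng.integers(n_range[0], n_range[1] + 1))
        mzs = rng.uniform(50.0, 0.95 * precursor_mz, k)
        intens = 10 ** rng.uniform(1.0, 3.0, k)
        frags = [(float(m), float(i)) for m, i in zip(mzs, intens)]
        frags.extend((float(m), float(i)) for m, i in core)
        top = max(i for _, i in frags)
        model[energy] = sorted(
            (m, 100.0 * i / top) for m, i in frags
        )
    return model


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------

def _envelope(formula: MolecularFormula, label: str) -> List[Tuple[float, float]]:
    species = get_ion_species(label)
    ion_f = species.ion_formula(formula)
    pat = isotope_pattern(ion_f, prune_below=0.05)
    mono_mz = ion_mz(formula, species)
    base_mz, base_ab = pat.entries[0]
    return [(mono_mz + (m - base_mz), ab / base_ab) for m, ab in pat.entries]


def _merge_peaks(
    mzs: List[float], intens: List[float], width: float = 5e-4
) -> Tuple[np.ndarray, np.ndarray]:
    if not mzs:
        return np.array([]), np.array([])
    a = np.array(mzs)
    b = np.array(intens)
    order = np.argsort(a)
    a, b = a[order], b[order]
    out_mz, out_in = [], []
    start = 0
    for i in range(1, len(a) + 1):
        if i == len(a) or a[i] - a[i - 1] > width:
            seg_m, seg_i = a[start:i], b[start:i]
            tot = seg_i.sum()
            out_mz.append(float(np.dot(seg_m, seg_i) / tot) if tot > 0 else float(seg_m.mean()))
            out_in.append(float(tot))
            start = i
    return np.array(out_mz), np.array(out_in)


def simulate_run(recipe: RunRecipe) -> Tuple[ScanSeries, GroundTruth]:
    """Simulate an LC-MS(/MS) run; returns the scans and the truth ledger.

    Reproducible: the same recipe (including seed) yields an identical run.
    """
    rng = np.random.default_rng(recipe.seed)
    comps = recipe.compounds
    if recipe.run_length is None:
        run_length = max(c.rt + 6 * c.peak_sigma for c in comps) if comps else 1.0
    else:
        run_length = recipe.run_length
    dt = recipe.scan_interval / 60.0  # min
    times = np.arange(dt, run_length, dt)

    # Per emitted ion: (name, label, envelope, ratio, compound, insource flag)
    emitters = []
    truth_ions: List[dict] = []
    for c in comps:
        for label, ratio in sorted(c.adduct_ratios.items()):
            if ratio <= 0:
                continue
            env = _envelope(c.formula, label)
            emitters.append((c, label, env, ratio, None))
            truth_ions.append(
                {"name": c.name, "ion_label": label, "mz": env[0][0],
                 "apex_intensity": c.response * ratio, "rt": c.rt,
                 "insource_of": None}
            )
        for ins in c.insource:
            env = _envelope(ins.formula, ins.ion_label)
            emitters.append((c, ins.ion_label, env, ins.ratio, ins))
            truth_ions.append(
                {"name": c.name, "ion_label": ins.ion_label, "mz": env[0][0],
                 "apex_intensity": c.response * ins.ratio, "rt": c.rt,
                 "insource_of": c.name}
            )

    truth = GroundTruth(seed=recipe.seed, compounds={c.name: c for c in comps},
                        ions=truth_ions)

    ms1_scans: List[Spectrum] = []
    # (scan position in ms1 list) -> list of candidate precursors for DDA:
    candidates_per_scan: List[List[Tuple[float, float, SyntheticCompound, str, Optional[InsourceIon]]]] = []
    clipped_tmp: Dict[Tuple[str, str], List[int]] = {}

    for si, t in enumerate(times):
        mzs: List[float] = []
        intens: List[float] = []
        cands = []
        for c, label, env, ratio, ins in emitters:
            g = c.response * ratio * math.exp(
                -((t - c.rt) ** 2) / (2 * c.peak_sigma ** 2)
            )
            if g < 1e-2:
                continue
            mono = g
            clipped_here = mono > recipe.detector_ceiling
            if clipped_here:
                key = (c.name, label)
                clipped_tmp.setdefault(key, []).append(si)
            for j, (mz_j, frac) in enumerate(env):
                inten = g * frac
                if clipped_here and j == 1:
                    inten *= 1.0 + recipe.a1_inflation
                inten = min(inten, recipe.detector_ceiling)
                if clipped_here:
                    mz_j += recipe.clip_mz_shift
                mzs.append(mz_j)
                intens.append(inten)
            cands.append((env[0][0], min(mono, recipe.detector_ceiling), c, label, ins))
        if recipe.noise_level > 0:
            intens = [
                max(0.0, i + rng.normal(0.0, recipe.noise_level)) for i in intens
            ]
            for _ in range(5):  # sparse chemical-noise peaks
                mzs.append(float(rng.uniform(85.0, 1700.0)))
                intens.append(float(abs(rng.normal(0.0, recipe.noise_level))))
        mz_arr, in_arr = _merge_peaks(mzs, intens)
        keep = in_arr > 0
        ms1_scans.append(
            Spectrum(mz_arr[keep], in_arr[keep], polarity=recipe.polarity,
                     ms_level=1, rt=float(t))
        )
        candidates_per_scan.append(cands)

    if recipe.dda is None:
        scans = list(ms1_scans)
        series = ScanSeries(scans, run_id=f"synthetic-seed{recipe.seed}",
                            polarity=recipe.polarity)
        # map ms1 positions to global indices (identity here)
        truth.clipped = {k: v for k, v in clipped_tmp.items()}
        return series, truth

    scans, events, ms1_global = _interleave_dda(
        ms1_scans, candidates_per_scan, recipe
    )
    truth.dda_events = events
    truth.clipped = {
        k: [ms1_global[i] for i in v] for k, v in clipped_tmp.items()
    }
    series = ScanSeries(scans, run_id=f"synthetic-seed{recipe.seed}",
                        polarity=recipe.polarity)
    return series, truth


def _fragment_spectrum(
    c: SyntheticCompound,
    ins: Optional[InsourceIon],
    label: str,
    energy: float,
    precursor_mz: float,
    precursor_intensity: float,
    rt: float,
    polarity: str,
) -> Spectrum:
    model = c.fragment_model
    if ins is not None and ins.fragment_model is not None:
        model = ins.fragment_model
    unspecific_na = label == "[M+Na]+" and not c.sodiated_specific
    mzs, intens = [precursor_mz], [0.1 * precursor_intensity]
    if unspecific_na:
        mzs, intens = [precursor_mz], [precursor_intensity]
    elif model:
        key = min(model, key=lambda e: abs(e - energy))
        for mz, rel in model[key]:
            if mz < precursor_mz:
                mzs.append(mz)
                intens.append(0.5 * precursor_intensity * rel / 100.0)
    return Spectrum(np.array(mzs), np.array(intens), polarity=polarity,
                    ms_level=2, rt=rt, precursor_mz=precursor_mz,
                    collision_energy=energy)


def _interleave_dda(ms1_scans, candidates_per_scan, recipe: RunRecipe):
    """Top-N precursor selection with dynamic exclusion, interleaving MS2
    scans after each MS1 scan (one cycle per MS1 scan)."""
    dda = recipe.dda
    scans: List[Spectrum] = []
    events: List[DDAEvent] = []
    ms1_global: List[int] = []
    exclusion: List[Tuple[float, float]] = []  # (mz, excluded until rt)
    n_cycle_slots = max(1, dda.top_n * len(dda.energies)) + 1
    for si, ms1 in enumerate(ms1_scans):
        ms1_global.append(len(scans))
        scans.append(ms1)
        t = ms1.rt
        exclusion = [(m, until) for m, until in exclusion if until > t]
        eligible = [
            cand for cand in candidates_per_scan[si]
            if cand[1] >= dda.threshold
            and not any(abs(cand[0] - m) <= 0.01 for m, _ in exclusion)
        ]
        eligible.sort(key=lambda cand: -cand[1])
        dt_scan = (recipe.scan_interval / 60.0) / n_cycle_slots
        slot = 1
        for mz, inten, c, label, ins in eligible[: dda.top_n]:
            exclusion.append((mz, t + dda.exclusion))
            idxs = []
            for energy in dda.energies:
                rt2 = t + slot * dt_scan
                slot += 1
                idxs.append(len(scans))
                scans.append(
                    _fragment_spectrum(c, ins, label, energy, mz, inten, rt2,
                                       recipe.polarity)
                )
            events.append(DDAEvent(t, mz, c.name, label, idxs))
    return scans, events, ms1_global


def simulate_dda(
    ms1_run: ScanSeries, recipe: RunRecipe
) -> Tuple[ScanSeries, List[DDAEvent]]:
    """Interleave DDA MS2 scans into an MS1-only run.

    Candidate precursors are re-derived by matching each MS1 scan's peaks to
    the theoretical ion m/z values of the recipe's compounds (±0.005 Da), so
    this can run on any MS1 stream covering the recipe's compounds.
    """
    if recipe.dda is None:
        raise ValueError("recipe has no DDA parameters")
    targets = []
    for c in recipe.compounds:
        for label, ratio in sorted(c.adduct_ratios.items()):
            if ratio > 0:
                targets.append((ion_mz(c.formula, label), c, label, None))
        for ins in c.insource:
            targets.append((ins.mz, c, ins.ion_label, ins))
    ms1_scans = ms1_run.ms1_scans()
    candidates_per_scan = []
    for scan in ms1_scans:
        cands = []
        for mz, c, label, ins in targets:
            lo, hi = np.searchsorted(scan.mz, (mz - 0.005, mz + 0.005))
            if hi > lo:
                inten = float(scan.intensity[lo:hi].max())
                cands.append((mz, inten, c, label, ins))
        candidates_per_scan.append(cands)
    scans, events, _ = _interleave_dda(ms1_scans, candidates_per_scan, recipe)
    return (
        ScanSeries(scans, run_id=ms1_run.run_id, polarity=ms1_run.polarity),
        events,
    )


def carbon_series_compounds(
    n: int = 21,
    c_min: int = 10,
    c_max: int = 50,
    response: float = 8e5,
    rt_start: float = 1.0,
    rt_step: float = 0.25,
) -> List[SyntheticCompound]:
    """A panel of CxHyOz compounds spanning a carbon-count range.

    Used to probe isotope-ratio fidelity across the envelope sizes natural
    products cover (A+1 from ~11% to ~55%): carbon counts are evenly spaced
    over [c_min, c_max] with H ≈ 1.5·C and O ≈ C/5, eluting at regular
    intervals with equal response.
    """
    comps = []
    for i in range(n):
        nc = round(c_min + i * (c_max - c_min) / max(n - 1, 1))
        formula = MolecularFormula(
            {"C": nc, "H": int(nc * 1.5), "O": max(2, nc // 5)}
        )
        comps.append(
            SyntheticCompound(
                name=f"series-C{nc}-{i:02d}",
                formula=formula,
                rt=rt_start + rt_step * i,
                response=response,
                adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.3},
            )
        )
    return comps


# ---------------------------------------------------------------------------
# fixture library
# ---------------------------------------------------------------------------

_TABLE1_ISOBARS = [  # name, retention time (min); all share C7H6O4
    ("Patulin", 3.15),
    ("2,3-dihydroxybenzoic acid", 3.85),
    ("2,4-dihydroxybenzoic acid", 3.74),
    ("2,6-dihydroxybenzoic acid", 3.87),
    ("3,4-dihydroxybenzoic acid", 2.80),
    ("3,5-dihydroxybenzoic acid", 2.63),
    ("Terreic acid", 3.99),
]

# shared fragment core of the asperphenamate-like family (benzamide side)
_ASPER_CORE = [(238.1226, 800.0), (256.1332, 600.0), (105.0335, 300.0)]


def fixture_compounds(seed: int = 0) -> Dict[str, SyntheticCompound]:
    """Deterministic scenario compounds mirroring the library fixture.

    Includes, beyond plain library compounds: a large molecule whose
    in-source fragment mimics a smaller library compound's [M+H]+ (and
    produces no Na adduct at that m/z); a dimer-forming compound whose
    [2M+H]+/[2M+Na]+ coincide with another formula's [M+H]+/[M+Na]+; a
    water-loss isomer pair; and an acetate-loss-dominated base ion with a
    confirming Na adduct.
    """
    rng = np.random.default_rng(seed)
    comps: Dict[str, SyntheticCompound] = {}

    def add(c: SyntheticCompound) -> SyntheticCompound:
        comps[c.name] = c
        return c

    # --- small-molecule isobar panel (negative mode) ---------------------
    f_iso = parse_formula("C7H6O4")
    mz_iso = ion_mz(f_iso, "[M-H]-")
    for name, rt in _TABLE1_ISOBARS:
        core = [(109.0295, 500.0)] if "acid" in name or name == "Patulin" else []
        add(
            SyntheticCompound(
                name=name, formula=f_iso, rt=rt, response=8e5,
                adduct_ratios={"[M-H]-": 1.0},
                fragment_model=_random_fragments(rng, mz_iso, core=core),
            )
        )

    # --- asperphenamate-like family (positive mode) ----------------------
    f_asper = parse_formula("C30H26N2O4")
    add(
        SyntheticCompound(
            name="Asperphenamate", formula=f_asper, rt=9.50, response=1.2e6,
            adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.3},
            fragment_model=_random_fragments(
                rng, ion_mz(f_asper, "[M+H]+"), core=_ASPER_CORE
            ),
        )
    )
    f_asper_o = parse_formula("C30H26N2O5")  # +O analogue (not in library)
    add(
        SyntheticCompound(
            name="Asperphenamate +O analogue", formula=f_asper_o, rt=9.20,
            response=9e5, adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.25},
            fragment_model=_random_fragments(
                rng, ion_mz(f_asper_o, "[M+H]+"), core=_ASPER_CORE
            ),
        )
    )

    # --- water-loss isomer pair (ophiobolin-like) ------------------------
    f_k = parse_formula("C25H36O3")  # loses water in the source
    f_g = f_k - parse_formula("H2O")
    shared = _random_fragments(rng, ion_mz(f_g, "[M+H]+"))
    add(
        SyntheticCompound(
            name="Ophiobolin K-like", formula=f_k, rt=12.60, response=1e6,
            adduct_ratios={"[M+H]+": 1.0, "[M+H-H2O]+": 0.8, "[M+Na]+": 0.35},
            fragment_model=shared,
        )
    )
    add(
        SyntheticCompound(
            name="Ophiobolin G-like", formula=f_g, rt=12.81, response=7e5,
            adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.3},
            fragment_model=shared,  # identical: dehydration product
        )
    )

    # --- acetate-loss base ion with confirming Na adduct ------------------
    f_helv = parse_formula("C33H44O8")
    add(
        SyntheticCompound(
            name="Helvolic acid-like", formula=f_helv, rt=11.20, response=1e6,
            adduct_ratios={
                "[M+H-CH3COOH]+": 1.0, "[M+Na]+": 0.4, "[M+H]+": 0.15,
            },
            fragment_model=_random_fragments(
                rng, ion_mz(f_helv, "[M+H-CH3COOH]+")
            ),
        )
    )

    # --- in-source fragment scenario --------------------------------------
    f_mpa = parse_formula("C17H20O6")
    mpa = add(
        SyntheticCompound(
            name="Mycophenolic acid-like", formula=f_mpa, rt=7.95,
            response=1.1e6,
            adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.35},
            fragment_model=_random_fragments(
                rng, ion_mz(f_mpa, "[M+H]+"),
                core=[(207.0652, 700.0), (159.0441, 500.0)],
            ),
        )
    )
    f_big = parse_formula("C27H28O11")  # larger conjugate, fragments in-source
    add(
        SyntheticCompound(
            name="MPA conjugate-like", formula=f_big, rt=9.05, response=8e5,
            adduct_ratios={"[M+H]+": 1.0, "[M+Na]+": 0.3},
            fragment_model=_random_fragments(rng, ion_mz(f_big, "[M+H]+")),
            insource=(
                InsourceIon(
                    formula=f_mpa, ion_label="[M+H]+", ratio=0.7,
                    fragment_model=mpa.fragment_model,
                ),
            ),
        )
    )

    # --- dimer coincidence pair -------------------------------------------
    f_quin = parse_formula("C16H18N2O2")
    add(
        SyntheticCompound(
            name="Quinolactacin-like", formula=f_quin, rt=6.40, response=1.5e6,
            adduct_ratios={
                "[M+H]+": 1.0, "[M+Na]+": 0.3, "[2M+H]+": 0.25, "[2M+Na]+": 0.15,
            },
            fragment_model=_random_fragments(rng, ion_mz(f_quin, "[M+H]+")),
        )
    )
    # a formula whose monoisotopic mass is exactly twice f_quin's
    f_fellu = f_quin * 2
    add(
        SyntheticCompound(
            name="Fellutanine-like", formula=f_fellu, rt=6.40, response=0.0,
            adduct_ratios={"[M+H]+": 0.0},
            fragment_model=_random_fragments(rng, ion_mz(f_fellu, "[M+H]+")),
        )
    )
    return comps


def make_fixture_library(seed: int = 0) -> SpectralLibrary:
    """Build the deterministic fixture library from the scenario compounds.

    Contains the seven-compound isobar panel, the asperphenamate-like parent
    (the +O analogue is deliberately absent so similarity search must find
    it), the water-loss isomer pair (with the water-loss ion of the hydrated
    compound stored, as in the real library), the acetate-loss compound, the
    in-source-fragment pair, and the dimer-coincidence pair.
    """
    comps = fixture_compounds(seed)
    lib = SpectralLibrary()
    skip = {"Asperphenamate +O analogue"}
    for name, c in comps.items():
        if name in skip:
            continue
        entry = LibraryEntry(name=c.name, formula=c.formula, rt=c.rt)
        polarity = (
            "negative"
            if all(l.endswith("-") for l in c.adduct_ratios)
            else "positive"
        )
        base_label = (
            "[M-H]-" if polarity == "negative" else
            ("[M+H]+" if c.adduct_ratios.get("[M+H]+", 0) > 0 else
             max(c.adduct_ratios, key=c.adduct_ratios.get))
        )
        labels = [base_label]
        # the hydrated isomer's water-loss ion is itself in the library
        if c.adduct_ratios.get("[M+H-H2O]+", 0) >= 0.5:
            labels.append("[M+H-H2O]+")
        for label in labels:
            pmz = ion_mz(c.formula, label)
            for energy in LIBRARY_ENERGIES:
                frags = [
                    (m, i) for m, i in c.fragment_model.get(energy, [])
                    if m < pmz
                ]
                if not frags:
                    continue
                spec = Spectrum(
                    mz=np.array([m for m, _ in frags]),
                    intensity=np.array([i for _, i in frags]),
                    polarity=polarity, ms_level=2, rt=c.rt,
                    precursor_mz=pmz, collision_energy=energy,
                )
                entry.add_spectrum(label, energy, spec)
        lib.add(entry)
    return lib
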