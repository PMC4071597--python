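"""Dereplication pipelines.

Two complementary strategies are implemented:

* **Library screening** of auto-MS/MS runs: MS2 scans are grouped by
  precursor and retention time, merged per group, and searched against the
  multi-energy MS/HRMS library with forward/reverse scoring.
* **Aggressive dereplication** of full-scan data: every formula in a search
  list is hunted by extracted ion chromatograms of its expected ion species
  ([M+H]+/[M+Na]+ in positive mode, [M-H]-/[M+HCOO]- in negative mode),
  with an area cutoff, accurate-mass check and isotope-pattern score.

Adduct logic cross-validates both: a genuine identification should show a
co-eluting sodium adduct of its own formula; a match lacking it at the wrong
retention time is likely an in-source fragment of a larger molecule, and an
ion explainable as another co-eluting compound's 2M dimer is flagged as a
probable dimer artifact. Water-loss isomer pairs (where one compound's
[M+H-H2O]+ coincides with another's [M+H]+) are disambiguated the same way,
by which sodiated EIC co-elutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .chem import (
    IsotopePattern,
    MassTolerance,
    MolecularFormula,
    get_ion_species,
    ion_mz,
    isotope_pattern,
    ppm_error,
)
from .config import Config
from .scoring import MatchResult, search as _lib_search
from .speclib import SpectralLibrary
from .spectra import (
    ChromPeak,
    ScanSeries,
    Spectrum,
    detect_chrom_peaks,
    extract_eic,
    flag_saturated_scans,
    measure_isotope_ratio,
    merge_peak_spectrum,
    merge_spectra,
)

__all__ = [
    "SearchListEntry",
    "FormulaHit",
    "Feature",
    "library_screen",
    "aggressive_derep",
    "isotope_score",
    "adduct_crosscheck",
    "annotate_adduct_flags",
    "disambiguate_isomer_series",
    "feature_extract",
    "count_isobars",
]

POSITIVE_SPECIES = ("[M+H]+", "[M+Na]+")
NEGATIVE_SPECIES = ("[M-H]-", "[M+HCOO]-")


@dataclass(frozen=True)
class SearchListEntry:
    """A formula-list record for aggressive dereplication."""

    name: str
    formula: MolecularFormula
    rt: Optional[float] = None
    source_taxon: Optional[str] = None


@dataclass
class FormulaHit:
    """A full-scan hit of a search-list formula."""

    entry: SearchListEntry
    ion_species: str
    chrom_peak: ChromPeak
    observed_mz: float
    mass_ppm: float
    isotope_score: float
    flags: Set[str] = field(default_factory=set)

    @property
    def rt(self) -> float:
        return self.chrom_peak.apex_rt


@dataclass
class Feature:
    """A group of co-eluting ions attributed to one neutral compound."""

    neutral_mass: float
    rt: float
    ions: List[Tuple[str, float, float]]  # (ion label, m/z, area)
    quality: float


# ---------------------------------------------------------------------------
# isotope-pattern scoring
# ---------------------------------------------------------------------------

def isotope_score(
    observed: IsotopePattern | Tuple[float, float],
    theoretical: IsotopePattern,
    sigma: Tuple[float, float] = (7.0, 7.0),
) -> float:
    """Gaussian agreement score (0–100) between measured and theoretical
    A+1/A and A+2/A abundances (percent of the monoisotopic peak).

    ``100·exp(−[(ΔA1/σ1)² + (ΔA2/σ2)²]/2)``; exact agreement scores 100 and
    a deviation of ±2 percentage points on both ratios (typical instrument
    accuracy on non-saturated data) still scores above 90.
    ``observed`` may be an IsotopePattern or a raw (A+1/A, A+2/A) pair.
    """
    if isinstance(observed, IsotopePattern):
        obs = (observed.relative(1), observed.relative(2))
    else:
        obs = (float(observed[0]), float(observed[1]))
    theo = (theoretical.relative(1), theoretical.relative(2))
    z = sum(((o - t) / s) ** 2 for o, t, s in zip(obs, theo, sigma))
    return 100.0 * math.exp(-z / 2.0)


# ---------------------------------------------------------------------------
# MS/HRMS library screening
# ---------------------------------------------------------------------------

def _group_ms2(
    run: ScanSeries, tol: MassTolerance, rt_gap: float
) -> List[List[int]]:
    """Group MS2 scan indices by (precursor within tolerance, energy) into
    retention-time-contiguous blocks."""
    recs = [
        (i, s)
        for i, s in enumerate(run.scans)
        if s.ms_level == 2 and s.precursor_mz is not None
    ]
    recs.sort(key=lambda r: (r[1].precursor_mz, r[1].collision_energy or 0, r[1].rt))
    groups: List[List[int]] = []
    cur: List[int] = []
    prev: Optional[Spectrum] = None
    for i, s in recs:
        if (
            prev is not None
            and tol.matches(s.precursor_mz, prev.precursor_mz)
            and (s.collision_energy or 0) == (prev.collision_energy or 0)
            and s.rt - prev.rt <= rt_gap
        ):
            cur.append(i)
        else:
            if cur:
                groups.append(cur)
            cur = [i]
        prev = s
    if cur:
        groups.append(cur)
    return groups


def library_screen(
    run: ScanSeries,
    lib: SpectralLibrary,
    config: Config = Config(),
    rt_gap: float = 0.1,
) -> List[MatchResult]:
    """Screen an auto-MS/MS run against the MS/HRMS library.

    MS2 scans are grouped by precursor m/z (within the precursor tolerance),
    collision energy and retention-time contiguity; each group is merged
    into one spectrum and searched. Returns the best hit per group above
    the score thresholds, with retention times attached (and the deviation
    from the library retention time where the entry has one).
    """
    results: List[MatchResult] = []
    for group in _group_ms2(run, config.tol_precursor, rt_gap):
        scans = [run.scans[i] for i in group]
        merged = merge_spectra(scans, config.tol_product)
        merged.precursor_mz = float(
            np.median([s.precursor_mz for s in scans])
        )
        merged.collision_energy = scans[0].collision_energy
        hits = _lib_search(
            merged, lib,
            tol_precursor=config.tol_precursor,
            tol_product=config.tol_product,
            min_forward=config.min_forward,
            min_reverse=config.min_reverse,
        )
        if hits:
            results.append(hits[0])
    # keep the best-scoring result per (entry, rt neighborhood)
    results.sort(key=lambda r: (-r.forward, -r.reverse))
    deduped: List[MatchResult] = []
    for r in results:
        dup = any(
            d.entry.name == r.entry.name
            and d.query_rt is not None
            and r.query_rt is not None
            and abs(d.query_rt - r.query_rt) <= config.rt_window * 2
            for d in deduped
        )
        if not dup:
            deduped.append(r)
    deduped.sort(key=lambda r: (r.query_rt or 0.0))
    return deduped


# ---------------------------------------------------------------------------
# aggressive dereplication (full-scan)
# ---------------------------------------------------------------------------

def _merged_peak_spectrum(
    run: ScanSeries,
    peak: ChromPeak,
    target: float,
    formula: Optional[MolecularFormula],
    config: Config,
) -> Spectrum:
    exclude: Set[int] = set()
    if config.saturation_ceiling is not None:
        exclude = flag_saturated_scans(
            run, peak, target, config.saturation_ceiling, formula,
            config.tol_fullscan, config.isotope_deviation_limit,
        )
        peak.saturated_scan_indices = exclude
    try:
        return merge_peak_spectrum(
            run, peak, exclude, config.height_fraction, config.tol_fullscan
        )
    except ValueError:
        return merge_peak_spectrum(
            run, peak, (), config.height_fraction, config.tol_fullscan
        )


def aggressive_derep(
    run: ScanSeries,
    search_list: Sequence[SearchListEntry],
    polarity: str = "positive",
    config: Config = Config(),
    species: Optional[Sequence[str]] = None,
    min_height: float = 1000.0,
) -> List[FormulaHit]:
    """Full-scan screening of a run against a formula search list.

    For each entry × ion species: extract the EIC at the theoretical m/z,
    detect chromatographic peaks, keep those with area ≥ the cutoff, merge
    the peak spectrum from scans below the height fraction (excluding
    saturated scans), and accept the hit when the measured m/z is within
    tolerance and the isotope-pattern score reaches the threshold. All ions
    are treated as singly charged.
    """
    if species is None:
        species = (
            POSITIVE_SPECIES if polarity.startswith("pos") else NEGATIVE_SPECIES
        )
    hits: List[FormulaHit] = []
    for entry in search_list:
        for label in species:
            target = ion_mz(entry.formula, label)
            trace = extract_eic(run, target, config.tol_fullscan)
            theo = isotope_pattern(
                get_ion_species(label).ion_formula(entry.formula)
            )
            for peak in detect_chrom_peaks(trace, min_height):
                if peak.area < config.min_area:
                    continue
                merged = _merged_peak_spectrum(
                    run, peak, target, entry.formula, config
                )
                mono = merged.max_peak_within(target, config.tol_fullscan)
                if mono is None:
                    continue
                try:
                    ratios = measure_isotope_ratio(
                        merged, target, config.tol_fullscan
                    )
                except ValueError:
                    continue
                iso = isotope_score(ratios, theo)
                if iso < config.min_isotope_score:
                    continue
                hits.append(
                    FormulaHit(
                        entry=entry,
                        ion_species=label,
                        chrom_peak=peak,
                        observed_mz=mono.mz,
                        mass_ppm=ppm_error(mono.mz, target),
                        isotope_score=iso,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# adduct cross-validation
# ---------------------------------------------------------------------------

def _coeluting_peak(
    run: ScanSeries,
    target: float,
    rt: float,
    config: Config,
    min_height: float = 500.0,
) -> Optional[ChromPeak]:
    trace = extract_eic(run, target, config.tol_fullscan)
    for peak in detect_chrom_peaks(trace, min_height):
        if abs(peak.apex_rt - rt) <= config.rt_window:
            return peak
    return None


def adduct_crosscheck(
    hit,
    run: ScanSeries,
    others: Iterable = (),
    config: Config = Config(),
    library_rt: Optional[float] = None,
) -> Set[str]:
    """Flags for one identification based on adduct logic.

    * ``sodiated_confirmed`` — a co-eluting EIC peak exists at the
      identification's own [M+Na]+ m/z.
    * ``suspected_insource_fragment`` — no such sodium adduct, and the
      observed retention time disagrees with the library's for this
      compound: the matching ion is likely an in-source fragment of a
      larger co-eluting molecule.
    * ``suspected_dimer_artifact`` — the annotated [M+H]+/[M+Na]+ m/z
      coincide with the [2M+H]+/[2M+Na]+ of another co-eluting
      identification, which can fully explain the signal.

    ``hit`` may be a FormulaHit or a MatchResult; ``others`` are sibling
    identifications from the same run.
    """
    if isinstance(hit, MatchResult):
        formula = hit.entry.formula
        rt = hit.query_rt
        if library_rt is None:
            library_rt = hit.entry.rt
    else:
        formula = hit.entry.formula
        rt = hit.rt
        if library_rt is None:
            library_rt = hit.entry.rt
    if rt is None:
        return set()
    flags: Set[str] = set()
    na_mz = ion_mz(formula, "[M+Na]+")
    na_peak = _coeluting_peak(run, na_mz, rt, config)
    if na_peak is not None:
        flags.add("sodiated_confirmed")
    elif library_rt is not None and abs(rt - library_rt) > config.rt_match_window:
        flags.add("suspected_insource_fragment")

    own_h = ion_mz(formula, "[M+H]+")
    dimer_species = [("[M+H]+", "[2M+H]+"), ("[M+Na]+", "[2M+Na]+")]
    for other in others:
        of = other.entry.formula
        ort = other.query_rt if isinstance(other, MatchResult) else other.rt
        if ort is None or abs(ort - rt) > config.rt_window:
            continue
        if str(of) == str(formula):
            continue
        n_coincide = 0
        for mono_label, dimer_label in dimer_species:
            if config.tol_fullscan.matches(
                ion_mz(formula, mono_label), ion_mz(of, dimer_label)
            ):
                n_coincide += 1
        if n_coincide == len(dimer_species):
            flags.add("suspected_dimer_artifact")
    if hasattr(hit, "flags"):
        hit.flags |= flags
    return flags


def annotate_adduct_flags(
    hits: Sequence, run: ScanSeries, config: Config = Config()
) -> None:
    """Run :func:`adduct_crosscheck` over a batch of identifications."""
    for h in hits:
        others = [o for o in hits if o is not h]
        adduct_crosscheck(h, run, others, config)


def disambiguate_isomer_series(
    matches: Sequence[MatchResult],
    run: ScanSeries,
    config: Config = Config(),
) -> List[MatchResult]:
    """Resolve water-loss isomer ambiguities using sodium-adduct EICs.

    When a hydrated compound X (matched through its [M+H-H2O]+ library
    spectrum) and its dehydrated isomer Y (matched through [M+H]+, with
    formula(Y) = formula(X) − H2O) both explain the same chromatographic
    peak, the co-eluting [M+Na]+ EIC decides: sodium at X's sodiated m/z
    keeps X, at Y's keeps Y; neither leaves both flagged ``ambiguous``.
    """
    water = MolecularFormula({"H": 2, "O": 1})
    out = list(matches)
    for i, mx in enumerate(out):
        if mx.ion_species != "[M+H-H2O]+":
            continue
        for j, my in enumerate(out):
            if my is mx or my.ion_species != "[M+H]+":
                continue
            if mx.query_rt is None or my.query_rt is None:
                continue
            if abs(mx.query_rt - my.query_rt) > config.rt_window:
                continue
            try:
                dehydrated = mx.entry.formula - water
            except Exception:
                continue
            if str(dehydrated) != str(my.entry.formula):
                continue
            rt = mx.query_rt
            na_x = _coeluting_peak(
                run, ion_mz(mx.entry.formula, "[M+Na]+"), rt, config
            )
            na_y = _coeluting_peak(
                run, ion_mz(my.entry.formula, "[M+Na]+"), rt, config
            )
            if na_x is not None and na_y is None:
                my.flags.add("rejected_isomer")
                mx.flags.add("assigned_by_na_adduct")
            elif na_y is not None and na_x is None:
                mx.flags.add("rejected_isomer")
                my.flags.add("assigned_by_na_adduct")
            else:
                mx.flags.add("ambiguous")
                my.flags.add("ambiguous")
    return [m for m in out if "rejected_isomer" not in m.flags]


# ---------------------------------------------------------------------------
# molecular feature extraction
# ---------------------------------------------------------------------------

_POS_FEATURE_SPECIES = ("[M+H]+", "[M+Na]+", "[M+NH4]+", "[2M+H]+", "[2M+Na]+")
_NEG_FEATURE_SPECIES = ("[M-H]-", "[M+HCOO]-", "[2M-H]-")


def _neutral_mass(mz: float, label: str) -> float:
    """Invert ion_mz for a singly charged species."""
    s = get_ion_species(label)
    from .chem import ELECTRON_MASS, monoisotopic_mass

    m = mz * abs(s.charge) + s.charge * ELECTRON_MASS
    m -= monoisotopic_mass(s.delta_add) - monoisotopic_mass(s.delta_sub)
    return m / s.multimer


def _gaussian_shape_score(peak: ChromPeak, trace_rt, trace_in) -> float:
    """R² of a Gaussian least-squares fit to the peak's EIC points (0–100)."""
    sel = (trace_rt >= peak.start_rt) & (trace_rt <= peak.end_rt)
    x, y = trace_rt[sel], trace_in[sel]
    if len(x) < 4 or y.max() <= 0:
        return 100.0  # too few points to judge shape
    def gauss(t, a, mu, s):
        return a * np.exp(-((t - mu) ** 2) / (2 * s ** 2))
    try:
        popt, _ = curve_fit(
            gauss, x, y,
            p0=[y.max(), peak.apex_rt, max((peak.end_rt - peak.start_rt) / 4, 1e-4)],
            maxfev=2000,
        )
        resid = y - gauss(x, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    except Exception:
        return 0.0
    return 100.0 * max(0.0, min(1.0, r2))


def _mz_bins(run: ScanSeries, tol: MassTolerance, min_intensity: float):
    """Cluster all MS1 centroids in the run into m/z bins."""
    mzs, intens = [], []
    for s in run.ms1_scans():
        keep = s.intensity >= min_intensity
        mzs.append(s.mz[keep])
        intens.append(s.intensity[keep])
    if not mzs:
        return []
    allmz = np.concatenate(mzs)
    allin = np.concatenate(intens)
    order = np.argsort(allmz)
    allmz, allin = allmz[order], allin[order]
    bins = []
    start = 0
    for i in range(1, len(allmz) + 1):
        if i == len(allmz) or allmz[i] - allmz[i - 1] > tol.window(allmz[i - 1]):
            seg_m, seg_i = allmz[start:i], allin[start:i]
            tot = seg_i.sum()
            if tot > 0:
                bins.append(float(np.dot(seg_m, seg_i) / tot))
            start = i
    return bins


def feature_extract(
    run: ScanSeries,
    config: Config = Config(),
    min_height: float = 5000.0,
) -> List[Feature]:
    """Unbiased molecular-feature extraction from full-scan data.

    Detects chromatographic peaks in every m/z bin, discards isotopologue
    traces (bins ~1.00336 or ~2.00671 Da above a stronger co-eluting bin),
    groups co-eluting ions whose implied neutral masses agree within
    tolerance under the common ion species, and scores each feature by a
    composite quality: 0.5·mass coherence + 0.3·cross-ion isotope-ratio
    consistency + 0.2·Gaussian peak shape, each 0–100. Features below the
    quality threshold (default 99) are dropped.
    """
    polarity = run.polarity
    species = (
        _POS_FEATURE_SPECIES if polarity.startswith("pos") else _NEG_FEATURE_SPECIES
    )
    tol = config.tol_fullscan
    ion_peaks = []  # (mz, ChromPeak, trace)
    for mz in _mz_bins(run, tol, min_height * 0.1):
        trace = extract_eic(run, mz, tol)
        for peak in detect_chrom_peaks(trace, min_height):
            if peak.area < config.min_area:
                continue
            ion_peaks.append({"mz": mz, "peak": peak, "trace": trace})
    # drop isotopologue traces
    from .spectra import C13_SHIFT

    def is_isotopologue(rec) -> bool:
        for other in ion_peaks:
            if other is rec:
                continue
            if abs(other["peak"].apex_rt - rec["peak"].apex_rt) > config.rt_window:
                continue
            if other["peak"].height <= rec["peak"].height:
                continue
            for k in (1, 2):
                if abs(rec["mz"] - other["mz"] - k * C13_SHIFT) <= tol.window(rec["mz"]):
                    return True
        return False

    monos = [rec for rec in ion_peaks if not is_isotopologue(rec)]
    monos.sort(key=lambda r: -r["peak"].height)
    features: List[Feature] = []
    used = [False] * len(monos)
    for i, rec in enumerate(monos):
        if used[i]:
            continue
        # hypothesize a species for the anchor ion; prefer the protonated /
        # deprotonated form, then count supporting co-eluting ions
        best_group, best_label = None, None
        for label in species:
            neutral = _neutral_mass(rec["mz"], label)
            if neutral <= 0:
                continue
            group = [(i, label)]
            for j, other in enumerate(monos):
                if j == i or used[j]:
                    continue
                if abs(other["peak"].apex_rt - rec["peak"].apex_rt) > config.rt_window:
                    continue
                for lab2 in species:
                    if lab2 == label:
                        continue
                    n2 = _neutral_mass(other["mz"], lab2)
                    if abs(n2 - neutral) <= tol.window(max(neutral, 1.0)):
                        group.append((j, lab2))
                        break
            if best_group is None or len(group) > len(best_group):
                best_group, best_label = group, label
        assert best_group is not None
        members = []
        neutral = _neutral_mass(rec["mz"], best_label)
        neutrals = []
        for j, lab in best_group:
            used[j] = True
            m = monos[j]
            members.append((lab, m["mz"], m["peak"].area))
            neutrals.append(_neutral_mass(m["mz"], lab))
        # quality subscores
        if len(neutrals) > 1:
            spread = max(neutrals) - min(neutrals)
            mass_q = 100.0 * max(0.0, 1.0 - spread / tol.window(max(neutral, 1.0)))
        else:
            mass_q = 100.0
        iso_q = _cross_ion_isotope_consistency(run, best_group, monos, tol)
        shape_q = _gaussian_shape_score(
            rec["peak"], rec["trace"].rt, rec["trace"].intensity
        )
        quality = 0.5 * mass_q + 0.3 * iso_q + 0.2 * shape_q
        if quality >= config.min_feature_quality:
            features.append(
                Feature(
                    neutral_mass=float(np.mean(neutrals)),
                    rt=rec["peak"].apex_rt,
                    ions=members,
                    quality=quality,
                )
            )
    features.sort(key=lambda f: f.rt)
    return features


def _cross_ion_isotope_consistency(run, group, monos, tol) -> float:
    """Ions of one compound share its isotope envelope: compare A+1/A across
    the group's member ions (100 when they agree or only one is measurable).
    Multimer ions carry n copies of the molecule, so their A+1 ratio is
    divided by n before comparison."""
    ratios = []
    for j, label in group:
        n = get_ion_species(label).multimer
        rec = monos[j]
        try:
            spec = merge_peak_spectrum(
                run, rec["peak"], (), 1.0, tol, subtract_background=False
            )
            a1, _ = measure_isotope_ratio(spec, rec["mz"], tol)
            ratios.append(a1 / n)
        except ValueError:
            continue
    if len(ratios) < 2:
        return 100.0
    spread = max(ratios) - min(ratios)
    return 100.0 * math.exp(-((spread / 7.0) ** 2) / 2.0)


# ---------------------------------------------------------------------------
# isobar bookkeeping
# ---------------------------------------------------------------------------

def count_isobars(collection, query) -> int:
    """Number of *other* records sharing a composition.

    ``collection`` is a SpectralLibrary or a sequence of entries with a
    ``formula`` attribute. ``query`` may be an entry (excluded from the
    count) or a bare formula (all matching records are counted).
    """
    if hasattr(query, "formula"):
        formula, self_entry = query.formula, query
    else:
        formula, self_entry = query, None
    entries = collection.entries if hasattr(collection, "entries") else list(collection)
    n = 0
    for e in entries:
        if self_entry is not None and (
            e is self_entry or getattr(e, "name", None) == getattr(self_entry, "name", None)
        ):
            continue
        if str(e.formula) == str(formula):
            n += 1
    return n
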