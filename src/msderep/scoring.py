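"""Forward, reverse and similarity scoring of MS/HRMS spectra.

The score family is a square-root-intensity cosine:

``forward = 100 · [Σ_pairs √(I_q · I_l)]² / (Σ_all I_q · Σ_all I_l)``

so a spectrum searched against itself scores 100, unexplained peaks on
either side penalise the forward score, and the reverse score — the same
statistic computed after discarding query peaks the library spectrum cannot
explain — is tolerant of extra query content (co-eluting compounds, noise).
Forward ≤ reverse holds for every pair by construction. Searches match the
precursor m/z first (forward/reverse) or skip it entirely (similarity, for
finding structural analogues that share fragment ions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .chem import MassTolerance, ppm_error, tolerance_window
from .speclib import LibraryEntry, SpectralLibrary
from .spectra import Peak, Spectrum

__all__ = [
    "PeakMatchSet",
    "MatchResult",
    "match_peaks",
    "forward_score",
    "reverse_score",
    "search",
    "similarity_search",
]


@dataclass
class PeakMatchSet:
    """Pairing of query and library peaks within the mass tolerance."""

    pairs: List[Tuple[Peak, Peak]]
    unmatched_query: List[Peak]
    unmatched_library: List[Peak]


@dataclass
class MatchResult:
    """A scored library hit for one query spectrum."""

    entry: LibraryEntry
    ion_species: str
    collision_energy: float
    forward: float
    reverse: float
    precursor_ppm: float
    n_matched: int
    query_rt: Optional[float] = None
    delta_rt: Optional[float] = None
    flags: set = field(default_factory=set)


def match_peaks(
    query: Spectrum, libspec: Spectrum, tol: MassTolerance = MassTolerance()
) -> PeakMatchSet:
    """Greedy peak assignment, most intense library peaks first.

    Each library peak claims the nearest unassigned query peak within the
    tolerance window; equidistant candidates break toward the more intense
    query peak. Deterministic.
    """
    if query.polarity != libspec.polarity:
        raise ValueError(
            f"polarity mismatch: query {query.polarity}, library {libspec.polarity}"
        )
    qmz, qint = query.mz, query.intensity
    taken = np.zeros(len(qmz), dtype=bool)
    pairs: List[Tuple[Peak, Peak]] = []
    unmatched_lib: List[Peak] = []
    lib_order = np.argsort(-libspec.intensity, kind="stable")
    for li in lib_order:
        lmz, lint = float(libspec.mz[li]), float(libspec.intensity[li])
        w = tolerance_window(lmz, tol)
        lo, hi = np.searchsorted(qmz, (lmz - w, lmz + w))
        best = -1
        best_key = None
        for qi in range(lo, hi):
            if taken[qi]:
                continue
            key = (abs(qmz[qi] - lmz), -qint[qi])
            if best_key is None or key < best_key:
                best, best_key = qi, key
        if best >= 0:
            taken[best] = True
            pairs.append((Peak(float(qmz[best]), float(qint[best])), Peak(lmz, lint)))
        else:
            unmatched_lib.append(Peak(lmz, lint))
    unmatched_q = [
        Peak(float(m), float(i))
        for m, i, t in zip(qmz, qint, taken)
        if not t
    ]
    return PeakMatchSet(pairs, unmatched_q, unmatched_lib)


def _score(pairs, total_q: float, total_l: float) -> float:
    if total_q <= 0 or total_l <= 0:
        return 0.0
    dot = sum(np.sqrt(q.intensity * l.intensity) for q, l in pairs)
    return float(min(100.0, 100.0 * dot * dot / (total_q * total_l)))


def forward_score(
    query: Spectrum, libspec: Spectrum, tol: MassTolerance = MassTolerance()
) -> float:
    """Score penalising unexplained peaks on both sides (0–100)."""
    if len(query) == 0 or len(libspec) == 0:
        return 0.0
    ms = match_peaks(query, libspec, tol)
    return _score(ms.pairs, float(query.intensity.sum()), float(libspec.intensity.sum()))


def reverse_score(
    query: Spectrum, libspec: Spectrum, tol: MassTolerance = MassTolerance()
) -> float:
    """Score over library-explained content only; extra query peaks ignored."""
    if len(query) == 0 or len(libspec) == 0:
        return 0.0
    ms = match_peaks(query, libspec, tol)
    total_q = sum(q.intensity for q, _ in ms.pairs)
    return _score(ms.pairs, total_q, float(libspec.intensity.sum()))


def _score_candidate(
    query: Spectrum,
    entry: LibraryEntry,
    ion_label: str,
    theo_mz: float,
    tol_product: MassTolerance,
) -> Optional[MatchResult]:
    energy = query.collision_energy if query.collision_energy is not None else 20.0
    got = entry.spectrum_at(ion_label, energy)
    if got is None:
        return None
    used_energy, libspec = got
    if libspec.polarity != query.polarity:
        return None
    ms = match_peaks(query, libspec, tol_product)
    total_q = float(query.intensity.sum())
    total_l = float(libspec.intensity.sum())
    fwd = _score(ms.pairs, total_q, total_l)
    rev = _score(ms.pairs, sum(q.intensity for q, _ in ms.pairs), total_l)
    delta_rt = None
    if entry.rt is not None and query.rt:
        delta_rt = query.rt - entry.rt
    return MatchResult(
        entry=entry,
        ion_species=ion_label,
        collision_energy=used_energy,
        forward=fwd,
        reverse=rev,
        precursor_ppm=ppm_error(query.precursor_mz, theo_mz),
        n_matched=len(ms.pairs),
        query_rt=query.rt or None,
        delta_rt=delta_rt,
    )


def search(
    query: Spectrum,
    lib: SpectralLibrary,
    tol_precursor: MassTolerance = MassTolerance(),
    tol_product: MassTolerance = MassTolerance(),
    min_forward: float = 50.0,
    min_reverse: float = 50.0,
) -> List[MatchResult]:
    """Precursor-constrained library search, ranked by forward score.

    Candidates come from the precursor index; each (entry, ion species) is
    scored at the query's collision energy (nearest stored energy if that
    exact energy is absent), filtered by the score thresholds, and ranked by
    forward score with ties broken by reverse score then |precursor ppm|.
    """
    if query.precursor_mz is None:
        raise ValueError("query spectrum has no precursor m/z")
    results = []
    for entry, ion_label, theo_mz in lib.lookup_by_precursor(
        query.precursor_mz, tol_precursor
    ):
        r = _score_candidate(query, entry, ion_label, theo_mz, tol_product)
        if r is None:
            continue
        if r.forward >= min_forward and r.reverse >= min_reverse:
            results.append(r)
    results.sort(key=lambda r: (-r.forward, -r.reverse, abs(r.precursor_ppm)))
    return results


def similarity_search(
    query: Spectrum,
    lib: SpectralLibrary,
    tol_product: MassTolerance = MassTolerance(),
    min_score: float = 50.0,
) -> List[Tuple[LibraryEntry, float]]:
    """Reverse-score the query against every library spectrum, ignoring the
    precursor mass; used to find analogues sharing fragment ions."""
    best: dict = {}
    for entry in lib:
        for (label, energy), libspec in entry.spectra.items():
            if libspec.polarity != query.polarity or len(libspec) == 0:
                continue
            s = reverse_score(query, libspec, tol_product)
            if s >= min_score and s > best.get(entry.name, (None, -1.0))[1]:
                best[entry.name] = (entry, s)
    ranked = sorted(best.values(), key=lambda es: -es[1])
    return ranked
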