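"""Scan data model, EIC extraction, peak detection and spectrum merging.

The central QTOF-specific concern here is detector saturation: in overloaded
scans the monoisotopic centroid drifts and the A+1/A isotope ratio is
distorted, so chromatographic-peak spectra are assembled only from scans low
on the peak flanks (below a height fraction, default 10%) and scans flagged
as saturated are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.signal import find_peaks

from .chem import (
    MassTolerance,
    MolecularFormula,
    isotope_pattern,
    tolerance_window,
)

__all__ = [
    "Peak",
    "Spectrum",
    "ScanSeries",
    "EICTrace",
    "ChromPeak",
    "extract_eic",
    "detect_chrom_peaks",
    "flag_saturated_scans",
    "merge_peak_spectrum",
    "merge_spectra",
    "measure_isotope_ratio",
    "C13_SHIFT",
]

#: Nominal A+1 / A+2 mass shifts used when reading isotope ratios off spectra.
C13_SHIFT = 1.00336
C13_SHIFT2 = 2.00671


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided mass spectrum (peaks kept as parallel numpy arrays)."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    ms_level: int = 1
    rt: float = 0.0
    precursor_mz: Optional[float] = None
    collision_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("require mz > 0 and intensity >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> List[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def intensity_within(self, target: float, tol: MassTolerance) -> float:
        """Summed intensity of peaks within the tolerance window of target."""
        w = tolerance_window(target, tol)
        lo, hi = np.searchsorted(self.mz, (target - w, target + w))
        return float(self.intensity[lo:hi].sum())

    def max_peak_within(
        self, target: float, tol: MassTolerance
    ) -> Optional[Peak]:
        """Most intense peak within the window, or None."""
        w = tolerance_window(target, tol)
        lo, hi = np.searchsorted(self.mz, (target - w, target + w))
        if hi <= lo:
            return None
        k = lo + int(np.argmax(self.intensity[lo:hi]))
        return Peak(float(self.mz[k]), float(self.intensity[k]))

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * factor)


@dataclass
class ScanSeries:
    """A time-ordered LC-MS run: interleaved MS1 and MS2 scans."""

    scans: List[Spectrum]
    run_id: str = "run"
    polarity: str = "positive"

    def __post_init__(self) -> None:
        for level in (1, 2):
            rts = [s.rt for s in self.scans if s.ms_level == level]
            if any(b <= a for a, b in zip(rts, rts[1:])):
                raise ValueError(
                    f"MS{level} retention times must be strictly increasing"
                )

    def ms1_indices(self) -> List[int]:
        return [i for i, s in enumerate(self.scans) if s.ms_level == 1]

    def ms1_scans(self) -> List[Spectrum]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> List[Spectrum]:
        return [s for s in self.scans if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class EICTrace:
    """Extracted ion chromatogram: one point per MS1 scan."""

    target_mz: float
    tolerance: MassTolerance
    rt: np.ndarray
    intensity: np.ndarray
    scan_indices: np.ndarray  # indices into the parent ScanSeries.scans

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class ChromPeak:
    """A detected chromatographic peak on an EIC."""

    apex_rt: float
    start_rt: float
    end_rt: float
    height: float
    area: float
    scan_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    eic_intensities: np.ndarray = field(default_factory=lambda: np.array([]))
    saturated_scan_indices: Set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.start_rt <= self.apex_rt <= self.end_rt):
            raise ValueError("require start_rt <= apex_rt <= end_rt")


def extract_eic(
    run: ScanSeries, target: float, tol: MassTolerance
) -> EICTrace:
    """Per-MS1-scan summed intensity within the tolerance window of target."""
    idx = run.ms1_indices()
    if not idx:
        raise ValueError("run contains no MS1 scans")
    rt = np.array([run.scans[i].rt for i in idx])
    inten = np.array(
        [run.scans[i].intensity_within(target, tol) for i in idx]
    )
    return EICTrace(target, tol, rt, inten, np.array(idx))


def detect_chrom_peaks(
    trace: EICTrace,
    min_height: float = 0.0,
    boundary_fraction: float = 0.05,
) -> List[ChromPeak]:
    """Local-maximum peak picking with flank boundaries.

    Boundaries extend from each apex to the first surrounding local minimum
    that falls below ``boundary_fraction`` of the apex height (or the trace
    edge / a higher intervening minimum); the area is the trapezoid integral
    over [start, end] in counts·min.
    """
    if len(trace) == 0:
        raise ValueError("empty EIC trace")
    y = trace.intensity
    apexes, _ = find_peaks(y, height=max(min_height, np.finfo(float).tiny))
    peaks: List[ChromPeak] = []
    for a in apexes:
        floor = boundary_fraction * y[a]
        lo = a
        while lo > 0:
            if y[lo - 1] <= floor:
                lo -= 1
                break
            if y[lo - 1] > y[lo]:  # rising again: valley between peaks
                break
            lo -= 1
        hi = a
        n = len(y) - 1
        while hi < n:
            if y[hi + 1] <= floor:
                hi += 1
                break
            if y[hi + 1] > y[hi]:
                break
            hi += 1
        if hi == lo:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], trace.rt[lo : hi + 1]))
        if area <= 0:
            continue
        peaks.append(
            ChromPeak(
                apex_rt=float(trace.rt[a]),
                start_rt=float(trace.rt[lo]),
                end_rt=float(trace.rt[hi]),
                height=float(y[a]),
                area=area,
                scan_indices=trace.scan_indices[lo : hi + 1].copy(),
                eic_intensities=y[lo : hi + 1].copy(),
            )
        )
    return peaks


def measure_isotope_ratio(
    spectrum: Spectrum, mono: float, tol: MassTolerance
) -> Tuple[float, float]:
    """(A+1/A, A+2/A) in percent, read at mono + 1.00336 / + 2.00671.

    Raises if no peak lies within tolerance of the monoisotopic m/z; missing
    heavier isotopologues read as 0.
    """
    mono_peak = spectrum.max_peak_within(mono, tol)
    if mono_peak is None or mono_peak.intensity <= 0:
        raise ValueError(
            f"monoisotopic peak not found within tolerance of m/z {mono}"
        )
    out = []
    for shift in (C13_SHIFT, C13_SHIFT2):
        p = spectrum.max_peak_within(mono + shift, tol)
        out.append(100.0 * p.intensity / mono_peak.intensity if p else 0.0)
    return out[0], out[1]


def flag_saturated_scans(
    run: ScanSeries,
    peak: ChromPeak,
    target: float,
    ceiling: float,
    formula: Optional[MolecularFormula] = None,
    tol: MassTolerance = MassTolerance(),
    isotope_deviation_limit: float = 5.0,
) -> Set[int]:
    """Scan indices within the peak that look detector-overloaded.

    A scan is flagged when (a) the target-ion intensity reaches ``ceiling``
    or (b), if a formula is supplied, its measured A+1/A ratio deviates from
    the theoretical envelope by more than ``isotope_deviation_limit``
    percentage points (the signature of clipping the monoisotopic peak).
    """
    theo_a1 = None
    if formula is not None:
        theo_a1 = isotope_pattern(formula).relative(1)
    flagged: Set[int] = set()
    for i in peak.scan_indices:
        scan = run.scans[int(i)]
        p = scan.max_peak_within(target, tol)
        if p is None:
            continue
        if p.intensity >= ceiling:
            flagged.add(int(i))
            continue
        if theo_a1 is not None:
            try:
                a1, _ = measure_isotope_ratio(scan, target, tol)
            except ValueError:
                continue
            if abs(a1 - theo_a1) > isotope_deviation_limit:
                flagged.add(int(i))
    return flagged


def _bin_centroids(
    mzs: np.ndarray, intens: np.ndarray, tol: MassTolerance
) -> Tuple[np.ndarray, np.ndarray, List[np.ndarray]]:
    """Cluster centroids across scans at tolerance-window width.

    Consecutive sorted m/z values are merged while the gap stays within the
    window; each bin reports the intensity-weighted centroid m/z. Returns
    (centroid_mz, summed_intensity, member index arrays).
    """
    order = np.argsort(mzs, kind="stable")
    mzs, intens = mzs[order], intens[order]
    cmz, csum, members = [], [], []
    start = 0
    for i in range(1, len(mzs) + 1):
        if i == len(mzs) or mzs[i] - mzs[i - 1] > tolerance_window(mzs[i - 1], tol):
            seg_mz, seg_in = mzs[start:i], intens[start:i]
            tot = seg_in.sum()
            if tot > 0:
                cmz.append(float(np.dot(seg_mz, seg_in) / tot))
            else:
                cmz.append(float(seg_mz.mean()))
            csum.append(float(tot))
            members.append(order[start:i])
            start = i
    return np.array(cmz), np.array(csum), members


def merge_spectra(
    spectra: Sequence[Spectrum], tol: MassTolerance = MassTolerance()
) -> Spectrum:
    """Average spectra across scans: bin centroids, mean intensity per bin.

    Intensities are divided by the number of contributing scans so that a
    flanking-scan background (a per-scan median) can be subtracted on the
    same scale.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    mzs = np.concatenate([s.mz for s in spectra])
    intens = np.concatenate([s.intensity for s in spectra])
    if len(mzs) == 0:
        first = spectra[0]
        return replace(first, mz=np.array([]), intensity=np.array([]))
    cmz, csum, _ = _bin_centroids(mzs, intens, tol)
    first = spectra[0]
    return Spectrum(
        mz=cmz,
        intensity=csum / len(spectra),
        polarity=first.polarity,
        ms_level=first.ms_level,
        rt=float(np.mean([s.rt for s in spectra])),
        precursor_mz=first.precursor_mz,
        collision_energy=first.collision_energy,
    )


def _background_spectrum(
    run: ScanSeries, peak: ChromPeak, tol: MassTolerance
) -> Optional[Spectrum]:
    """Per-bin median of MS1 scans flanking the peak (2x width each side)."""
    width = peak.end_rt - peak.start_rt
    lo_rt, hi_rt = peak.start_rt - 2 * width, peak.end_rt + 2 * width
    flank = [
        s
        for s in run.ms1_scans()
        if (lo_rt <= s.rt < peak.start_rt) or (peak.end_rt < s.rt <= hi_rt)
    ]
    if not flank:
        return None
    mzs = np.concatenate([s.mz for s in flank])
    intens = np.concatenate([s.intensity for s in flank])
    if len(mzs) == 0:
        return None
    order = np.argsort(mzs, kind="stable")
    mzs, intens = mzs[order], intens[order]
    out_mz, out_in = [], []
    start = 0
    n_scans = len(flank)
    for i in range(1, len(mzs) + 1):
        if i == len(mzs) or mzs[i] - mzs[i - 1] > tolerance_window(mzs[i - 1], tol):
            seg_in = intens[start:i]
            # a bin absent from a scan contributes 0 to that scan's median
            vals = np.zeros(max(n_scans, len(seg_in)))
            vals[: len(seg_in)] = np.sort(seg_in)[::-1]
            med = float(np.median(vals))
            if med > 0:
                tot = seg_in.sum()
                out_mz.append(float(np.dot(mzs[start:i], seg_in) / tot))
                out_in.append(med)
            start = i
    if not out_mz:
        return None
    return Spectrum(np.array(out_mz), np.array(out_in))


def _subtract_background(
    spec: Spectrum, bg: Optional[Spectrum], tol: MassTolerance
) -> Spectrum:
    if bg is None or len(spec) == 0:
        return spec
    inten = spec.intensity.copy()
    for j, m in enumerate(spec.mz):
        p = bg.max_peak_within(m, tol)
        if p is not None:
            inten[j] = max(0.0, inten[j] - p.intensity)
    keep = inten > 0
    return replace(spec, mz=spec.mz[keep], intensity=inten[keep])


def merge_peak_spectrum(
    run: ScanSeries,
    peak: ChromPeak,
    exclude: Iterable[int] = (),
    height_fraction: float = 0.10,
    tol: MassTolerance = MassTolerance(),
    subtract_background: bool = True,
) -> Spectrum:
    """Merged spectrum of a chromatographic peak from low-flank scans.

    Uses the scans whose EIC intensity is at or below ``height_fraction`` of
    the peak height (default 10%, avoiding detector overload at the apex),
    after removing explicitly excluded scans; if none qualify the two
    boundary scans are used. The per-bin median spectrum of flanking scans
    is subtracted as background, floored at zero.
    """
    if not (0 < height_fraction <= 1):
        raise ValueError("height_fraction must be in (0, 1]")
    exclude = set(int(i) for i in exclude)
    usable = [
        (int(i), float(h))
        for i, h in zip(peak.scan_indices, peak.eic_intensities)
        if int(i) not in exclude
    ]
    if not usable:
        raise ValueError("peak has no usable scans after exclusions")
    chosen = [i for i, h in usable if h <= height_fraction * peak.height]
    if not chosen:
        chosen = [usable[0][0], usable[-1][0]] if len(usable) > 1 else [usable[0][0]]
    spectra = [run.scans[i] for i in sorted(set(chosen))]
    merged = merge_spectra(spectra, tol)
    if subtract_background:
        bg = _background_spectrum(run, peak, tol)
        merged = _subtract_background(merged, bg, tol)
    return merged
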