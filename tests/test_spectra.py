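"""EIC extraction, chromatographic peak detection, saturation handling and
cross-scan spectrum merging."""

import numpy as np
import pytest

import msderep as M
from conftest import gaussian_ms1_run, simple_compound

TOL = M.MassTolerance()


def _mz(c, label="[M+H]+"):
    return M.ion_mz(c.formula, label)


# ---------------------------------------------------------------------------
# EIC extraction
# ---------------------------------------------------------------------------

def test_eic_identity_for_single_target_peak():
    scans = [
        M.Spectrum(np.array([200.0]), np.array([float(i)]), rt=0.1 * (i + 1))
        for i in range(5)
    ]
    run = M.ScanSeries(scans)
    trace = M.extract_eic(run, 200.0, TOL)
    assert np.allclose(trace.intensity, [0, 1, 2, 3, 4])


def test_eic_zero_window_misses_offset_peak():
    scans = [M.Spectrum(np.array([200.01]), np.array([5.0]), rt=0.1)]
    trace = M.extract_eic(M.ScanSeries(scans), 200.0, M.MassTolerance(0, 0))
    assert np.all(trace.intensity == 0)


def test_eic_area_matches_injected_gaussian():
    c = simple_compound(response=1e6, sigma=0.05)
    run, _ = gaussian_ms1_run([c])
    trace = M.extract_eic(run, _mz(c), TOL)
    area = np.trapezoid(trace.intensity, trace.rt)
    # mono + isotopologues fall in the window only for the mono target
    expected = 1e6 * np.sqrt(2 * np.pi) * 0.05
    assert area == pytest.approx(expected, rel=0.01)


def test_eic_additive_over_scan_partition():
    c = simple_compound()
    run, _ = gaussian_ms1_run([c], noise=100.0, seed=5)
    even = M.ScanSeries(run.scans[::2])
    odd = M.ScanSeries(run.scans[1::2])
    full = M.extract_eic(run, _mz(c), TOL).intensity.sum()
    parts = (
        M.extract_eic(even, _mz(c), TOL).intensity.sum()
        + M.extract_eic(odd, _mz(c), TOL).intensity.sum()
    )
    assert full == pytest.approx(parts, rel=1e-12)


def test_eic_requires_ms1():
    with pytest.raises(ValueError):
        M.extract_eic(M.ScanSeries([]), 100.0, TOL)


# ---------------------------------------------------------------------------
# chromatographic peak detection
# ---------------------------------------------------------------------------

def test_single_gaussian_gives_one_peak_at_apex():
    c = simple_compound(rt=2.0)
    run, _ = gaussian_ms1_run([c])
    peaks = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)
    assert len(peaks) == 1
    assert abs(peaks[0].apex_rt - 2.0) <= 0.5 / 60 + 1e-9


def test_flat_trace_gives_no_peaks():
    scans = [
        M.Spectrum(np.array([100.0]), np.array([0.0]), rt=0.1 * (i + 1))
        for i in range(10)
    ]
    trace = M.extract_eic(M.ScanSeries(scans), 500.0, TOL)
    assert M.detect_chrom_peaks(trace, 10) == []


def test_two_separated_gaussians_resolved_with_accurate_areas():
    f = "C20H30O5"
    c1 = simple_compound("A", f, rt=1.0, sigma=0.05, response=1e6)
    c2 = simple_compound("B", f, rt=1.5, sigma=0.05, response=5e5)  # 10 sigma
    run, _ = gaussian_ms1_run([c1, c2])
    peaks = M.detect_chrom_peaks(
        M.extract_eic(run, _mz(c1), TOL), 1000
    )
    assert len(peaks) == 2
    expected = [1e6 * np.sqrt(2 * np.pi) * 0.05, 5e5 * np.sqrt(2 * np.pi) * 0.05]
    for p, e in zip(peaks, expected):
        assert p.area == pytest.approx(e, rel=0.02)


# ---------------------------------------------------------------------------
# saturation flagging
# ---------------------------------------------------------------------------

def _clipped_run(ceiling=5e5):
    c = simple_compound(response=2e6)
    run, truth = gaussian_ms1_run([c], ceiling=ceiling, seed=3)
    return c, run, truth


def test_clipped_scans_flagged_by_intensity_rule():
    c, run, truth = _clipped_run()
    pk = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)[0]
    flagged = M.flag_saturated_scans(run, pk, _mz(c), 5e5)
    assert flagged == set(truth.clipped[(c.name, "[M+H]+")])


def test_unclipped_run_flags_nothing():
    c = simple_compound(response=2e5)
    run, truth = gaussian_ms1_run([c])
    assert truth.clipped == {}
    pk = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)[0]
    assert M.flag_saturated_scans(run, pk, _mz(c), 5e5, c.formula) == set()


def test_isotope_distortion_rule_flags_apex_without_ceiling_hint():
    # detection via rule (b) only: pass an unreachable ceiling
    c, run, truth = _clipped_run()
    pk = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)[0]
    flagged = M.flag_saturated_scans(
        run, pk, _mz(c), ceiling=1e12, formula=c.formula
    )
    clipped = set(truth.clipped[(c.name, "[M+H]+")])
    assert flagged  # distortion detected
    assert flagged <= clipped


# ---------------------------------------------------------------------------
# spectrum merging
# ---------------------------------------------------------------------------

def test_merge_identical_scans_is_idempotent():
    spec = M.Spectrum(np.array([100.0, 150.0]), np.array([50.0, 100.0]))
    merged = M.merge_spectra([spec, spec, spec], TOL)
    assert np.allclose(merged.mz, spec.mz)
    assert np.allclose(merged.intensity, spec.intensity)


def test_merge_invariant_to_scan_order():
    c = simple_compound()
    run, _ = gaussian_ms1_run([c], noise=100.0, seed=9)
    pk = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)[0]
    m1 = M.merge_peak_spectrum(run, pk)
    pk2 = M.ChromPeak(
        pk.apex_rt, pk.start_rt, pk.end_rt, pk.height, pk.area,
        pk.scan_indices[::-1].copy(), pk.eic_intensities[::-1].copy(),
    )
    m2 = M.merge_peak_spectrum(run, pk2)
    assert np.allclose(m1.mz, m2.mz)
    assert np.allclose(m1.intensity, m2.intensity)


def test_merged_low_scans_recover_isotope_ratio_of_clipped_peak():
    c, run, truth = _clipped_run()
    mz = _mz(c)
    pk = M.detect_chrom_peaks(M.extract_eic(run, mz, TOL), 1000)[0]
    theo = M.isotope_pattern(
        M.get_ion_species("[M+H]+").ion_formula(c.formula)
    ).relative(1)
    apex_idx = int(pk.scan_indices[np.argmax(pk.eic_intensities)])
    a1_apex, _ = M.measure_isotope_ratio(run.scans[apex_idx], mz, TOL)
    merged = M.merge_peak_spectrum(run, pk)
    a1_merged, _ = M.measure_isotope_ratio(merged, mz, TOL)
    assert abs(a1_apex - theo) > 5.0
    assert abs(a1_merged - theo) <= 2.0


def test_constant_background_ion_removed_by_subtraction():
    c = simple_compound(rt=2.0, response=1e6)
    run, _ = gaussian_ms1_run([c])
    bg_mz = 400.123
    scans = [
        M.Spectrum(
            np.append(s.mz, bg_mz), np.append(s.intensity, 5000.0), rt=s.rt
        )
        for s in run.scans
    ]
    run2 = M.ScanSeries(scans)
    pk = M.detect_chrom_peaks(M.extract_eic(run2, _mz(c), TOL), 1000)[0]
    merged = M.merge_peak_spectrum(run2, pk)
    assert merged.intensity_within(bg_mz, TOL) == 0.0
    assert merged.intensity_within(_mz(c), TOL) > 0.0


def test_merge_with_all_scans_excluded_raises():
    c = simple_compound()
    run, _ = gaussian_ms1_run([c])
    pk = M.detect_chrom_peaks(M.extract_eic(run, _mz(c), TOL), 1000)[0]
    with pytest.raises(ValueError):
        M.merge_peak_spectrum(run, pk, exclude=set(map(int, pk.scan_indices)))


def test_saturation_exclusion_never_degrades_merged_mass_accuracy():
    c, run, truth = _clipped_run()
    mz = _mz(c)
    pk = M.detect_chrom_peaks(M.extract_eic(run, mz, TOL), 1000)[0]
    flagged = M.flag_saturated_scans(run, pk, mz, 5e5, c.formula)
    m_all = M.merge_peak_spectrum(run, pk, (), height_fraction=1.0)
    m_excl = M.merge_peak_spectrum(run, pk, flagged, height_fraction=1.0)
    err_all = abs(M.ppm_error(m_all.max_peak_within(mz, TOL).mz, mz))
    err_excl = abs(M.ppm_error(m_excl.max_peak_within(mz, TOL).mz, mz))
    assert err_excl <= err_all


# ---------------------------------------------------------------------------
# isotope-ratio measurement
# ---------------------------------------------------------------------------

def test_measure_isotope_ratio_direct_reading():
    m = 300.0
    spec = M.Spectrum(
        np.array([m, m + 1.00336]), np.array([100.0, 10.0])
    )
    a1, a2 = M.measure_isotope_ratio(spec, m, TOL)
    assert a1 == pytest.approx(10.0)
    assert a2 == 0.0


def test_measure_isotope_ratio_mono_only():
    spec = M.Spectrum(np.array([300.0]), np.array([50.0]))
    assert M.measure_isotope_ratio(spec, 300.0, TOL) == (0.0, 0.0)


def test_measure_isotope_ratio_missing_mono_raises():
    spec = M.Spectrum(np.array([300.0]), np.array([50.0]))
    with pytest.raises(ValueError):
        M.measure_isotope_ratio(spec, 500.0, TOL)


def test_synthetic_c40_a1_near_theory():
    c = simple_compound("C40", "C40H60O4", rt=1.0, response=1e6)
    run, _ = gaussian_ms1_run([c])
    mz = _mz(c)
    pk = M.detect_chrom_peaks(M.extract_eic(run, mz, TOL), 1000)[0]
    merged = M.merge_peak_spectrum(run, pk)
    a1, _ = M.measure_isotope_ratio(merged, mz, TOL)
    # dominated by the 13C single-substitution probability of 40 carbons
    assert a1 == pytest.approx(40 * 1.08, abs=2.0)
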