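"""Dereplication pipelines: library screening, full-scan formula search,
isotope scoring, adduct cross-validation and feature extraction."""

import dataclasses

import numpy as np
import pytest

import msderep as M
from conftest import gaussian_ms1_run, simple_compound
from msderep.derep import count_isobars

TOL = M.MassTolerance()
CFG = M.Config()


def _pattern(formula, label="[M+H]+"):
    return M.isotope_pattern(M.get_ion_species(label).ion_formula(formula))


# ---------------------------------------------------------------------------
# isotope scoring
# ---------------------------------------------------------------------------

def test_isotope_score_exact_agreement_is_100():
    theo = _pattern(M.parse_formula("C20H30O5"))
    assert M.isotope_score(theo, theo) == pytest.approx(100.0)


def test_isotope_score_instrument_accuracy_still_high():
    theo = _pattern(M.parse_formula("C20H30O5"))
    obs = (theo.relative(1) + 2.0, theo.relative(2) + 2.0)
    assert M.isotope_score(obs, theo) > 90.0


def test_isotope_score_halved_a1_fails_threshold_for_c20():
    theo = _pattern(M.parse_formula("C20H30O5"))
    obs = (theo.relative(1) * 0.5, theo.relative(2))
    assert M.isotope_score(obs, theo) < 70.0


def test_isotope_score_missing_a1_for_c30_near_zero():
    theo = _pattern(M.parse_formula("C30H46O4"))
    obs = (0.0, theo.relative(2))
    assert M.isotope_score(obs, theo) < 1.0


# ---------------------------------------------------------------------------
# isobar bookkeeping
# ---------------------------------------------------------------------------

def test_patulin_has_six_isobars(fixture_library):
    assert count_isobars(fixture_library, fixture_library.by_name("Patulin")) == 6


def test_single_entry_library_has_no_isobars(fixture_library):
    solo = M.SpectralLibrary([fixture_library.by_name("Patulin")])
    assert count_isobars(solo, solo.by_name("Patulin")) == 0


def test_count_isobars_matches_brute_force(fixture_library):
    for e in fixture_library:
        brute = sum(
            1
            for o in fixture_library
            if o.name != e.name and str(o.formula) == str(e.formula)
        )
        assert count_isobars(fixture_library, e) == brute


# ---------------------------------------------------------------------------
# library screening of auto-MS/MS runs
# ---------------------------------------------------------------------------

def test_screen_identifies_all_spiked_compounds(
    negative_run, positive_run, fixture_library
):
    # recall 1.0 (no false negatives) across both polarities; every spiked
    # compound elutes above the DDA intensity floor
    for run, truth in (negative_run, positive_run):
        hits = M.library_screen(run, fixture_library)
        found = {h.entry.name for h in hits}
        spiked = {
            name for name in truth.compounds
            if truth.compounds[name].name in
            {e.name for e in fixture_library}
            and truth.compounds[name].response > 0
        }
        assert spiked <= found


def test_screen_non_library_compound_yields_nothing(fixture_library):
    c = M.SyntheticCompound(
        "unknown", M.parse_formula("C11H16N2O8"), rt=1.0, response=5e5,
        fragment_model={
            10.0: [(91.05, 100.0)], 20.0: [(77.04, 100.0)], 40.0: [(55.05, 100.0)],
        },
    )
    run, _ = M.simulate_run(M.RunRecipe(compounds=[c], seed=4))
    assert M.library_screen(run, fixture_library) == []


def test_coeluting_isobars_with_distinct_fragments_both_identified(
    fixture_library, fixture_comps
):
    # same formula, overlapping peaks 0.13 min apart, distinct fragment sets
    a = dataclasses.replace(fixture_comps["Patulin"], rt=3.00)
    b = dataclasses.replace(fixture_comps["Terreic acid"], rt=3.13)
    run, _ = M.simulate_run(
        M.RunRecipe(compounds=[a, b], polarity="negative", seed=6)
    )
    found = {h.entry.name for h in M.library_screen(run, fixture_library)}
    assert {"Patulin", "Terreic acid"} <= found


# ---------------------------------------------------------------------------
# aggressive dereplication (full-scan)
# ---------------------------------------------------------------------------

def _search_list(*comps):
    return [M.SearchListEntry(c.name, c.formula, c.rt) for c in comps]


def test_spiked_compound_hits_with_correct_species():
    c = simple_compound(adducts={"[M+H]+": 1.0, "[M+Na]+": 0.4})
    run, _ = gaussian_ms1_run([c], noise=100.0, seed=8)
    hits = M.aggressive_derep(run, _search_list(c), "positive")
    species = {h.ion_species for h in hits}
    assert {"[M+H]+", "[M+Na]+"} <= species
    assert all(h.isotope_score >= 70 for h in hits)


def test_small_area_peak_excluded():
    c = simple_compound(response=3000.0)  # area ~ 376 counts*min
    run, _ = gaussian_ms1_run([c])
    hits = M.aggressive_derep(
        run, _search_list(c), "positive", min_height=100.0
    )
    assert hits == []


def test_wrong_envelope_isobar_rejected_by_isotope_score():
    # C14H14O5 [M+H]+ and C8H19O7Cl [M+H]+ differ by 2.2 mDa: inside the
    # mass window, but the Cl formula demands a large A+2 the data lacks
    c = simple_compound("true", "C14H14O5", rt=1.0)
    run, _ = gaussian_ms1_run([c], noise=100.0, seed=10)
    wrong = M.SearchListEntry("impostor", M.parse_formula("C8H19O7Cl"))
    right = M.SearchListEntry("true", M.parse_formula("C14H14O5"))
    hits = M.aggressive_derep(run, [wrong, right], "positive")
    names = {h.entry.name for h in hits}
    assert "true" in names and "impostor" not in names


def test_hit_set_shrinks_with_stricter_thresholds():
    c1 = simple_compound("A", "C14H14O5", rt=1.0, response=5e5)
    c2 = simple_compound("B", "C20H30O5", rt=1.6, response=5e4)
    run, _ = gaussian_ms1_run([c1, c2], noise=150.0, seed=12)
    sl = _search_list(c1, c2)
    base = M.aggressive_derep(run, sl, "positive", CFG)
    strict_area = M.aggressive_derep(
        run, sl, "positive", dataclasses.replace(CFG, min_area=50_000)
    )
    strict_iso = M.aggressive_derep(
        run, sl, "positive", dataclasses.replace(CFG, min_isotope_score=99.5)
    )
    key = lambda hs: {(h.entry.name, h.ion_species, round(h.rt, 2)) for h in hs}
    assert key(strict_area) <= key(base)
    assert key(strict_iso) <= key(base)


# ---------------------------------------------------------------------------
# adduct cross-validation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def screened_positive(request):
    fixture_library = M.make_fixture_library(0)
    comps = M.fixture_compounds(0)
    pos = [
        c for c in comps.values()
        if not all(l.endswith("-") for l in c.adduct_ratios)
    ]
    run, truth = M.simulate_run(
        M.RunRecipe(compounds=pos, noise_level=200.0, seed=1)
    )
    hits = M.library_screen(run, fixture_library)
    M.annotate_adduct_flags(hits, run)
    return run, truth, hits


def test_insource_fragment_match_flagged(screened_positive):
    run, truth, hits = screened_positive
    mpa = [h for h in hits if h.entry.name == "Mycophenolic acid-like"]
    wrong_rt = [h for h in mpa if abs(h.query_rt - 7.95) > 0.5]
    assert wrong_rt and all(
        "suspected_insource_fragment" in h.flags for h in wrong_rt
    )


def test_genuine_compounds_confirmed_by_sodium_adduct(screened_positive):
    run, truth, hits = screened_positive
    for h in hits:
        c = truth.compounds.get(h.entry.name)
        if c is None or abs(h.query_rt - c.rt) > 0.1:
            continue
        if c.adduct_ratios.get("[M+Na]+", 0) > 0:
            assert "sodiated_confirmed" in h.flags
            assert "suspected_insource_fragment" not in h.flags


def test_dimer_coincidence_flagged_in_fullscan_screen(screened_positive):
    run, truth, _ = screened_positive
    quin = truth.compounds["Quinolactacin-like"]
    fellu_formula = quin.formula * 2
    sl = [
        M.SearchListEntry("Quinolactacin-like", quin.formula, quin.rt),
        M.SearchListEntry("Fellutanine-like", fellu_formula, quin.rt),
    ]
    hits = M.aggressive_derep(run, sl, "positive")
    M.annotate_adduct_flags(hits, run)
    fellu = [h for h in hits if h.entry.name == "Fellutanine-like"]
    assert fellu and all("suspected_dimer_artifact" in h.flags for h in fellu)
    quin_hits = [h for h in hits if h.entry.name == "Quinolactacin-like"]
    assert quin_hits and all(
        "suspected_dimer_artifact" not in h.flags for h in quin_hits
    )


# ---------------------------------------------------------------------------
# water-loss isomer disambiguation
# ---------------------------------------------------------------------------

def _isomer_matches(run, lib, rt):
    """Search the merged MS2 group at the shared fragment-precursor m/z."""
    hits = []
    shared_mz = M.ion_mz(lib.by_name("Ophiobolin G-like").formula, "[M+H]+")
    group = [
        s for s in run.ms2_scans()
        if abs(s.precursor_mz - shared_mz) < 0.02
        and abs(s.rt - rt) < 0.1
        and s.collision_energy == 20.0
    ]
    merged = M.merge_spectra(group, TOL)
    merged.precursor_mz = shared_mz
    merged.collision_energy = 20.0
    return M.search(merged, lib, min_forward=0, min_reverse=0)


def test_hydrated_compound_assigned_when_its_na_adduct_coelutes(
    fixture_library, positive_run
):
    run, truth = positive_run
    matches = _isomer_matches(run, fixture_library, 12.60)
    assert {m.entry.name for m in matches} >= {
        "Ophiobolin K-like", "Ophiobolin G-like"
    }
    kept = M.disambiguate_isomer_series(matches, run)
    names = {m.entry.name for m in kept}
    assert "Ophiobolin K-like" in names
    assert "Ophiobolin G-like" not in names


def test_dehydrated_compound_assigned_at_its_own_peak(
    fixture_library, positive_run
):
    run, truth = positive_run
    matches = _isomer_matches(run, fixture_library, 12.81)
    kept = M.disambiguate_isomer_series(matches, run)
    names = {m.entry.name for m in kept}
    assert "Ophiobolin G-like" in names
    assert "Ophiobolin K-like" not in names


def test_no_sodium_adduct_leaves_ambiguity():
    comps = M.fixture_compounds(0)
    k = dataclasses.replace(
        comps["Ophiobolin K-like"],
        adduct_ratios={"[M+H]+": 1.0, "[M+H-H2O]+": 0.8},
    )
    run, _ = M.simulate_run(M.RunRecipe(compounds=[k], seed=13))
    lib = M.make_fixture_library(0)
    matches = _isomer_matches(run, lib, 12.60)
    kept = M.disambiguate_isomer_series(matches, run)
    flagged = [m for m in kept if "ambiguous" in m.flags]
    assert len(flagged) >= 2


# ---------------------------------------------------------------------------
# molecular feature extraction
# ---------------------------------------------------------------------------

def test_adducts_and_dimer_grouped_into_one_feature():
    c = simple_compound(
        "F", "C16H18N2O2", rt=1.0,
        adducts={"[M+H]+": 1.0, "[M+Na]+": 0.5, "[2M+H]+": 0.3},
    )
    run, _ = gaussian_ms1_run([c])
    feats = M.feature_extract(run)
    assert len(feats) == 1
    f = feats[0]
    assert len(f.ions) == 3
    neutral = M.monoisotopic_mass(c.formula)
    assert abs(f.neutral_mass - neutral) <= TOL.window(neutral)
    assert f.quality >= 99.0


def test_coeluting_unrelated_compounds_give_two_features():
    c1 = simple_compound("A", "C16H18N2O2", rt=1.0,
                         adducts={"[M+H]+": 1.0, "[M+Na]+": 0.4})
    c2 = simple_compound("B", "C27H28O11", rt=1.0,
                         adducts={"[M+H]+": 1.0, "[M+Na]+": 0.4})
    run, _ = gaussian_ms1_run([c1, c2])
    feats = M.feature_extract(run)
    assert len(feats) == 2
    masses = sorted(f.neutral_mass for f in feats)
    expected = sorted(
        M.monoisotopic_mass(c.formula) for c in (c1, c2)
    )
    for got, want in zip(masses, expected):
        assert abs(got - want) <= TOL.window(want)


def test_feature_extract_empty_run_is_empty():
    assert M.feature_extract(M.ScanSeries([])) == []
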