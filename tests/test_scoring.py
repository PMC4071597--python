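"""Forward/reverse/similarity scoring behavior and search ranking."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msderep as M

TOL = M.MassTolerance()


def _spec(mz, inten, **kw):
    kw.setdefault("ms_level", 2)
    return M.Spectrum(np.array(mz, float), np.array(inten, float), **kw)


RNG_SPEC = st.integers(0, 10_000)


def _random_spectrum(seed, n_min=3, n_max=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max))
    # well-separated m/z so greedy matching is a bijection on shared peaks
    mz = np.sort(rng.choice(np.arange(50, 500, 1.0), size=n, replace=False))
    mz = mz + rng.uniform(-0.2, 0.2, n)
    inten = 10 ** rng.uniform(1, 4, n)
    return _spec(mz, inten)


# ---------------------------------------------------------------------------
# peak matching
# ---------------------------------------------------------------------------

def test_identical_spectra_fully_paired():
    s = _spec([100, 150, 200], [10, 50, 30])
    ms = M.match_peaks(s, s, TOL)
    assert len(ms.pairs) == 3
    assert not ms.unmatched_query and not ms.unmatched_library


def test_disjoint_spectra_zero_pairs():
    a = _spec([100, 150], [10, 20])
    b = _spec([300, 350], [10, 20])
    ms = M.match_peaks(a, b, TOL)
    assert ms.pairs == []
    assert len(ms.unmatched_query) == 2 and len(ms.unmatched_library) == 2


def test_nearest_query_peak_wins_ties_by_intensity():
    lib = _spec([200.000], [100.0])
    q_near = _spec([199.9995, 200.003], [5.0, 50.0])
    ms = M.match_peaks(q_near, lib, TOL)
    assert len(ms.pairs) == 1
    assert ms.pairs[0][0].mz == pytest.approx(199.9995)  # nearest m/z wins
    q_tie = _spec([199.998, 200.002], [5.0, 50.0])
    ms = M.match_peaks(q_tie, lib, TOL)
    assert ms.pairs[0][0].intensity == 50.0  # exact tie -> higher intensity


def test_polarity_mismatch_rejected():
    a = _spec([100], [1], polarity="positive")
    b = _spec([100], [1], polarity="negative")
    with pytest.raises(ValueError, match="polarity"):
        M.match_peaks(a, b, TOL)


# ---------------------------------------------------------------------------
# score definitions
# ---------------------------------------------------------------------------

def test_self_match_scores_100():
    s = _random_spectrum(42)
    assert M.forward_score(s, s, TOL) == pytest.approx(100.0, abs=1e-9)
    assert M.reverse_score(s, s, TOL) == pytest.approx(100.0, abs=1e-9)


def test_no_shared_peaks_scores_zero():
    a = _spec([100, 150], [10, 20])
    b = _spec([300, 350], [10, 20])
    assert M.forward_score(a, b, TOL) == 0.0
    assert M.reverse_score(a, b, TOL) == 0.0


def test_extra_query_peaks_penalize_forward_not_reverse():
    lib = _spec([100, 150, 200], [30, 60, 100])
    extra = _spec(
        [100, 150, 200, 250, 300], [30, 60, 100, 120, 70]
    )  # extra peaks carry ~50% of total intensity
    fwd = M.forward_score(extra, lib, TOL)
    rev = M.reverse_score(extra, lib, TOL)
    assert rev == pytest.approx(100.0, abs=1e-9)
    assert fwd < rev
    assert fwd < 60.0


def test_missing_library_peak_penalizes_reverse():
    lib = _spec([100, 150, 200], [30, 60, 100])
    q = _spec([100, 150], [30, 60])
    assert M.reverse_score(q, lib, TOL) < 100.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(RNG_SPEC, RNG_SPEC)
def test_forward_le_reverse_and_symmetry(seed_a, seed_b):
    a, b = _random_spectrum(seed_a), _random_spectrum(seed_b)
    fwd = M.forward_score(a, b, TOL)
    rev = M.reverse_score(a, b, TOL)
    assert 0.0 <= fwd <= rev + 1e-9
    assert rev <= 100.0
    assert fwd == pytest.approx(M.forward_score(b, a, TOL), abs=1e-6)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(RNG_SPEC, st.floats(0.01, 1e4))
def test_scores_invariant_to_intensity_scaling(seed, factor):
    a = _random_spectrum(seed)
    b = _random_spectrum(seed + 1)
    assert M.forward_score(a.scaled(factor), b, TOL) == pytest.approx(
        M.forward_score(a, b, TOL), rel=1e-9
    )
    assert M.reverse_score(a, b.scaled(factor), TOL) == pytest.approx(
        M.reverse_score(a, b, TOL), rel=1e-9
    )


# ---------------------------------------------------------------------------
# precursor-constrained search
# ---------------------------------------------------------------------------

def _self_query(lib, name, key_index=0):
    entry = lib.by_name(name)
    key = sorted(entry.spectra)[key_index]
    return dataclasses.replace(entry.spectra[key]), key


def test_self_retrieval_ranks_first_with_forward_100(fixture_library):
    q, _ = _self_query(fixture_library, "Patulin")
    res = M.search(q, fixture_library)
    assert res[0].entry.name == "Patulin"
    assert res[0].forward == pytest.approx(100.0, abs=1e-9)
    assert res[0].reverse == pytest.approx(100.0, abs=1e-9)


def test_isobar_is_best_hit_when_true_compound_removed(fixture_library):
    q, _ = _self_query(fixture_library, "Patulin")
    rest = M.SpectralLibrary(
        [e for e in fixture_library if e.name != "Patulin"]
    )
    res = M.search(q, rest, min_forward=0, min_reverse=0)
    assert res, "isobars should still be in the matching pool"
    assert res[0].entry.formula == fixture_library.by_name("Patulin").formula
    assert res[0].forward < 100.0


def test_precursor_off_by_10da_finds_nothing(fixture_library):
    q, _ = _self_query(fixture_library, "Patulin")
    q.precursor_mz += 10.0
    assert M.search(q, fixture_library) == []


def test_threshold_filtering_is_monotone(fixture_library):
    q, _ = _self_query(fixture_library, "Patulin")
    loose = {
        (r.entry.name, r.ion_species)
        for r in M.search(q, fixture_library, min_forward=0, min_reverse=0)
    }
    tight = {
        (r.entry.name, r.ion_species)
        for r in M.search(q, fixture_library, min_forward=50, min_reverse=70)
    }
    assert tight <= loose


def test_query_without_precursor_rejected(fixture_library):
    q, _ = _self_query(fixture_library, "Patulin")
    q.precursor_mz = None
    with pytest.raises(ValueError):
        M.search(q, fixture_library)


# ---------------------------------------------------------------------------
# similarity search (no precursor constraint)
# ---------------------------------------------------------------------------

def test_analogue_query_retrieves_parent_by_shared_fragments(
    fixture_library, fixture_comps
):
    analogue = fixture_comps["Asperphenamate +O analogue"]
    frags = analogue.fragment_model[20.0]
    q = _spec([m for m, _ in frags], [i for _, i in frags],
              precursor_mz=M.ion_mz(analogue.formula, "[M+H]+"))
    ranked = M.similarity_search(q, fixture_library, min_score=50)
    names = [e.name for e, _ in ranked]
    assert "Asperphenamate" in names
    # precursor-constrained search cannot find it (different parent mass)
    assert all(
        r.entry.name != "Asperphenamate" for r in M.search(q, fixture_library)
    )


def test_similarity_no_shared_fragments_empty(fixture_library):
    q = _spec([1234.5, 1250.7], [100, 50])
    assert M.similarity_search(q, fixture_library, min_score=10) == []


def test_similarity_self_query_scores_100(fixture_library):
    q, _ = _self_query(fixture_library, "Terreic acid")
    ranked = M.similarity_search(q, fixture_library, min_score=99.9)
    assert ranked[0][0].name == "Terreic acid"
    assert ranked[0][1] == pytest.approx(100.0, abs=1e-9)
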