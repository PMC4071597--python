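"""Molecular formulas, exact masses, ion species and isotope patterns.

All mass arithmetic in the package goes through this module. Atomic masses
and isotope abundances are pinned to a single embedded IUPAC/CODATA table so
that computed m/z values are stable across environments; the table can be
exported with :func:`element_table` for audit.

Conventions
-----------
* Ion m/z includes the electron mass: protonation adds
  ``m(H) - m(e) = 1.0072765`` Da, deprotonation subtracts it. This is required
  to reproduce QTOF lock-mass values at four decimal places.
* Only singly charged ions are supported; electrospray spectra of small
  molecules are treated as singly charged throughout.
* Isotopologue fine structure is aggregated by nominal mass shift (A+1, A+2,
  ...) with abundance-weighted centroid masses, matching how isotope ratios
  are read off centroided QTOF spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Tuple

import pandas as pd
from pyteomics import mass as _pyt_mass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "IonSpecies",
    "IsotopePattern",
    "MassTolerance",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_pattern",
    "tolerance_window",
    "ppm_error",
    "ION_SPECIES",
    "get_ion_species",
    "element_table",
]

ELECTRON_MASS = 0.000548579909
#: Mass added by protonation / removed by deprotonation (H minus one electron).
PROTON_MASS = 1.0072765

# Monoisotopic masses (Da) and isotope tables, IUPAC 2013 atomic masses with
# representative natural abundances. Each entry: lightest-first list of
# (isotope mass, fractional abundance). Elements without a listed heavy
# isotope are effectively monoisotopic at natural abundance.
_ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548351, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "F": [(18.9984031627, 1.0)],
    "P": [(30.9737615120, 1.0)],
    "S": [
        (31.9720706912, 0.9499),
        (32.9714585909, 0.0075),
        (33.9678669900, 0.0425),
        (35.9670807620, 0.0001),
    ],
    "Cl": [(34.9688527100, 0.7576), (36.9659025900, 0.2424)],
    "Br": [(78.9183376000, 0.5069), (80.9162906000, 0.4931)],
    "Na": [(22.9897692820, 1.0)],
    "K": [(38.9637064864, 0.932581), (39.9639981660, 0.000117), (40.9618252579, 0.067302)],
    "Si": [(27.9769265350, 0.92223), (28.9764946653, 0.04685), (29.9737701370, 0.03092)],
    "I": [(126.9044719, 1.0)],
}

_MONO: Dict[str, float] = {el: iso[0][0] for el, iso in _ISOTOPES.items()}


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


def element_table() -> pd.DataFrame:
    """Return the pinned element/isotope constants as a tidy DataFrame.

    Columns: element, isotope_mass, abundance, nominal_shift. Intended for
    export (``msderep lib constants``) so downstream users can audit every
    mass this package produces.
    """
    rows = []
    for el, isos in sorted(_ISOTOPES.items()):
        base = round(isos[0][0])
        for m, a in isos:
            rows.append(
                {"element": el, "isotope_mass": m, "abundance": a,
                 "nominal_shift": round(m) - base}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: a map element symbol -> non-negative count."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in _ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction would give negative {el} count"
                )
        return MolecularFormula(merged)

    def __mul__(self, n: int) -> "MolecularFormula":
        if n < 0:
            raise FormulaError("multiplier must be non-negative")
        return MolecularFormula({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(str(self))

    def __str__(self) -> str:
        return self.hill()

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style element-count string (any element order).

    Raises :class:`FormulaError` naming the offending token for unknown
    element symbols or malformed counts; no parentheses or isotope labels.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    if any(ch in text for ch in "()[]{}"):
        raise FormulaError(f"parenthesised formulas not supported: {text!r}")
    try:
        comp = _pyt_mass.Composition(formula=text)
    except Exception as exc:  # pyteomics raises its own error type
        raise FormulaError(f"malformed formula {text!r}: {exc}") from exc
    for token in comp:
        if token not in _ISOTOPES:
            raise FormulaError(
                f"unknown element symbol {token!r} in formula {text!r}"
            )
    return MolecularFormula(dict(comp))


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic (lightest-isotope) mass in Da; empty formula -> 0."""
    return sum(_MONO[el] * n for el, n in f.counts.items())


_EMPTY = MolecularFormula({})


@dataclass(frozen=True)
class IonSpecies:
    """An adduct/loss/multimer rule mapping a neutral formula to an ion m/z.

    ``m/z = (n·M + Δadd − Δsub − z·m_e) / |z|`` with ``z = ±1``. A "bare"
    species (no add/sub) represents an already-charged fragment composition
    such as ``[C16H16NO]+`` and only corrects for the electron mass.
    """

    label: str
    multimer: int = 1
    delta_add: MolecularFormula = _EMPTY
    delta_sub: MolecularFormula = _EMPTY
    charge: int = 1

    def __post_init__(self) -> None:
        if self.multimer < 1:
            raise ValueError("multimer count must be >= 1")
        if self.charge not in (-1, 1):
            raise ValueError(
                f"unsupported charge {self.charge}: only singly charged ions"
            )

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def ion_formula(self, neutral: MolecularFormula) -> MolecularFormula:
        """Elemental composition of the ion (electron ignored)."""
        return neutral * self.multimer + self.delta_add - self.delta_sub

    def mz(self, neutral: MolecularFormula) -> float:
        m = (
            self.multimer * monoisotopic_mass(neutral)
            + monoisotopic_mass(self.delta_add)
            - monoisotopic_mass(self.delta_sub)
            - self.charge * ELECTRON_MASS
        )
        return m / abs(self.charge)


def _F(text: str) -> MolecularFormula:
    return parse_formula(text)


def _build_species() -> Dict[str, IonSpecies]:
    H, Na, NH4, H2O = _F("H"), _F("Na"), _F("NH4"), _F("H2O")
    HCOO, HCOOH, CH3COOH = _F("CHO2"), _F("CH2O2"), _F("C2H4O2")
    specs = [
        IonSpecies("[M+H]+", 1, H, _EMPTY, +1),
        IonSpecies("[M+Na]+", 1, Na, _EMPTY, +1),
        IonSpecies("[M+NH4]+", 1, NH4, _EMPTY, +1),
        IonSpecies("[M+K]+", 1, _F("K"), _EMPTY, +1),
        IonSpecies("[M+H-H2O]+", 1, H, H2O, +1),
        IonSpecies("[M+H-2H2O]+", 1, H, _F("H4O2"), +1),
        IonSpecies("[M+H-HCOOH]+", 1, H, HCOOH, +1),
        IonSpecies("[M+H-CH3COOH]+", 1, H, CH3COOH, +1),
        IonSpecies("[2M+H]+", 2, H, _EMPTY, +1),
        IonSpecies("[2M+Na]+", 2, Na, _EMPTY, +1),
        IonSpecies("[M]+", 1, _EMPTY, _EMPTY, +1),
        IonSpecies("[M-H]-", 1, _EMPTY, H, -1),
        IonSpecies("[M+HCOO]-", 1, HCOO, _EMPTY, -1),
        IonSpecies("[2M-H]-", 2, _EMPTY, H, -1),
        IonSpecies("[M]-", 1, _EMPTY, _EMPTY, -1),
    ]
    return {s.label: s for s in specs}


#: Registry of the ion species used across the package, keyed by label.
ION_SPECIES: Dict[str, IonSpecies] = _build_species()

_LABEL_TRANSLATE = str.maketrans({"−": "-", "–": "-", " ": ""})


def get_ion_species(label: str) -> IonSpecies:
    """Resolve an ion-species label (unicode minus and spaces tolerated)."""
    key = label.translate(_LABEL_TRANSLATE)
    try:
        return ION_SPECIES[key]
    except KeyError:
        raise KeyError(f"unknown ion species label: {label!r}") from None


def ion_mz(f: MolecularFormula, ion: IonSpecies | str) -> float:
    """m/z of formula ``f`` observed as ion species ``ion`` (singly charged)."""
    if isinstance(ion, str):
        ion = get_ion_species(ion)
    return ion.mz(f)


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue envelope: (m/z, % of base peak) pairs.

    Entries are sorted by m/z; the base (most abundant) isotopologue is
    normalised to 100. ``relative(k)`` returns the A+k abundance in percent
    of the monoisotopic (A) peak, the quantity compared against measured
    spectra.
    """

    entries: Tuple[Tuple[float, float], ...]

    def __iter__(self) -> Iterator[Tuple[float, float]]:
        return iter(self.entries)

    def relative(self, shift: int) -> float:
        """Abundance of the A+``shift`` isotopologue as % of the A peak."""
        if not self.entries:
            return 0.0
        mono_mz, mono_ab = self.entries[0]
        if mono_ab == 0:
            return 0.0
        for mz, ab in self.entries:
            if round(mz - mono_mz) == shift:
                return 100.0 * ab / mono_ab
        return 0.0


def _single_atom(el: str) -> Dict[int, Tuple[float, float]]:
    isos = _ISOTOPES[el]
    base = round(isos[0][0])
    out: Dict[int, Tuple[float, float]] = {}
    for m, a in isos:
        k = round(m) - base
        p, ms = out.get(k, (0.0, 0.0))
        out[k] = (p + a, ms + a * m)
    return out


def _convolve(
    a: Dict[int, Tuple[float, float]],
    b: Dict[int, Tuple[float, float]],
    prune: float,
) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, Tuple[float, float]] = {}
    for ka, (pa, msa) in a.items():
        ma = msa / pa
        for kb, (pb, msb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            k = ka + kb
            mp, ms = out.get(k, (0.0, 0.0))
            out[k] = (mp + p, ms + p * (ma + msb / pb))
    return out


def isotope_pattern(f: MolecularFormula, prune_below: float = 0.01) -> IsotopePattern:
    """Theoretical isotopologue envelope of a formula.

    Computed by iterative convolution of per-element single-atom isotope
    distributions, aggregating fine structure by nominal mass shift with
    abundance-weighted centroid masses. ``prune_below`` is the abundance
    threshold in percent of the base peak below which entries are dropped.
    """
    if not (0 <= prune_below < 100):
        raise ValueError("prune_below must be in [0, 100)")
    dist: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    hard_prune = 1e-12
    for el, n in f.counts.items():
        atom = _single_atom(el)
        # exponentiation by squaring over the convolution
        power, k = atom, n
        acc: Dict[int, Tuple[float, float]] | None = None
        while k:
            if k & 1:
                acc = power if acc is None else _convolve(acc, power, hard_prune)
            k >>= 1
            if k:
                power = _convolve(power, power, hard_prune)
        assert acc is not None
        dist = _convolve(dist, acc, hard_prune)
    if not dist:
        return IsotopePattern(())
    base_p = max(p for p, _ in dist.values())
    entries = []
    for k in sorted(dist):
        p, ms = dist[k]
        ab = 100.0 * p / base_p
        if ab > prune_below:
            entries.append((ms / p, ab))
    return IsotopePattern(tuple(entries))


@dataclass(frozen=True)
class MassTolerance:
    """A ppm + mDa mass tolerance; window(m) = m·ppm·1e-6 + mda/1000 Da."""

    ppm: float = 50.0
    mda: float = 2.0

    def __post_init__(self) -> None:
        if self.ppm < 0 or self.mda < 0:
            raise ValueError("tolerance components must be >= 0")

    def window(self, m: float) -> float:
        return tolerance_window(m, self)

    def matches(self, observed: float, theoretical: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)


def tolerance_window(m: float, tol: MassTolerance) -> float:
    """Half-width in Da of the tolerance window at m/z ``m``."""
    if m <= 0:
        raise ValueError(f"m/z must be positive, got {m}")
    return m * tol.ppm * 1e-6 + tol.mda * 1e-3


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6
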