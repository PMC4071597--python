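"""The multi-energy MS/HRMS spectral library: data model, ion-inclusion
rules, and text formats (canonical JSON plus MSP/MGF interop).

A library entry couples one compound (name, CAS, elemental composition,
retention time) with reference MS/HRMS spectra recorded at fixed collision
energies of 10, 20 and 40 eV for each ion species deemed informative for
that compound. Spectra of very stable sodiated ions that fragment only by
losing Na+ are excluded from the searchable pool, since any ion at the right
m/z would match them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .chem import (
    MassTolerance,
    MolecularFormula,
    get_ion_species,
    ion_mz,
    parse_formula,
)
from .spectra import Spectrum

__all__ = [
    "LIBRARY_ENERGIES",
    "LibraryEntry",
    "SpectralLibrary",
    "select_library_ions",
    "validate_sodiated_spectrum",
    "read_library",
    "write_library",
]

#: The three fixed CID energies every library spectrum is recorded at.
LIBRARY_ENERGIES = (10.0, 20.0, 40.0)

SODIUM_MZ = 22.98922070  # Na+ (Na minus one electron)


@dataclass
class LibraryEntry:
    """One compound with per-ion-species, per-collision-energy spectra."""

    name: str
    formula: MolecularFormula
    cas: Optional[str] = None
    rt: Optional[float] = None
    spectra: Dict[Tuple[str, float], Spectrum] = field(default_factory=dict)
    uv_trace: Optional[List[Tuple[float, float]]] = None  # opaque metadata

    def add_spectrum(
        self,
        ion_label: str,
        energy: float,
        spec: Spectrum,
        tol: MassTolerance = MassTolerance(),
    ) -> None:
        if energy not in LIBRARY_ENERGIES:
            raise ValueError(
                f"collision energy {energy} eV not in {LIBRARY_ENERGIES}"
            )
        species = get_ion_species(ion_label)  # validates the label
        expected = ion_mz(self.formula, species)
        if spec.precursor_mz is not None and not tol.matches(
            spec.precursor_mz, expected
        ):
            raise ValueError(
                f"{self.name} {ion_label}: precursor m/z {spec.precursor_mz:.4f}"
                f" inconsistent with theoretical {expected:.4f}"
            )
        key = (species.label, float(energy))
        if key in self.spectra:
            warnings.warn(
                f"duplicate spectrum for {self.name} {key}; keeping last"
            )
        self.spectra[key] = spec

    def ion_labels(self) -> List[str]:
        return sorted({label for label, _ in self.spectra})

    def spectrum_at(
        self, ion_label: str, energy: float
    ) -> Optional[Tuple[float, Spectrum]]:
        """Spectrum at the requested energy, else nearest recorded energy."""
        cands = [
            (e, s) for (label, e), s in self.spectra.items() if label == ion_label
        ]
        if not cands:
            return None
        e, s = min(cands, key=lambda es: abs(es[0] - energy))
        return e, s


class SpectralLibrary:
    """A searchable collection of library entries with m/z/formula indexes."""

    def __init__(self, entries: Iterable[LibraryEntry] = ()) -> None:
        self.entries: List[LibraryEntry] = list(entries)
        self._rebuild()

    def _rebuild(self) -> None:
        rows = []
        for i, e in enumerate(self.entries):
            for (label, energy) in e.spectra:
                rows.append((ion_mz(e.formula, label), i, label, energy))
        rows.sort(key=lambda r: r[0])
        self._prec_mz = np.array([r[0] for r in rows])
        self._prec_rows = rows
        self._by_name = {e.name: i for i, e in enumerate(self.entries)}
        self._by_formula: Dict[str, List[int]] = {}
        for i, e in enumerate(self.entries):
            self._by_formula.setdefault(str(e.formula), []).append(i)

    def add(self, entry: LibraryEntry) -> None:
        if entry.name in self._by_name:
            warnings.warn(f"duplicate entry name {entry.name!r}; keeping last")
            self.entries[self._by_name[entry.name]] = entry
        else:
            self.entries.append(entry)
        self._rebuild()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_name(self, name: str) -> LibraryEntry:
        return self.entries[self._by_name[name]]

    def by_formula(self, formula: MolecularFormula | str) -> List[LibraryEntry]:
        return [
            self.entries[i] for i in self._by_formula.get(str(formula), [])
        ]

    def lookup_by_precursor(
        self, mz: float, tol: MassTolerance
    ) -> List[Tuple[LibraryEntry, str, float]]:
        """All (entry, ion label, theoretical m/z) with |ion_mz − mz| ≤ window.

        Binary search on the sorted precursor index; one hit per
        (entry, ion species) even when several energies are stored.
        """
        w = tol.window(mz)
        lo, hi = np.searchsorted(self._prec_mz, (mz - w, mz + w + 1e-12))
        seen = set()
        out = []
        for r in self._prec_rows[lo:hi]:
            key = (r[1], r[2])
            if key in seen:
                continue
            seen.add(key)
            out.append((self.entries[r[1]], r[2], r[0]))
        return out

    def index_frame(self):
        """Flat per-spectrum index (name, cas, formula, rt, ion, energy,
        precursor m/z, peak count) as a DataFrame, for CSV export."""
        import pandas as pd

        rows = []
        for e in self.entries:
            for (label, energy), s in sorted(e.spectra.items()):
                rows.append(
                    {
                        "name": e.name, "cas": e.cas, "formula": str(e.formula),
                        "rt": e.rt, "ion": label, "collision_energy": energy,
                        "precursor_mz": s.precursor_mz, "n_peaks": len(s),
                    }
                )
        return pd.DataFrame(rows)

    def stats(self) -> Dict[str, int]:
        n_spec = sum(len(e.spectra) for e in self.entries)
        energies = sorted({e_ for e in self.entries for (_, e_) in e.spectra})
        return {
            "entries": len(self.entries),
            "spectra": n_spec,
            "energies": len(energies),
            "ion_species": len(
                {lab for e in self.entries for (lab, _) in e.spectra}
            ),
        }


# ---------------------------------------------------------------------------
# Ion-inclusion rules for building a library from full-scan standard runs
# ---------------------------------------------------------------------------

_POS_ADDUCTS_50 = ("[M+Na]+", "[M+NH4]+")
_POS_LOSSES = ("[M+H-H2O]+", "[M+H-2H2O]+", "[M+H-HCOOH]+", "[M+H-CH3COOH]+")


def select_library_ions(
    fullscan: Spectrum,
    formula: MolecularFormula,
    polarity: str,
    tol: MassTolerance = MassTolerance(),
) -> List[str]:
    """Which ion species of a pure standard should receive library spectra.

    Positive mode: [M+H]+ whenever present; Na+/NH4+ adducts when their
    full-scan intensity exceeds 50% of [M+H]+; in-source loss ions (water
    x1-2, formic acid, acetic acid) only when more intense than [M+H]+.
    Negative mode: [M-H]- whenever present; the formate adduct when above
    50% of [M-H]-. Returns an empty list (with a warning) when no ion of
    the formula is recognizable.
    """
    def inten(label: str) -> float:
        return fullscan.intensity_within(ion_mz(formula, label), tol)

    selected: List[str] = []
    if polarity.startswith("pos"):
        base = inten("[M+H]+")
        if base > 0:
            selected.append("[M+H]+")
        for label in _POS_ADDUCTS_50:
            if base > 0 and inten(label) > 0.5 * base:
                selected.append(label)
        for label in _POS_LOSSES:
            if inten(label) > base and inten(label) > 0:
                selected.append(label)
    else:
        base = inten("[M-H]-")
        if base > 0:
            selected.append("[M-H]-")
        if base > 0 and inten("[M+HCOO]-") > 0.5 * base:
            selected.append("[M+HCOO]-")
    if not selected:
        warnings.warn(
            f"no recognizable ion of {formula} in the full-scan spectrum"
        )
    return selected


def validate_sodiated_spectrum(
    spec: Spectrum,
    formula: MolecularFormula,
    tol: MassTolerance = MassTolerance(),
    min_fraction: float = 0.01,
) -> str:
    """Classify an [M+Na]+ MS/HRMS spectrum as "specific" or "unspecific".

    Stable sodiated ions often fragment only by losing Na+ (leaving no
    informative product ions); such spectra match any ion at the right m/z
    and are excluded from the searchable pool. A spectrum is unspecific when
    every fragment above ``min_fraction`` of the base peak is the precursor
    itself or bare Na+.
    """
    precursor = ion_mz(formula, "[M+Na]+")
    if len(spec) == 0:
        return "unspecific"
    floor = min_fraction * spec.base_peak_intensity
    for m, i in zip(spec.mz, spec.intensity):
        if i <= floor:
            continue
        if tol.matches(m, precursor) or tol.matches(m, SODIUM_MZ):
            continue
        return "specific"
    return "unspecific"


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def _entry_to_dict(e: LibraryEntry) -> dict:
    return {
        "name": e.name,
        "cas": e.cas,
        "formula": str(e.formula),
        "rt": e.rt,
        "uv_trace": e.uv_trace,
        "spectra": [
            {
                "ion": label,
                "collision_energy": energy,
                "precursor_mz": s.precursor_mz,
                "polarity": s.polarity,
                "rt": s.rt,
                "peaks": [[float(m), float(i)] for m, i in zip(s.mz, s.intensity)],
            }
            for (label, energy), s in sorted(e.spectra.items())
        ],
    }


def _entry_from_dict(d: dict, where: str) -> LibraryEntry:
    try:
        entry = LibraryEntry(
            name=d["name"],
            formula=parse_formula(d["formula"]),
            cas=d.get("cas"),
            rt=d.get("rt"),
            uv_trace=[tuple(p) for p in d["uv_trace"]] if d.get("uv_trace") else None,
        )
        for rec in d.get("spectra", []):
            peaks = np.array(rec["peaks"], dtype=float).reshape(-1, 2)
            spec = Spectrum(
                mz=peaks[:, 0],
                intensity=peaks[:, 1],
                polarity=rec.get("polarity", "positive"),
                ms_level=2,
                rt=rec.get("rt") or 0.0,
                precursor_mz=rec.get("precursor_mz"),
                collision_energy=rec.get("collision_energy"),
            )
            entry.add_spectrum(rec["ion"], rec["collision_energy"], spec)
    except KeyError as exc:
        raise ValueError(f"{where}: missing required field {exc}") from exc
    return entry


def _write_json(lib: SpectralLibrary, path: Path) -> None:
    doc = {
        "format": "msderep-library",
        "version": 1,
        "entries": [_entry_to_dict(e) for e in lib.entries],
    }
    path.write_text(json.dumps(doc, indent=1))


def _read_json(path: Path) -> SpectralLibrary:
    doc = json.loads(path.read_text())
    if "entries" not in doc:
        raise ValueError(f"{path}: not a msderep library file")
    lib = SpectralLibrary()
    for k, d in enumerate(doc["entries"]):
        lib.add(_entry_from_dict(d, f"{path} entry {k}"))
    return lib


def _spectra_records(lib: SpectralLibrary):
    for e in lib.entries:
        for (label, energy), s in sorted(e.spectra.items()):
            yield e, label, energy, s


def _write_msp(lib: SpectralLibrary, path: Path) -> None:
    from matchms import Spectrum as MMSpectrum
    from matchms.exporting import save_as_msp

    records = []
    for e, label, energy, s in _spectra_records(lib):
        meta = {
            "compound_name": e.name,
            "formula": str(e.formula),
            "adduct": label,
            "collision_energy": str(energy),
            "precursor_mz": s.precursor_mz or ion_mz(e.formula, label),
            "ionmode": s.polarity,
        }
        if e.rt is not None:
            meta["retention_time"] = e.rt
        if e.cas:
            meta["cas"] = e.cas
        records.append(
            MMSpectrum(
                mz=s.mz.astype(float),
                intensities=s.intensity.astype(float),
                metadata=meta,
                metadata_harmonization=False,
            )
        )
    path.unlink(missing_ok=True)
    save_as_msp(records, str(path))


def _read_msp(path: Path) -> SpectralLibrary:
    from matchms.importing import load_from_msp

    lib = SpectralLibrary()
    staged: Dict[str, LibraryEntry] = {}
    for k, ms in enumerate(load_from_msp(str(path), metadata_harmonization=True)):
        meta = ms.metadata
        name = meta.get("compound_name") or meta.get("name")
        where = f"{path} record {k} ({name or 'unnamed'})"
        if not name or "formula" not in meta:
            raise ValueError(f"{where}: missing name/formula")
        if meta.get("precursor_mz") in (None, ""):
            raise ValueError(f"{where}: missing precursor m/z")
        entry = staged.get(name)
        if entry is None:
            rt = meta.get("retention_time")
            entry = LibraryEntry(
                name=name,
                formula=parse_formula(meta["formula"]),
                cas=meta.get("cas"),
                rt=float(rt) if rt not in (None, "") else None,
            )
            staged[name] = entry
        energy = float(meta.get("collision_energy", 20))
        spec = Spectrum(
            mz=ms.peaks.mz,
            intensity=ms.peaks.intensities,
            polarity=meta.get("ionmode", "positive"),
            ms_level=2,
            precursor_mz=float(meta["precursor_mz"]),
            collision_energy=energy,
        )
        entry.add_spectrum(meta.get("adduct", "[M+H]+"), energy, spec)
    for entry in staged.values():
        lib.add(entry)
    return lib


def _write_mgf(lib: SpectralLibrary, path: Path) -> None:
    from pyteomics import mgf

    spectra = []
    for e, label, energy, s in _spectra_records(lib):
        params = {
            "title": f"{e.name}|{label}|{energy:g}eV",
            "pepmass": s.precursor_mz or ion_mz(e.formula, label),
            "charge": "1+" if s.polarity.startswith("pos") else "1-",
            "formula": str(e.formula),
            "adduct": label,
            "collision_energy": f"{energy:g}",
            "ionmode": s.polarity,
        }
        if e.rt is not None:
            params["rtinseconds"] = e.rt * 60.0
        if e.cas:
            params["cas"] = e.cas
        spectra.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w") as fh:
        mgf.write(spectra, fh)


def _read_mgf(path: Path) -> SpectralLibrary:
    from pyteomics import mgf

    lib = SpectralLibrary()
    staged: Dict[str, LibraryEntry] = {}
    with mgf.MGF(str(path)) as reader:
        for k, rec in enumerate(reader):
            params = rec["params"]
            title = params.get("title", "")
            name = title.split("|")[0] if "|" in title else title
            where = f"{path} record {k} ({name or 'unnamed'})"
            if not name or "formula" not in params:
                raise ValueError(f"{where}: missing name/formula")
            if "pepmass" not in params:
                raise ValueError(f"{where}: missing precursor m/z")
            entry = staged.get(name)
            if entry is None:
                rt = params.get("rtinseconds")
                entry = LibraryEntry(
                    name=name,
                    formula=parse_formula(params["formula"]),
                    cas=params.get("cas"),
                    rt=float(rt) / 60.0 if rt is not None else None,
                )
                staged[name] = entry
            energy = float(params.get("collision_energy", 20))
            spec = Spectrum(
                mz=rec["m/z array"],
                intensity=rec["intensity array"],
                polarity=params.get("ionmode", "positive"),
                ms_level=2,
                precursor_mz=float(params["pepmass"][0]),
                collision_energy=energy,
            )
            entry.add_spectrum(params.get("adduct", "[M+H]+"), energy, spec)
    for entry in staged.values():
        lib.add(entry)
    return lib


_DIALECTS = {"json": (_read_json, _write_json), "msp": (_read_msp, _write_msp),
             "mgf": (_read_mgf, _write_mgf)}


def _dialect_for(path: Path, dialect: Optional[str]) -> str:
    if dialect:
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown library dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _DIALECTS:
        return suffix
    raise ValueError(f"cannot infer library dialect from {path.name!r}")


def read_library(path: str | Path, dialect: Optional[str] = None) -> SpectralLibrary:
    """Read a spectral library (dialect inferred from the extension)."""
    path = Path(path)
    return _DIALECTS[_dialect_for(path, dialect)][0](path)


def write_library(
    lib: SpectralLibrary, path: str | Path, dialect: Optional[str] = None
) -> None:
    """Write a spectral library; JSON is the canonical lossless dialect."""
    path = Path(path)
    _DIALECTS[_dialect_for(path, dialect)][1](lib, path)
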