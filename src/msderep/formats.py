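"""Run-level I/O: a plain-text scan-list format and centroided mzML.

The scan-list format is the package's simple, diff-friendly on-disk form
for synthetic and fixture runs: one block per scan,

    SCAN rt=<min> level=<1|2> polarity=<positive|negative> \
         [energy=<eV>] [precursor=<m/z>]
    <m/z> <intensity>
    ...
    (blank line)

mzML is read through :mod:`pyteomics.mzml`; writing uses a minimal
serializer emitting centroided spectra with 64-bit uncompressed binary
arrays and the CV terms pyteomics (and other readers) need: ms level, scan
start time, polarity, selected precursor m/z and collision energy.
"""

from __future__ import annotations

import base64
import struct
from pathlib import Path
from typing import List
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np

from .spectra import ScanSeries, Spectrum

__all__ = [
    "write_scanlist",
    "read_scanlist",
    "write_mzml",
    "read_mzml",
    "read_run",
]


# ---------------------------------------------------------------------------
# scan-list text format
# ---------------------------------------------------------------------------

def write_scanlist(run: ScanSeries, path: str | Path) -> None:
    lines: List[str] = [f"# msderep scan list v1 run={run.run_id}"]
    for s in run.scans:
        head = f"SCAN rt={s.rt:.6f} level={s.ms_level} polarity={s.polarity}"
        if s.collision_energy is not None:
            head += f" energy={s.collision_energy:g}"
        if s.precursor_mz is not None:
            head += f" precursor={s.precursor_mz:.6f}"
        lines.append(head)
        for m, i in zip(s.mz, s.intensity):
            lines.append(f"{m:.6f} {i:.4f}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scanlist(path: str | Path) -> ScanSeries:
    path = Path(path)
    run_id = path.stem
    scans: List[Spectrum] = []
    polarity = "positive"
    cur_meta = None
    cur_mz: List[float] = []
    cur_in: List[float] = []

    def flush():
        nonlocal cur_meta, cur_mz, cur_in
        if cur_meta is not None:
            scans.append(
                Spectrum(np.array(cur_mz), np.array(cur_in), **cur_meta)
            )
        cur_meta, cur_mz, cur_in = None, [], []

    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "run=" in line:
                run_id = line.split("run=", 1)[1].strip()
            continue
        if line.startswith("SCAN"):
            flush()
            meta = {"rt": 0.0, "ms_level": 1, "polarity": "positive",
                    "precursor_mz": None, "collision_energy": None}
            for tok in line.split()[1:]:
                try:
                    key, val = tok.split("=", 1)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad token {tok!r}")
                if key == "rt":
                    meta["rt"] = float(val)
                elif key == "level":
                    meta["ms_level"] = int(val)
                elif key == "polarity":
                    meta["polarity"] = val
                elif key == "energy":
                    meta["collision_energy"] = float(val)
                elif key == "precursor":
                    meta["precursor_mz"] = float(val)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            polarity = meta["polarity"]
            cur_meta = meta
        else:
            if cur_meta is None:
                raise ValueError(f"{path}:{lineno}: peak line before SCAN header")
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'm/z intensity'")
            cur_mz.append(float(parts[0]))
            cur_in.append(float(parts[1]))
    flush()
    return ScanSeries(scans, run_id=run_id, polarity=polarity)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(arr)}d", *map(float, arr))
    ).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="msderep" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1">
      <processingMethod order="1" softwareRef="msderep">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""


def write_mzml(run: ScanSeries, path: str | Path) -> None:
    """Write centroided spectra as minimal, pyteomics-readable mzML."""
    out = [_MZML_HEADER]
    out.append(
        f'  <run id={quoteattr(run.run_id)} defaultInstrumentConfigurationRef="IC1">\n'
        f'    <spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp1">\n'
    )
    for i, s in enumerate(run.scans):
        pol = (
            '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
            if s.polarity.startswith("pos")
            else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
        )
        mz64, in64 = _b64(s.mz), _b64(s.intensity)
        prec = ""
        if s.ms_level == 2 and s.precursor_mz is not None:
            energy = (
                f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
                f'value="{s.collision_energy:g}" unitName="electronvolt"/>'
                if s.collision_energy is not None
                else ""
            )
            prec = f"""
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}"/>
                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="1"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation" value=""/>
              {energy}
            </activation>
          </precursor>
        </precursorList>"""
        out.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        {pol}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt!r}" unitName="minute" unitCvRef="UO" unitAccession="UO:0000031"/>
          </scan>
        </scanList>{prec}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitName="m/z" unitCvRef="MS" unitAccession="MS:1000040"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitName="number of detector counts" unitCvRef="MS" unitAccession="MS:1000131"/>
            <binary>{in64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    out.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(out))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: ET.Element) -> np.ndarray:
    """Decode one binaryDataArray (64/32-bit float, zlib or none)."""
    import zlib

    dtype = "<f8"
    compressed = False
    text = ""
    for el in bda.iter():
        tag = _local(el.tag)
        if tag == "cvParam":
            acc = el.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            text = el.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> ScanSeries:
    """Read centroided mzML.

    A self-contained namespace-agnostic reader (cvParam accessions for ms
    level, scan start time, polarity, selected ion m/z and collision
    energy); handles 32/64-bit float arrays with or without zlib
    compression. Retention times in seconds are converted to minutes.
    """
    scans: List[Spectrum] = []
    polarity = "positive"
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        level, rt, pol = 1, 0.0, None
        precursor, energy = None, None
        mz_arr = np.array([])
        in_arr = np.array([])
        in_precursor = False
        for el in elem.iter():
            tag = _local(el.tag)
            if tag == "cvParam":
                acc = el.get("accession", "")
                val = el.get("value", "")
                if acc == "MS:1000511":
                    level = int(val)
                elif acc == "MS:1000016":
                    rt = float(val)
                    if el.get("unitName", "").startswith("second"):
                        rt /= 60.0
                elif acc == "MS:1000129":
                    pol = "negative"
                elif acc == "MS:1000130":
                    pol = "positive"
                elif acc == "MS:1000744":
                    precursor = float(val)
                elif acc == "MS:1000045":
                    energy = float(val)
        arrays = []
        for el in elem.iter():
            if _local(el.tag) == "binaryDataArray":
                arrays.append((el, _decode_binary(el)))
        for el, arr in arrays:
            accs = {
                c.get("accession")
                for c in el.iter()
                if _local(c.tag) == "cvParam"
            }
            if "MS:1000514" in accs:
                mz_arr = arr
            elif "MS:1000515" in accs:
                in_arr = arr
        if pol is not None:
            polarity = pol
        scans.append(
            Spectrum(
                mz=mz_arr,
                intensity=in_arr,
                polarity=pol or polarity,
                ms_level=level,
                rt=rt,
                precursor_mz=precursor if level == 2 else None,
                collision_energy=energy if level == 2 else None,
            )
        )
        elem.clear()
    return ScanSeries(scans, run_id=Path(path).stem, polarity=polarity)


def read_run(path: str | Path) -> ScanSeries:
    """Read a run from mzML or the scan-list format, by extension."""
    p = Path(path)
    if p.suffix.lower() == ".mzml":
        return read_mzml(p)
    return read_scanlist(p)
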