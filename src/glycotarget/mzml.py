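"""Minimal centroided mzML reading and writing.

Covers exactly what a targeted SIM/ddMS2 workflow needs: MS1 and MS2
spectra with retention times (minutes), centroided m/z / intensity arrays,
and MS2 precursor isolation windows.  Arrays are encoded as 64-bit
little-endian floats, base64, uncompressed.  Profile-mode spectra are
rejected on read — this package operates on centroided data only.

This is intentionally not a general mzML implementation; it writes a small,
schema-shaped subset and reads back the same subset (plus any file using
the standard CV accessions for the fields above).
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .run import Run, Spectrum

__all__ = ["read_mzml", "write_mzml"]

_NS = "http://psi.hupo.org/ms/mzml"

# CV accessions used
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_NO_COMP = "MS:1000576"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MINUTE = "UO:0000031"
_ACC_SECOND = "UO:0000010"


def _encode(arr: np.ndarray) -> str:
    data = struct.pack(f"<{len(arr)}d", *map(float, arr))
    return base64.b64encode(data).decode("ascii")


def _decode(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.array(struct.unpack(f"<{n}d", raw), dtype=float)


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: tuple[str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrs.update(
            unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
        )
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, arr: np.ndarray, accession: str, name: str) -> None:
    encoded = _encode(arr)
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(encoded))})
    _cv(bda, _ACC_64BIT, "64-bit float")
    _cv(bda, _ACC_NO_COMP, "no compression")
    _cv(bda, accession, name)
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a centroided run; deterministic byte output for a given run."""
    spectra = sorted(run.ms1 + run.ms2, key=lambda s: (s.rt, s.ms_level))
    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    ET.SubElement(root, "cvList", {"count": "2"})
    run_el = ET.SubElement(root, "run", {"id": str(run.metadata.get("id", "synthetic"))})
    slist = ET.SubElement(run_el, "spectrumList", {"count": str(len(spectra))})
    for i, sp in enumerate(spectra):
        sp_el = ET.SubElement(
            slist, "spectrum",
            {"index": str(i), "id": f"scan={i + 1}", "defaultArrayLength": str(len(sp.mz))},
        )
        _cv(sp_el, _ACC_MS_LEVEL, "ms level", str(sp.ms_level))
        _cv(sp_el, _ACC_CENTROID, "centroid spectrum")
        scan_list = ET.SubElement(sp_el, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, _ACC_SCAN_START, "scan start time", repr(sp.rt), unit=(_ACC_MINUTE, "minute"))
        if sp.ms_level == 2 and sp.precursor_mz is not None:
            plist = ET.SubElement(sp_el, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, _ACC_ISO_TARGET, "isolation window target m/z", repr(sp.precursor_mz))
            half = (sp.isolation_width or 2.0) / 2.0
            _cv(iso, _ACC_ISO_LOWER, "isolation window lower offset", repr(half))
            _cv(iso, _ACC_ISO_UPPER, "isolation window upper offset", repr(half))
        bal = ET.SubElement(sp_el, "binaryDataArrayList", {"count": "2"})
        _binary_array(bal, sp.mz, _ACC_MZ_ARRAY, "m/z array")
        _binary_array(bal, sp.intensity, _ACC_INT_ARRAY, "intensity array")
    tree = ET.ElementTree(root)
    ET.indent(tree, space=" ")
    tree.write(str(path), encoding="utf-8", xml_declaration=True)


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file into a :class:`~glycotarget.run.Run`.

    Raises ``ValueError`` for profile-mode spectra with guidance to
    centroid the data first; an mzML without spectra yields an empty run
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed mzML ({path}): {exc}") from exc
    ms1: list[Spectrum] = []
    ms2: list[Spectrum] = []
    for sp_el in tree.iter():
        if _strip(sp_el.tag) != "spectrum":
            continue
        ms_level = 1
        rt = 0.0
        prec_mz = None
        iso_width = None
        n = int(sp_el.get("defaultArrayLength", "0"))
        mz = np.zeros(0)
        inten = np.zeros(0)
        for el in sp_el.iter():
            tag = _strip(el.tag)
            if tag == "cvParam":
                acc = el.get("accession")
                if acc == _ACC_MS_LEVEL:
                    ms_level = int(el.get("value"))
                elif acc == _ACC_PROFILE:
                    raise ValueError(
                        f"profile-mode spectrum in {path.name}; centroid the data "
                        "before reading (this package operates on centroided runs)"
                    )
                elif acc == _ACC_SCAN_START:
                    rt = float(el.get("value"))
                    if el.get("unitAccession") == _ACC_SECOND:
                        rt /= 60.0
                elif acc == _ACC_ISO_TARGET:
                    prec_mz = float(el.get("value"))
                elif acc == _ACC_ISO_LOWER:
                    iso_width = 2.0 * float(el.get("value"))
        for bda in sp_el.iter():
            if _strip(bda.tag) != "binaryDataArray":
                continue
            kind = None
            payload = ""
            for el in bda:
                tag = _strip(el.tag)
                if tag == "cvParam":
                    if el.get("accession") == _ACC_MZ_ARRAY:
                        kind = "mz"
                    elif el.get("accession") == _ACC_INT_ARRAY:
                        kind = "intensity"
                elif tag == "binary":
                    payload = el.text or ""
            if kind == "mz":
                mz = _decode(payload, n)
            elif kind == "intensity":
                inten = _decode(payload, n)
        spec = Spectrum(rt=rt, mz=mz, intensity=inten, ms_level=ms_level,
                        precursor_mz=prec_mz, isolation_width=iso_width)
        (ms1 if ms_level == 1 else ms2).append(spec)
    if not ms1 and not ms2:
        warnings.warn(f"{path.name}: no spectra found; returning empty run", stacklevel=2)
    return Run(ms1=sorted(ms1, key=lambda s: s.rt),
               ms2=sorted(ms2, key=lambda s: s.rt),
               metadata={"source": str(path)})
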