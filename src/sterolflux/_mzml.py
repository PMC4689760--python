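"""Minimal, deterministic mzML reading and writing for centroided MS1 runs.

The writer emits just enough of the PSI mzML 1.1 vocabulary (64-bit float,
uncompressed, base64-encoded arrays; scan start times in minutes) for
standard readers; output contains no timestamps or environment-dependent
fields, so identical inputs produce byte-identical files. The reader handles
the common centroided-MS1 subset: 32/64-bit float arrays, zlib or no
compression, scan start times in minutes or seconds.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path

import numpy as np
from lxml import etree

_NSMAP = {None: "http://psi.hupo.org/ms/mzml"}
_NS = "{http://psi.hupo.org/ms/mzml}"


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **attrs
    )


def write_mzml(path, spectra) -> None:
    """Write centroided MS1 spectra to an mzML file.

    ``spectra`` is an iterable of objects with ``rt_min`` (float, minutes),
    ``mz`` and ``intensity`` arrays, and ``ms_level``.
    """
    spectra = list(spectra)
    root = etree.Element("mzML", nsmap=_NSMAP, version="1.1.0", id="sterolflux_run")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    run = etree.SubElement(root, "run", id="run1")
    spec_list = etree.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, spectrum in enumerate(spectra):
        mz = np.asarray(spectrum.mz, dtype=float)
        intensity = np.asarray(spectrum.intensity, dtype=float)
        elem = etree.SubElement(
            spec_list, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(mz.size),
        )
        _cv(elem, "MS:1000511", "ms level", str(getattr(spectrum, "ms_level", 1)))
        _cv(elem, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(elem, "scanList", count="1")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", f"{spectrum.rt_min:.6f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        arrays = etree.SubElement(elem, "binaryDataArrayList", count="2")
        for accession, name, unit, data in (
            ("MS:1000514", "m/z array", "m/z", mz),
            ("MS:1000515", "intensity array", "number of detector counts", intensity),
        ):
            encoded = _encode(data)
            array_elem = etree.SubElement(
                arrays, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(array_elem, "MS:1000523", "64-bit float")
            _cv(array_elem, "MS:1000576", "no compression")
            _cv(array_elem, accession, name)
            etree.SubElement(array_elem, "binary").text = encoded
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    )


def _accessions(element) -> dict[str, "etree._Element"]:
    return {
        cv.get("accession"): cv
        for cv in element.findall(f"{_NS}cvParam") + element.findall("cvParam")
    }


def _decode_array(array_elem) -> np.ndarray:
    params = _accessions(array_elem)
    binary = array_elem.find(f"{_NS}binary")
    if binary is None:
        binary = array_elem.find("binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def iter_spectra(path):
    """Yield dicts for each spectrum in an mzML file.

    Keys: ``ms_level``, ``centroided`` (True/False/None if unstated),
    ``rt_min``, ``mz``, ``intensity``.
    """
    tree = etree.parse(str(path))
    spectra = tree.findall(f".//{_NS}spectrum") or tree.findall(".//spectrum")
    for elem in spectra:
        params = _accessions(elem)
        ms_level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
        centroided: bool | None = None
        if "MS:1000127" in params:
            centroided = True
        elif "MS:1000128" in params:
            centroided = False
        rt_min = float("nan")
        scan = elem.find(f".//{_NS}scan")
        if scan is None:
            scan = elem.find(".//scan")
        if scan is not None:
            scan_params = _accessions(scan)
            if "MS:1000016" in scan_params:
                cv = scan_params["MS:1000016"]
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
                rt_min = rt
        mz = intensity = None
        arrays = elem.findall(f".//{_NS}binaryDataArray") or elem.findall(".//binaryDataArray")
        for array_elem in arrays:
            params = _accessions(array_elem)
            if "MS:1000514" in params:
                mz = _decode_array(array_elem)
            elif "MS:1000515" in params:
                intensity = _decode_array(array_elem)
        if mz is None or intensity is None:
            continue
        yield {
            "ms_level": ms_level,
            "centroided": centroided,
            "rt_min": rt_min,
            "mz": mz,
            "intensity": intensity,
        }
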