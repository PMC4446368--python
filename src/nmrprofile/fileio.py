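"""File formats: library XML/JSON, JCAMP-DX and internal JSON spectra/FIDs,
profile and ground-truth files.

JCAMP-DX support covers the vendor-neutral uncompressed dialect: AFFN numeric
tables in ``(X++(Y..Y))`` form, with NTUPLES real/imaginary pages for FIDs.
Compressed ASDF forms (PAC/SQZ/DIF/DUP) are detected and rejected with an
explicit error.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Cluster,
    CompoundSignature,
    DEFAULT_SHIFT_WINDOW,
    Peak,
    ProfileAssignment,
    SpectralLibrary,
    Spectrum,
)
from .processing import FID
from .quantify import EvaluationReport, MetabolicProfile

__all__ = [
    "SchemaError",
    "UnsupportedDialectError",
    "read_library",
    "write_library",
    "read_spectrum",
    "write_spectrum",
    "read_fid",
    "write_fid",
    "write_profile",
    "read_profile",
    "write_truth",
    "read_truth",
    "write_report",
]


class SchemaError(ValueError):
    """A file violates the expected schema."""


class UnsupportedDialectError(ValueError):
    """A JCAMP-DX file uses an unsupported encoding."""


# ---------------------------------------------------------------------------
# Spectral library (XML and JSON dialects)
# ---------------------------------------------------------------------------

def _peak_from_attrs(attrs: dict, where: str) -> Peak:
    for key in ("center", "height", "fwhm"):
        if key not in attrs:
            raise SchemaError(f"{where}: missing peak attribute {key!r}")
    return Peak(
        height=float(attrs["height"]),
        center=float(attrs["center"]),
        fwhm=float(attrs["fwhm"]),
    )


def _library_from_xml(path: Path) -> SpectralLibrary:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SchemaError(f"{path}: not well-formed XML ({exc})") from exc
    if root.tag != "library":
        raise SchemaError(f"{path}: root element must be <library>, got <{root.tag}>")
    compounds = []
    for ce in root.findall("compound"):
        name = ce.get("name")
        if not name:
            raise SchemaError(f"{path}: <compound> without name attribute")
        clusters = []
        for k, cle in enumerate(ce.findall("cluster")):
            cid = cle.get("id") or f"{name}:{k}"
            lo = float(cle.get("shift_lo", -DEFAULT_SHIFT_WINDOW))
            hi = float(cle.get("shift_hi", DEFAULT_SHIFT_WINDOW))
            peaks = tuple(
                _peak_from_attrs(pe.attrib, f"{path}: compound {name!r} cluster {cid!r} peak {i}")
                for i, pe in enumerate(cle.findall("peak"))
            )
            if not peaks:
                raise SchemaError(f"{path}: cluster {cid!r} of {name!r} has no peaks")
            clusters.append(Cluster(cid, peaks, lo, hi))
        if not clusters:
            raise SchemaError(f"{path}: compound {name!r} has no clusters")
        compounds.append(
            CompoundSignature(name, tuple(clusters), float(ce.get("detectability", 1.0)))
        )
    return SpectralLibrary(
        compounds,
        frequency=float(root.get("freq", 500.0)),
        biofluid_tag=root.get("biofluid", ""),
    )


def _library_from_json(path: Path) -> SpectralLibrary:
    data = json.loads(Path(path).read_text())
    compounds = []
    for cd in data.get("compounds", []):
        if "name" not in cd:
            raise SchemaError(f"{path}: compound without 'name'")
        clusters = []
        for k, cld in enumerate(cd.get("clusters", [])):
            peaks = tuple(
                _peak_from_attrs(pd_, f"{path}: compound {cd['name']!r} cluster {k} peak {i}")
                for i, pd_ in enumerate(cld.get("peaks", []))
            )
            if not peaks:
                raise SchemaError(f"{path}: cluster {k} of {cd['name']!r} has no peaks")
            clusters.append(
                Cluster(
                    cld.get("id", f"{cd['name']}:{k}"),
                    peaks,
                    float(cld.get("shift_lo", -DEFAULT_SHIFT_WINDOW)),
                    float(cld.get("shift_hi", DEFAULT_SHIFT_WINDOW)),
                )
            )
        if not clusters:
            raise SchemaError(f"{path}: compound {cd['name']!r} has no clusters")
        compounds.append(
            CompoundSignature(cd["name"], tuple(clusters), float(cd.get("detectability", 1.0)))
        )
    return SpectralLibrary(
        compounds,
        frequency=float(data.get("frequency", 500.0)),
        biofluid_tag=data.get("biofluid", ""),
    )


def read_library(path: str | Path) -> SpectralLibrary:
    """Read a compound library from the XML or JSON dialect (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return _library_from_xml(path)
    return _library_from_json(path)


def _library_to_dict(lib: SpectralLibrary) -> dict:
    return {
        "frequency": lib.frequency,
        "biofluid": lib.biofluid_tag,
        "compounds": [
            {
                "name": c.name,
                "detectability": c.detectability_factor,
                "clusters": [
                    {
                        "id": cl.cluster_id,
                        "shift_lo": cl.shift_lo,
                        "shift_hi": cl.shift_hi,
                        "peaks": [
                            {"center": p.center, "height": p.height, "fwhm": p.fwhm}
                            for p in cl.peaks
                        ],
                    }
                    for cl in c.clusters
                ],
            }
            for c in lib.compounds
        ],
    }


def write_library(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a library losslessly (floats via repr) as XML or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        root = ET.Element("library", freq=repr(lib.frequency), biofluid=lib.biofluid_tag)
        for c in lib.compounds:
            ce = ET.SubElement(
                root, "compound", name=c.name, detectability=repr(c.detectability_factor)
            )
            for cl in c.clusters:
                cle = ET.SubElement(
                    ce, "cluster", id=cl.cluster_id,
                    shift_lo=repr(cl.shift_lo), shift_hi=repr(cl.shift_hi),
                )
                for p in cl.peaks:
                    ET.SubElement(
                        cle, "peak",
                        center=repr(p.center), height=repr(p.height), fwhm=repr(p.fwhm),
                    )
        ET.indent(root)
        path.write_text(ET.tostring(root, encoding="unicode") + "\n")
    else:
        path.write_text(json.dumps(_library_to_dict(lib), indent=1) + "\n")


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_AFFN_TOKEN = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_jcamp_records(text: str) -> tuple[dict[str, str], list[tuple[str, list[str]]]]:
    """Split a JCAMP file into labeled records; data records keep their
    following numeric lines."""
    records: dict[str, str] = {}
    tables: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label in ("XYDATA", "DATATABLE"):
                current = []
                tables.append((value, current))
            else:
                records[label] = value
                current = None
        elif current is not None:
            current.append(line)
    return records, tables


def _decode_affn_table(lines: list[str], yfactor: float, where: str) -> np.ndarray:
    ys: list[float] = []
    for line in lines:
        toks = line.replace(",", " ").split()
        for tok in toks:
            if not _AFFN_TOKEN.match(tok):
                raise UnsupportedDialectError(
                    f"{where}: token {tok!r} is not plain AFFN; compressed ASDF "
                    "forms (PAC/SQZ/DIF/DUP) are not supported — supported "
                    "forms: AFFN (X++(Y..Y)) and NTUPLES pages of the same"
                )
        vals = [float(t) for t in toks]
        ys.extend(vals[1:])  # first token is the abscissa check value
    return np.asarray(ys) * yfactor


def write_spectrum_jcamp(spec: Spectrum, path: str | Path, title: str = "spectrum") -> None:
    y = spec.real
    ymax = float(np.abs(y).max()) or 1.0
    yfac = ymax / 2**30
    yint = np.round(y / yfac).astype(np.int64)
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= XYDATA",
        f"##.OBSERVE FREQUENCY= {spec.frequency!r}",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY UNITS",
        f"##FIRSTX= {float(spec.ppm_axis[0])!r}",
        f"##LASTX= {float(spec.ppm_axis[-1])!r}",
        f"##NPOINTS= {spec.n_points}",
        "##XFACTOR= 1.0",
        f"##YFACTOR= {yfac!r}",
    ]
    if spec.noise_sigma is not None:
        lines.append(f"##$NOISESIGMA= {spec.noise_sigma!r}")
    lines.append("##XYDATA= (X++(Y..Y))")
    for i in range(0, yint.size, 8):
        chunk = yint[i : i + 8]
        lines.append(f"{spec.ppm_axis[i]:.6f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_spectrum_jcamp(path: Path) -> Spectrum:
    records, tables = _parse_jcamp_records(path.read_text())
    if not tables:
        raise SchemaError(f"{path}: no ##XYDATA table")
    form, lines = tables[0]
    if "X++" not in form.replace(" ", ""):
        raise UnsupportedDialectError(
            f"{path}: table form {form!r} unsupported; supported: (X++(Y..Y)) AFFN"
        )
    yfac = float(records.get("YFACTOR", 1.0))
    y = _decode_affn_table(lines, yfac, str(path))
    n = int(records.get("NPOINTS", y.size))
    if y.size != n:
        raise SchemaError(f"{path}: NPOINTS={n} but table has {y.size} values")
    firstx = float(records["FIRSTX"])
    lastx = float(records["LASTX"])
    axis = np.linspace(firstx, lastx, n)
    if axis[0] > axis[-1]:
        axis = axis[::-1].copy()
        y = y[::-1].copy()
    freq = float(records.get(".OBSERVEFREQUENCY", 500.0))
    sigma = records.get("$NOISESIGMA")
    return Spectrum(axis, y, None, freq, float(sigma) if sigma else None)


def write_fid_jcamp(fid: FID, path: str | Path, title: str = "fid") -> None:
    n = fid.n_points
    t = np.arange(n) * fid.dwell_time
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR FID",
        "##DATA CLASS= NTUPLES",
        f"##.OBSERVE FREQUENCY= {fid.frequency!r}",
        f"##$DWELLTIME= {fid.dwell_time!r}",
        f"##$CARRIERPPM= {fid.carrier_ppm!r}",
        f"##NPOINTS= {n}",
        "##NTUPLES= NMR FID",
        "##VAR_NAME= TIME, FID/REAL, FID/IMAG",
        "##PAGE= N=1",
    ]
    for channel, page in ((fid.points.real, 1), (fid.points.imag, 2)):
        if page == 2:
            lines.append("##PAGE= N=2")
        lines.append("##DATA TABLE= (X++(R..R)), XYDATA")
        for i in range(0, n, 6):
            chunk = channel[i : i + 6]
            lines.append(f"{t[i]:.9e} " + " ".join(repr(float(v)) for v in chunk))
    lines += ["##END NTUPLES= NMR FID", "##END="]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_fid_jcamp(path: Path) -> FID:
    records, tables = _parse_jcamp_records(path.read_text())
    if len(tables) < 2:
        raise SchemaError(f"{path}: FID needs real and imaginary data tables")
    real = _decode_affn_table(tables[0][1], 1.0, str(path))
    imag = _decode_affn_table(tables[1][1], 1.0, str(path))
    if real.size != imag.size:
        raise SchemaError(f"{path}: real/imag lengths differ ({real.size}/{imag.size})")
    return FID(
        real + 1j * imag,
        dwell_time=float(records["$DWELLTIME"]),
        frequency=float(records.get(".OBSERVEFREQUENCY", 500.0)),
        carrier_ppm=float(records.get("$CARRIERPPM", 0.0)),
    )


# ---------------------------------------------------------------------------
# Internal JSON spectrum / FID
# ---------------------------------------------------------------------------

def _spectrum_to_json(spec: Spectrum) -> dict:
    return {
        "type": "spectrum",
        "frequency": spec.frequency,
        "ppm_start": float(spec.ppm_axis[0]),
        "ppm_spacing": spec.spacing,
        "npoints": spec.n_points,
        "noise_sigma": spec.noise_sigma,
        "real": spec.real.tolist(),
        "imag": None if spec.imag is None else spec.imag.tolist(),
    }


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as JCAMP-DX (``.jdx``/``.dx``) or internal JSON."""
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        write_spectrum_jcamp(spec, path)
    else:
        path.write_text(json.dumps(_spectrum_to_json(spec)) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        return _read_spectrum_jcamp(path)
    data = json.loads(path.read_text())
    if data.get("type") != "spectrum":
        raise SchemaError(f"{path}: not a spectrum JSON file")
    n = int(data["npoints"])
    real = np.asarray(data["real"], dtype=float)
    if real.size != n:
        raise SchemaError(f"{path}: npoints={n} but real has {real.size}")
    imag = data.get("imag")
    if imag is not None:
        imag = np.asarray(imag, dtype=float)
        if imag.size != n:
            raise SchemaError(f"{path}: npoints={n} but imag has {imag.size}")
    axis = data["ppm_start"] + data["ppm_spacing"] * np.arange(n)
    return Spectrum(axis, real, imag, float(data["frequency"]), data.get("noise_sigma"))


def write_fid(fid: FID, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        write_fid_jcamp(fid, path)
    else:
        path.write_text(
            json.dumps(
                {
                    "type": "fid",
                    "frequency": fid.frequency,
                    "dwell_time": fid.dwell_time,
                    "carrier_ppm": fid.carrier_ppm,
                    "real": fid.points.real.tolist(),
                    "imag": fid.points.imag.tolist(),
                }
            )
            + "\n"
        )


def read_fid(path: str | Path) -> FID:
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        return _read_fid_jcamp(path)
    data = json.loads(path.read_text())
    if data.get("type") != "fid":
        raise SchemaError(f"{path}: not a FID JSON file")
    real = np.asarray(data["real"], dtype=float)
    imag = np.asarray(data["imag"], dtype=float)
    if real.size != imag.size:
        raise SchemaError(f"{path}: real/imag lengths differ ({real.size}/{imag.size})")
    return FID(
        real + 1j * imag,
        dwell_time=float(data["dwell_time"]),
        frequency=float(data["frequency"]),
        carrier_ppm=float(data.get("carrier_ppm", 0.0)),
    )


# ---------------------------------------------------------------------------
# Profiles, ground truth, reports
# ---------------------------------------------------------------------------

def write_profile(profile: MetabolicProfile, path: str | Path) -> None:
    """Write a metabolic profile as CSV or JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for name in profile.concentrations:
            rows.append(
                {
                    "compound": name,
                    "concentration_uM": profile.concentrations[name],
                    "threshold_uM": profile.thresholds[name],
                    "detected": profile.detected[name],
                    "cluster_shifts": ";".join(
                        f"{cid}={d!r}"
                        for cid, d in profile.shifts.items()
                        if cid.startswith(name + ":") or cid.split(":")[0] == name
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        path.write_text(
            json.dumps(
                {
                    "concentrations": profile.concentrations,
                    "thresholds": profile.thresholds,
                    "detected": profile.detected,
                    "shifts": profile.shifts,
                },
                indent=1,
            )
            + "\n"
        )


def read_profile(path: str | Path) -> MetabolicProfile:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        shifts: dict[str, float] = {}
        for cell in df.get("cluster_shifts", pd.Series(dtype=str)).dropna():
            for part in str(cell).split(";"):
                if "=" in part:
                    cid, val = part.split("=", 1)
                    shifts[cid] = float(val)
        return MetabolicProfile(
            dict(zip(df["compound"], df["concentration_uM"].astype(float))),
            dict(zip(df["compound"], df["threshold_uM"].astype(float))),
            dict(zip(df["compound"], df["detected"].astype(bool))),
            shifts,
        )
    data = json.loads(path.read_text())
    return MetabolicProfile(
        data["concentrations"], data["thresholds"], data["detected"], data.get("shifts", {})
    )


def write_truth(truth: ProfileAssignment, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"concentrations": truth.concentrations, "shifts": truth.shifts}, indent=1
        )
        + "\n"
    )


def read_truth(path: str | Path) -> ProfileAssignment:
    data = json.loads(Path(path).read_text())
    return ProfileAssignment(data.get("concentrations", {}), data.get("shifts", {}))


def write_report(report: EvaluationReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "tp": report.tp,
                "fp": report.fp,
                "tn": report.tn,
                "fn": report.fn,
                "id_accuracy": report.id_accuracy,
                "median_rel_error": report.median_rel_error,
            },
            indent=1,
        )
        + "\n"
    )
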