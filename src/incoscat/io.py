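"""Columnar text formats for elastic curves, QENS spectra and datasets.

Files are plain-text, tab-separated, with a '#'-prefixed key: value header:

    # incoscat curve v1
    # sample: LP60
    # temperature_K: 295
    # resolution_ueV: 8
    # normalized: true
    # columns: q_invA intensity error
    0.2<TAB>0.995<TAB>0.01
    ...

Values round-trip at 9 significant digits.  A temperature series is a
directory of curve files; a QENS dataset is a directory of spectrum files
plus a `resolution.yaml` with the per-Q elastic-peak parameters.
"""

from __future__ import annotations

import glob
import os
from typing import Mapping

import numpy as np
import yaml

from .eins import EinsCurve, EinsSeries
from .exceptions import FormatError
from .models import ResolutionParams
from .qens import QensDataset, QensSpectrum

__all__ = [
    "read_curve", "write_curve", "read_series", "write_series",
    "read_spectrum", "write_spectrum",
    "load_qens_dataset", "save_qens_dataset",
]

_FMT = "%.9g"


def _write_table(path, magic: str, header: dict, columns: list[str],
                 data: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {magic}\n")
        for key, val in header.items():
            if isinstance(val, bool):
                val = "true" if val else "false"
            elif isinstance(val, float):
                val = _FMT % val
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# columns: {' '.join(columns)}\n")
        for row in data:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def _read_table(path, magic: str) -> tuple[dict, np.ndarray, list[int]]:
    header: dict[str, str] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    if not lines or lines[0].strip() != f"# {magic}":
        raise FormatError(f"not a '{magic}' file: {path}", line=1)
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"expected 3 columns, found {len(parts)}",
                              line=lineno)
        try:
            rows.append(([float(p) for p in parts], lineno))
        except ValueError as exc:
            raise FormatError(f"non-numeric value: {exc}", line=lineno) from exc
    if not rows:
        raise FormatError("file contains no data rows")
    data = np.array([r for r, _ in rows])
    return header, data, [ln for _, ln in rows]


def _as_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


# --------------------------------------------------------------------------
# elastic curves
# --------------------------------------------------------------------------

def write_curve(curve: EinsCurve, path, sample: str = "",
                resolution_ueV: float = 8.0, normalized: bool = True) -> None:
    data = np.column_stack([curve.q, curve.intensity, curve.error])
    _write_table(path, "incoscat curve v1",
                 {"sample": sample, "temperature_K": float(curve.temperature),
                  "resolution_ueV": float(resolution_ueV),
                  "normalized": normalized},
                 ["q_invA", "intensity", "error"], data)


def read_curve(path) -> tuple[EinsCurve, dict]:
    """Read one elastic curve; returns (curve, header metadata dict)."""
    header, data, linenos = _read_table(path, "incoscat curve v1")
    q, i, e = data.T
    bad = np.flatnonzero(np.diff(q) <= 0)
    if bad.size:
        raise FormatError("Q values not strictly increasing",
                          line=linenos[bad[0] + 1])
    bad = np.flatnonzero(e <= 0)
    if bad.size:
        raise FormatError("errors must be > 0", line=linenos[bad[0]])
    try:
        temp = float(header["temperature_K"])
    except KeyError as exc:
        raise FormatError("missing 'temperature_K' header") from exc
    meta = {
        "sample": header.get("sample", ""),
        "resolution_ueV": float(header.get("resolution_ueV", "8")),
        "normalized": _as_bool(header.get("normalized", "false")),
    }
    return EinsCurve(q=q, intensity=i, error=e, temperature=temp), meta


def write_series(series: EinsSeries, directory, sample: str = "") -> list[str]:
    """Write one curve file per temperature into `directory`."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for curve in series.curves:
        path = os.path.join(directory, f"eins_T{curve.temperature:07.2f}K.dat")
        write_curve(curve, path, sample=sample,
                    resolution_ueV=series.resolution_ueV,
                    normalized=series.normalized)
        paths.append(path)
    return paths


def read_series(directory) -> EinsSeries:
    paths = sorted(glob.glob(os.path.join(directory, "eins_T*K.dat")))
    if not paths:
        raise FormatError(f"no curve files (eins_T*K.dat) in {directory}")
    curves, metas = zip(*(read_curve(p) for p in paths))
    curves = tuple(sorted(curves, key=lambda c: c.temperature))
    return EinsSeries(curves=curves,
                      resolution_ueV=metas[0]["resolution_ueV"],
                      normalized=all(m["normalized"] for m in metas))


# --------------------------------------------------------------------------
# QENS spectra and datasets
# --------------------------------------------------------------------------

def write_spectrum(spec: QensSpectrum, path, sample: str = "",
                   temperature: float = 300.0) -> None:
    data = np.column_stack([spec.omega, spec.intensity, spec.error])
    _write_table(path, "incoscat spectrum v1",
                 {"sample": sample, "q_invA": float(spec.q),
                  "temperature_K": float(temperature)},
                 ["omega_ueV", "intensity", "error"], data)


def read_spectrum(path) -> tuple[QensSpectrum, dict]:
    header, data, linenos = _read_table(path, "incoscat spectrum v1")
    w, i, e = data.T
    bad = np.flatnonzero(e <= 0)
    if bad.size:
        raise FormatError("errors must be > 0", line=linenos[bad[0]])
    try:
        q = float(header["q_invA"])
    except KeyError as exc:
        raise FormatError("missing 'q_invA' header") from exc
    meta = {"sample": header.get("sample", ""),
            "temperature_K": float(header.get("temperature_K", "300"))}
    # QensSpectrum validates grid uniformity on construction
    return QensSpectrum(q=q, omega=w, intensity=i, error=e), meta


def save_qens_dataset(dataset: QensDataset, directory, sample: str = "") -> None:
    """Spectrum file per Q plus resolution.yaml with the per-Q peak parameters."""
    os.makedirs(directory, exist_ok=True)
    for k, spec in enumerate(dataset.spectra):
        path = os.path.join(directory, f"qens_{k:02d}_q{spec.q:05.2f}.dat")
        write_spectrum(spec, path, sample=sample,
                       temperature=dataset.temperature)
    if dataset.resolution is not None:
        entries = []
        for q in dataset.q_values:
            p = dataset.resolution_at(q)
            entries.append({"q": float(q), "amp": float(p.amp),
                            "omega0": float(p.omega0), "sigma": float(p.sigma),
                            "xi": float(p.xi), "bg": float(p.bg)})
        doc = {"temperature_K": float(dataset.temperature),
               "resolution": entries}
        with open(os.path.join(directory, "resolution.yaml"), "w",
                  encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_qens_dataset(directory) -> QensDataset:
    paths = sorted(glob.glob(os.path.join(directory, "qens_*.dat")))
    if not paths:
        raise FormatError(f"no spectrum files (qens_*.dat) in {directory}")
    specs, metas = zip(*(read_spectrum(p) for p in paths))
    temperature = metas[0]["temperature_K"]
    respath = os.path.join(directory, "resolution.yaml")
    resolution = None
    if os.path.exists(respath):
        with open(respath, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        resolution = {float(e["q"]): ResolutionParams(
            amp=float(e["amp"]), omega0=float(e["omega0"]),
            sigma=float(e["sigma"]), xi=float(e["xi"]), bg=float(e["bg"]))
            for e in doc.get("resolution", [])}
        temperature = float(doc.get("temperature_K", temperature))
    return QensDataset(spectra=tuple(specs), temperature=temperature,
                       resolution=resolution)
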