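"""File formats: drying-curve CSV, spectra-matrix CSV, ENVI cubes.

The ENVI reader/writer is deliberately minimal: plain ``key = value`` header
beside a raw binary file, BIL/BIP/BSQ interleaves, little/big endian, with
wavelengths parsed from the ``wavelength`` header field.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import DryingCurve, TransportParams
from .spectra import HyperCube, SpectralProfile

__all__ = [
    "read_drying_curves",
    "write_drying_curves",
    "write_transport_table",
    "read_spectra_matrix",
    "write_spectra_matrix",
    "read_envi",
    "write_envi",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}


# ---------------------------------------------------------------------------
# drying-curve CSV
# ---------------------------------------------------------------------------

def read_drying_curves(path) -> list[DryingCurve]:
    """Read curves from a tidy CSV: temperature_C, replicate, time_h, moisture_pct, basis."""
    df = pd.read_csv(path)
    required = {"temperature_C", "replicate", "time_h", "moisture_pct", "basis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drying-curve CSV lacks columns: {sorted(missing)}")
    curves = []
    for (temp, rep), grp in df.groupby(["temperature_C", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        basis = grp["basis"].unique()
        if basis.size != 1:
            raise ValueError(f"mixed moisture bases for replicate {rep!r}")
        curves.append(DryingCurve(float(temp), grp["time_h"].to_numpy(),
                                  grp["moisture_pct"].to_numpy(),
                                  basis=str(basis[0]), replicate_id=str(rep)))
    return curves


def write_drying_curves(curves, path):
    rows = []
    for c in curves:
        for t, m in zip(c.times, c.moisture):
            rows.append({"temperature_C": c.temperature,
                         "replicate": c.replicate_id, "time_h": t,
                         "moisture_pct": m, "basis": c.basis})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_transport_table(params: list[TransportParams], path):
    """Tidy per-temperature transport-parameter report."""
    rows = [{"temperature_C": p.temperature, "mu": p.mu,
             "d_eff_m2_s": p.d_eff, "biot": p.biot, "h_m_m_s": p.h_m,
             "fit_mse": p.fit_mse} for p in params]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectra matrix CSV
# ---------------------------------------------------------------------------

def read_spectra_matrix(path):
    """Read a per-sample spectra matrix CSV.

    First column ``sample_id``, remaining columns one per wavelength with
    numeric headers in nm.  Returns ``(sample_ids, wavelengths_nm, X)``.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a spectra matrix must be 'sample_id'")
    wl = np.array([float(c) for c in df.columns[1:]])
    return df["sample_id"].astype(str).to_list(), wl, df.iloc[:, 1:].to_numpy(dtype=float)


def write_spectra_matrix(profiles: list[SpectralProfile], path):
    wl = profiles[0].wavelengths_nm
    for p in profiles[1:]:
        if not np.array_equal(p.wavelengths_nm, wl):
            raise ValueError("profiles must share one wavelength grid")
    df = pd.DataFrame([p.values for p in profiles],
                      columns=[f"{w:.4f}" for w in wl])
    df.insert(0, "sample_id", [p.sample_id for p in profiles])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header")
    fields = {}
    # brace-delimited values may span lines
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         text, flags=re.M):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def read_envi(hdr_path) -> HyperCube:
    """Read a header+raw ENVI pair into a cube (band axis last)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(fields.get("data type", 4))])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))

    raw_path = hdr_path.with_suffix("")  # img.hdr -> img
    if not raw_path.exists():
        for ext in (".raw", ".img", ".dat", ".bil", ".bip", ".bsq"):
            cand = hdr_path.with_suffix(ext)
            if cand.exists():
                raw_path = cand
                break
        else:
            raise FileNotFoundError(f"no raw file found beside {hdr_path}")
    data = np.fromfile(raw_path, dtype=dtype, offset=offset,
                       count=lines * samples * bands)
    if interleave == "bil":
        data = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = data.reshape(lines, samples, bands)
    elif interleave == "bsq":
        data = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].split(",") if v.strip()])
    else:
        wl = np.arange(bands, dtype=float)
    return HyperCube(data.astype(float), wl, calibrated=False)


def write_envi(cube: HyperCube, hdr_path, interleave: str = "bil"):
    """Write a cube as float64 header+raw pair (raw file drops the .hdr suffix).

    Double precision is kept because calibrated bean reflectances can be
    very small (deep absorbances) and must survive the round trip.
    """
    hdr_path = Path(hdr_path)
    h, w, b = cube.data.shape
    arr = cube.data.astype(np.float64)
    interleave = interleave.lower()
    if interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        out = arr
    elif interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    raw_path = hdr_path.with_suffix("")
    out.tofile(raw_path)
    wl = ", ".join(f"{v:.4f}" for v in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\ndata type = 5\n"
        f"interleave = {interleave}\nbyte order = 0\n"
        f"wavelength = {{ {wl} }}\n")
    return raw_path
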