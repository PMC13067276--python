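"""Reading and writing spectra as JCAMP-DX and plain CSV.

The JCAMP-DX support targets the simple AFFN ``(X++(Y..Y))`` dialect on an
evenly spaced axis -- sufficient for processed 1D spectra exchanged as text.
2D planes use a long-format CSV (``f1_ppm,f2_ppm,intensity``) with ``#``
header comments recording the axes and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Spectrum1D, Spectrum2D


def write_jcampdx(spec: Spectrum1D, path, title: str = "") -> None:
    ppm, y = spec.ppm, spec.intensity
    lines = [
        f"##TITLE={title or spec.meta.get('label', 'spectrum')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={ppm[0]:.6f}",
        f"##LASTX={ppm[-1]:.6f}",
        f"##NPOINTS={ppm.size}",
        f"##$META={json.dumps(spec.meta, default=str)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, ppm.size, per_line):
        ys = " ".join(f"{v:.10e}" for v in y[i : i + per_line])
        lines.append(f"{ppm[i]:.6f} {ys}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path) -> Spectrum1D:
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
            elif key == "END":
                break
            else:
                header[key] = value.strip()
            continue
        if in_data:
            ys.extend(float(t) for t in line.split()[1:])
    npoints = int(header["NPOINTS"])
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} points, parsed {len(ys)}")
    first = float(header["FIRSTX"])
    last = float(header["LASTX"])
    yfac = float(header.get("YFACTOR", "1.0"))
    ppm = np.linspace(first, last, npoints)
    y = np.asarray(ys) * yfac
    if first > last:  # stored descending; flip to the internal convention
        ppm, y = ppm[::-1], y[::-1]
    meta = json.loads(header.get("$META", "{}"))
    meta.setdefault("label", header.get("TITLE", ""))
    return Spectrum1D(ppm, y, meta)


def write_csv_1d(spec: Spectrum1D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# meta: {json.dumps(spec.meta, default=str)}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spec.ppm, spec.intensity):
            fh.write(f"{x:.6f},{y:.10e}\n")


def read_csv_1d(path) -> Spectrum1D:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# meta:"):
            meta = json.loads(first[7:])
    df = pd.read_csv(path, comment="#")
    ppm = df["ppm"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    order = np.argsort(ppm)
    return Spectrum1D(ppm[order], y[order], meta)


def read_spectrum_1d(path) -> Spectrum1D:
    """Dispatch on extension: ``.jdx``/``.dx`` -> JCAMP-DX, else CSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".jdx", ".dx", ".jcamp"):
        return read_jcampdx(path)
    return read_csv_1d(path)


def write_csv_2d(spec: Spectrum2D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# meta: {json.dumps(spec.meta, default=str)}\n")
        fh.write(f"# f1: {spec.f1_ppm[0]:.6f} {spec.f1_ppm[-1]:.6f} {spec.f1_ppm.size}\n")
        fh.write(f"# f2: {spec.f2_ppm[0]:.6f} {spec.f2_ppm[-1]:.6f} {spec.f2_ppm.size}\n")
        fh.write("f1_ppm,f2_ppm,intensity\n")
        for i, x1 in enumerate(spec.f1_ppm):
            for j, x2 in enumerate(spec.f2_ppm):
                fh.write(f"{x1:.4f},{x2:.4f},{spec.intensity[i, j]:.8e}\n")


def read_csv_2d(path) -> Spectrum2D:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta:"):
                meta = json.loads(line[7:])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    f1 = np.unique(df["f1_ppm"].to_numpy(dtype=float))
    f2 = np.unique(df["f2_ppm"].to_numpy(dtype=float))
    grid = (
        df.pivot(index="f1_ppm", columns="f2_ppm", values="intensity")
        .sort_index()
        .sort_index(axis=1)
        .to_numpy(dtype=float)
    )
    return Spectrum2D(f1, f2, grid, meta)
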