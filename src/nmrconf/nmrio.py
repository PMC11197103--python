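"""Spectrum file I/O: a minimal JCAMP-DX dialect and two-column text.

The JCAMP-DX writer emits an AFFN ``(X++(Y..Y))`` XYDATA block with the
acquisition metadata carried in user-defined ``##$`` labels so a spectrum
round-trips losslessly (real part; NMR absorption data).  The reader is
tolerant: it needs ``##NPOINTS``, ``##FIRSTX``/``##LASTX`` and an XYDATA
block, and falls back to generic acquisition metadata when the ``##$``
labels are absent.  Delimited text files are two columns (ppm, intensity)
with ``# key = value`` header lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulator import Spectrum
from .spin_system import AcquisitionParams

__all__ = [
    "write_jcampdx",
    "read_jcampdx",
    "write_text_spectrum",
    "read_text_spectrum",
    "write_spectrum",
    "read_spectrum",
]

_JCAMP_SUFFIXES = {".dx", ".jdx", ".jcamp"}


def _acq_labels(spec: Spectrum) -> dict[str, str]:
    p = spec.params
    return {
        "$DETECTISOTOPE": p.detect_isotope,
        "$BASEFREQMHZ": repr(float(spec.base_frequency_mhz)),
        "$NPOINTSTD": str(p.n_points),
        "$ZEROFILLTO": str(p.zerofill_to),
        "$SWEEPPPM": repr(float(p.sweep_ppm)),
        "$CENTERPPM": repr(float(p.center_ppm)),
        "$LINEBROADENINGHZ": repr(float(p.line_broadening_hz)),
    }


def write_jcampdx(spec: Spectrum, path: str | Path,
                  title: str = "simulated NMR spectrum") -> None:
    """Write the absorption spectrum as a JCAMP-DX XYDATA file."""
    axis = spec.axis_ppm
    y = spec.absorption
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= XYDATA",
        "##ORIGIN= nmrconf",
        "##OWNER= public",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY UNITS",
    ]
    for k, v in _acq_labels(spec).items():
        lines.append(f"##{k}= {v}")
    lines += [
        f"##FIRSTX= {float(axis[0])!r}",
        f"##LASTX= {float(axis[-1])!r}",
        f"##NPOINTS= {len(axis)}",
        "##XFACTOR= 1.0",
        "##YFACTOR= 1.0",
        "##XYDATA= (X++(Y..Y))",
    ]
    per_line = 6
    for k0 in range(0, len(y), per_line):
        chunk = y[k0:k0 + per_line]
        vals = " ".join(repr(float(v)) for v in chunk)
        lines.append(f"{float(axis[k0])!r} {vals}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a spectrum written by :func:`write_jcampdx` (or a compatible
    AFFN XYDATA file)."""
    text = Path(path).read_text()
    labels: dict[str, str] = {}
    ydata: list[float] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            labels[key] = val.strip()
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            ydata.extend(float(v) for v in parts[1:])  # first token is X
    if "NPOINTS" not in labels or not ydata:
        raise ValueError(f"{path}: not a readable JCAMP-DX XYDATA file")
    n = int(labels["NPOINTS"])
    if len(ydata) != n:
        raise ValueError(
            f"{path}: NPOINTS={n} but {len(ydata)} ordinates found"
        )
    yfac = float(labels.get("YFACTOR", "1.0"))
    y = np.asarray(ydata) * yfac
    first = float(labels["FIRSTX"])
    last = float(labels["LASTX"])
    axis = np.linspace(first, last, n)
    base = float(labels.get("$BASEFREQMHZ", "500.0"))
    params = AcquisitionParams(
        detect_isotope=labels.get("$DETECTISOTOPE", "1H"),
        n_points=int(labels.get("$NPOINTSTD", n)),
        zerofill_to=int(labels.get("$ZEROFILLTO", n)),
        sweep_ppm=float(labels.get("$SWEEPPPM", abs(last - first))),
        center_ppm=float(labels.get("$CENTERPPM", 0.5 * (first + last))),
        line_broadening_hz=float(labels.get("$LINEBROADENINGHZ", "0.5")),
    )
    return Spectrum(axis, y.astype(complex), params, base)


def write_text_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Two-column delimited text (ppm, absorption intensity) with metadata
    header comments."""
    header = "\n".join(
        f"{k.lstrip('$')} = {v}" for k, v in _acq_labels(spec).items()
    )
    np.savetxt(path, np.column_stack([spec.axis_ppm, spec.absorption]),
               header=header)


def read_text_spectrum(path: str | Path) -> Spectrum:
    meta: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#") and "=" in raw:
            key, _, val = raw.lstrip("# ").partition("=")
            meta[key.strip().upper()] = val.strip()
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited columns")
    axis, y = data[:, 0], data[:, 1]
    n = len(axis)
    base = float(meta.get("BASEFREQMHZ", "500.0"))
    params = AcquisitionParams(
        detect_isotope=meta.get("DETECTISOTOPE", "1H"),
        n_points=int(meta.get("NPOINTSTD", n)),
        zerofill_to=int(meta.get("ZEROFILLTO", n)),
        sweep_ppm=float(meta.get("SWEEPPPM", abs(axis[-1] - axis[0]))),
        center_ppm=float(meta.get("CENTERPPM",
                                  0.5 * (axis[0] + axis[-1]))),
        line_broadening_hz=float(meta.get("LINEBROADENINGHZ", "0.5")),
    )
    return Spectrum(axis, y.astype(complex), params, base)


def write_spectrum(spec: Spectrum, path: str | Path, **kw) -> None:
    """Dispatch on suffix: ``.dx``/``.jdx``/``.jcamp`` → JCAMP-DX, anything
    else → delimited text."""
    if Path(path).suffix.lower() in _JCAMP_SUFFIXES:
        write_jcampdx(spec, path, **kw)
    else:
        write_text_spectrum(spec, path)


def read_spectrum(path: str | Path) -> Spectrum:
    """Sniff the format (JCAMP header vs columns) and read."""
    head = Path(path).read_text(encoding="utf-8", errors="replace")[:64]
    if head.lstrip().startswith("##"):
        return read_jcampdx(path)
    return read_text_spectrum(path)
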