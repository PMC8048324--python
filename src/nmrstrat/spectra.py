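"""One-dimensional NMR spectrum container and plain-text I/O.

A :class:`Spectrum` is a single processed 1D trace: a strictly descending
chemical-shift (ppm) axis, real intensities, an acquisition-channel tag and
sample/patient/timepoint identifiers.  Two channels are distinguished
throughout the package:

``cpmg``
    A CPMG-like spectrum emphasising low-molecular-weight metabolites
    (sharp lines); stands in for the 1D positive projection of a JRES
    acquisition when small metabolites are quantified.
``diff``
    A diffusion-edited-like spectrum retaining only broad lipid and
    macromolecule signals; used for lipid quantification.

Spectra are read and written as two-column delimited text (ppm, intensity)
or as minimal JCAMP-DX 1D files (AFFN ``XYDATA (X++(Y..Y))``).  The package
assumes already-phased real spectra; line broadening and phase correction
are acquisition-side steps performed before export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CHANNEL_CPMG = "cpmg"
CHANNEL_DIFF = "diff"
CHANNELS = (CHANNEL_CPMG, CHANNEL_DIFF)

TIMEPOINT_PRE = "pre"
TIMEPOINT_POST = "post"


@dataclass
class Spectrum:
    """A processed 1D 1H NMR spectrum.

    Parameters
    ----------
    ppm
        Chemical-shift axis in ppm, strictly descending (NMR plotting
        convention, high field to the right).
    intensity
        Real intensities, same length as ``ppm``.
    channel
        Acquisition channel tag, ``"cpmg"`` or ``"diff"``.
    sample_id, patient_id, timepoint
        Identifiers; ``timepoint`` is ``"pre"`` or ``"post"`` when known.
    referenced
        True once the axis has been shift-referenced.
    reference_failed
        Set when referencing was attempted but no usable peak was found.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    channel: str = CHANNEL_CPMG
    sample_id: str = ""
    patient_id: str = ""
    timepoint: str = ""
    referenced: bool = False
    reference_failed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity must have the same length")
        if self.ppm.size >= 2:
            d = np.diff(self.ppm)
            if np.all(d > 0):  # ascending input: flip to convention
                self.ppm = self.ppm[::-1].copy()
                self.intensity = self.intensity[::-1].copy()
            elif not np.all(d < 0):
                raise ValueError("ppm axis must be strictly monotone")

    @property
    def n_points(self) -> int:
        return int(self.ppm.size)

    def shifted(self, delta_ppm: float) -> "Spectrum":
        """Return a copy with the ppm axis shifted by ``delta_ppm``."""
        return replace(self, ppm=self.ppm + delta_ppm)

    def covers(self, low: float, high: float) -> bool:
        """Whether the axis spans the closed interval [low, high]."""
        return bool(self.ppm.min() <= low and self.ppm.max() >= high)


# ---------------------------------------------------------------------------
# delimited text


def write_text(spectrum: Spectrum, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a spectrum as two-column text (ppm, intensity)."""
    data = np.column_stack([spectrum.ppm, spectrum.intensity])
    header = f"ppm{delimiter}intensity"
    np.savetxt(path, data, delimiter=delimiter, header=header, comments="# ")


def read_text(path: str | Path, *, channel: str = CHANNEL_CPMG, sample_id: str = "",
              patient_id: str = "", timepoint: str = "") -> Spectrum:
    """Read a two-column delimited spectrum (whitespace, tab or comma)."""
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#")
    except ValueError:
        data = np.loadtxt(path, comments="#", delimiter=",")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(data[:, 0], data[:, 1], channel=channel,
                    sample_id=sample_id or path.stem,
                    patient_id=patient_id, timepoint=timepoint)


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (no installed package reads this format; AFFN only)


def write_jcampdx(spectrum: Spectrum, path: str | Path, *, title: str | None = None) -> None:
    """Write a minimal JCAMP-DX 4.24 file, AFFN ``XYDATA (X++(Y..Y))``.

    Only the subset of the standard needed for an evenly spaced real 1D
    spectrum is emitted; compressed (SQZ/DIF) forms are not supported.
    """
    ppm = spectrum.ppm[::-1]  # ascending for X++(Y..Y)
    y = spectrum.intensity[::-1]
    lines = [
        f"##TITLE={title or spectrum.sample_id or 'spectrum'}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={ppm.size}",
        f"##FIRSTX={ppm[0]:.6f}",
        f"##LASTX={ppm[-1]:.6f}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, ppm.size, per_line):
        chunk = y[i:i + per_line]
        lines.append(f"{ppm[i]:.6f} " + " ".join(f"{v:.6e}" for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path, *, channel: str = CHANNEL_CPMG, sample_id: str = "",
                 patient_id: str = "", timepoint: str = "") -> Spectrum:
    """Read the minimal JCAMP-DX subset written by :func:`write_jcampdx`.

    Handles AFFN ``XYDATA (X++(Y..Y))`` and ``XYPOINTS (XY..XY)`` blocks.
    """
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            meta[key] = value.strip()
            if key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            continue
        if mode is not None:
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS block found")
    xfac = float(meta.get("XFACTOR", "1.0"))
    yfac = float(meta.get("YFACTOR", "1.0"))
    xs: list[float] = []
    ys: list[float] = []
    if mode is None and "XYDATA" in meta:
        mode = "xydata"
    if "XYPOINTS" in meta and "XYDATA" not in meta:
        for line in data_lines:
            for pair in line.replace(";", " ").split():
                if "," in pair:
                    a, b = pair.split(",")
                    xs.append(float(a))
                    ys.append(float(b))
    else:
        rows = []
        for line in data_lines:
            vals = [float(v) for v in line.replace(",", " ").split()]
            rows.append((vals[0], vals[1:]))
        npts = int(meta.get("NPOINTS", sum(len(r[1]) for r in rows)))
        firstx = float(meta.get("FIRSTX", rows[0][0]))
        lastx = float(meta.get("LASTX", rows[-1][0]))
        dx = (lastx - firstx) / (npts - 1) if npts > 1 else 0.0
        for x0, yvals in rows:
            for j, v in enumerate(yvals):
                xs.append(x0 * xfac + j * dx)
                ys.append(v)
    x = np.asarray(xs)
    y = np.asarray(ys) * yfac
    return Spectrum(x, y, channel=channel, sample_id=sample_id or Path(path).stem,
                    patient_id=patient_id, timepoint=timepoint)
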