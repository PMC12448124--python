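"""Transient-absorption data container and delimited text I/O.

A TA matrix holds difference-absorption values dA(wavelength, delay) in mOD
on a wavelength (nm) x delay (ps) grid, with the pump wavelength as metadata.

File dialect (UTF-8, comma-delimited): lines starting with '#' are comments;
cell (1,1) is the literal ``wavelength_nm``; the first row holds the delays
in ps; the first column the wavelengths in nm; the body is in mOD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TAMatrix", "read_ta_csv", "write_ta_csv"]


@dataclass
class TAMatrix:
    """dA(wavelength, delay) in mOD; ``values[i, j]`` pairs
    ``wavelengths[i]`` with ``delays[j]``."""

    wavelengths: np.ndarray
    delays: np.ndarray
    values: np.ndarray
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.delays.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.wavelengths.size} wavelengths x {self.delays.size} delays"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def kinetic_trace(self, wavelength: float) -> np.ndarray:
        """Signal vs delay at the grid wavelength closest to ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.values[i]

    def spectrum_at(self, delay: float) -> np.ndarray:
        """Spectrum at the grid delay closest to ``delay``."""
        j = int(np.argmin(np.abs(self.delays - delay)))
        return self.values[:, j]


def write_ta_csv(data: TAMatrix, path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        if data.excitation_nm is not None:
            fh.write(f"# excitation_nm = {data.excitation_nm:g}\n")
        fh.write("# wavelengths in nm (rows), delays in ps (columns), values in mOD\n")
        fh.write("wavelength_nm," + ",".join(f"{t:.10g}" for t in data.delays) + "\n")
        for wl, row in zip(data.wavelengths, data.values):
            fh.write(f"{wl:.10g}," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_ta_csv(path) -> TAMatrix:
    excitation = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "excitation_nm" in line and "=" in line:
                    try:
                        excitation = float(line.split("=", 1)[1])
                    except ValueError:
                        pass
                continue
            rows.append(line.split(","))
    if not rows or rows[0][0] != "wavelength_nm":
        raise ValueError(f"{path}: not a TA matrix file (missing 'wavelength_nm' cell)")
    delays = np.array([float(x) for x in rows[0][1:]])
    wavelengths = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return TAMatrix(wavelengths, delays, values, excitation_nm=excitation)
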