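"""Steady-state spectrum arithmetic and band metrics.

Difference spectra between redox forms (e.g. oxidized-minus-semireduced
flavin) are built by linear resampling onto a common grid; band positions
and widths are measured with sub-grid refinement.  All resampling is linear
— difference spectra are sensitive to interpolation overshoot, so splines
and out-of-overlap extrapolation are deliberately avoided.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "difference_spectrum",
    "normalize_spectrum",
    "band_stats",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class Spectrum:
    """Absorbance (OD, or dOD for differences) on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have the same length")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """a - b, with b linearly resampled onto a's grid restricted to the
    overlap of both wavelength ranges.  Raises if the ranges do not overlap."""
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo > hi:
        raise ValueError(
            f"no wavelength overlap between [{a.wavelengths[0]}, {a.wavelengths[-1]}]"
            f" and [{b.wavelengths[0]}, {b.wavelengths[-1]}]"
        )
    keep = (a.wavelengths >= lo) & (a.wavelengths <= hi)
    grid = a.wavelengths[keep]
    b_res = np.interp(grid, b.wavelengths, b.absorbance)
    label = f"{a.label} minus {b.label}".strip()
    return Spectrum(grid, a.absorbance[keep] - b_res, label=label)


def normalize_spectrum(s: Spectrum, mode: str = "max", wavelength: float | None = None) -> Spectrum:
    """Scale so the reference equals 1 in magnitude.

    ``mode='max'`` uses the absorbance maximum; ``mode='at_wavelength'`` uses
    the (interpolated) value at ``wavelength``.  A negative reference scales
    to -1, preserving the sign convention of difference spectra.
    """
    if mode == "max":
        ref = float(np.max(s.absorbance))
    elif mode == "at_wavelength":
        if wavelength is None:
            raise ValueError("mode 'at_wavelength' requires a wavelength")
        if not (s.wavelengths[0] <= wavelength <= s.wavelengths[-1]):
            raise ValueError(f"wavelength {wavelength} outside spectrum range")
        ref = float(np.interp(wavelength, s.wavelengths, s.absorbance))
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'max' or 'at_wavelength'")
    if ref == 0.0:
        raise ValueError("normalization reference is zero")
    return Spectrum(s.wavelengths, s.absorbance / abs(ref), label=s.label)


def band_stats(s: Spectrum, window: tuple[float, float],
               smooth_fwhm: float | None = None) -> tuple[float, float | None]:
    """Peak position and FWHM (nm) of a positive band inside ``window``.

    The peak is the grid argmax refined by a local quadratic through the
    three points around it; the FWHM comes from linear interpolation of the
    half-maximum crossings.  Returns ``(peak_nm, fwhm_nm)``; the FWHM is
    ``None`` when a half-maximum crossing is missing inside the window.

    For noisy spectra, ``smooth_fwhm`` (nm) applies a Gaussian smoothing
    kernel before the peak search (requires a uniform grid).  A Gaussian
    kernel does not shift the center of a symmetric band and widens it in
    quadrature, so the reported FWHM is deconvolved back
    (sqrt(measured^2 - kernel^2)); a kernel of roughly a quarter of the
    expected band width suppresses pixel noise at negligible bias.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be (low, high) with low < high")
    if lo < s.wavelengths[0] or hi > s.wavelengths[-1]:
        raise ValueError(f"window {window} outside spectrum grid")
    absorbance = s.absorbance
    if smooth_fwhm is not None:
        from scipy.ndimage import gaussian_filter1d

        steps = np.diff(s.wavelengths)
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > 1e-6 * step:
            raise ValueError("smoothing requires a uniform wavelength grid")
        sigma_px = smooth_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / step
        absorbance = gaussian_filter1d(s.absorbance, sigma_px, mode="nearest")
    sel = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    wl = s.wavelengths[sel]
    y = absorbance[sel]
    if wl.size < 3:
        raise ValueError("window contains fewer than 3 grid points")
    i = int(np.argmax(y))
    if np.max(y) <= 0:
        raise ValueError("no positive band inside window")
    if 0 < i < wl.size - 1:
        # quadratic through the three points around the maximum
        a, b, c = np.polyfit(wl[i - 1 : i + 2], y[i - 1 : i + 2], 2)
        if a < 0:
            peak = float(np.clip(-b / (2 * a), wl[i - 1], wl[i + 1]))
            ymax = float(np.polyval([a, b, c], peak))
        else:  # flat/degenerate: keep the grid point
            peak, ymax = float(wl[i]), float(y[i])
    else:
        peak, ymax = float(wl[i]), float(y[i])
    half = ymax / 2.0

    def _crossing(idxs) -> float | None:
        # walk from the peak outwards until y drops below half-max
        prev = i
        for j in idxs:
            if y[j] <= half:
                x1, x2 = wl[prev], wl[j]
                y1, y2 = y[prev], y[j]
                return float(x1 + (half - y1) * (x2 - x1) / (y2 - y1))
            prev = j
        return None

    left = _crossing(range(i - 1, -1, -1))
    right = _crossing(range(i + 1, wl.size))
    fwhm = None if (left is None or right is None) else right - left
    if fwhm is not None and smooth_fwhm is not None:
        fwhm = float(np.sqrt(max(fwhm**2 - smooth_fwhm**2, 0.0)))
    return peak, fwhm


def write_spectrum(s: Spectrum, path, delimiter: str = " ") -> None:
    """Two-column text: nm then OD; '#' comments carry the label."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if s.label:
            fh.write(f"# {s.label}\n")
        fh.write("# wavelength_nm absorbance\n")
        for wl, a in zip(s.wavelengths, s.absorbance):
            fh.write(f"{wl:.10g}{delimiter}{a:.10g}\n")


def read_spectrum(path) -> Spectrum:
    """Read two-column whitespace- or comma-delimited text; '#' comments."""
    label = ""
    wls, abso = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if text and "wavelength" not in text and not label:
                    label = text
                continue
            parts = line.replace(",", " ").split()
            wls.append(float(parts[0]))
            abso.append(float(parts[1]))
    return Spectrum(np.array(wls), np.array(abso), label=label)
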