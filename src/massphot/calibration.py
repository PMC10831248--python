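"""Contrast-to-mass calibration and kernel-density mass spectra.

Calibration is an ordinary least-squares line through (mean contrast, known
mass) pairs of standards.  Mass spectra are fixed-bandwidth Gaussian kernel
density estimates on a uniform kDa grid, normalized to unit area, with simple
peak detection and FWHM measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from massphot.synthetic import EventTable

__all__ = [
    "MassCalibration",
    "MassSpectrum",
    "fit_calibration",
    "fit_calibration_pooled",
    "apply_calibration",
    "kde_spectrum",
    "find_peaks",
    "peak_fwhm",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class MassCalibration:
    """Linear contrast-to-mass map fitted against known standards."""

    slope: float  # kDa per contrast unit
    intercept: float  # kDa
    r_squared: float
    standards: tuple[tuple[str, float, float], ...]  # (name, known_mass_kda, mean_contrast)

    def mass_from_contrast(self, contrast):
        return self.slope * np.asarray(contrast, float) + self.intercept

    def contrast_from_mass(self, mass_kda):
        return (np.asarray(mass_kda, float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "standards": [list(s) for s in self.standards],
        }


def _normalize_standards(standards) -> list[tuple[str, float, float]]:
    out = []
    for i, std in enumerate(standards):
        if len(std) == 2:
            mass, contrast = std
            name = f"standard_{i}"
        else:
            name, mass, contrast = std
        out.append((str(name), float(mass), float(contrast)))
    return out


def fit_calibration(standards: Sequence) -> MassCalibration:
    """Fit mass = slope * contrast + intercept by unweighted least squares.

    ``standards`` is a sequence of (known_mass_kda, mean_contrast) or
    (name, known_mass_kda, mean_contrast) tuples; at least two with distinct
    contrasts are required.
    """
    stds = _normalize_standards(standards)
    if len(stds) < 2:
        raise ValueError("at least 2 calibration standards are required")
    contrasts = np.array([s[2] for s in stds], float)
    masses = np.array([s[1] for s in stds], float)
    if np.ptp(contrasts) == 0:
        raise ValueError("singular calibration fit: all standards have identical contrast")
    res = stats.linregress(contrasts, masses)
    r2 = float(res.rvalue) ** 2 if math.isfinite(res.rvalue) else 1.0
    return MassCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        standards=tuple(stds),
    )


def fit_calibration_pooled(runs: Sequence[Sequence]) -> tuple[MassCalibration, list[float]]:
    """Pool standards from several calibrant runs (e.g. before/after) into one fit.

    Returns the pooled calibration and the per-run slopes so that drift between
    runs can be reported; drift is not corrected for.
    """
    if not runs:
        raise ValueError("at least one calibrant run is required")
    per_run_slopes = [fit_calibration(run).slope for run in runs]
    pooled = [std for run in runs for std in _normalize_standards(run)]
    return fit_calibration(pooled), per_run_slopes


def apply_calibration(events: EventTable, cal: MassCalibration) -> EventTable:
    """Return a copy of an event table with masses computed from contrasts."""
    table = events.events.copy()
    if len(table) == 0:
        return EventTable(
            sample_id=events.sample_id,
            events=table,
            dilution_factor=events.dilution_factor,
            nominal_receptor_total=events.nominal_receptor_total,
            nominal_ligand_total=events.nominal_ligand_total,
        )
    contrasts = table["contrast"].to_numpy(float)
    bad = ~np.isfinite(contrasts)
    if bad.any():
        rows = table.loc[bad, "event_index"].tolist()
        raise ValueError(f"events missing contrast values: event_index {rows}")
    table["mass_kda"] = cal.mass_from_contrast(contrasts)
    return EventTable(
        sample_id=events.sample_id,
        events=table,
        dilution_factor=events.dilution_factor,
        nominal_receptor_total=events.nominal_receptor_total,
        nominal_ligand_total=events.nominal_ligand_total,
    )


@dataclass(frozen=True)
class MassSpectrum:
    """Unit-area kernel density estimate of an event-mass distribution."""

    grid: np.ndarray  # kDa, uniform ascending
    density: np.ndarray  # per kDa
    kernel_sigma: float  # kDa
    n_events: int

    @property
    def grid_spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid_kda": self.grid, "density": self.density})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def kde_spectrum(
    masses: Sequence[float],
    kernel_sigma: float = 5.0,
    grid_spacing: float = 1.0,
) -> MassSpectrum:
    """Gaussian KDE of event masses on a uniform grid spanning the data +/- 5 sigma.

    density(x) = (1/n) sum_i Normal(x; mass_i, kernel_sigma), renormalized so
    the trapezoidal integral over the grid is exactly 1.
    """
    m = np.asarray(masses, float)
    if m.size == 0:
        raise ValueError("cannot build a spectrum from zero events")
    if not kernel_sigma > 0:
        raise ValueError("kernel_sigma must be > 0")
    if grid_spacing <= 0 or grid_spacing > kernel_sigma / 2.0:
        raise ValueError("grid_spacing must be in (0, kernel_sigma/2]")
    lo = m.min() - 5.0 * kernel_sigma
    hi = m.max() + 5.0 * kernel_sigma
    n_pts = int(math.ceil((hi - lo) / grid_spacing)) + 1
    grid = lo + grid_spacing * np.arange(n_pts)
    density = np.zeros(n_pts)
    # chunked exact evaluation keeps memory bounded for large event counts
    for start in range(0, m.size, 4096):
        chunk = m[start : start + 4096]
        z = (grid[:, None] - chunk[None, :]) / kernel_sigma
        density += np.exp(-0.5 * z * z).sum(axis=1)
    density /= m.size * kernel_sigma * _SQRT2PI
    density /= np.trapezoid(density, grid)
    return MassSpectrum(grid=grid, density=density, kernel_sigma=float(kernel_sigma), n_events=int(m.size))


def find_peaks(
    spectrum: MassSpectrum, min_prominence_fraction: float = 0.05
) -> list[tuple[float, float]]:
    """Local maxima above ``min_prominence_fraction`` of the global maximum.

    Returns (peak_mass, height) pairs sorted by mass; may be empty.
    """
    threshold = min_prominence_fraction * spectrum.density.max()
    idx, _ = signal.find_peaks(spectrum.density, height=threshold)
    return [(float(spectrum.grid[i]), float(spectrum.density[i])) for i in idx]


def peak_fwhm(spectrum: MassSpectrum, peak_mass: float) -> float:
    """Full width at half maximum of the peak bracketing ``peak_mass``.

    Half-height crossings are located by linear interpolation between grid
    points; raises if the density never falls below half height on either side.
    """
    grid, density = spectrum.grid, spectrum.density
    i = int(np.argmin(np.abs(grid - peak_mass)))
    half = density[i] / 2.0

    def _crossing(direction: int) -> float:
        j = i
        while 0 <= j + direction < len(grid):
            k = j + direction
            if density[k] < half:
                # interpolate between j (>= half) and k (< half)
                frac = (density[j] - half) / (density[j] - density[k])
                return float(grid[j] + frac * (grid[k] - grid[j]))
            j = k
        raise ValueError(
            f"half height of peak at {peak_mass} kDa not crossed within the grid "
            f"({'right' if direction > 0 else 'left'} side)"
        )

    left = _crossing(-1)
    right = _crossing(+1)
    return right - left
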