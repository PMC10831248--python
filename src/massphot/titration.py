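"""Depletion-corrected binding isotherms and bounded hyperbolic (Hill n=1) fits.

Per-condition bound fractions become titration points carrying the computed
free-ligand concentration ``[free] = [titrated] - f * [receptor]``; points
with free ligand under a threshold (default 1 nM) are flagged out, and the
remainder are fitted to ``A + (B - A) L / (K_D + L)`` with A, B bounded to
[0, 100] percent.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from massphot.decomposition import (
    FitConvergenceError,
    baseline_correct,
    fit_receptor_only,
    fit_two_component,
)
from massphot.synthetic import EventTable

__all__ = [
    "TitrationPoint",
    "HillFitResult",
    "ReplicateSummary",
    "AllPointsExcludedError",
    "hill_curve",
    "compute_free_ligand",
    "attach_free_ligand",
    "filter_points",
    "fit_hill",
    "summarize_replicates",
    "points_from_event_tables",
]


class AllPointsExcludedError(ValueError):
    """Every titration point failed the free-ligand filter; no fit is possible."""


@dataclass
class TitrationPoint:
    """One incubation condition of a binding titration (concentrations in nM)."""

    ligand_total: float
    receptor_total_nominal: float
    receptor_total_effective: float
    fraction_raw: float
    fraction_corrected: float
    ligand_free: float | None = None
    included: bool = True

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")
        if self.receptor_total_effective > self.receptor_total_nominal + 1e-9:
            raise ValueError("receptor_total_effective cannot exceed the nominal total")


@dataclass
class HillFitResult:
    """Bounded hyperbolic fit: K_D in nM, asymptotes A and B in percent."""

    kd: float
    a: float
    b: float
    kd_se: float
    a_se: float
    b_se: float
    n_points_used: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd,
            "a_percent": self.a,
            "b_percent": self.b,
            "kd_se": self.kd_se,
            "a_se": self.a_se,
            "b_se": self.b_se,
            "n_points_used": self.n_points_used,
            "flags": self.flags,
        }


def hill_curve(ligand_free, a, b, kd):
    """Complex fraction (percent) at free ligand L: A + (B - A) L / (K_D + L)."""
    L = np.asarray(ligand_free, float)
    return a + (b - a) * L / (kd + L)


def compute_free_ligand(point: TitrationPoint) -> float:
    """Free ligand = total titrated ligand - bound fraction x effective receptor."""
    return point.ligand_total - point.fraction_corrected * point.receptor_total_effective


def attach_free_ligand(points: Sequence[TitrationPoint]) -> list[TitrationPoint]:
    for p in points:
        p.ligand_free = compute_free_ligand(p)
    return list(points)


def filter_points(
    points: Sequence[TitrationPoint], min_free: float = 1.0
) -> list[TitrationPoint]:
    """Flag points whose apparent free ligand is below ``min_free`` (default 1 nM).

    Points are flagged, never deleted; order is preserved.  Raises
    ``AllPointsExcludedError`` if nothing survives.
    """
    for p in points:
        if p.ligand_free is None:
            raise ValueError("free ligand must be computed before filtering")
        p.included = p.ligand_free >= min_free
    if not any(p.included for p in points):
        raise AllPointsExcludedError(
            f"all {len(points)} points have free ligand < {min_free} nM; fit impossible"
        )
    return list(points)


_KD_LO, _KD_HI = 1e-9, 1e9


def fit_hill(points: Sequence[TitrationPoint]) -> HillFitResult:
    """Fit included points to A + (B - A) L / (K_D + L) with 0 <= A, B <= 100.

    Fractions are fitted in percent against the computed free-ligand axis,
    unweighted.  K_D is initialized at the geometric mean of the included
    free-ligand values; A at 0 and B at the maximum observed fraction.
    A K_D estimate at its bounds is flagged, not silently accepted.
    """
    used = [p for p in points if p.included and p.ligand_free is not None]
    if len(used) < 4:
        raise ValueError(f"need at least 4 included points, got {len(used)}")
    L = np.array([p.ligand_free for p in used], float)
    y = np.array([p.fraction_corrected for p in used], float) * 100.0
    positive = L[L > 0]
    if positive.size == 0 or positive.max() / positive.min() < 10.0:
        raise ValueError("included points must span at least a factor 10 in free ligand")
    kd0 = float(np.exp(np.mean(np.log(positive))))
    b0 = float(min(max(y.max(), 1.0), 100.0))
    try:
        popt, pcov = curve_fit(
            hill_curve,
            L,
            y,
            p0=(0.0, b0, kd0),
            bounds=([0.0, 0.0, _KD_LO], [100.0, 100.0, _KD_HI]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"Hill fit did not converge: {exc}") from exc
    a, b, kd = (float(v) for v in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    flags = []
    if kd <= _KD_LO * 10 or kd >= _KD_HI / 10:
        flags.append("kd_at_bound")
    return HillFitResult(
        kd=kd,
        a=a,
        b=b,
        kd_se=float(se[2]),
        a_se=float(se[0]),
        b_se=float(se[1]),
        n_points_used=len(used),
        flags=flags,
    )


@dataclass
class ReplicateSummary:
    """Per-replicate and pooled Hill fits plus display binning of the isotherm."""

    per_replicate: list[HillFitResult]
    pooled: HillFitResult
    kd_values: list[float]
    kd_mean: float
    kd_sd: float | None
    binned: list[dict]  # bin_center_nM, fraction_mean_percent, fraction_sd_percent, n


def summarize_replicates(
    replicate_points: Sequence[Sequence[TitrationPoint]], n_bins: int = 8
) -> ReplicateSummary:
    """Summarize repeated titrations: per-replicate fits, a pooled fit over all
    included points, and log-binned mean +/- s.d. fraction-vs-free-ligand points.

    Bins are log-spaced over the positive free-ligand range with geometric bin
    centers (free ligand differs across replicates, so per-condition averaging
    is not possible).
    """
    if len(replicate_points) < 1:
        raise ValueError("at least one replicate is required")
    per_replicate = [fit_hill(points) for points in replicate_points]
    all_points = [p for points in replicate_points for p in points]
    pooled = fit_hill(all_points)
    kd_values = [fit.kd for fit in per_replicate]
    kd_mean = float(statistics.fmean(kd_values))
    kd_sd = float(statistics.stdev(kd_values)) if len(kd_values) >= 2 else None

    used = [
        (p.ligand_free, p.fraction_corrected * 100.0)
        for p in all_points
        if p.included and p.ligand_free is not None and p.ligand_free > 0
    ]
    binned: list[dict] = []
    if used:
        L = np.array([u[0] for u in used])
        y = np.array([u[1] for u in used])
        edges = np.geomspace(L.min(), L.max(), n_bins + 1)
        edges[-1] *= 1 + 1e-12  # keep the max inside the last bin
        which = np.clip(np.digitize(L, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            mask = which == b
            if not mask.any():
                continue
            vals = y[mask]
            binned.append(
                {
                    "bin_center_nM": float(math.sqrt(edges[b] * edges[b + 1])),
                    "fraction_mean_percent": float(vals.mean()),
                    "fraction_sd_percent": float(vals.std(ddof=1)) if vals.size >= 2 else None,
                    "n": int(vals.size),
                }
            )
    return ReplicateSummary(
        per_replicate=per_replicate,
        pooled=pooled,
        kd_values=kd_values,
        kd_mean=kd_mean,
        kd_sd=kd_sd,
        binned=binned,
    )


def points_from_event_tables(
    tables: Sequence[EventTable],
    receptor_mass: float,
    ligand_mass: float,
    *,
    kernel_sigma: float = 5.0,
    mu_tolerance: float = 1.0,
    min_free: float = 1.0,
    sigma_warn_range: tuple[float, float] = (10.0, 15.0),
) -> tuple[list[TitrationPoint], dict]:
    """Run the full per-titration analysis from raw event tables to fit-ready points.

    Steps: (1) fit the zero-ligand table with a single Gaussian to obtain the
    sample purity and the shared sigma for the constrained fits; (2) fit every
    condition with the constrained two-Gaussian model; (3) subtract the
    zero-ligand apparent complex fraction from all conditions; (4) compute the
    free-ligand axis with the depletion correction and flag points below
    ``min_free``.  Returns the points plus a diagnostics record.
    """
    zero = [t for t in tables if t.nominal_ligand_total == 0]
    if len(zero) != 1:
        raise ValueError(f"expected exactly one zero-ligand table, found {len(zero)}")
    receptor_component, purity = fit_receptor_only(
        zero[0].masses, mu_init=receptor_mass, kernel_sigma=kernel_sigma
    )
    sigma_fixed = receptor_component.sigma
    if not sigma_warn_range[0] <= sigma_fixed <= sigma_warn_range[1]:
        warnings.warn(
            f"fitted peak sigma {sigma_fixed:.1f} kDa is outside the expected "
            f"range {sigma_warn_range}",
            UserWarning,
            stacklevel=2,
        )

    raw: list[tuple[EventTable, float]] = []
    for table in sorted(tables, key=lambda t: t.nominal_ligand_total):
        fit = fit_two_component(
            table.masses,
            receptor_mass=receptor_mass,
            ligand_sequence_mass=ligand_mass,
            sigma_fixed=sigma_fixed,
            mu_tolerance=mu_tolerance,
            kernel_sigma=kernel_sigma,
        )
        raw.append((table, fit.fraction_complex))
    baseline = next(f for t, f in raw if t.nominal_ligand_total == 0)
    corrected = baseline_correct([(t, f) for t, f in raw], baseline)

    points = []
    for (table, raw_fraction), (_, corr_fraction) in zip(raw, corrected):
        nominal = table.nominal_receptor_total
        if nominal is None:
            raise ValueError(f"table {table.sample_id!r} lacks a nominal receptor total")
        points.append(
            TitrationPoint(
                ligand_total=table.nominal_ligand_total,
                receptor_total_nominal=nominal,
                receptor_total_effective=purity * nominal,
                fraction_raw=raw_fraction,
                fraction_corrected=corr_fraction,
            )
        )
    attach_free_ligand(points)
    filter_points(points, min_free=min_free)
    diagnostics = {
        "purity": purity,
        "sigma_fixed": sigma_fixed,
        "baseline_fraction": baseline,
        "receptor_mu": receptor_component.mu,
    }
    return points, diagnostics
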