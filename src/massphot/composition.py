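"""Phosphate-assay standard curve, disc composition arithmetic and integer
stoichiometry assignment of multi-component species masses."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PhosphateStandardCurve",
    "DiscComposition",
    "StoichAssignment",
    "fit_phosphate_curve",
    "lipids_per_disc",
    "disc_composition",
    "assign_stoichiometry",
]

LIPID_UNIT_MASS_KDA = 0.8  # average phospholipid, 800 Da
PEPTIDE_UNIT_MASS_KDA = 4.5  # scaffold peptide


@dataclass(frozen=True)
class PhosphateStandardCurve:
    """Linear absorbance-vs-nmol standard curve for the colorimetric assay."""

    slope: float  # absorbance per nmol
    intercept: float  # absorbance
    r_squared: float

    def absorbance_from_nmol(self, nmol):
        return self.slope * np.asarray(nmol, float) + self.intercept

    def nmol_from_absorbance(self, absorbance):
        return (np.asarray(absorbance, float) - self.intercept) / self.slope


def fit_phosphate_curve(standards: Sequence[tuple[float, float]]) -> PhosphateStandardCurve:
    """Least-squares standard curve from (nmol phosphate, absorbance) pairs.

    Duplicate measurements at the same nmol level are averaged before the
    regression; at least 3 distinct levels are required.
    """
    levels: dict[float, list[float]] = {}
    for nmol, absorbance in standards:
        levels.setdefault(float(nmol), []).append(float(absorbance))
    if len(levels) < 3:
        raise ValueError("at least 3 distinct standard levels are required")
    nmols = np.array(sorted(levels))
    if np.ptp(nmols) == 0:
        raise ValueError("singular fit: standards have zero variance in nmol")
    means = np.array([np.mean(levels[n]) for n in nmols])
    res = stats.linregress(nmols, means)
    if not res.slope > 0:
        raise ValueError(f"standard curve slope must be > 0, got {res.slope}")
    r2 = float(res.rvalue) ** 2 if math.isfinite(res.rvalue) else 1.0
    return PhosphateStandardCurve(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def lipids_per_disc(
    nmol_phosphate: "float | Sequence[float]", nmol_disc: float
) -> tuple[float, float | None]:
    """Lipid:disc molar ratio; replicate phosphate measurements give a s.d.

    Returns ``(ratio, sd)`` where ``sd`` is None for a single measurement.
    """
    if not nmol_disc > 0:
        raise ValueError("nmol_disc must be > 0")
    values = np.atleast_1d(np.asarray(nmol_phosphate, float))
    if np.any(values < 0):
        raise ValueError("nmol_phosphate must be >= 0")
    ratios = values / nmol_disc
    sd = float(ratios.std(ddof=1)) if ratios.size >= 2 else None
    return float(ratios.mean()), sd


@dataclass(frozen=True)
class DiscComposition:
    """Measured particle mass split into protein, lipid and scaffold parts."""

    mass_measured: float  # kDa
    mass_protein: float  # kDa
    lipids_per_disc: float
    lipid_unit_mass: float
    lipid_mass: float  # kDa
    scaffold_mass: float  # kDa
    peptide_unit_mass: float
    n_peptides: int

    def to_dict(self) -> dict:
        return {
            "mass_measured_kda": self.mass_measured,
            "mass_protein_kda": self.mass_protein,
            "lipids_per_disc": self.lipids_per_disc,
            "lipid_mass_kda": self.lipid_mass,
            "scaffold_mass_kda": self.scaffold_mass,
            "n_peptides": self.n_peptides,
        }


def disc_composition(
    mass_measured: float,
    mass_protein: float,
    lipids_per_disc: float,
    lipid_unit_mass: float = LIPID_UNIT_MASS_KDA,
    peptide_unit_mass: float = PEPTIDE_UNIT_MASS_KDA,
) -> DiscComposition:
    """Decompose a measured disc mass into lipid and scaffold contributions.

    lipid mass = lipids x 0.8 kDa (configurable); scaffold mass is the
    remainder after subtracting the protein; the scaffold-peptide count is the
    scaffold mass over 4.5 kDa rounded half-up to the nearest integer.
    """
    if mass_measured < mass_protein:
        raise ValueError("mass_measured must be >= mass_protein")
    lipid_mass = lipids_per_disc * lipid_unit_mass
    scaffold_mass = mass_measured - mass_protein - lipid_mass
    if scaffold_mass < -1e-9:
        raise ValueError(
            f"inconsistent inputs: scaffold mass would be negative ({scaffold_mass:.3g} kDa)"
        )
    scaffold_mass = max(scaffold_mass, 0.0)
    n_peptides = int(math.floor(scaffold_mass / peptide_unit_mass + 0.5))
    return DiscComposition(
        mass_measured=float(mass_measured),
        mass_protein=float(mass_protein),
        lipids_per_disc=float(lipids_per_disc),
        lipid_unit_mass=float(lipid_unit_mass),
        lipid_mass=float(lipid_mass),
        scaffold_mass=float(scaffold_mass),
        peptide_unit_mass=float(peptide_unit_mass),
        n_peptides=n_peptides,
    )


@dataclass(frozen=True)
class StoichAssignment:
    """Best integer composition explaining a species mass."""

    counts: dict  # component name -> integer count
    predicted_mass: float  # kDa
    relative_error: float

    def total_count(self) -> int:
        return sum(self.counts.values())


def assign_stoichiometry(
    species_mass: float,
    components: Sequence[tuple[str, float]],
    max_count_per_component: int = 4,
    rel_tolerance: float = 0.05,
) -> StoichAssignment | None:
    """Exhaustively enumerate integer component counts explaining a species mass.

    All count vectors with entries in [0, max_count_per_component] (not all
    zero) are scored by ``|species - predicted| / predicted``; the minimizer is
    returned if within ``rel_tolerance``, else None.  Ties are broken by the
    smaller total count, then lexicographically by the count vector.
    """
    if not species_mass > 0:
        raise ValueError("species_mass must be > 0")
    names = [str(name) for name, _ in components]
    masses = np.array([float(mass) for _, mass in components])
    if np.any(masses <= 0):
        raise ValueError("component masses must be > 0")
    best: tuple[float, int, tuple[int, ...]] | None = None
    for counts in itertools.product(range(max_count_per_component + 1), repeat=len(components)):
        if not any(counts):
            continue
        predicted = float(np.dot(counts, masses))
        rel_error = abs(species_mass - predicted) / predicted
        key = (rel_error, sum(counts), counts)
        if best is None or key < best:
            best = key
    assert best is not None
    rel_error, _, counts = best
    if rel_error > rel_tolerance:
        return None
    return StoichAssignment(
        counts=dict(zip(names, counts)),
        predicted_mass=float(np.dot(counts, masses)),
        relative_error=rel_error,
    )
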