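"""Energy matrices and the arc-length-dependent minimax energy requirement.

For one patient, E_max[i, j] is the proton energy needed to reach the distal
edge of target i from gantry angle j.  For an arc of length phi the per-patient
requirement is

    En(phi) = max_i  min_k  max_{j in window k} E_max[i, j]

where the windows are the J circular groups of m consecutive gantry angles
spanning phi degrees (m = floor(phi / increment) + 1, clamped to J), one
window starting at each grid angle.  En is nondecreasing in phi because
every smaller arc is contained in some larger arc; En(360) is the global
maximum and En at a single angle (phi = 1 deg) is max_i min_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beams import BeamSpec, GantrySet, distal_spots, gantry_angles, spot_grid
from .density import TissueClassification, effective_density
from .range_energy import FLAG_OK, RangeEnergyTable, build_range_table, energy_for_depth
from .raytrace import dmax
from .volumes import DensityVolume, TargetROI

__all__ = [
    "EnergyMatrix",
    "ArcRequirementCurve",
    "DEFAULT_ARC_LENGTHS",
    "energy_matrix",
    "window_size",
    "arc_requirement",
    "compute_curve",
    "cohort_requirement",
]

DEFAULT_ARC_LENGTHS = (1.0, 90.0, 180.0, 270.0, 360.0)


@dataclass(frozen=True)
class EnergyMatrix:
    """E_max[i, j] (MeV) for all targets i and gantry angles j of one
    patient, with per-entry range-grid clamping flags."""

    values: np.ndarray  # (I, J) MeV
    flags: np.ndarray  # (I, J) str
    patient_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("energy matrix must be 2D (targets x angles)")
        if np.any(v < 50) or np.any(v > 250):
            raise ValueError("energies must lie within the 50-250 MeV grid")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "flags", np.asarray(self.flags))

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]

    @property
    def any_clamped(self) -> bool:
        return bool(np.any(self.flags != FLAG_OK))


@dataclass(frozen=True)
class ArcRequirementCurve:
    """En(phi) for one patient over a set of arc lengths, with the winning
    arc start index per phi (smallest start on ties)."""

    patient_id: str
    arc_lengths_deg: np.ndarray
    energies_mev: np.ndarray
    win_start: np.ndarray
    clamped: bool = False

    def __post_init__(self) -> None:
        phi = np.asarray(self.arc_lengths_deg, float)
        en = np.asarray(self.energies_mev, float)
        if np.any(np.diff(phi) <= 0):
            raise ValueError("arc lengths must be strictly increasing")
        if np.any(np.diff(en) < 0):
            raise ValueError("En(phi) must be nondecreasing in phi")
        object.__setattr__(self, "arc_lengths_deg", phi)
        object.__setattr__(self, "energies_mev", en)
        object.__setattr__(self, "win_start", np.asarray(self.win_start, int))


def energy_matrix(
    volume: DensityVolume,
    targets: list[TargetROI],
    gantry: GantrySet | None = None,
    beam: BeamSpec | None = None,
    table: RangeEnergyTable | None = None,
    classification: TissueClassification | None = None,
    margin_cm: float = 0.0,
    patient_id: str = "",
) -> EnergyMatrix:
    """Run the full per-patient pipeline: effective density -> spot grid ->
    distal spots -> d_max -> energy, for every (target, angle) pair.

    The default gantry is 51 parallel-beam angles with the isocenter at the
    centroid of the target masks.  Raises ``ValueError`` identifying (i, j)
    if some pair yields no distal spots.
    """
    if not targets:
        raise ValueError("at least one target ROI is required")
    beam = beam or BeamSpec()
    table = table if table is not None else build_range_table()
    if gantry is None:
        centroid = np.mean([t.mask_centroid() for t in targets], axis=0)
        gantry = gantry_angles(51, isocenter=centroid)

    eff = effective_density(volume, classification)
    I, J = len(targets), gantry.count
    values = np.empty((I, J))
    flags = np.empty((I, J), dtype=object)
    for i, target in enumerate(targets):
        spots = spot_grid(target, beam)
        for j in range(J):
            sel = distal_spots(target, spots, gantry, j, spacing_cm=beam.spot_spacing_cm)
            if len(sel) == 0:
                raise ValueError(
                    f"no distal spots for target {target.label!r} (i={i}) "
                    f"at gantry index j={j}"
                )
            rec = dmax(eff, sel, gantry, margin_cm=margin_cm)
            lookup = energy_for_depth(rec.dmax_cm, table)
            values[i, j] = lookup.energy_mev
            flags[i, j] = lookup.flag
    return EnergyMatrix(values, flags, patient_id=patient_id)


def window_size(phi_deg: float, n_angles: int) -> int:
    """Number of consecutive gantry angles spanning an arc of phi degrees:
    m = floor(phi / increment) + 1, clamped to the angle count.  phi = 1 deg
    is a single beam direction."""
    if not (0 < phi_deg <= 360):
        raise ValueError(f"arc length must be in (0, 360], got {phi_deg}")
    if n_angles < 1:
        raise ValueError("need at least one gantry angle")
    increment = 360.0 / n_angles
    return min(n_angles, int(np.floor(phi_deg / increment)) + 1)


def arc_requirement(matrix: EnergyMatrix, phi_deg: float) -> tuple[float, int]:
    """En(phi) for one patient and the winning arc start index.

    For each target the within-window maximum is minimized over all J
    circular window placements; the requirement is the maximum of those
    minima over targets.  The reported start index is the first minimizing
    window for the first requirement-setting target.
    """
    E = matrix.values
    J = matrix.n_angles
    m = window_size(phi_deg, J)
    # window maxima for all starts at once: stack m circular shifts
    shifted = np.stack([np.roll(E, -s, axis=1) for s in range(m)], axis=0)
    wmax = shifted.max(axis=0)  # (I, J): max over window starting at each k
    per_target_min = wmax.min(axis=1)
    i_star = int(np.argmax(per_target_min))
    k_star = int(np.argmin(wmax[i_star]))
    return float(per_target_min.max()), k_star


def compute_curve(
    matrix: EnergyMatrix, arc_lengths_deg=DEFAULT_ARC_LENGTHS
) -> ArcRequirementCurve:
    """Evaluate En(phi) over a set of arc lengths for one patient."""
    phis = np.asarray(sorted(arc_lengths_deg), float)
    energies = np.empty(len(phis))
    starts = np.empty(len(phis), int)
    for n, phi in enumerate(phis):
        energies[n], starts[n] = arc_requirement(matrix, phi)
    return ArcRequirementCurve(
        matrix.patient_id, phis, energies, starts, clamped=matrix.any_clamped
    )


def cohort_requirement(
    energies_mev, coverage: float = 1.0
) -> float:
    """Smallest energy treating at least ``coverage`` of the cohort.

    ``energies_mev`` are per-patient En(phi) values at one arc length.
    The required patient count is coverage * N rounded to the nearest whole
    patient (half rounds up, minimum one), so e.g. coverage 0.67 of three
    patients means two of them; coverage 1.0 gives the cohort maximum.
    """
    e = np.sort(np.asarray(list(energies_mev), float))
    if e.size == 0:
        raise ValueError("cohort is empty")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    m = min(e.size, max(1, int(np.floor(coverage * e.size + 0.5))))
    return float(e[m - 1])
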