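"""Depth-to-energy conversion via a Bragg-Kleeman range model.

The Bragg peak depth of a proton pencil beam in water is approximated by its
CSDA range, and the range-energy relation over 50-250 MeV by the
Bragg-Kleeman power law R = alpha * E^p fitted (least squares on
log R vs log E) to an embedded published CSDA water-range table.  The fitted
model is evaluated on a 1 MeV grid from 50 to 250 MeV; a water-equivalent
depth maps to the grid energy whose range is closest, ties broken toward the
lower energy.

The CSDA approximation and the fit both sit far below the ~2% energy
uncertainty already inherent in stopping-power conversion, which is why no
Monte Carlo beamlet transport is needed for a maximum-energy estimate.
Depths outside the covered interval are clamped to the grid ends and
flagged, never raised, so cohort summaries survive a single shallow or deep
target while reports can still surface the clamping.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "RangeEnergyTable",
    "EnergyLookup",
    "build_range_table",
    "energy_for_depth",
]

E_MIN, E_MAX = 50, 250
FIT_TOLERANCE = 0.02  # max relative deviation of the fit from any fixture point

FLAG_OK = "ok"
FLAG_BELOW = "below-grid"
FLAG_ABOVE = "above-grid"


@dataclass(frozen=True)
class RangeEnergyTable:
    """Range in water (cm) on a 1 MeV energy grid, 50-250 MeV inclusive."""

    energies_mev: np.ndarray
    ranges_cm: np.ndarray
    alpha: float  # cm / MeV^p
    p: float
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_mev, float)
        r = np.asarray(self.ranges_cm, float)
        if len(e) != len(r):
            raise ValueError("energy and range arrays differ in length")
        if len(e) != E_MAX - E_MIN + 1:
            raise ValueError(f"expected {E_MAX - E_MIN + 1} grid entries, got {len(e)}")
        if np.any(np.diff(r) <= 0):
            raise ValueError("ranges must be strictly increasing with energy")
        object.__setattr__(self, "energies_mev", e)
        object.__setattr__(self, "ranges_cm", r)

    def range_for_energy(self, energy_mev) -> np.ndarray:
        """Model range (cm water) at arbitrary energies."""
        return self.alpha * np.asarray(energy_mev, float) ** self.p


def _load_fixture(path=None) -> pd.DataFrame:
    if path is None:
        src = resources.files("protonarc.data") / "pstar_water_csda.csv"
        with resources.as_file(src) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def build_range_table(fixture_path=None) -> RangeEnergyTable:
    """Fit the Bragg-Kleeman law to the CSDA fixture and tabulate 1 MeV steps.

    Raises ``ValueError`` if the fixture is non-monotone, does not cover
    50-250 MeV, or is not reproduced by the fit to within 2% at every point.
    """
    df = _load_fixture(fixture_path)
    e = df["energy_MeV"].to_numpy(float)
    r = df["csda_range_g_per_cm2"].to_numpy(float)
    order = np.argsort(e)
    e, r = e[order], r[order]
    if np.any(np.diff(r) <= 0):
        raise ValueError("fixture ranges are not strictly increasing")
    if e.min() > E_MIN or e.max() < E_MAX:
        raise ValueError(f"fixture must cover {E_MIN}-{E_MAX} MeV")

    p, log_alpha = np.polyfit(np.log(e), np.log(r), 1)
    alpha = float(np.exp(log_alpha))
    rel = np.abs(alpha * e**p - r) / r
    if rel.max() >= FIT_TOLERANCE:
        raise ValueError(
            f"Bragg-Kleeman fit misses a fixture point by {rel.max():.2%} (>2%)"
        )

    grid = np.arange(E_MIN, E_MAX + 1, dtype=float)
    return RangeEnergyTable(grid, alpha * grid**p, alpha, float(p))


@dataclass(frozen=True)
class EnergyLookup:
    """Result of a depth-to-energy lookup: grid energy plus a clamping flag
    (``ok``, ``below-grid`` or ``above-grid``)."""

    energy_mev: float
    flag: str

    @property
    def clamped(self) -> bool:
        return self.flag != FLAG_OK


def energy_for_depth(depth_cm: float, table: RangeEnergyTable) -> EnergyLookup:
    """Grid energy whose tabulated range is closest to ``depth_cm``.

    Ties between two neighbouring grid energies go to the lower energy.
    Depths below the 50 MeV range (or above the 250 MeV range) return the
    grid end flagged ``below-grid`` / ``above-grid``.
    """
    if not np.isfinite(depth_cm) or depth_cm < 0:
        raise ValueError(f"depth must be a non-negative number, got {depth_cm}")
    r = table.ranges_cm
    if depth_cm < r[0]:
        return EnergyLookup(float(table.energies_mev[0]), FLAG_BELOW)
    if depth_cm > r[-1]:
        return EnergyLookup(float(table.energies_mev[-1]), FLAG_ABOVE)
    k = int(np.searchsorted(r, depth_cm))
    if k == 0:
        return EnergyLookup(float(table.energies_mev[0]), FLAG_OK)
    # nearest of r[k-1], r[k]; tie -> lower energy
    if depth_cm - r[k - 1] <= r[k] - depth_cm:
        k = k - 1
    return EnergyLookup(float(table.energies_mev[k]), FLAG_OK)
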