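import numpy as np
import pytest

import protonarc as pa
from protonarc.density import WATER


@pytest.fixture(scope="session")
def range_table() -> pa.RangeEnergyTable:
    return pa.build_range_table()


@pytest.fixture(scope="session")
def sphere_oracle() -> pa.SpherePhantom:
    """Water sphere R=8 cm with a concentric 1 cm target: analytic distal
    depth 9.0 cm from every direction."""
    return pa.make_uniform_sphere_phantom(
        radius_cm=8.0, density=1.0, target_radius_cm=1.0,
        voxel_size=(0.125, 0.125, 0.125),
    )


@pytest.fixture(scope="session")
def sphere_eff(sphere_oracle) -> pa.EffectiveDensityVolume:
    """Identity (water) scaling so chord lengths are directly comparable."""
    return pa.effective_density(sphere_oracle.volume, WATER)


@pytest.fixture()
def small_head_spec() -> pa.PhantomSpec:
    """Coarse head phantom that keeps unit tests fast."""
    return pa.PhantomSpec(
        shape=(96, 96, 48),
        voxel_size=(0.2, 0.2, 0.35),
        targets=(pa.TargetSpec((0.0, 0.0, 0.0), (1.2, 1.2, 1.2), "central"),),
    )


def brute_force_arc_requirement(values: np.ndarray, phi_deg: float) -> float:
    """Independent oracle: naive double loop over all circular window starts
    and window members, then min over starts and max over targets."""
    I, J = values.shape
    increment = 360.0 / J
    m = min(J, int(np.floor(phi_deg / increment)) + 1)
    per_target = []
    for i in range(I):
        best = np.inf
        for k in range(J):
            wmax = max(values[i, (k + s) % J] for s in range(m))
            best = min(best, wmax)
        per_target.append(best)
    return float(max(per_target))
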