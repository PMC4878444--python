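"""Synthetic head phantoms and analytic reference phantoms.

The head phantom is an ellipsoidal skull: exterior air, a bone shell of
configurable thickness, a near-unit-density brain interior, an optional
scalp-fat layer outside the bone, and one or more ellipsoidal target ROIs.
It stands in for converted clinical CT + contour data, which is why it emits
mass density directly rather than Hounsfield units.  The uniform sphere
phantom exists for closed-form geometry oracles: chord lengths through a
sphere of known density are exact, so ray-traced water-equivalent depths can
be checked analytically.

All phantoms are deterministic: the same spec and seed reproduce
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .volumes import DensityVolume, TargetROI, write_volume

__all__ = [
    "TargetSpec",
    "PhantomSpec",
    "SpherePhantom",
    "make_head_phantom",
    "make_uniform_sphere_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class TargetSpec:
    """One ellipsoidal target: centre (cm, relative to head centre),
    semi-axes (cm), label."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: str = "target"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic head.

    Defaults use the clinical-export voxel size (0.0703 x 0.0703 x 0.125 cm);
    tests and the bundled cohort generator pass a coarser grid explicitly.
    Densities in g/cm^3; the exterior defaults to 0.0012 (sea-level air, not
    exactly zero) so the air classification branch is exercised downstream.
    """

    shape: tuple[int, int, int] = (256, 288, 128)
    voxel_size: tuple[float, float, float] = (0.0703, 0.0703, 0.125)
    head_semi_axes: tuple[float, float, float] = (6.8, 8.2, 6.0)
    shell_thickness_cm: float = 0.6
    fat_thickness_cm: float = 0.0
    density_air: float = 0.0012
    density_brain: float = 1.040
    density_bone: float = 1.610
    density_fat: float = 0.950
    targets: tuple[TargetSpec, ...] = (TargetSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0)),)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.head_semi_axes):
            raise ValueError("head semi-axes must be strictly positive")
        if self.shell_thickness_cm <= 0:
            raise ValueError("shell thickness must be strictly positive")
        if self.fat_thickness_cm < 0:
            raise ValueError("fat thickness must be non-negative")
        for t in self.targets:
            if any(a <= 0 for a in t.semi_axes):
                raise ValueError(f"target {t.label!r} semi-axes must be positive")


def _ellipsoid_mask(centers, center, semi_axes) -> np.ndarray:
    """Boolean mask of voxel centres inside an axis-aligned ellipsoid."""
    xs, ys, zs = centers
    a, b, c = semi_axes
    r2 = (
        ((xs - center[0]) / a)[:, None, None] ** 2
        + ((ys - center[1]) / b)[None, :, None] ** 2
        + ((zs - center[2]) / c)[None, None, :] ** 2
    )
    return r2 <= 1.0


def _axis_centers(shape, voxel_size):
    return tuple(
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    )


def make_head_phantom(spec: PhantomSpec) -> tuple[DensityVolume, list[TargetROI]]:
    """Voxelize a head phantom and its target ROIs.

    The head is centred in the volume.  Nested layer surfaces are the head
    ellipsoid with semi-axes shrunk by the fat and shell thicknesses (an
    offset-surface approximation adequate for thin shells).  Gaussian noise,
    if requested, is seeded, applied only inside the head, and clipped at 0.

    Raises ``ValueError`` naming the target if any target ellipsoid is not
    fully contained in the brain interior.
    """
    vs = np.asarray(spec.voxel_size, dtype=float)
    shape = tuple(spec.shape)
    centers = _axis_centers(shape, vs)
    head_center = 0.5 * np.asarray(shape) * vs

    semi = np.asarray(spec.head_semi_axes, dtype=float)
    semi_bone = semi - spec.fat_thickness_cm
    semi_brain = semi_bone - spec.shell_thickness_cm
    if np.any(semi_brain <= 0):
        raise ValueError("shell and fat layers leave no brain interior")

    head = _ellipsoid_mask(centers, head_center, semi)
    bone = _ellipsoid_mask(centers, head_center, semi_bone)
    brain = _ellipsoid_mask(centers, head_center, semi_brain)

    values = np.full(shape, spec.density_air, dtype=float)
    if spec.fat_thickness_cm > 0:
        values[head] = spec.density_fat
    else:
        values[head] = spec.density_bone
    values[bone] = spec.density_bone
    values[brain] = spec.density_brain

    rois: list[TargetROI] = []
    for i, t in enumerate(spec.targets):
        c = head_center + np.asarray(t.center, dtype=float)
        mask = _ellipsoid_mask(centers, c, t.semi_axes)
        if not mask.any():
            raise ValueError(f"target {t.label!r} covers no voxels at this resolution")
        if np.any(mask & ~brain):
            raise ValueError(f"target {t.label!r} is not fully inside the brain interior")
        rois.append(TargetROI(mask, label=t.label, index=i, voxel_size=vs))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=shape)
        values[head] += noise[head]
        np.clip(values, 0.0, None, out=values)

    return DensityVolume(values, vs), rois


@dataclass
class SpherePhantom:
    """Uniform sphere with a spherical target; analytic descriptors included
    so tests can evaluate entry-to-distal-edge chord lengths in closed form."""

    volume: DensityVolume
    target: TargetROI
    center: np.ndarray
    radius_cm: float
    density: float
    target_center: np.ndarray
    target_radius_cm: float

    def distal_depth_cm(self, direction) -> float:
        """Closed-form depth, along a parallel beam with unit ``direction``,
        from the sphere entry point to the distal edge of the target along
        the ray through the target centre."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        off = self.target_center - self.center
        # lateral offset of the target-centre ray from the sphere centre
        lat2 = float(np.dot(off, off) - np.dot(off, d) ** 2)
        entry_t = -np.sqrt(self.radius_cm**2 - lat2)  # along d, rel. sphere centre plane
        return float(np.dot(off, d) + self.target_radius_cm - entry_t)


def make_uniform_sphere_phantom(
    radius_cm: float = 8.0,
    density: float = 1.0,
    target_radius_cm: float = 1.0,
    target_offset_cm=(0.0, 0.0, 0.0),
    voxel_size=(0.125, 0.125, 0.125),
    padding_cm: float = 0.5,
) -> SpherePhantom:
    """Uniform-density sphere (0 outside) with a spherical target ROI.

    Raises ``ValueError`` if the target protrudes from the outer sphere.
    """
    off = np.asarray(target_offset_cm, dtype=float)
    if np.linalg.norm(off) + target_radius_cm > radius_cm:
        raise ValueError("target sphere protrudes from the phantom sphere")
    vs = np.asarray(voxel_size, dtype=float)
    extent = 2.0 * (radius_cm + padding_cm)
    shape = tuple(int(np.ceil(extent / v)) for v in vs)
    centers = _axis_centers(shape, vs)
    center = 0.5 * np.asarray(shape) * vs

    inside = _ellipsoid_mask(centers, center, (radius_cm,) * 3)
    values = np.where(inside, float(density), 0.0)
    tmask = _ellipsoid_mask(centers, center + off, (target_radius_cm,) * 3)
    vol = DensityVolume(values, vs)
    roi = TargetROI(tmask, label="sphere-target", index=0, voxel_size=vs)
    return SpherePhantom(vol, roi, center, radius_cm, density, center + off, target_radius_cm)


# Disease mix of a typical cranial SRS case load (fractions sum to 1);
# used only to label synthetic patients so grouped summaries have content.
DISEASE_MIX = (
    ("Metastases", 0.51),
    ("Trigeminal Neuralgia", 0.22),
    ("Meningioma", 0.07),
    ("Vestibular Schwannoma", 0.05),
    ("Astrocytoma", 0.05),
    ("Glioblastoma Multiforme", 0.04),
    ("Arteriovenous Malformation", 0.03),
    ("Other", 0.03),
)


def make_cohort(
    n_patients: int,
    seed: int,
    out_dir=None,
    shape=(128, 128, 64),
    voxel_size=(0.15, 0.15, 0.25),
    noise_sigma: float = 0.0,
) -> list[dict]:
    """Generate a seeded cohort of head-phantom specs (optionally written to
    disk as NIfTI volumes + masks with a YAML manifest).

    Per patient the head semi-axes are jittered a few percent, one or
    (20% of the time) two ellipsoidal targets of 0.7-1.4 cm semi-axes are
    placed within 55% of the brain radius, and a disease label is drawn from
    a typical SRS case mix.  Returns a list of manifest entries; each has a
    ``spec`` (PhantomSpec) plus id/disease, and file paths when written.
    """
    if n_patients < 1:
        raise ValueError("cohort needs at least one patient")
    rng = np.random.default_rng(seed)
    labels = [d for d, _ in DISEASE_MIX]
    probs = np.asarray([p for _, p in DISEASE_MIX])

    entries: list[dict] = []
    for n in range(n_patients):
        scale = rng.uniform(0.92, 1.05)
        head = tuple(float(s * scale) for s in (6.8, 8.2, 6.0))
        brain = np.asarray(head) - 0.6
        n_targets = 2 if rng.uniform() < 0.2 else 1
        targets = []
        for t in range(n_targets):
            semi = tuple(float(a) for a in rng.uniform(0.7, 1.4, size=3))
            u = rng.uniform(0.0, 0.55)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = tuple(float(c) for c in u * brain * direction)
            targets.append(TargetSpec(center, semi, label=f"target-{t}"))
        spec = PhantomSpec(
            shape=tuple(shape),
            voxel_size=tuple(voxel_size),
            head_semi_axes=head,
            targets=tuple(targets),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        disease = labels[int(rng.choice(len(labels), p=probs))]
        entries.append({"id": f"phantom-{n:03d}", "disease": disease, "spec": spec})

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"patients": []}
        for e in entries:
            vol, rois = make_head_phantom(e["spec"])
            vpath = out / f"{e['id']}.nii.gz"
            write_volume(vol, vpath)
            roi_entries = []
            for roi in rois:
                rpath = out / f"{e['id']}_{roi.label}.nii.gz"
                write_volume(roi, rpath)
                roi_entries.append({"path": rpath.name, "label": roi.label})
            manifest["patients"].append(
                {
                    "id": e["id"],
                    "disease": e["disease"],
                    "volume": vpath.name,
                    "rois": roi_entries,
                }
            )
            e["volume"] = vpath
            e["rois"] = roi_entries
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return entries
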