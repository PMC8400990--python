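"""Synthetic test inputs with analytic ground truth.

Two generators stand in for restricted clinical data:

* voxelized geometric phantoms (ball, ellipsoid, cube, slab, two-blob)
  whose exact volume and surface curvature are known in closed form, so
  every reconstruction and curvature routine can be checked against an
  analytic oracle rather than against itself;
* two-group per-region feature cohorts drawn from a common-factor
  Gaussian model with planted effect sizes in chosen regions, emulating
  an NC/MCI case–control table (default group sizes 60 vs 86).

Generation is bit-reproducible from (spec, seed); no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region_table import FEATURE_NAMES, RegionFeatureTable
from .volume_io import LabelVolume, VolumeGrid


@dataclass
class PhantomSpec:
    """Recipe for a voxelized geometric phantom.

    ``shape`` is one of ball / ellipsoid / cube / slab / two_blob; sizes
    are in mm.  Intensities are ``background`` outside and ``tissue``
    inside, with optional partial-volume antialiasing (fractional
    occupancy at boundary voxels) and Gaussian noise.  ``partition_axis``
    splits the shape's label into two half-labels at the midplane, for
    volume-additivity fixtures.
    """

    shape: str = "ball"
    radius: float = 10.0  # ball / two_blob component radius
    semi_axes: tuple[float, float, float] = (15.0, 10.0, 10.0)
    side: float = 10.0  # cube edge
    thickness: float = 8.0  # slab
    separation: float = 24.0  # two_blob center-to-center
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background: float = 0.0
    tissue: float = 100.0
    noise_sd: float = 2.0  # default 2% of tissue intensity
    antialias: bool = True
    partition_axis: int | None = None
    seed: int = 0


@dataclass
class Phantom:
    volume: VolumeGrid
    labels: LabelVolume
    analytic: dict
    spec: PhantomSpec


def _coords_mm(spec: PhantomSpec):
    sp = np.asarray(spec.spacing, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, sp)]
    center = np.array([(n - 1) * s / 2.0 for n, s in zip(spec.grid_shape, sp)])
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return X - center[0], Y - center[1], Z - center[2], sp


def _signed_distance(spec: PhantomSpec, X, Y, Z):
    """Signed distance to the shape surface (negative inside), per component."""
    if spec.shape == "ball":
        return [np.sqrt(X * X + Y * Y + Z * Z) - spec.radius]
    if spec.shape == "ellipsoid":
        a, b, c = spec.semi_axes
        q = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
        grad = np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2 + (Z / c**2) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.where(grad > 0, q * (q - 1.0) / np.maximum(grad, 1e-12), -min(a, b, c))
        return [sd]
    if spec.shape == "cube":
        h = spec.side / 2.0
        qx, qy, qz = np.abs(X) - h, np.abs(Y) - h, np.abs(Z) - h
        outside = np.sqrt(
            np.maximum(qx, 0) ** 2 + np.maximum(qy, 0) ** 2 + np.maximum(qz, 0) ** 2
        )
        inside = np.minimum(np.maximum(qx, np.maximum(qy, qz)), 0)
        return [outside + inside]
    if spec.shape == "slab":
        # finite slab: thick in z, wide in x/y but clear of the grid edge
        nx, ny, _ = spec.grid_shape
        sx, sy, _ = spec.spacing
        hx = (nx - 8) * sx / 2.0
        hy = (ny - 8) * sy / 2.0
        hz = spec.thickness / 2.0
        qx, qy, qz = np.abs(X) - hx, np.abs(Y) - hy, np.abs(Z) - hz
        outside = np.sqrt(
            np.maximum(qx, 0) ** 2 + np.maximum(qy, 0) ** 2 + np.maximum(qz, 0) ** 2
        )
        inside = np.minimum(np.maximum(qx, np.maximum(qy, qz)), 0)
        return [outside + inside]
    if spec.shape == "two_blob":
        d = spec.separation / 2.0
        sd1 = np.sqrt((X + d) ** 2 + Y * Y + Z * Z) - spec.radius
        sd2 = np.sqrt((X - d) ** 2 + Y * Y + Z * Z) - spec.radius
        return [sd1, sd2]
    raise ValueError(f"unknown phantom shape: {spec.shape!r}")


def _analytic(spec: PhantomSpec) -> dict:
    if spec.shape == "ball":
        R = spec.radius
        return {
            "volume": 4.0 / 3.0 * np.pi * R**3,
            "mean_curvature": 1.0 / R,
            "gaussian_curvature": 1.0 / R**2,
            "principal_curvatures": (1.0 / R, 1.0 / R),
        }
    if spec.shape == "ellipsoid":
        a, b, c = spec.semi_axes
        return {
            "volume": 4.0 / 3.0 * np.pi * a * b * c,
            # principal curvatures at the pole on the first axis
            "principal_curvatures_at_pole": (a / b**2, a / c**2),
        }
    if spec.shape == "cube":
        return {"volume": spec.side**3, "face_curvature": 0.0}
    if spec.shape == "slab":
        nx, ny, _ = spec.grid_shape
        sx, sy, _ = spec.spacing
        return {
            "volume": (nx - 8) * sx * (ny - 8) * sy * spec.thickness,
            "face_curvature": 0.0,
        }
    if spec.shape == "two_blob":
        R = spec.radius
        return {
            "volume": 2 * (4.0 / 3.0 * np.pi * R**3),
            "component_volume": 4.0 / 3.0 * np.pi * R**3,
            "mean_curvature": 1.0 / R,
        }
    raise ValueError(spec.shape)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a geometric phantom with its analytic reference attached.

    Partial-volume antialiasing ramps the boundary voxel intensity with
    the signed distance over one voxel, so the half-tissue level set
    sits on the true surface; with ``antialias=False`` occupancy is hard
    binarized.  Gaussian noise of ``noise_sd`` is added everywhere.
    """
    X, Y, Z, sp = _coords_mm(spec)
    extent = np.array(spec.grid_shape) * sp
    _check_margin(spec, extent, sp)
    sds = _signed_distance(spec, X, Y, Z)
    h = float(sp.mean())
    occs = []
    for sd in sds:
        if spec.antialias:
            occs.append(np.clip(0.5 - sd / h, 0.0, 1.0))
        else:
            occs.append((sd < 0).astype(float))
    occ = np.clip(np.sum(occs, axis=0), 0.0, 1.0)
    data = spec.background + (spec.tissue - spec.background) * occ
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    affine = np.diag([sp[0], sp[1], sp[2], 1.0])
    vol = VolumeGrid(data, affine)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    if spec.shape == "two_blob":
        labels[occs[0] > 0.5] = 1
        labels[occs[1] > 0.5] = 2
        table = {1: "blob_A", 2: "blob_B"}
    else:
        inside = occ > 0.5
        if spec.partition_axis is not None:
            ax = spec.partition_axis
            coord = (X, Y, Z)[ax]
            labels[inside & (coord < 0)] = 1
            labels[inside & (coord >= 0)] = 2
            table = {1: f"{spec.shape}_lower", 2: f"{spec.shape}_upper"}
        else:
            labels[inside] = 1
            table = {1: spec.shape}
    lab = LabelVolume(labels, affine, table)
    return Phantom(vol, lab, _analytic(spec), spec)


def _check_margin(spec: PhantomSpec, extent, sp) -> None:
    margin = 2.0 * sp.max()
    half = extent / 2.0
    if spec.shape == "ball":
        reach = np.full(3, spec.radius)
    elif spec.shape == "ellipsoid":
        reach = np.asarray(spec.semi_axes, dtype=float)
    elif spec.shape == "cube":
        reach = np.full(3, spec.side / 2.0)
    elif spec.shape == "slab":
        reach = np.array([half[0] - 4 * sp[0], half[1] - 4 * sp[1],
                          spec.thickness / 2.0])
    elif spec.shape == "two_blob":
        reach = np.array([spec.separation / 2.0 + spec.radius,
                          spec.radius, spec.radius])
    else:
        raise ValueError(spec.shape)
    if np.any(reach > half - margin):
        raise ValueError(
            f"{spec.shape} of reach {reach} mm does not fit inside the grid "
            f"(half-extent {half} mm) with a 2-voxel margin"
        )


# ---------------------------------------------------------------------------
# cohort generator

#: per-feature (location, scale) on which the standardized factor model rides;
#: loosely realistic magnitudes for cortical curvature stats and region volume
FEATURE_SCALES = {
    "gaussian": (0.010, 0.004),
    "mean": (0.10, 0.02),
    "sharpness": (0.020, 0.008),
    "curvedness": (0.12, 0.025),
    "volume": (8000.0, 1200.0),
}


@dataclass
class CohortSpec:
    """Recipe for a two-group per-region feature cohort.

    Within each (subject, region) the five features share a latent
    factor u ~ N(0,1) entering with ``factor_loading``, plus independent
    noise of sd ``noise_sd`` (the standardized feature variance is
    loading² + noise_sd², scaled to each feature's natural units).  In
    the MCI group, every feature of every affected region is shifted by
    ``effect_size`` pooled standard deviations.
    """

    n_per_group: tuple[int, int] = (60, 86)  # (NC, MCI), mirrors the study cohort
    n_regions: int = 76
    affected_regions: tuple[int, ...] | None = None  # default: first 5 region ids
    effect_size: float = 3.0
    factor_loading: float = 0.6
    noise_sd: float = 0.8
    seed: int = 0
    region_ids: tuple[int, ...] | None = None


def make_cohort(spec: CohortSpec):
    """Generate (RegionFeatureTable, group labels, ground-truth record)."""
    n_nc, n_mci = spec.n_per_group
    if n_nc < 2 or n_mci < 2:
        raise ValueError("need at least 2 subjects per group")
    if spec.effect_size < 0:
        raise ValueError("effect size must be >= 0")
    if spec.region_ids is not None:
        regions = list(spec.region_ids)
        if len(regions) != spec.n_regions:
            raise ValueError("region_ids length must equal n_regions")
    elif spec.n_regions == 76:
        from .volume_io import aal_cortical_table

        regions = sorted(aal_cortical_table())
    else:
        regions = list(range(1, spec.n_regions + 1))
    affected = (
        tuple(spec.affected_regions)
        if spec.affected_regions is not None
        else tuple(regions[:5])
    )
    if not set(affected) <= set(regions):
        raise ValueError("affected_regions must be a subset of the region ids")

    n = n_nc + n_mci
    labels = np.array(["NC"] * n_nc + ["MCI"] * n_mci)
    rng = np.random.default_rng(spec.seed)
    total_sd = float(np.hypot(spec.factor_loading, spec.noise_sd))
    u = rng.normal(size=(n, spec.n_regions, 1))
    eps = rng.normal(size=(n, spec.n_regions, 5))
    std = (spec.factor_loading * u + spec.noise_sd * eps) / total_sd

    feats = np.empty((n, spec.n_regions, 5))
    for j, name in enumerate(FEATURE_NAMES):
        loc, scale = FEATURE_SCALES[name]
        feats[:, :, j] = loc + scale * std[:, :, j]
    aff_idx = [regions.index(r) for r in affected]
    for j, name in enumerate(FEATURE_NAMES):
        _, scale = FEATURE_SCALES[name]
        for ri in aff_idx:
            feats[n_nc:, ri, j] += spec.effect_size * scale

    subjects = [f"NC{i:03d}" for i in range(n_nc)] + [f"MCI{i:03d}" for i in range(n_mci)]
    table = RegionFeatureTable(subjects=subjects, regions=regions, features=feats)
    truth = {
        "labels": labels.tolist(),
        "affected_regions": list(affected),
        "effect_size": spec.effect_size,
        "factor_loading": spec.factor_loading,
        "noise_sd": spec.noise_sd,
        "n_per_group": list(spec.n_per_group),
        "seed": spec.seed,
        "feature_scales": {k: list(v) for k, v in FEATURE_SCALES.items()},
    }
    return table, labels, truth
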