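"""Synthetic multimodal 3D volume pairs for registration experiments.

The generator rasterizes a small set of geometric primitives (ellipsoids
and boxes, placed in millimetres about the volume center) into a scalar
volume, then derives a "fixed" and a "moving" image from it through two
different intensity lookups. The default moving-image lookup is
deliberately non-monotone, so the pair emulates a cross-modality (CT/MR
like) relationship in which correlation-based similarity fails but mutual
information peaks at the correct alignment.

The default field is 128 x 128 x 15 voxels at 2.59 x 2.59 x 8.0 mm — a
thick-slice axial acquisition — and the default anatomy is deliberately
asymmetric (an elongated body ellipsoid with off-center inner structures,
smooth oblique shading and a fixed fine-scale texture) so that all three
rotations are identifiable and the mutual-information surface has both a
wide capture basin and a sharp peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .transform import RigidTransform3D, Volume, resample

__all__ = [
    "Ellipsoid",
    "Box",
    "PhantomSpec",
    "default_geometry",
    "default_modality_remap",
    "make_phantom",
    "make_multimodal_pair",
    "ground_truth_transform",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center is a world offset (mm) from the volume center."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float

    def contains(self, points_centered: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        return np.sum(((points_centered - c) / r) ** 2, axis=1) <= 1.0

    def extent(self) -> np.ndarray:
        return np.abs(np.asarray(self.center)) + np.asarray(self.radii)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box; center is a world offset (mm) from the volume center."""

    center: tuple[float, float, float]
    half_size: tuple[float, float, float]
    intensity: float

    def contains(self, points_centered: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        h = np.asarray(self.half_size, dtype=float)
        return np.all(np.abs(points_centered - c) <= h, axis=1)

    def extent(self) -> np.ndarray:
        return np.abs(np.asarray(self.center)) + np.asarray(self.half_size)


def default_geometry(size: Sequence[int], spacing: Sequence[float]) -> list:
    """Asymmetric four-primitive anatomy scaled to the field of view.

    A large elongated "body" ellipsoid nearly filling the field, an
    off-center "organ" ellipsoid inside it, a small bright inclusion, and
    an off-center box in the opposite quadrant. Later primitives overwrite
    earlier ones, so the inner structures sit inside the body. The
    in-plane elongation of the body makes rotations strongly identifiable,
    and the off-center structures break its residual two-fold symmetry.
    """
    fov = np.asarray(size, dtype=float) * np.asarray(spacing, dtype=float)
    return [
        Ellipsoid(
            center=(0.0, 0.0, 0.0),
            radii=tuple(np.array([0.46, 0.34, 0.46]) * fov),
            intensity=60.0,
        ),
        Ellipsoid(
            center=(0.05 * fov[0], 0.03 * fov[1], 0.0),
            radii=tuple(np.array([0.28, 0.16, 0.30]) * fov),
            intensity=120.0,
        ),
        Ellipsoid(
            center=(0.17 * fov[0], 0.06 * fov[1], 0.05 * fov[2]),
            radii=tuple(np.array([0.07, 0.05, 0.10]) * fov),
            intensity=200.0,
        ),
        Box(
            center=(-0.13 * fov[0], 0.11 * fov[1], -0.08 * fov[2]),
            half_size=tuple(np.array([0.06, 0.04, 0.10]) * fov),
            intensity=160.0,
        ),
    ]


_GRADIENT_DIRECTION = np.array([1.0, 0.6, 0.3])
_TEXTURE_SEED = 20120822  # fixed: the texture is anatomy, not experiment noise
_TEXTURE_NODES = (9, 9, 5)


def _texture_field(size: Sequence[int]) -> np.ndarray:
    """Smooth aperiodic unit-scale random field, fixed across specs.

    A coarse Gaussian lattice interpolated (cubic) onto the requested grid:
    the same world-scale pattern at any resolution. Being aperiodic it
    correlates between the two modalities only at true alignment, which is
    what gives the MI surface its sharp, unambiguous peak.
    """
    rng = np.random.default_rng(_TEXTURE_SEED)
    coarse = rng.normal(size=_TEXTURE_NODES)
    nodes = np.asarray(_TEXTURE_NODES, dtype=float) - 1.0
    grid = np.indices(tuple(size), dtype=float)
    coords = [
        grid[axis] / max(size[axis] - 1, 1) * nodes[axis] for axis in range(3)
    ]
    return ndimage.map_coordinates(coarse, np.stack(coords).reshape(3, -1), order=3)


_LEVELS = np.array([0.0, 60.0, 120.0, 200.0])
_REMAPPED = np.array([180.0, 20.0, 220.0, 80.0])


def default_modality_remap(values: np.ndarray) -> np.ndarray:
    """Non-monotone piecewise-linear intensity lookup emulating a second modality.

    Background becomes bright, the main tissue level dark, and the two
    inclusion levels swap their ordering relative to the source image, so
    intensities of the two modalities are related only through a
    non-monotone lookup — the regime where mutual information is needed.
    """
    return np.interp(np.asarray(values, dtype=float), _LEVELS, _REMAPPED)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic multimodal volume pair.

    ``gradient`` applies a smooth oblique intensity modulation across the
    rasterized anatomy and ``texture_amplitude`` adds a fixed aperiodic
    fine-scale field inside it; together they give the phantom the
    multi-scale content of real acquisitions (a broad shading that provides
    capture range and fine detail that provides sub-voxel precision). Set
    both to 0 for piecewise-constant primitives.

    ``noise_sd=None`` applies the default additive Gaussian noise of 1% of
    the moving image's dynamic range; pass 0 for a noise-free pair.
    """

    size: tuple[int, int, int] = (128, 128, 15)
    spacing: tuple[float, float, float] = (2.59, 2.59, 8.0)
    geometry: list | None = None
    modality_map_a: Callable[[np.ndarray], np.ndarray] | None = None
    modality_map_b: Callable[[np.ndarray], np.ndarray] | None = None
    gradient: float = 0.4
    texture_amplitude: float = 18.0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be non-negative")
        if any(s < 1 for s in self.size):
            raise ValueError("size must be positive")


def make_phantom(spec: PhantomSpec) -> Volume:
    """Rasterize the spec's geometry into a volume; fully deterministic.

    Primitives are painted in order (later ones overwrite earlier ones) on
    a zero background; every primitive must lie inside the field of view.
    The oblique ``gradient`` shading and the fixed aperiodic texture are
    then applied inside the anatomy (background stays zero).
    """
    geometry = spec.geometry if spec.geometry is not None else default_geometry(
        spec.size, spec.spacing
    )
    if len(geometry) == 0:
        raise ValueError("phantom geometry must contain at least one primitive")

    volume = Volume(np.zeros(spec.size), spec.spacing)
    half_fov = np.asarray(spec.size) * np.asarray(spec.spacing) / 2.0
    for primitive in geometry:
        if np.any(primitive.extent() > half_fov):
            raise ValueError(f"primitive {primitive} extends beyond the field of view")

    centered = volume.world_coordinates() - volume.world_center
    data = np.zeros(centered.shape[0])
    for primitive in geometry:
        data[primitive.contains(centered)] = primitive.intensity

    inside = data > 0
    if spec.gradient != 0.0:
        fov = np.asarray(spec.size, dtype=float) * np.asarray(spec.spacing, dtype=float)
        projection = centered @ (_GRADIENT_DIRECTION / fov)
        data[inside] *= 1.0 + spec.gradient * projection[inside]
    if spec.texture_amplitude > 0.0:
        data[inside] += spec.texture_amplitude * _texture_field(spec.size)[inside]
    return Volume(data.reshape(spec.size), spec.spacing)


def ground_truth_transform(
    spec: PhantomSpec,
    tx: float = 0.0,
    ty: float = 0.0,
    tz: float = 0.0,
    alpha: float = 0.0,
    beta: float = 0.0,
    gamma: float = 0.0,
) -> RigidTransform3D:
    """Rigid transform with rotation center at the phantom's volume center."""
    center = (np.asarray(spec.size) - 1) * np.asarray(spec.spacing) / 2.0
    return RigidTransform3D(
        alpha=alpha, beta=beta, gamma=gamma, tx=tx, ty=ty, tz=tz, center=center
    )


def make_multimodal_pair(
    spec: PhantomSpec, true_transform: RigidTransform3D | None = None
) -> tuple[Volume, Volume, RigidTransform3D]:
    """Fixed/moving pair whose correct registration is ``true_transform``.

    The fixed image is the phantom through ``modality_map_a`` (identity by
    default). The moving image is the phantom through ``modality_map_b``
    (non-monotone remap by default), warped through the *inverse* of the
    ground-truth transform and with additive Gaussian noise — so pulling
    the moving image back through ``true_transform`` re-aligns it with the
    fixed image. Returns ``(fixed, moving, true_transform)``.
    """
    if true_transform is None:
        true_transform = ground_truth_transform(spec)
    map_a = spec.modality_map_a or (lambda v: v)
    map_b = spec.modality_map_b or default_modality_remap

    phantom = make_phantom(spec)
    fixed = Volume(map_a(phantom.data), spec.spacing)
    moving_source = Volume(map_b(phantom.data), spec.spacing)
    moving = resample(moving_source, true_transform.inverse(), moving_source)

    noise_sd = spec.noise_sd
    if noise_sd is None:
        noise_sd = 0.01 * float(np.ptp(moving.data))
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        moving.data = moving.data + rng.normal(0.0, noise_sd, size=moving.shape)
    return fixed, moving, true_transform
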