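"""Rigid 3D transforms, volumes, resampling and landmark error.

World-coordinate conventions used throughout the package:

* A :class:`Volume` is a scalar grid ``data[ix, iy, iz]`` with per-axis
  voxel ``spacing`` in millimetres and a world ``origin`` (the coordinate of
  voxel ``(0, 0, 0)``); voxel centers sit at ``origin + index * spacing``.
* A :class:`RigidTransform3D` is parameterized by three Euler angles in
  degrees (about x, y, z) and three translations in millimetres, applied
  about a configurable rotation ``center`` (by default the volume center):
  ``T(p) = R (p - c) + c + t``.
* Resampling is backward (pull) warping: every output voxel's world
  coordinate is mapped through the transform into the source volume and
  trilinearly interpolated there.

The Euler matrix used here is, with ``ca = cos(alpha)`` etc.::

    [  cb*cg   ca*sg + sa*sb*cg   sa*sg - ca*sb*cg ]
    [ -cb*sg   ca*cg - sa*sb*sg   sa*cg + ca*sb*sg ]
    [  sb      -sa*cb             ca*cb            ]

which equals the composition ``Rz(-gamma) @ Ry(-beta) @ Rx(-alpha)`` and is
orthonormal with determinant +1 for every angle triple (property-tested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "RigidTransform3D",
    "AffineMap",
    "rotation_matrix",
    "apply_to_point",
    "resample",
    "landmark_error",
    "load_volume",
    "save_volume",
]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = (1.0, 1.0, 1.0)
    origin: np.ndarray = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be a 3-d array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0) or not np.all(np.isfinite(self.spacing)):
            raise ValueError("voxel spacing must be strictly positive and finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def world_center(self) -> np.ndarray:
        """World coordinate of the geometric center of the grid."""
        return self.origin + self.spacing * (np.asarray(self.shape) - 1) / 2.0

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of all voxel centers as an (n_voxels, 3) array."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Euler rotation matrix for angles in degrees about x, y, z.

    Equals ``Rz(-gamma) @ Ry(-beta) @ Rx(-alpha)``; orthonormal with unit
    determinant for any angles.
    """
    a, b, g = np.deg2rad([alpha, beta, gamma])
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    return np.array(
        [
            [cb * cg, ca * sg + sa * sb * cg, sa * sg - ca * sb * cg],
            [-cb * sg, ca * cg - sa * sb * sg, sa * cg + ca * sb * sg],
            [sb, -sa * cb, ca * cb],
        ]
    )


@dataclass(frozen=True)
class AffineMap:
    """A generic affine point map p -> M p + b (world mm to world mm)."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + self.offset
        return out[0] if single else out


@dataclass(frozen=True)
class RigidTransform3D:
    """Six-parameter rigid transform: rotation (degrees) then translation (mm).

    The rotation is applied about ``center`` (world mm):
    ``T(p) = R (p - center) + center + t``. Parameter vector order is
    ``(tx, ty, tz, alpha, beta, gamma)`` matching how the registration
    search space is laid out.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    center: np.ndarray = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        values = [self.alpha, self.beta, self.gamma, self.tx, self.ty, self.tz]
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(self.center)):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def from_params(
        cls, params: Sequence[float], center: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform3D":
        """Build from ``(tx, ty, tz, alpha, beta, gamma)``."""
        tx, ty, tz, alpha, beta, gamma = (float(v) for v in params)
        return cls(alpha=alpha, beta=beta, gamma=gamma, tx=tx, ty=ty, tz=tz, center=center)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.alpha, self.beta, self.gamma])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.alpha, self.beta, self.gamma)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (single (3,) or stacked (n, 3)) through the transform."""
        R = self.rotation
        offset = self.center + self.translation - R @ self.center
        return AffineMap(R, offset).apply(points)

    def inverse(self) -> AffineMap:
        """Exact inverse map: p = R^T (q - center - t) + center."""
        R = self.rotation
        return AffineMap(R.T, self.center - R.T @ (self.center + self.translation))

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form of the transform."""
        R = self.rotation
        mat = np.eye(4)
        mat[:3, :3] = R
        mat[:3, 3] = self.center + self.translation - R @ self.center
        return mat

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "tx": self.tx,
            "ty": self.ty,
            "tz": self.tz,
            "center": self.center.tolist(),
            "matrix": self.as_matrix().tolist(),
        }

    @classmethod
    def from_dict(cls, record: dict) -> "RigidTransform3D":
        return cls(
            alpha=float(record["alpha"]),
            beta=float(record["beta"]),
            gamma=float(record["gamma"]),
            tx=float(record["tx"]),
            ty=float(record["ty"]),
            tz=float(record["tz"]),
            center=record.get("center", (0.0, 0.0, 0.0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RigidTransform3D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_to_point(transform: RigidTransform3D, point: Sequence[float]) -> np.ndarray:
    """Map a single world point (mm) through a rigid transform."""
    return transform.apply(np.asarray(point, dtype=float))


def resample(
    moving: Volume,
    transform,
    reference: Volume,
    *,
    order: int = 1,
    fill: float = 0.0,
    return_mask: bool = False,
):
    """Backward-warp ``moving`` onto the grid of ``reference``.

    Each reference voxel's world coordinate is mapped through ``transform``
    (any object with an ``apply(points)`` method) into moving-image space
    and interpolated there (``order=1`` is trilinear). Coordinates falling
    outside the moving volume take ``fill``; with ``return_mask=True`` a
    boolean validity mask on the reference grid is returned as well so
    downstream metrics can exclude those voxels.
    """
    mapped = transform.apply(reference.world_coordinates())
    idx = (mapped - moving.origin) / moving.spacing
    values = ndimage.map_coordinates(
        moving.data, idx.T, order=order, mode="constant", cval=fill
    )
    out = Volume(values.reshape(reference.shape), reference.spacing.copy(), reference.origin.copy())
    if return_mask:
        upper = np.asarray(moving.shape, dtype=float) - 1.0
        mask = np.all((idx >= 0.0) & (idx <= upper), axis=1).reshape(reference.shape)
        return out, mask
    return out


def landmark_error(
    transform_est: RigidTransform3D,
    landmarks: np.ndarray,
    transform_golden: RigidTransform3D,
) -> float:
    """Mean Euclidean distance (mm) between two transforms' images of landmarks.

    Landmarks are world points, one per row. This is the standard fiducial
    comparison of an estimated registration against a gold-standard one.
    """
    pts = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if pts.size == 0:
        raise ValueError("landmark_error requires at least one landmark")
    if pts.shape[1] != 3:
        raise ValueError("landmarks must be (n, 3) world points")
    delta = transform_est.apply(pts) - transform_golden.apply(pts)
    return float(np.mean(np.linalg.norm(delta, axis=1)))


# ---------------------------------------------------------------------------
# Volume I/O: NIfTI through nibabel, MetaImage through SimpleITK.

def save_volume(volume: Volume, path) -> None:
    """Write a volume to .nii/.nii.gz (NIfTI) or .mha/.mhd (MetaImage)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        image = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))
        image.SetSpacing(tuple(float(s) for s in volume.spacing))
        image.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(image, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path) -> Volume:
    """Read a volume from .nii/.nii.gz (NIfTI) or .mha/.mhd (MetaImage)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        image = nib.load(str(path))
        affine = image.affine
        data = np.asarray(image.dataobj, dtype=float)
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return Volume(data, spacing, affine[:3, 3])
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        image = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
        return Volume(np.asarray(data, dtype=float), image.GetSpacing(), image.GetOrigin())
    raise ValueError(f"unsupported volume format: {path.name}")
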