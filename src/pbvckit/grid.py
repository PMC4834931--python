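"""Image container, NIfTI I/O, resampling and rigid transforms.

All stages of the pipeline exchange :class:`VolumeGrid` objects: a 3D scalar
array plus the geometry needed to place each voxel in world (scanner)
coordinates.  Conventions, fixed once for the whole package:

* voxel indices are 0-based; world coordinates refer to voxel *centers*;
* ``world = origin + direction @ (spacing * index)``;
* internal orientation is RAS (readers reorient on load);
* a :class:`RigidTransform` maps points as ``y = R @ (x - c) + c + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VolumeGrid:
    """A 3D scalar image with anisotropic voxel spacing, origin and orientation.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing_mm : array-like of 3 floats
        Voxel size along each axis, strictly positive.
    origin_mm : array-like of 3 floats
        World position of the center of voxel (0, 0, 0).
    direction : (3, 3) ndarray
        Orthonormal axis matrix (columns are world directions of the axes).
    """

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None
    direction: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VolumeGrid requires a 3D array, got {self.data.ndim}D"
            )
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be 3 strictly positive floats")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=float)
        d = self.direction
        if abs(abs(np.linalg.det(d)) - 1.0) > 1e-6 or not np.allclose(
            d @ d.T, np.eye(3), atol=1e-6
        ):
            raise ValueError("direction must be orthonormal (|det| = 1)")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (NIfTI convention, voxel centers)."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing_mm)
        a[:3, 3] = self.origin_mm
        return a

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (self.direction @ (self.spacing_mm * idx).T).T + self.origin_mm

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.direction.T @ (xyz - self.origin_mm).T).T / self.spacing_mm

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"),
            axis=-1,
        ).astype(float)
        flat = self.voxel_to_world(idx.reshape(-1, 3))
        return flat.reshape(idx.shape)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new voxel values."""
        return replace(self, data=np.asarray(data))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class RigidTransform:
    """6-parameter rigid transform ``y = R @ (x - c) + c + t``.

    ``rotation`` are Euler angles (radians) composed as Rz @ Ry @ Rx.
    The identity has all-zero parameters.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        R = self.matrix
        h[:3, :3] = R
        h[:3, 3] = self.center_mm + self.translation_mm - R @ self.center_mm
        return h

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        h = self.homogeneous()
        return (h[:3, :3] @ xyz.T).T + h[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        h = self.homogeneous() @ other.homogeneous()
        return RigidTransform.from_matrix(h[:3, :3], h[:3, 3])

    def inverse(self) -> "RigidTransform":
        h = np.linalg.inv(self.homogeneous())
        return RigidTransform.from_matrix(h[:3, :3], h[:3, 3])

    @staticmethod
    def from_matrix(R: np.ndarray, offset: np.ndarray) -> "RigidTransform":
        """Build from rotation matrix and offset of ``y = R x + offset``."""
        # Euler angles for R = Rz @ Ry @ Rx
        ry = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-8:
            rx = np.arctan2(R[2, 1], R[2, 2])
            rz = np.arctan2(R[1, 0], R[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-R[1, 2], R[1, 1])
            rz = 0.0
        return RigidTransform(
            rotation=np.array([rx, ry, rz]),
            translation_mm=np.asarray(offset, dtype=float),
            center_mm=np.zeros(3),
        )

    def to_dict(self) -> dict:
        return {
            "convention": "y = R(z,y,x) @ (x - center) + center + translation",
            "rotation_rad": list(map(float, self.rotation)),
            "translation_mm": list(map(float, self.translation_mm)),
            "center_mm": list(map(float, self.center_mm)),
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(
            rotation=d["rotation_rad"],
            translation_mm=d["translation_mm"],
            center_mm=d["center_mm"],
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume, reoriented to RAS."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    aff = img.affine
    m = aff[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return VolumeGrid(
        data=np.asanyarray(img.dataobj),
        spacing_mm=spacing,
        origin_mm=aff[:3, 3],
        direction=direction,
    )


def write_volume(v: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data), v.affine), str(path))


# ---------------------------------------------------------------------------
# Resampling

_ORDERS = {"nearest": 0, "linear": 1, "bspline3": 3}


def resample(
    v: VolumeGrid,
    target: VolumeGrid,
    transform: RigidTransform | None = None,
    order: str = "linear",
    cval: float = 0.0,
) -> VolumeGrid:
    """Resample ``v`` onto the geometry of ``target``.

    ``transform`` maps *target*-space world points into *v*-space world
    points (the ITK resampling convention); identity when omitted.
    Out-of-field voxels are filled with ``cval``.  ``nearest`` must be used
    for label maps; ``bspline3`` may overshoot and is excluded from them.
    """
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {sorted(_ORDERS)}")
    if transform is None:
        transform = RigidTransform()
    if abs(np.linalg.det(transform.homogeneous()[:3, :3])) < 1e-12:
        raise ValueError("singular transform")
    # target index -> target world -> v world -> v index, as one affine
    A = np.linalg.inv(v.affine) @ transform.homogeneous() @ target.affine
    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in target.shape), indexing="ij"),
        axis=0,
    ).astype(float)
    coords = np.einsum("ij,j...->i...", A[:3, :3], idx) + A[:3, 3, None, None, None]
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float),
        coords,
        order=_ORDERS[order],
        mode="constant",
        cval=cval,
        prefilter=order == "bspline3",
    )
    return VolumeGrid(
        data=out,
        spacing_mm=target.spacing_mm,
        origin_mm=target.origin_mm,
        direction=target.direction,
    )


# ---------------------------------------------------------------------------
# SimpleITK interop (used by the registration stages)


def to_sitk(v: VolumeGrid):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(v.data, dtype=np.float64).T))
    img.SetSpacing(tuple(map(float, v.spacing_mm)))
    img.SetOrigin(tuple(map(float, v.origin_mm)))
    img.SetDirection(tuple(v.direction.flatten(order="C")))
    return img


def from_sitk(img) -> VolumeGrid:
    import SimpleITK as sitk

    data = sitk.GetArrayFromImage(img).T
    return VolumeGrid(
        data=np.ascontiguousarray(data),
        spacing_mm=np.array(img.GetSpacing()),
        origin_mm=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )
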