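"""Volume geometry shared by every pipeline stage.

Rasters live on a :class:`VolumeGrid` (shape + voxel-index -> MNI-mm affine).
The region of interest is a :class:`HemiMask` whose voxels carry a left/right
hemisphere label derived from the sign of their MNI x coordinate.  Searchlight
spheres are precomputed integer offset sets; statistical maps are reduced to
cluster tables with MNI peak / centre-of-mass coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FormatError",
    "VolumeGrid",
    "HemiMask",
    "SphereOffsets",
    "sphere_offsets",
    "neighborhood",
    "Cluster",
    "ClusterTable",
    "extract_clusters",
    "read_volume",
    "write_volume",
]

LEFT, RIGHT = 1, 2  # hemisphere raster labels


class FormatError(ValueError):
    """A file could not be interpreted as the expected format."""


@dataclass(frozen=True)
class VolumeGrid:
    """3-D raster geometry: shape and voxel-index -> MNI-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"bad raster shape {self.shape}")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths recovered from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def to_mni(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to MNI mm coordinates of voxel centres."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]

    def compatible(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class HemiMask:
    """Boolean region on a grid with a per-voxel left/right hemisphere label.

    ``labels`` is 0 outside the region, 1 (left, MNI x < 0) or 2 (right,
    MNI x > 0) inside.  Voxels whose centre sits exactly on the midline
    (x == 0) belong to neither hemisphere and are dropped from the region so
    that laterality sums never double-count them.
    """

    grid: VolumeGrid
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("labels raster does not match grid shape")
        if not np.isin(labels, (0, LEFT, RIGHT)).all():
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = labels.astype(np.uint8)
        if not self.labels.any():
            raise ValueError("mask region is empty")

    @classmethod
    def from_region(cls, region: np.ndarray, grid: VolumeGrid) -> "HemiMask":
        """Label a boolean region by hemisphere from the sign of MNI x."""
        region = np.asarray(region, dtype=bool)
        idx = np.argwhere(region)
        x = grid.to_mni(idx)[:, 0]
        labels = np.zeros(grid.shape, dtype=np.uint8)
        labels[tuple(idx[x < 0].T)] = LEFT
        labels[tuple(idx[x > 0].T)] = RIGHT
        return cls(grid=grid, labels=labels)

    @property
    def region(self) -> np.ndarray:
        return self.labels > 0

    def hemisphere(self, side: str) -> np.ndarray:
        """Boolean raster of one hemisphere ('left' or 'right')."""
        code = {"left": LEFT, "right": RIGHT}[side]
        return self.labels == code

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) voxel indices of the region in lexicographic order."""
        return np.argwhere(self.region)

    @property
    def n_voxels(self) -> int:
        return int(self.region.sum())


@dataclass(frozen=True)
class SphereOffsets:
    """All integer offsets with squared Euclidean norm <= radius^2."""

    radius_vox: int
    offsets: np.ndarray  # (n, 3) int, lexicographic order

    def __len__(self) -> int:
        return len(self.offsets)


def sphere_offsets(radius_vox: int) -> SphereOffsets:
    """Lattice ball of a searchlight sphere.

    Radius 3 gives the 123-voxel sphere used for the RSA searchlight; radius
    0 is the single centre voxel.
    """
    if radius_vox < 0 or int(radius_vox) != radius_vox:
        raise ValueError(f"radius_vox must be a nonnegative integer, got {radius_vox}")
    r = int(radius_vox)
    rng = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = (grid**2).sum(axis=1) <= r * r
    offs = grid[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return SphereOffsets(radius_vox=r, offsets=np.ascontiguousarray(offs[order]))


def neighborhood(center, offsets: SphereOffsets, mask) -> np.ndarray:
    """Voxel indices of ``center + offsets`` inside the mask.

    ``mask`` may be a HemiMask or a boolean raster.  The centre must lie in
    the mask and is always part of the result; ordering is the deterministic
    lexicographic offset order.
    """
    region = mask.region if isinstance(mask, HemiMask) else np.asarray(mask, dtype=bool)
    center = np.asarray(center, dtype=int)
    if center.shape != (3,):
        raise ValueError("center must be a voxel index triple")
    if (
        (center < 0).any()
        or (center >= np.array(region.shape)).any()
        or not region[tuple(center)]
    ):
        raise ValueError(f"center {tuple(center)} is outside the mask")
    pts = center[None, :] + offsets.offsets
    inb = ((pts >= 0) & (pts < np.array(region.shape))).all(axis=1)
    pts = pts[inb]
    keep = region[tuple(pts.T)]
    return pts[keep]


@dataclass
class Cluster:
    indices: np.ndarray  # (k, 3) member voxel indices
    size: int
    peak_mni: np.ndarray  # (3,) mm, peak-statistic voxel (or COM-nearest voxel)
    com_mni: np.ndarray  # (3,) mm, centre of mass
    peak_index: np.ndarray  # (3,) voxel index of the peak
    movement: str | None = None
    side: str | None = None


@dataclass
class ClusterTable:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        """Tab-separable summary: movement, side, peak x/y/z (mm), size."""
        rows = [
            {
                "movement": c.movement,
                "side": c.side,
                "x": c.peak_mni[0],
                "y": c.peak_mni[1],
                "z": c.peak_mni[2],
                "size": c.size,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows, columns=["movement", "side", "x", "y", "z", "size"])


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def extract_clusters(
    binary_map: np.ndarray,
    min_size: int,
    grid: VolumeGrid,
    stat_map: np.ndarray | None = None,
    connectivity: int = 26,
    movement: str | None = None,
    side: str | None = None,
) -> ClusterTable:
    """Connected components of a binary raster, small components dropped.

    The peak is the member voxel maximising ``stat_map`` (lexicographically
    smallest index on ties); without a statistic the member voxel nearest the
    centre of mass is reported.  26-connectivity by default, as is usual for
    statistical-map cluster reporting.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    binary_map = np.asarray(binary_map, dtype=bool)
    if binary_map.shape != grid.shape:
        raise ValueError("binary map does not match grid shape")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labeled, n = ndimage.label(binary_map, structure=structure)
    out = ClusterTable()
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        if len(idx) < min_size:
            continue
        # lexicographic member order for determinism
        idx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))]
        com = idx.mean(axis=0)
        if stat_map is not None:
            vals = np.asarray(stat_map)[tuple(idx.T)]
            peak = idx[int(np.argmax(vals))]  # argmax -> first (lexicographic) max
        else:
            d2 = ((idx - com) ** 2).sum(axis=1)
            peak = idx[int(np.argmin(d2))]
        out.clusters.append(
            Cluster(
                indices=idx,
                size=len(idx),
                peak_mni=grid.to_mni(peak)[0],
                com_mni=grid.to_mni(com)[0],
                peak_index=peak,
                movement=movement,
                side=side,
            )
        )
    return out


def read_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3-D/4-D NIfTI raster and its grid."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read NIfTI volume {path!s}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path!s}: expected a 3-D or 4-D raster, got ndim={data.ndim}")
    return data, VolumeGrid(shape=data.shape[:3], affine=affine)


def write_volume(path, data: np.ndarray, grid: VolumeGrid) -> None:
    data = np.asarray(data)
    if data.shape[:3] != grid.shape:
        raise ValueError("data does not match grid shape")
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))
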