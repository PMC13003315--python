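"""Core data containers and coordinate conventions.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based;
* physical positions in µm are voxel indices multiplied by the grid spacing
  ``(dz, dy, dx)``;
* label 0 is background everywhere; labels need not be consecutive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and voxel spacing of a 3D acquisition.

    Parameters
    ----------
    shape : tuple of int
        ``(nz, ny, nx)`` voxel counts, each >= 1.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel sizes in µm, each > 0.  ``dz`` is typically
        larger than the lateral spacing (anisotropic Z sampling) but no
        ordering is required.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("shape and spacing must be length-3 (z, y, x)")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³ (dz·dy·dx)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def plane_shape(self) -> tuple[int, int]:
        """Lateral ``(ny, nx)`` shape of one Z plane."""
        return self.shape[1:]


@dataclass
class VolumeImage:
    """One channel of a 3D stack with its voxel grid."""

    grid: VoxelGrid
    data: np.ndarray
    channel_name: str = "ch0"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class ZReferenceMap:
    """Apical reference surface: per-pixel Z index plus the projected intensity."""

    zmap: np.ndarray
    projection: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.zmap = np.asarray(self.zmap, dtype=float)
        self.projection = np.asarray(self.projection)
        if self.zmap.shape != self.projection.shape:
            raise ValueError("zmap and projection shapes differ")
        if self.zmap.shape != self.grid.plane_shape:
            raise ValueError("zmap shape does not match grid plane shape")
        nz = self.grid.shape[0]
        if self.zmap.min() < 0 or self.zmap.max() > nz - 1:
            raise ValueError("zmap values out of Z bounds")


@dataclass
class ApicalCellMap:
    """2.5D cell map: 2D integer labels plus one Z coordinate per cell.

    ``labels2d`` is a ``(ny, nx)`` integer image (0 = background) and
    ``cell_z`` maps every positive label to its apical Z position in voxel
    units (float allowed).
    """

    labels2d: np.ndarray
    cell_z: dict[int, float]
    grid: VoxelGrid

    def __post_init__(self):
        self.labels2d = np.asarray(self.labels2d)
        if not np.issubdtype(self.labels2d.dtype, np.integer):
            raise TypeError("labels2d must be an integer array")
        if self.labels2d.shape != self.grid.plane_shape:
            raise ValueError("labels2d shape does not match grid plane shape")
        if self.labels2d.min() < 0:
            raise ValueError("negative labels are not allowed")
        self.cell_z = {int(k): float(v) for k, v in self.cell_z.items()}
        self.validate()

    def validate(self):
        present = set(np.unique(self.labels2d)) - {0}
        present = {int(p) for p in present}
        if 0 in self.cell_z:
            raise ValueError("label 0 (background) must not appear in cell_z")
        missing = present - set(self.cell_z)
        if missing:
            raise ValueError(f"labels without a Z entry: {sorted(missing)}")
        nz = self.grid.shape[0]
        for c, z in self.cell_z.items():
            if not (0 <= z <= nz - 1):
                raise ValueError(f"cell {c}: z={z} outside [0, {nz - 1}]")

    @property
    def labels(self) -> list[int]:
        """Sorted list of cell labels present in the image."""
        out = np.unique(self.labels2d)
        return [int(v) for v in out if v != 0]


NUCLEI_PROP_COLUMNS = ["label", "z", "y", "x", "volume_um3", "mean_intensity"]


def nuclei_props_from_labels(
    labels3d: np.ndarray,
    grid: VoxelGrid,
    intensity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-nucleus properties from a 3D label volume.

    Returns a DataFrame with columns label, centroid z/y/x (voxel units),
    volume in µm³ (voxel count × dz·dy·dx) and mean intensity (NaN when no
    intensity image is given).
    """
    labels3d = np.asarray(labels3d)
    if labels3d.max() == 0:
        return pd.DataFrame(columns=NUCLEI_PROP_COLUMNS)
    props = ["label", "centroid", "area"]
    kwargs = {}
    if intensity is not None:
        props.append("intensity_mean")
        kwargs["intensity_image"] = np.asarray(intensity, dtype=float)
    tab = regionprops_table(labels3d, properties=props, **kwargs)
    df = pd.DataFrame(
        {
            "label": tab["label"].astype(int),
            "z": tab["centroid-0"],
            "y": tab["centroid-1"],
            "x": tab["centroid-2"],
            "volume_um3": tab["area"] * grid.voxel_volume,
            "mean_intensity": tab.get("intensity_mean", np.full(len(tab["label"]), np.nan)),
        }
    )
    return df.sort_values("label").reset_index(drop=True)


@dataclass
class NucleiLabels:
    """3D nucleus segmentation: label volume plus per-nucleus properties."""

    labels3d: np.ndarray
    props: pd.DataFrame
    grid: VoxelGrid

    def __post_init__(self):
        self.labels3d = np.asarray(self.labels3d)
        if not np.issubdtype(self.labels3d.dtype, np.integer):
            raise TypeError("labels3d must be an integer array")
        if self.labels3d.shape != self.grid.shape:
            raise ValueError("labels3d shape does not match grid shape")
        present = {int(v) for v in np.unique(self.labels3d)} - {0}
        listed = set(int(v) for v in self.props["label"]) if len(self.props) else set()
        if present != listed:
            raise ValueError(
                f"props cover labels {sorted(listed)} but volume has {sorted(present)}"
            )

    @classmethod
    def from_labels(
        cls, labels3d: np.ndarray, grid: VoxelGrid, intensity: np.ndarray | None = None
    ) -> "NucleiLabels":
        return cls(labels3d, nuclei_props_from_labels(labels3d, grid, intensity), grid)

    @property
    def labels(self) -> list[int]:
        return [int(v) for v in self.props["label"]]

    def centroids_um(self) -> np.ndarray:
        """Nucleus centroids in µm, shape (n, 3), order (z, y, x)."""
        if len(self.props) == 0:
            return np.zeros((0, 3))
        vox = self.props[["z", "y", "x"]].to_numpy(dtype=float)
        return vox * np.asarray(self.grid.spacing)


@dataclass
class SpotSet:
    """Sub-voxel 3D point detections for one channel.

    ``cell`` holds the assigned cell label per spot; 0 means unassigned.
    """

    coords: np.ndarray
    channel: str = "rna"
    intensity: np.ndarray | None = None
    cell: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if self.intensity is None:
            self.intensity = np.full(n, np.nan)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.cell is None:
            self.cell = np.zeros(n, dtype=int)
        self.cell = np.asarray(self.cell, dtype=int)
        if len(self.intensity) != n or len(self.cell) != n:
            raise ValueError("per-spot arrays must have equal length")

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "SpotSet":
        return SpotSet(
            self.coords.copy(), self.channel, self.intensity.copy(), self.cell.copy()
        )


@dataclass
class CellNucleusPairing:
    """Injective cell → nucleus assignment with its total cost in µm."""

    pairs: dict[int, int]
    cost: float = 0.0

    def __post_init__(self):
        self.pairs = {int(k): int(v) for k, v in self.pairs.items()}
        vals = list(self.pairs.values())
        if len(vals) != len(set(vals)):
            raise ValueError("pairing is not injective: a nucleus is used twice")

    @property
    def nucleus_to_cell(self) -> dict[int, int]:
        return {n: c for c, n in self.pairs.items()}
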