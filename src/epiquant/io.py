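"""Readers and writers for TIFF stacks, label images and CSV tables.

On-disk conventions: images and labels are (multipage) TIFF; the per-cell Z
coordinate of a 2.5D cell map lives in a two-column CSV sidecar
``(label, z)`` next to the label TIFF; tables are CSV with floats at 6
significant digits and missing values as empty fields (0 is a legal count,
so it is never used as a missing sentinel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import relabel_sequential as _skimage_relabel

from .core import ApicalCellMap, SpotSet, VolumeImage, VoxelGrid

#: stable CellTable column order by block
CELL_TABLE_ID_COLUMNS = ["cell"]


def read_stack(
    path,
    channel_axis: int | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[VolumeImage]:
    """Read a 3D or 4D TIFF stack into one :class:`VolumeImage` per channel.

    A 3D array is a single channel named ``ch0``.  A 4D array requires
    ``channel_axis`` to say which axis enumerates channels; the remaining
    axes are taken as (z, y, x) in order.
    """
    try:
        arr = np.asarray(tifffile.imread(path))
    except Exception as exc:  # pragma: no cover - delegated to tifffile
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3:
        grid = VoxelGrid(arr.shape, spacing)
        return [VolumeImage(grid, arr, "ch0")]
    if arr.ndim == 4:
        if channel_axis is None:
            raise ValueError(
                f"4D stack of shape {arr.shape} is ambiguous: pass channel_axis"
            )
        arr = np.moveaxis(arr, channel_axis, 0)
        grid = VoxelGrid(arr.shape[1:], spacing)
        return [
            VolumeImage(grid, arr[c], f"ch{c}") for c in range(arr.shape[0])
        ]
    raise ValueError(f"expected a 3D or 4D TIFF, got shape {arr.shape}")


def write_stack(images: list[VolumeImage], path) -> None:
    """Write channels as a 4D TIFF (channel axis first)."""
    data = np.stack([im.data for im in images], axis=0)
    tifffile.imwrite(path, data)


def write_volume(image: VolumeImage, path) -> None:
    tifffile.imwrite(path, image.data)


def read_labels(path) -> np.ndarray:
    """Read a 2D or 3D integer label image (0 = background)."""
    arr = np.asarray(tifffile.imread(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"label image {path} has non-integer pixel type {arr.dtype}"
        )
    return arr


def write_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError(f"labels must be integer, got {labels.dtype}")
    tifffile.imwrite(path, labels)


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..n preserving order; never applied implicitly."""
    out, _, _ = _skimage_relabel(labels)
    return out


# ---------------------------------------------------------------- cell_z CSV


def write_cell_z(cell_z: dict[int, float], path) -> None:
    df = pd.DataFrame(
        {"label": sorted(cell_z), "z": [cell_z[k] for k in sorted(cell_z)]}
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_cell_z(path) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(r.label): float(r.z) for r in df.itertuples()}


def read_apical_map(labels_path, cell_z_path, grid: VoxelGrid) -> ApicalCellMap:
    """Assemble a 2.5D cell map from a label TIFF plus its Z sidecar."""
    labels = read_labels(labels_path)
    if labels.ndim != 2:
        raise ValueError(f"expected a 2D label image, got shape {labels.shape}")
    return ApicalCellMap(labels, read_cell_z(cell_z_path), grid)


# ------------------------------------------------------------------ spots CSV


def write_spots(spots: SpotSet, path) -> None:
    df = pd.DataFrame(
        {
            "z": spots.coords[:, 0],
            "y": spots.coords[:, 1],
            "x": spots.coords[:, 2],
            "intensity": spots.intensity,
            "cell": spots.cell,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_spots(path, channel: str = "rna") -> SpotSet:
    df = pd.read_csv(path)
    if len(df) == 0:
        return SpotSet(np.zeros((0, 3)), channel)
    return SpotSet(
        df[["z", "y", "x"]].to_numpy(dtype=float),
        channel,
        df["intensity"].to_numpy(dtype=float),
        df["cell"].to_numpy(dtype=int),
    )


# ------------------------------------------------------------------ CellTable


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write the cell-by-cell table as CSV.

    One header row; floats at 6 significant digits; missing values (e.g. a
    cell without a nucleus) become empty fields.
    """
    table.to_csv(path, index=False, float_format="%.6g")


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
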