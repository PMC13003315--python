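"""Apical projection, 2D cell segmentation and lifting labels to 2.5D.

The junction channel of an epithelium approximates a bright 2D sheet bent in
3D.  The pipeline projects it to 2D, segments cells on the projection (a
classical watershed stands in for external learned segmenters, whose label
images are accepted as input instead), and then lifts the 2D labels back to
3D by estimating one apical Z position per cell from the reference surface.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .core import ApicalCellMap, VolumeImage, ZReferenceMap


def project_apical(
    junction: VolumeImage,
    method: str = "max",
    smooth_sigma: float = 1.0,
    z_range: tuple[int, int] | None = None,
) -> ZReferenceMap:
    """Project the junction channel to 2D and record the peak Z per pixel.

    Parameters
    ----------
    method : {"max", "local_peak"}
        ``max`` takes the per-pixel maximum and its argmax Z.  ``local_peak``
        Gaussian-smooths along Z (``smooth_sigma`` in µm, converted through
        dz) before the argmax and returns the *unsmoothed* intensity at that
        Z, which suppresses single-voxel noise peaks.
    z_range : (lo, hi), optional
        Inclusive Z interval to which the search is restricted.

    Argmax ties break toward the smallest Z (first occurrence).
    """
    data = junction.data
    nz = junction.grid.shape[0]
    lo, hi = 0, nz - 1
    if z_range is not None:
        lo, hi = int(z_range[0]), int(z_range[1])
        if lo < 0 or hi > nz - 1 or lo > hi:
            raise ValueError(f"empty or out-of-bounds z_range {z_range}")
    sub = data[lo : hi + 1]
    if method == "max":
        search = sub
    elif method == "local_peak":
        dz = junction.grid.spacing[0]
        search = ndi.gaussian_filter1d(
            sub.astype(float), sigma=max(smooth_sigma / dz, 1e-9), axis=0
        )
    else:
        raise ValueError(f"unknown projection method {method!r}")
    idx = np.argmax(search, axis=0)  # first occurrence on ties
    proj = np.take_along_axis(sub, idx[None], axis=0)[0]
    return ZReferenceMap(idx.astype(float) + lo, proj, junction.grid)


def segment_cells_2d(
    zref: ZReferenceMap,
    seed_h: float,
    min_area: float = 0.0,
    max_area: float = np.inf,
) -> np.ndarray:
    """Seeded watershed of the junction projection into cell labels.

    Seeds are the connected minima of the h-minima transform (depth
    ``seed_h``, in intensity units) of the projection; watershed ridges
    (the junctions) become background 0.  Regions with apical area outside
    ``[min_area, max_area]`` (µm²) are removed.
    """
    proj = np.asarray(zref.projection, dtype=float)
    if np.ptp(proj) == 0:
        raise ValueError("projection is constant: no seeds (decrease seed_h)")
    seeds = h_minima(proj, seed_h)
    markers, n_seeds = ndi.label(seeds)
    if n_seeds == 0:
        raise ValueError("no watershed seeds found: decrease seed_h")
    labels = watershed(proj, markers, watershed_line=True)
    labels = labels.astype(np.int32)
    _, dy, dx = zref.grid.spacing
    px_area = dy * dx
    counts = np.bincount(labels.ravel())
    bad = np.zeros(len(counts), dtype=bool)
    areas = counts * px_area
    bad[1:] = (areas[1:] < min_area) | (areas[1:] > max_area)
    labels[bad[labels]] = 0
    return labels


def merge_cells(labels2d: np.ndarray, a: int, b: int) -> np.ndarray:
    """Merge cells ``a`` and ``b``; the merged cell keeps the smaller label."""
    present = set(np.unique(labels2d))
    for lab in (a, b):
        if lab not in present or lab == 0:
            raise ValueError(f"label {lab} not present")
    out = labels2d.copy()
    keep, drop = min(a, b), max(a, b)
    out[out == drop] = keep
    return out


def delete_cell(labels2d: np.ndarray, a: int) -> np.ndarray:
    """Remove cell ``a`` (its region becomes background)."""
    if a == 0 or a not in set(np.unique(labels2d)):
        raise ValueError(f"label {a} not present")
    out = labels2d.copy()
    out[out == a] = 0
    return out


def _boundary_band(mask: np.ndarray) -> np.ndarray:
    """One-pixel-dilated boundary of a binary region, clipped to the image."""
    boundary = mask & ~ndi.binary_erosion(mask, border_value=0)
    return ndi.binary_dilation(boundary)


def estimate_cell_z(
    labels2d: np.ndarray, zref: ZReferenceMap, stat: str = "median"
) -> ApicalCellMap:
    """Lift 2D labels to 2.5D: one apical Z per cell from the reference map.

    The Z statistic (median or mean) is taken over a one-pixel-dilated band
    around each cell's boundary — only the junctions carry apical signal, so
    the boundary band, not the interior, holds the informative Z values.
    The result is clamped to the stack's Z extent.
    """
    if labels2d.shape != zref.zmap.shape:
        raise ValueError("labels2d and zmap shapes differ")
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    reduce = np.median if stat == "median" else np.mean
    nz = zref.grid.shape[0]
    cell_z: dict[int, float] = {}
    objects = ndi.find_objects(labels2d)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad the bounding box so the dilated band is not clipped
        sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, labels2d.shape)
        )
        mask = labels2d[sl] == lab
        band = _boundary_band(mask)
        if not band.any():  # pragma: no cover - nonempty regions always band
            raise RuntimeError(f"cell {lab} has an empty boundary band")
        z = float(reduce(zref.zmap[sl][band]))
        cell_z[lab] = float(np.clip(z, 0, nz - 1))
    return ApicalCellMap(labels2d, cell_z, zref.grid)
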