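"""3D nucleus segmentation (classical blob detector) and filtering.

The detector is a scale-matched, anisotropy-aware Laplacian-of-Gaussian:
for a ball of radius r the LoG response at sigma = r/sqrt(3) is extremal,
so each axis uses sigma = radius / sqrt(3) / spacing.  Maxima of the
response seed a watershed on the inverted smoothed intensity restricted to
an Otsu foreground mask, which splits touching nuclei.  External 3D label
volumes (e.g. from learned segmenters) can bypass this and go straight to
:func:`filter_nuclei`.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .core import NucleiLabels, VolumeImage

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _split_disconnected(labels: np.ndarray) -> np.ndarray:
    """Give each 26-connected component of every label its own label."""
    out = labels.copy()
    next_label = int(labels.max()) + 1
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        comp, n = ndi.label(labels[sl] == lab, structure=_CONN26)
        for k in range(2, n + 1):
            out[sl][comp == k] = next_label
            next_label += 1
    return out


def segment_nuclei(
    nuclear: VolumeImage, radius: float, threshold="auto"
) -> NucleiLabels:
    """Segment blob-like nuclei of approximate radius ``radius`` (µm).

    ``threshold`` applies to the LoG response; ``"auto"`` uses Otsu on the
    response.  An image with no foreground yields an empty result, not an
    error.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    data = nuclear.data.astype(float)
    grid = nuclear.grid
    empty = NucleiLabels.from_labels(
        np.zeros(grid.shape, dtype=np.int32), grid, data
    )
    if np.ptp(data) == 0:
        return empty
    sigma = tuple(radius / np.sqrt(3.0) / s for s in grid.spacing)
    smoothed = ndi.gaussian_filter(data, sigma)
    resp = -ndi.gaussian_laplace(data, sigma)
    fg = smoothed > threshold_otsu(smoothed)
    if not fg.any():
        return empty
    thr = threshold_otsu(resp) if threshold == "auto" else float(threshold)
    cand = (resp == ndi.maximum_filter(resp, size=3)) & (resp > thr) & fg
    coords = np.argwhere(cand)
    if len(coords) == 0:
        return empty
    # non-maximum suppression at the nucleus scale so one nucleus gets one seed
    responses = resp[tuple(coords.T)]
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -responses))
    coords = coords[order]
    pos_um = coords * np.asarray(grid.spacing)
    kept: list[int] = []
    tree_pts: list[np.ndarray] = []
    for i in range(len(coords)):
        if tree_pts:
            d = cKDTree(np.asarray(tree_pts)).query(pos_um[i])[0]
            if d < radius:
                continue
        kept.append(i)
        tree_pts.append(pos_um[i])
    markers = np.zeros(grid.shape, dtype=np.int32)
    for lab, i in enumerate(kept, start=1):
        markers[tuple(coords[i])] = lab
    labels = watershed(smoothed.max() - smoothed, markers, mask=fg)
    labels = _split_disconnected(labels.astype(np.int32))
    return NucleiLabels.from_labels(labels, grid, data)


def filter_nuclei(
    nuclei: NucleiLabels,
    min_volume: float = 0.0,
    max_volume: float = np.inf,
    z_keep: tuple[float, float] | None = None,
) -> NucleiLabels:
    """Remove nuclei outside volume bounds (µm³) or with centroid Z outside
    ``z_keep`` (voxel units).  Idempotent; an empty result is legal."""
    if min_volume > max_volume:
        raise ValueError("min_volume must be <= max_volume")
    props = nuclei.props
    keep = (props["volume_um3"] >= min_volume) & (props["volume_um3"] <= max_volume)
    if z_keep is not None:
        keep &= (props["z"] >= z_keep[0]) & (props["z"] <= z_keep[1])
    kept_labels = set(int(v) for v in props.loc[keep, "label"])
    labels3d = nuclei.labels3d.copy()
    drop_mask = ~np.isin(labels3d, list(kept_labels) + [0])
    labels3d[drop_mask] = 0
    new_props = props.loc[keep].reset_index(drop=True)
    return NucleiLabels(labels3d, new_props, nuclei.grid)
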