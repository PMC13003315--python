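"""Per-cell features: morphology, intensities, classes, counts, clustering.

Everything measured by the pipeline is joined into one cell-by-cell table
(one row per apical cell label) for downstream analysis.  Missing values
(no paired nucleus, no class call) propagate as missing — 0 is a legal
count and is never used as a sentinel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .assign import AssignmentResult
from .core import ApicalCellMap, CellNucleusPairing, NucleiLabels, VolumeImage


def _prism_z_range(cell_z: float, depth: float, dz: float, nz: int) -> tuple[int, int]:
    """Integer Z planes z with cell_z <= z <= cell_z + depth/dz, clipped."""
    lo = int(np.ceil(cell_z - 1e-9))
    hi = int(np.floor(cell_z + depth / dz + 1e-9))
    return max(lo, 0), min(hi, nz - 1)


def measure_cytoplasmic_intensity(
    channel: VolumeImage,
    cells: ApicalCellMap,
    depth: float,
    exclude_nucleus: NucleiLabels | None = None,
) -> pd.DataFrame:
    """Mean and sum intensity in a prism of ``depth`` µm below each cell's apex.

    The measurement region of cell c is its 2D apical footprint extruded
    from z = cell_z[c] down ``depth`` µm, clipped to the volume.  When
    ``exclude_nucleus`` is given, nucleus voxels are removed from the
    region.  An empty region yields missing values.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    dz = channel.grid.spacing[0]
    nz = channel.grid.shape[0]
    data = channel.data
    rows = []
    for c in cells.labels:
        mask2d = cells.labels2d == c
        zlo, zhi = _prism_z_range(cells.cell_z[c], depth, dz, nz)
        if zlo > zhi or not mask2d.any():
            rows.append((c, np.nan, np.nan))
            continue
        block = data[zlo : zhi + 1, mask2d]
        if exclude_nucleus is not None:
            nucblock = exclude_nucleus.labels3d[zlo : zhi + 1, mask2d]
            block = block[nucblock == 0]
        if block.size == 0:
            rows.append((c, np.nan, np.nan))
            continue
        rows.append((c, float(np.mean(block)), float(np.sum(block))))
    return pd.DataFrame(rows, columns=["cell", "mean", "sum"]).set_index("cell")


def measure_nuclear_intensity(
    channel: VolumeImage, nuclei: NucleiLabels
) -> pd.DataFrame:
    """Mean and sum intensity over each nucleus's voxels."""
    rows = []
    data = channel.data
    lab = nuclei.labels3d
    for n in nuclei.labels:
        vals = data[lab == n]
        rows.append((n, float(np.mean(vals)), float(np.sum(vals))))
    return pd.DataFrame(rows, columns=["nucleus", "mean", "sum"]).set_index("nucleus")


def crofton_free_perimeter_um(mask: np.ndarray, dy: float, dx: float) -> float:
    """Boundary-step (crack) perimeter: count boundary edges × pixel pitch.

    Horizontal steps (along x) have length dx, vertical steps length dy; a
    10×10 square at 0.2 µm pitch measures 40 × 0.2 = 8 µm.
    """
    padded = np.pad(mask, 1)
    # transitions along y contribute edges of length dx, and vice versa
    steps_y = np.sum(padded[1:, :] != padded[:-1, :])
    steps_x = np.sum(padded[:, 1:] != padded[:, :-1])
    return float(steps_y * dx + steps_x * dy)


def neighbor_counts(labels2d: np.ndarray) -> dict[int, int]:
    """Number of distinct cells sharing a boundary with each cell.

    Cells separated by a one-pixel watershed ridge still count as neighbours
    (adjacency is evaluated across up to two background pixels).
    """
    pairs: set[tuple[int, int]] = set()
    for axis in range(2):
        for gap in (1, 2, 3):
            a = labels2d.take(range(labels2d.shape[axis] - gap), axis=axis)
            b = labels2d.take(range(gap, labels2d.shape[axis]), axis=axis)
            touch = (a > 0) & (b > 0) & (a != b)
            for u, v in zip(a[touch].ravel(), b[touch].ravel()):
                pairs.add((min(int(u), int(v)), max(int(u), int(v))))
    counts: dict[int, int] = {}
    for u, v in pairs:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    return counts


def morphometrics(
    cells: ApicalCellMap,
    nuclei: NucleiLabels | None = None,
    pairing: CellNucleusPairing | None = None,
) -> pd.DataFrame:
    """Per-cell morphology records.

    Apical area (pixel count × dy·dx, µm²), crack perimeter (µm),
    circularity 4πA/P², centroid in µm (z = cell_z·dz), neighbour count,
    and nucleus volume/centroid when paired.
    """
    dz, dy, dx = cells.grid.spacing
    nbrs = neighbor_counts(cells.labels2d)
    nuc_props = (
        nuclei.props.set_index("label") if nuclei is not None else None
    )
    pairs = pairing.pairs if pairing is not None else {}
    rows = []
    for rp in regionprops(cells.labels2d):
        c = int(rp.label)
        area = rp.area * dy * dx
        perim = crofton_free_perimeter_um(cells.labels2d == c, dy, dx)
        circ = 4 * np.pi * area / perim**2 if perim > 0 else np.nan
        cy, cx = rp.centroid
        rec = {
            "cell": c,
            "centroid_x_um": cx * dx,
            "centroid_y_um": cy * dy,
            "centroid_z_um": cells.cell_z[c] * dz,
            "area_um2": area,
            "perimeter_um": perim,
            "circularity": circ,
            "n_neighbors": nbrs.get(c, 0),
            "nucleus": np.nan,
            "nucleus_volume_um3": np.nan,
            "nucleus_z_um": np.nan,
            "nucleus_y_um": np.nan,
            "nucleus_x_um": np.nan,
        }
        n = pairs.get(c)
        if n is not None and nuc_props is not None and n in nuc_props.index:
            p = nuc_props.loc[n]
            rec.update(
                nucleus=n,
                nucleus_volume_um3=float(p["volume_um3"]),
                nucleus_z_um=float(p["z"]) * dz,
                nucleus_y_um=float(p["y"]) * dy,
                nucleus_x_um=float(p["x"]) * dx,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def prefill_classification(
    values: pd.Series,
    method: str = "otsu",
    threshold: float | None = None,
    name: str = "class",
) -> pd.Series:
    """Binary positive/negative pre-fill of a per-cell class from a value.

    ``otsu`` derives the threshold from the 256-bin histogram of the values;
    ``threshold`` uses the given cut.  Values above the threshold are
    ``positive``.
    """
    values = pd.Series(values).astype(float)
    if method == "otsu":
        if len(values) < 2:
            raise ValueError("otsu pre-fill needs at least 2 cells")
        if float(values.max()) == float(values.min()):
            raise ValueError(
                "constant values: otsu undefined, set a manual threshold"
            )
        thr = float(threshold_otsu(values.to_numpy(), nbins=256))
    elif method == "threshold":
        if threshold is None:
            raise ValueError("method='threshold' requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.Series(
        np.where(values > thr, "positive", "negative"), index=values.index, name=name
    )
    return out


def build_cell_table(
    cells: ApicalCellMap,
    nuclei: NucleiLabels | None = None,
    pairing: CellNucleusPairing | None = None,
    assignments: list[AssignmentResult] | None = None,
    cytoplasmic: dict[str, pd.DataFrame] | None = None,
    nuclear: dict[str, pd.DataFrame] | None = None,
    classes: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Join all per-cell measurements into the unified cell-by-cell table.

    One row per cell label; per-RNA-channel spot counts come from each
    assignment result (column ``count_<channel>``); intensity blocks are
    keyed by channel name; missing blocks give missing fields, never
    dropped rows.
    """
    table = morphometrics(cells, nuclei, pairing)
    valid = set(cells.labels)
    for res in assignments or []:
        bad = set(int(c) for c in np.unique(res.spots.cell)) - valid - {0}
        if bad:
            raise ValueError(
                f"assignment {res.strategy!r} refers to unknown cells {sorted(bad)}"
            )
        col = f"count_{res.spots.channel}"
        counts = pd.Series(res.spots.cell).value_counts()
        table[col] = [int(counts.get(c, 0)) for c in table["cell"]]
    for ch, block in (cytoplasmic or {}).items():
        table[f"cyto_mean_{ch}"] = [
            block["mean"].get(c, np.nan) for c in table["cell"]
        ]
        table[f"cyto_sum_{ch}"] = [
            block["sum"].get(c, np.nan) for c in table["cell"]
        ]
    for ch, block in (nuclear or {}).items():
        nuc_of = pairing.pairs if pairing is not None else {}
        table[f"nuc_mean_{ch}"] = [
            block["mean"].get(nuc_of.get(c), np.nan) for c in table["cell"]
        ]
        table[f"nuc_sum_{ch}"] = [
            block["sum"].get(nuc_of.get(c), np.nan) for c in table["cell"]
        ]
    for name, col in (classes or {}).items():
        bad = set(int(c) for c in col.index) - valid
        if bad:
            raise ValueError(f"class {name!r} refers to unknown cells {sorted(bad)}")
        table[f"class_{name}"] = [col.get(c, np.nan) for c in table["cell"]]
    return table


def cluster_cells(
    table: pd.DataFrame,
    features: list[str],
    k: int,
    linkage: str = "ward",
) -> pd.Series:
    """Agglomerative clustering of cells on z-scored feature columns.

    Rows with missing values in the chosen columns are excluded and get an
    empty cluster id; the rest are standardised per column, clustered with
    Euclidean distance and the requested linkage, and cut into ``k``
    clusters labelled 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    X = table[features].astype(float)
    usable = ~X.isna().any(axis=1)
    n_use = int(usable.sum())
    if k > n_use:
        raise ValueError(f"k={k} exceeds the {n_use} usable rows")
    ids = pd.Series(np.nan, index=table.index, name="cluster")
    Xu = X.loc[usable].to_numpy()
    sd = Xu.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Xu - Xu.mean(axis=0)) / sd
    if k == 1 or n_use == 1:
        ids.loc[usable] = 1
        return ids
    tree = scipy_linkage(Z, method=linkage, metric="euclidean")
    ids.loc[usable] = fcluster(tree, t=k, criterion="maxclust")
    return ids
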