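"""Assigning 3D RNA spots to cells defined only by their 2D apical areas.

Cell contours are marked apically, so a spot deep in the tissue has no
enclosing 3D cell boundary.  Five strategies bridge the gap:

* ``projection`` — drop the spot along Z onto the 2D apical labels;
* ``nearest_nucleus`` — nearest segmented nucleus (surface or centroid
  distance in µm), mapped to its paired cell;
* ``mixed`` — projection for spots shallower than a depth cut below their
  apical plane, nearest nucleus for deeper ones;
* ``hull`` — containment in a per-cell convex hull spanned by the apical
  boundary polygon at the cell's Z plus the paired nucleus's extrema;
* ``iterative`` — unassigned spots adopt the strict-majority cell of their
  k nearest already-assigned spots, repeated to a fixed point.

All distances are physical (µm); voxel distances would be distorted by Z
anisotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .core import ApicalCellMap, CellNucleusPairing, NucleiLabels, SpotSet

_TIE_RTOL = 1e-9


@dataclass
class AssignmentResult:
    """A SpotSet with the cell field filled by one strategy."""

    spots: SpotSet
    strategy: str

    @property
    def unassigned_count(self) -> int:
        return int(np.sum(self.spots.cell == 0))


def _rounded_pixels(spots: SpotSet, shape2d: tuple[int, int]) -> np.ndarray:
    yx = np.round(spots.coords[:, 1:]).astype(int)
    yx[:, 0] = np.clip(yx[:, 0], 0, shape2d[0] - 1)
    yx[:, 1] = np.clip(yx[:, 1], 0, shape2d[1] - 1)
    return yx


def assign_projection(spots: SpotSet, cells: ApicalCellMap) -> AssignmentResult:
    """Z-projection: each spot takes the apical label under its (y, x)."""
    out = spots.copy()
    if len(out):
        yx = _rounded_pixels(out, cells.labels2d.shape)
        out.cell = cells.labels2d[yx[:, 0], yx[:, 1]].astype(int)
    return AssignmentResult(out, "projection")


def _nucleus_surface_points(nuclei: NucleiLabels) -> tuple[np.ndarray, np.ndarray]:
    """Voxel coordinates and labels of nucleus surface voxels.

    Surface = labeled voxel with a 6-neighbour of different value, or on the
    volume border.
    """
    lab = nuclei.labels3d
    surface = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = lab[tuple(lo)] != lab[tuple(hi)]
        surface[tuple(lo)] |= diff
        surface[tuple(hi)] |= diff
        edge = [slice(None)] * 3
        edge[axis] = slice(0, 1)
        surface[tuple(edge)] = True
        edge[axis] = slice(-1, None)
        surface[tuple(edge)] = True
    surface &= lab > 0
    coords = np.argwhere(surface)
    return coords, lab[tuple(coords.T)]


def assign_nearest_nucleus(
    spots: SpotSet,
    nuclei: NucleiLabels,
    pairing: CellNucleusPairing,
    nucleus_distance: str = "surface",
) -> AssignmentResult:
    """Nearest-nucleus assignment in anisotropy-scaled µm distance.

    With ``nucleus_distance="surface"`` a spot whose voxel lies inside a
    nucleus is at distance 0 from it, otherwise the distance to the nearest
    labeled voxel counts; ``"centroid"`` uses nucleus centroids.  Equidistant
    nuclei break toward the lower nucleus label.  Nuclei without a paired
    cell leave their spots unassigned.
    """
    out = spots.copy()
    out.cell = np.zeros(len(out), dtype=int)
    if len(out) == 0 or len(nuclei.props) == 0:
        return AssignmentResult(out, "nearest_nucleus")
    spacing = np.asarray(nuclei.grid.spacing)
    spots_um = out.coords * spacing
    n2c = pairing.nucleus_to_cell

    nearest = np.zeros(len(out), dtype=int)
    if nucleus_distance == "centroid":
        pts = nuclei.centroids_um()
        pt_labels = np.asarray(nuclei.labels)
    elif nucleus_distance == "surface":
        coords, pt_labels = _nucleus_surface_points(nuclei)
        pts = coords * spacing
        # inside a nucleus -> that nucleus at distance 0
        vox = np.clip(
            np.round(out.coords).astype(int), 0, np.asarray(nuclei.grid.shape) - 1
        )
        inside = nuclei.labels3d[tuple(vox.T)]
        nearest[inside > 0] = inside[inside > 0]
    else:
        raise ValueError(f"unknown nucleus_distance {nucleus_distance!r}")

    todo = np.flatnonzero(nearest == 0)
    if len(todo):
        tree = cKDTree(pts)
        k = min(8, len(pts))
        dists, idx = tree.query(spots_um[todo], k=k)
        dists = np.atleast_2d(dists)
        idx = np.atleast_2d(idx)
        for row, i in enumerate(todo):
            dmin = dists[row, 0]
            tie = dists[row] <= dmin * (1 + _TIE_RTOL) + 1e-12
            nearest[i] = int(np.min(pt_labels[idx[row][tie]]))
    out.cell = np.array([n2c.get(int(n), 0) for n in nearest], dtype=int)
    return AssignmentResult(out, "nearest_nucleus")


def spot_depths_um(spots: SpotSet, cells: ApicalCellMap) -> np.ndarray:
    """Depth of each spot below the apical plane of its projection cell (µm).

    Spots projecting onto background get depth +inf.
    """
    dz = cells.grid.spacing[0]
    depth = np.full(len(spots), np.inf)
    if len(spots) == 0:
        return depth
    yx = _rounded_pixels(spots, cells.labels2d.shape)
    proj = cells.labels2d[yx[:, 0], yx[:, 1]]
    hit = proj > 0
    cz = np.array([cells.cell_z[int(c)] for c in proj[hit]])
    depth[hit] = (spots.coords[hit, 0] - cz) * dz
    return depth


def assign_mixed(
    spots: SpotSet,
    cells: ApicalCellMap,
    nuclei: NucleiLabels,
    pairing: CellNucleusPairing,
    depth_cut: float,
    nucleus_distance: str = "surface",
) -> AssignmentResult:
    """Projection for shallow spots, nearest nucleus for deep ones.

    A spot at depth <= ``depth_cut`` µm below its projection cell's apical
    plane keeps the projection assignment; deeper spots (and spots over
    background) use the nearest-nucleus assignment.
    """
    if depth_cut < 0:
        raise ValueError("depth_cut must be >= 0")
    proj = assign_projection(spots, cells)
    near = assign_nearest_nucleus(spots, nuclei, pairing, nucleus_distance)
    depth = spot_depths_um(spots, cells)
    out = spots.copy()
    shallow = depth <= depth_cut
    out.cell = np.where(shallow, proj.spots.cell, near.spots.cell)
    return AssignmentResult(out, "mixed")


def cell_hull_points_um(
    cells: ApicalCellMap,
    nuclei: NucleiLabels,
    pairing: CellNucleusPairing,
    cell: int,
) -> np.ndarray:
    """Hull support points of one cell in µm (z, y, x).

    The cell's 2D boundary pixels placed at z = cell_z, plus the six
    axis-extreme voxels of the paired nucleus.
    """
    spacing = np.asarray(cells.grid.spacing)
    mask = cells.labels2d == cell
    boundary = mask & ~ndi.binary_erosion(mask, border_value=0)
    yx = np.argwhere(boundary)
    apical = np.column_stack([np.full(len(yx), cells.cell_z[cell]), yx])
    pts = [apical]
    nuc = pairing.pairs.get(cell)
    if nuc is not None:
        vox = np.argwhere(nuclei.labels3d == nuc)
        if len(vox):
            extrema = []
            for axis in range(3):
                extrema.append(vox[np.argmin(vox[:, axis])])
                extrema.append(vox[np.argmax(vox[:, axis])])
            pts.append(np.asarray(extrema, dtype=float))
    return np.vstack(pts) * spacing


def assign_hull(
    spots: SpotSet,
    cells: ApicalCellMap,
    nuclei: NucleiLabels,
    pairing: CellNucleusPairing,
    pad: float = 0.5,
) -> AssignmentResult:
    """Containment in per-cell convex hulls, dilated facet-wise by ``pad`` µm.

    A spot inside exactly one hull takes that cell; inside several, the cell
    with the nearest hull centroid; inside none, unassigned.  A cell with a
    degenerate (coplanar) support set — e.g. no paired nucleus — assigns
    nothing and a warning is logged.
    """
    out = spots.copy()
    out.cell = np.zeros(len(out), dtype=int)
    if len(out) == 0:
        return AssignmentResult(out, "hull")
    spacing = np.asarray(cells.grid.spacing)
    spots_um = out.coords * spacing
    candidates: list[tuple[int, np.ndarray, np.ndarray]] = []
    for c in cells.labels:
        pts = cell_hull_points_um(cells, nuclei, pairing, c)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            warnings.warn(f"cell {c}: degenerate hull support, assigns nothing")
            continue
        # facet half-spaces: normal·x + offset <= 0 inside; pad dilates facets
        inside = (spots_um @ hull.equations[:, :3].T + hull.equations[:, 3]).max(
            axis=1
        ) <= pad
        centroid = pts[hull.vertices].mean(axis=0)
        candidates.append((c, inside, centroid))
    if not candidates:
        return AssignmentResult(out, "hull")
    inside_mat = np.stack([ins for _, ins, _ in candidates])
    labels = np.array([c for c, _, _ in candidates])
    centroids = np.stack([cen for _, _, cen in candidates])
    n_inside = inside_mat.sum(axis=0)
    for i in np.flatnonzero(n_inside == 1):
        out.cell[i] = labels[np.argmax(inside_mat[:, i])]
    for i in np.flatnonzero(n_inside > 1):
        cand = np.flatnonzero(inside_mat[:, i])
        d = np.linalg.norm(centroids[cand] - spots_um[i], axis=1)
        out.cell[i] = labels[cand[np.argmin(d)]]
    return AssignmentResult(out, "hull")


def assign_iterative(
    initial: AssignmentResult,
    spacing: tuple[float, float, float],
    k: int = 5,
    max_iter: int = 10,
) -> AssignmentResult:
    """Propagate assignments from a base strategy to unassigned spots.

    Each round, every unassigned spot looks at its ``k`` nearest assigned
    spots (µm distance via ``spacing``) and adopts their majority cell if
    that majority is strict (unique plurality); updates are synchronous and
    previously assigned spots never change, so the unassigned count is
    non-increasing and the process terminates.  With no assigned spots at
    all the input is returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = initial.spots.copy()
    name = f"iterative({initial.strategy})"
    if len(out) == 0 or int(np.sum(out.cell > 0)) == 0:
        return AssignmentResult(out, name)
    coords = out.coords * np.asarray(spacing, dtype=float)
    for _ in range(max_iter):
        assigned = np.flatnonzero(out.cell > 0)
        todo = np.flatnonzero(out.cell == 0)
        if len(todo) == 0:
            break
        tree = cKDTree(coords[assigned])
        kk = min(k, len(assigned))
        _, idx = tree.query(coords[todo], k=kk)
        idx = np.atleast_2d(idx.reshape(len(todo), kk))
        new = np.zeros(len(todo), dtype=int)
        for row in range(len(todo)):
            votes = out.cell[assigned[idx[row]]]
            cells_, counts = np.unique(votes, return_counts=True)
            top = np.argmax(counts)
            if np.sum(counts == counts[top]) == 1:
                new[row] = cells_[top]
        if not new.any():
            break
        out.cell[todo] = new
    return AssignmentResult(out, name)


def compare_strategies(
    results: list[AssignmentResult], truth: SpotSet | None = None
) -> pd.DataFrame:
    """Pairwise agreement matrix plus per-strategy summary.

    Agreement between two strategies is the fraction of spots assigned
    (cell > 0) by *both* on which they give the same cell.  The returned
    frame has one row per strategy: its agreement with every strategy, its
    unassigned fraction and, when per-spot truth labels are given, its
    accuracy over spots it assigned that have a nonzero truth cell.
    """
    if not results:
        raise ValueError("no results to compare")
    n = len(results[0].spots)
    for r in results:
        if len(r.spots) != n:
            raise ValueError("all results must cover the same SpotSet")
    names = [r.strategy for r in results]
    agree = np.full((len(results), len(results)), np.nan)
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            both = (a.spots.cell > 0) & (b.spots.cell > 0)
            if both.any():
                agree[i, j] = float(
                    np.mean(a.spots.cell[both] == b.spots.cell[both])
                )
    df = pd.DataFrame(agree, index=names, columns=names)
    df["unassigned_fraction"] = [
        r.unassigned_count / n if n else 0.0 for r in results
    ]
    if truth is not None:
        if len(truth) != n:
            raise ValueError("truth must cover the same SpotSet")
        acc = []
        for r in results:
            ok = (r.spots.cell > 0) & (truth.cell > 0)
            acc.append(
                float(np.mean(r.spots.cell[ok] == truth.cell[ok]))
                if ok.any()
                else np.nan
            )
        df["accuracy"] = acc
    return df


STRATEGIES = ("projection", "nearest_nucleus", "mixed", "hull", "iterative")
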