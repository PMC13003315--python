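"""Minimum-cost bipartite pairing of nuclei with apical cell footprints.

In a 2.5D epithelium each cell is an apical polygon with a Z position while
its nucleus sits basally at variable depth.  The pairing cost between a
cell and a nucleus is the Euclidean distance in µm between the cell's
apical anchor (2D centroid placed at the cell's Z) and the nucleus
centroid, with the lateral (y, x) terms at full weight and the axial term
down-weighted by ``wz`` (default 0.25) because the apex-to-nucleus depth is
variable and uninformative.  The Hungarian algorithm returns the matching
that pairs as many admissible (cost <= max_dist) cell/nucleus pairs as
possible at minimum total cost; excess cells or nuclei stay unmatched.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.measure import regionprops

from .core import ApicalCellMap, CellNucleusPairing, NucleiLabels


def cell_anchors_um(cells: ApicalCellMap) -> dict[int, np.ndarray]:
    """Apical anchor of each cell in µm: 2D centroid at the cell's Z."""
    dz, dy, dx = cells.grid.spacing
    anchors = {}
    for rp in regionprops(cells.labels2d):
        cy, cx = rp.centroid
        lab = int(rp.label)
        anchors[lab] = np.array([cells.cell_z[lab] * dz, cy * dy, cx * dx])
    return anchors


def pairing_cost_matrix(
    cells: ApicalCellMap, nuclei: NucleiLabels, wz: float = 0.25
) -> tuple[np.ndarray, list[int], list[int]]:
    """Cost matrix (cells × nuclei) in µm plus the label orderings."""
    anchors = cell_anchors_um(cells)
    cell_labels = sorted(anchors)
    nuc_labels = nuclei.labels
    nuc_pos = nuclei.centroids_um()
    C = np.zeros((len(cell_labels), len(nuc_labels)))
    for i, c in enumerate(cell_labels):
        d = nuc_pos - anchors[c]
        C[i] = np.sqrt((wz * d[:, 0]) ** 2 + d[:, 1] ** 2 + d[:, 2] ** 2)
    return C, cell_labels, nuc_labels


def match_min_cost(
    C: np.ndarray, max_dist: float
) -> tuple[list[tuple[int, int]], float]:
    """Maximum-cardinality minimum-cost matching on a rectangular cost matrix.

    Entries above ``max_dist`` are inadmissible.  Among matchings with the
    largest number of admissible pairs, the one with minimum total cost is
    returned as (row, col) index pairs plus that cost.  Implemented by
    giving every inadmissible entry one uniform large cost — the Hungarian
    solver then avoids inadmissible pairs whenever possible and minimises
    the admissible cost among equals — and dropping inadmissible pairs from
    the solution.
    """
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        return [], 0.0
    big = (min(C.shape) + 1) * max(max_dist, 1.0) * 1e3
    Cg = np.where(C <= max_dist, C, big)
    rows, cols = linear_sum_assignment(Cg)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if C[r, c] <= max_dist]
    total = float(sum(C[r, c] for r, c in pairs))
    return pairs, total


def pair_nuclei_to_cells(
    cells: ApicalCellMap,
    nuclei: NucleiLabels,
    max_dist: float,
    wz: float = 0.25,
) -> CellNucleusPairing:
    """Optimal cell ↔ nucleus matching under a distance gate.

    Pairs with cost above ``max_dist`` (µm) are forbidden; excess cells or
    nuclei stay unmatched.  See :func:`match_min_cost` for the objective.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    C, cell_labels, nuc_labels = pairing_cost_matrix(cells, nuclei, wz)
    idx_pairs, total = match_min_cost(C, max_dist)
    pairs = {cell_labels[r]: nuc_labels[c] for r, c in idx_pairs}
    return CellNucleusPairing(pairs, total)


def write_pairing(pairing: CellNucleusPairing, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "cell": sorted(pairing.pairs),
            "nucleus": [pairing.pairs[c] for c in sorted(pairing.pairs)],
        }
    )
    df.to_csv(path, index=False)


def read_pairing(path) -> CellNucleusPairing:
    import pandas as pd

    df = pd.read_csv(path)
    return CellNucleusPairing(
        {int(r.cell): int(r.nucleus) for r in df.itertuples()}, float("nan")
    )
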