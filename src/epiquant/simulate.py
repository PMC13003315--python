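"""Synthetic 3D epithelium generator with complete ground truth.

The generator emulates the data the pipeline targets: a curved apical sheet
of polygonal cells whose junctions fluoresce, one ellipsoidal nucleus per
cell offset basally below the apex, an optional cytoplasmic reporter (IHC)
channel with two intensity populations, and per-cell smFISH transcripts
drawn from a two-population Poisson model and rendered as diffraction-
limited 3D Gaussians, all under Gaussian read noise and optional shot
noise with anisotropic Z sampling.

Cells are modelled perpendicular to the apical surface: nuclei and
transcripts are displaced from the apex along the local inward surface
normal, so on a curved dome the basal content of a cell is laterally offset
from its 2D apical footprint — the geometry that makes pure Z-projection
assignment fail and motivates the alternative strategies.  A flat sheet
(curvature 0) is the vertical-prism limit where all strategies coincide.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .core import (
    ApicalCellMap,
    NucleiLabels,
    SpotSet,
    VolumeImage,
    VoxelGrid,
)


@dataclass
class TissueParams:
    """Generation parameters; defaults are the desk-scale study conditions."""

    shape: tuple[int, int, int] = (40, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 0.2, 0.2)
    n_cells: int = 50
    curvature: float = 0.0  # dome peak height in µm; 0 = flat
    junction_thickness: float = 0.6  # µm
    junction_intensity: float = 300.0
    nucleus_intensity: float = 200.0
    spot_amplitude: float = 100.0
    background: float = 100.0
    nucleus_radii: tuple[float, float] = (2.5, 2.2)  # (axial, lateral) µm
    nucleus_depth: float = 4.0  # µm below the apex, along the surface normal
    nucleus_jitter_frac: float = 0.2  # lateral offset cap, fraction of inradius
    n_rna_channels: int = 1
    lambda_high: float = 30.0
    lambda_low: float = 3.0
    frac_high: float = 0.5
    spot_sigma: tuple[float, float] = (0.75, 0.25)  # (axial, lateral) µm
    ihc_channel: bool = True
    mixed_channel: bool = False  # co-stained junction+nuclei channel
    ihc_high: float = 150.0
    ihc_low: float = 30.0
    cyto_depth: float = 4.0  # µm, IHC reporter depth below the apex
    gaussian_noise_sd: float = 20.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.frac_high <= 1):
            raise ValueError("frac_high must be in [0, 1]")
        for name in (
            "junction_intensity",
            "nucleus_intensity",
            "spot_amplitude",
            "background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.spacing)


@dataclass
class TissueBundle:
    """A generated tissue: channels plus complete ground truth."""

    params: TissueParams
    channels: dict[str, VolumeImage]
    truth_cells: ApicalCellMap
    truth_nuclei: NucleiLabels
    truth_spots: dict[str, SpotSet]
    truth_classes: dict[int, str]
    zstar: np.ndarray  # true apical surface, Z index per (y, x)
    truth_pairing: dict[int, int] = field(default_factory=dict)
    #: noise-free signal renders ("junction", "nuclei"), for unmixing checks
    truth_components: dict[str, np.ndarray] = field(default_factory=dict)


# --------------------------------------------------------------- tessellation


def _voronoi_labels(
    rng: np.random.Generator, ny: int, nx: int, n_cells: int
) -> np.ndarray:
    """Raster Voronoi labels 1..n from random seeds after one Lloyd step."""
    pts = rng.uniform((0, 0), (ny, nx), size=(n_cells, 2))
    yy, xx = np.mgrid[0:ny, 0:nx]
    pix = np.column_stack([yy.ravel(), xx.ravel()])
    lab = cKDTree(pts).query(pix)[1]
    # one Lloyd relaxation step: move each seed to its region's centroid
    cy = ndi.mean(pix[:, 0], labels=lab, index=np.arange(n_cells))
    cx = ndi.mean(pix[:, 1], labels=lab, index=np.arange(n_cells))
    pts = np.column_stack([cy, cx])
    lab = cKDTree(pts).query(pix)[1]
    return (lab + 1).reshape(ny, nx).astype(np.int32)


def _edge_mask(labels2d: np.ndarray) -> np.ndarray:
    """Pixels on a boundary between two different Voronoi cells."""
    edge = np.zeros(labels2d.shape, dtype=bool)
    edge[:-1, :] |= labels2d[:-1, :] != labels2d[1:, :]
    edge[1:, :] |= labels2d[:-1, :] != labels2d[1:, :]
    edge[:, :-1] |= labels2d[:, :-1] != labels2d[:, 1:]
    edge[:, 1:] |= labels2d[:, :-1] != labels2d[:, 1:]
    return edge


def _render_gaussian_spots(
    data: np.ndarray,
    coords_vox: np.ndarray,
    amplitude: float,
    sigma_vox: tuple[float, float, float],
) -> None:
    """Add unit-peak Gaussians (scaled by amplitude) at sub-voxel positions."""
    shape = data.shape
    half = [int(np.ceil(3 * s)) + 1 for s in sigma_vox]
    for p in coords_vox:
        lo = [max(int(np.floor(p[a])) - half[a], 0) for a in range(3)]
        hi = [min(int(np.floor(p[a])) + half[a] + 1, shape[a]) for a in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        axes = [np.arange(lo[a], hi[a]) - p[a] for a in range(3)]
        g = np.exp(
            -(
                (axes[0][:, None, None] / sigma_vox[0]) ** 2
                + (axes[1][None, :, None] / sigma_vox[1]) ** 2
                + (axes[2][None, None, :] / sigma_vox[2]) ** 2
            )
            / 2.0
        )
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * g


def _apply_noise(
    data: np.ndarray, rng: np.random.Generator, params: TissueParams
) -> np.ndarray:
    out = data + params.background
    if params.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if params.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, params.gaussian_noise_sd, out.shape)
    return np.clip(out, 0.0, None)


def generate_tissue(params: TissueParams) -> TissueBundle:
    """Generate one synthetic tissue bundle (deterministic under the seed)."""
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing
    r_ax, r_lat = params.nucleus_radii

    # --- tessellation; retry if a cell cannot host a nucleus
    for attempt in range(5):
        labels2d = _voronoi_labels(rng, ny, nx, params.n_cells)
        edge = _edge_mask(labels2d)
        dist_um = ndi.distance_transform_edt(~edge, sampling=(dy, dx))
        inradius = ndi.maximum(
            dist_um, labels=labels2d, index=np.arange(1, params.n_cells + 1)
        )
        if np.all(inradius >= 0.6 * r_lat):
            break
    else:
        raise RuntimeError(
            "could not place a nucleus in every cell after 5 attempts; "
            "reduce n_cells or nucleus_radii"
        )

    # --- apical surface: cosine dome of peak height `curvature`
    z_top = 3.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_um = np.hypot((yy - cy0) * dy, (xx - cx0) * dx)
    R = 0.48 * min(ny * dy, nx * dx)
    bump = np.where(
        r_um < R, 0.5 * params.curvature * (1 + np.cos(np.pi * r_um / R)), 0.0
    )
    zstar = z_top + (params.curvature - bump) / dz  # dome apex at z_top
    zstar = np.clip(zstar, 0, nz - 1)

    # inward (deeper-z) unit normal of the surface, per pixel, in µm space
    f_um = zstar * dz
    fy, fx = np.gradient(f_um, dy, dx)
    norm = np.sqrt(1.0 + fy**2 + fx**2)
    normal = np.stack([np.ones_like(fy) / norm, -fy / norm, -fx / norm])

    # --- per-cell geometry
    cell_ids = np.arange(1, params.n_cells + 1)
    ccy = ndi.mean(yy, labels=labels2d, index=cell_ids)
    ccx = ndi.mean(xx, labels=labels2d, index=cell_ids)
    cpy = np.clip(np.round(ccy).astype(int), 0, ny - 1)
    cpx = np.clip(np.round(ccx).astype(int), 0, nx - 1)
    cell_z = {int(c): float(zstar[cpy[i], cpx[i]]) for i, c in enumerate(cell_ids)}

    # --- junction channel: Gaussian tube along Voronoi edges at z*(y, x)
    junc = np.zeros(grid.shape)
    ez = np.clip(np.round(zstar[edge]).astype(int), 0, nz - 1)
    ey, ex = np.nonzero(edge)
    np.add.at(junc, (ez, ey, ex), 1.0)
    jt = params.junction_thickness
    sig_j = (max(jt / 2 / dz, 0.5), jt / 2 / dy, jt / 2 / dx)
    junc = ndi.gaussian_filter(junc, sig_j)
    if junc.max() > 0:
        junc *= params.junction_intensity / junc.max()

    # --- nuclei: one ellipsoid per cell, depth below the apex along the normal
    labels3d = np.zeros(grid.shape, dtype=np.int32)
    spacing_arr = np.asarray(grid.spacing)
    nuc_centers_vox = {}
    for i, c in enumerate(cell_ids):
        py, px = cpy[i], cpx[i]
        apex_um = np.array([zstar[py, px] * dz, ccy[i] * dy, ccx[i] * dx])
        n_hat = normal[:, py, px]
        theta = rng.uniform(0, 2 * np.pi)
        rad = params.nucleus_jitter_frac * inradius[i] * np.sqrt(rng.uniform())
        jitter = np.array([0.0, rad * np.sin(theta), rad * np.cos(theta)])
        center_um = apex_um + params.nucleus_depth * n_hat + jitter
        center_vox = center_um / spacing_arr
        nuc_centers_vox[int(c)] = center_vox
        half = np.array([r_ax / dz, r_lat / dy, r_lat / dx])
        lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
        hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        zz2, yy2, xx2 = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        ell = (
            ((zz2 - center_vox[0]) * dz / r_ax) ** 2
            + ((yy2 - center_vox[1]) * dy / r_lat) ** 2
            + ((xx2 - center_vox[2]) * dx / r_lat) ** 2
        ) <= 1.0
        block = labels3d[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        block[ell & (block == 0)] = c
    nuc_img = (labels3d > 0).astype(float) * params.nucleus_intensity
    nuc_img = ndi.gaussian_filter(nuc_img, (0.2 / dz, 0.2 / dy, 0.2 / dx))

    # --- cell classes (high/low expressors)
    high = rng.random(params.n_cells) < params.frac_high
    truth_classes = {
        int(c): ("high" if high[i] else "low") for i, c in enumerate(cell_ids)
    }

    # --- IHC-like cytoplasmic reporter channel
    ihc = None
    if params.ihc_channel:
        level = np.zeros(params.n_cells + 1)
        level[cell_ids] = np.where(high, params.ihc_high, params.ihc_low)
        level2d = level[labels2d]
        zz3 = np.arange(nz)[:, None, None]
        prism = (zz3 >= zstar[None]) & (zz3 <= zstar[None] + params.cyto_depth / dz)
        ihc = prism * level2d[None]

    # --- RNA channels: two-population Poisson counts, spots along the normal
    # placed in the cytoplasm (footprint eroded by the junction half-width)
    sigma_spot_vox = (
        params.spot_sigma[0] / dz,
        params.spot_sigma[1] / dy,
        params.spot_sigma[1] / dx,
    )
    cyto_ok = dist_um >= jt / 2
    rna_imgs = []
    truth_spots: dict[str, SpotSet] = {}
    depth_extra = r_ax + 2.0  # spots reach nucleus bottom + 2 µm
    for ch in range(params.n_rna_channels):
        coords = []
        owners = []
        for i, c in enumerate(cell_ids):
            lam = params.lambda_high if high[i] else params.lambda_low
            count = int(rng.poisson(lam))
            mask = (labels2d == c) & cyto_ok
            if not mask.any():
                mask = labels2d == c
            pys, pxs = np.nonzero(mask)
            for _ in range(count):
                j = int(rng.integers(len(pys)))
                y = pys[j] + rng.uniform(-0.5, 0.5)
                x = pxs[j] + rng.uniform(-0.5, 0.5)
                zs = zstar[pys[j], pxs[j]]
                n_hat = normal[:, pys[j], pxs[j]]
                d = rng.uniform(0.0, params.nucleus_depth + depth_extra)
                pos_um = np.array([zs * dz, y * dy, x * dx]) + d * n_hat
                pos_vox = pos_um / spacing_arr
                pos_vox = np.clip(
                    pos_vox, 1.0, np.asarray(grid.shape, dtype=float) - 2.0
                )
                coords.append(pos_vox)
                owners.append(int(c))
        coords = np.asarray(coords).reshape(-1, 3)
        img = np.zeros(grid.shape)
        _render_gaussian_spots(img, coords, params.spot_amplitude, sigma_spot_vox)
        rna_imgs.append(img)
        name = f"rna{ch}"
        truth_spots[name] = SpotSet(
            coords,
            name,
            np.full(len(coords), params.spot_amplitude),
            np.asarray(owners, dtype=int),
        )

    # --- compose channels with background and noise
    channels: dict[str, VolumeImage] = {}
    channels["junction"] = VolumeImage(
        grid, _apply_noise(junc, rng, params), "junction"
    )
    channels["nuclei"] = VolumeImage(
        grid, _apply_noise(nuc_img, rng, params), "nuclei"
    )
    if ihc is not None:
        channels["ihc"] = VolumeImage(grid, _apply_noise(ihc, rng, params), "ihc")
    for ch, img in enumerate(rna_imgs):
        channels[f"rna{ch}"] = VolumeImage(
            grid, _apply_noise(img, rng, params), f"rna{ch}"
        )
    if params.mixed_channel:
        channels["mixed"] = VolumeImage(
            grid, _apply_noise(junc + nuc_img, rng, params), "mixed"
        )

    truth_cells = ApicalCellMap(labels2d, cell_z, grid)
    truth_nuclei = NucleiLabels.from_labels(labels3d, grid, nuc_img)
    pairing = {int(c): int(c) for c in cell_ids if int(c) in truth_nuclei.labels}
    return TissueBundle(
        params=params,
        channels=channels,
        truth_cells=truth_cells,
        truth_nuclei=truth_nuclei,
        truth_spots=truth_spots,
        truth_classes=truth_classes,
        zstar=zstar,
        truth_pairing=pairing,
        truth_components={"junction": junc, "nuclei": nuc_img},
    )


# -------------------------------------------------------- plain spot field


def simulate_spot_field(
    shape: tuple[int, int, int] = (40, 256, 256),
    spacing: tuple[float, float, float] = (1.0, 0.2, 0.2),
    n_spots: int = 400,
    amplitude: float = 100.0,
    sigma: tuple[float, float] = (0.75, 0.25),
    background: float = 100.0,
    noise_sd: float = 20.0,
    min_separation: float = 1.5,
    seed: int = 0,
) -> tuple[VolumeImage, np.ndarray]:
    """Uniform random diffraction-limited spots in an empty volume.

    Spots keep ``min_separation`` µm apart (sparse smFISH regime) and 2
    voxels from the borders.  SNR is ``amplitude / noise_sd``.  Returns the
    rendered channel and the true sub-voxel coordinates (voxel units).
    """
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(shape, spacing)
    spacing_arr = np.asarray(spacing)
    lo = np.array([2.0, 2.0, 2.0])
    hi = np.asarray(shape, dtype=float) - 3.0
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_spots and attempts < 100 * n_spots:
        attempts += 1
        p = rng.uniform(lo, hi)
        if placed:
            d = np.linalg.norm(
                (np.asarray(placed) - p) * spacing_arr, axis=1
            ).min()
            if d < min_separation:
                continue
        placed.append(p)
    if len(placed) < n_spots:
        raise RuntimeError("volume too small for the requested spot density")
    coords = np.asarray(placed)
    img = np.zeros(grid.shape)
    sigma_vox = (sigma[0] / spacing[0], sigma[1] / spacing[1], sigma[1] / spacing[2])
    _render_gaussian_spots(img, coords, amplitude, sigma_vox)
    img = img + background
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    return VolumeImage(grid, img, "spots"), coords


# ------------------------------------------------------------------- scoring


def match_spots(
    predicted: np.ndarray, truth: np.ndarray, radius_vox: float = 2.0
) -> list[tuple[int, int]]:
    """Greedy nearest matching of predicted to true spots (voxel units).

    Pairs within ``radius_vox`` are matched closest-first, each spot at most
    once; returns (pred_index, truth_index) pairs.
    """
    predicted = np.asarray(predicted).reshape(-1, 3)
    truth = np.asarray(truth).reshape(-1, 3)
    if len(predicted) == 0 or len(truth) == 0:
        return []
    tree = cKDTree(truth)
    cand = []
    for i, p in enumerate(predicted):
        for j in tree.query_ball_point(p, radius_vox):
            cand.append((float(np.linalg.norm(p - truth[j])), i, j))
    cand.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, i, j in cand:
        if i in used_p or j in used_t:
            continue
        matches.append((i, j))
        used_p.add(i)
        used_t.add(j)
    return matches


def spot_detection_scores(
    predicted: np.ndarray, truth: np.ndarray, radius_vox: float = 2.0
) -> dict[str, float]:
    """Precision / recall / F1 of detected spot coordinates."""
    m = len(match_spots(predicted, truth, radius_vox))
    n_pred, n_true = len(np.asarray(predicted).reshape(-1, 3)), len(
        np.asarray(truth).reshape(-1, 3)
    )
    precision = m / n_pred if n_pred else 0.0
    recall = m / n_true if n_true else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1, "n_matched": m}


def assignment_accuracy(
    pred_spots: SpotSet,
    truth_spots: SpotSet,
    radius_vox: float = 2.0,
) -> dict[str, float]:
    """Accuracy of a strategy's cell labels against generation truth.

    Detected spots are greedily matched to truth spots (<= ``radius_vox``);
    accuracy is the fraction of matched *and assigned* spots whose cell
    equals the truth cell.  The unassigned fraction over matched spots is
    reported separately.
    """
    matches = match_spots(pred_spots.coords, truth_spots.coords, radius_vox)
    if not matches:
        return {"accuracy": np.nan, "unassigned_fraction": np.nan, "n_matched": 0}
    pred_cells = np.array([pred_spots.cell[i] for i, _ in matches])
    true_cells = np.array([truth_spots.cell[j] for _, j in matches])
    assigned = pred_cells > 0
    acc = float(np.mean(pred_cells[assigned] == true_cells[assigned])) if assigned.any() else np.nan
    return {
        "accuracy": acc,
        "unassigned_fraction": float(np.mean(~assigned)),
        "n_matched": len(matches),
    }


def segmentation_jaccard(
    predicted: np.ndarray, truth: np.ndarray
) -> pd.DataFrame:
    """Best-match intersection-over-union per true cell.

    Each true cell is matched to the predicted label with the largest
    overlap (background excluded); returns one row per true cell with the
    matched label and the Jaccard index.
    """
    rows = []
    for c in np.unique(truth):
        if c == 0:
            continue
        mask = truth == c
        overlap = predicted[mask]
        overlap = overlap[overlap > 0]
        if len(overlap) == 0:
            rows.append((int(c), 0, 0.0))
            continue
        vals, counts = np.unique(overlap, return_counts=True)
        best = vals[np.argmax(counts)]
        inter = counts.max()
        union = mask.sum() + np.sum(predicted == best) - inter
        rows.append((int(c), int(best), float(inter / union)))
    return pd.DataFrame(rows, columns=["truth_cell", "matched_label", "jaccard"])


def nucleus_detection_scores(
    predicted: NucleiLabels, truth: NucleiLabels, max_dist_um: float = 2.0
) -> dict[str, float]:
    """Greedy centroid matching (µm) → nucleus precision/recall."""
    p = predicted.centroids_um()
    t = truth.centroids_um()
    if len(p) == 0 or len(t) == 0:
        return {"precision": 0.0, "recall": 0.0, "mean_centroid_error_um": np.nan}
    tree = cKDTree(t)
    cand = []
    for i, pt in enumerate(p):
        for j in tree.query_ball_point(pt, max_dist_um):
            cand.append((float(np.linalg.norm(pt - t[j])), i, j))
    cand.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    errs = []
    for d, i, j in cand:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        errs.append(d)
    return {
        "precision": len(errs) / len(p),
        "recall": len(errs) / len(t),
        "mean_centroid_error_um": float(np.mean(errs)) if errs else np.nan,
    }


def classification_agreement(
    predicted: pd.Series, truth_classes: dict[int, str]
) -> float:
    """Fraction of cells where a positive call matches the true high class."""
    cells = [c for c in predicted.index if c in truth_classes]
    if not cells:
        return np.nan
    ok = [
        (predicted[c] == "positive") == (truth_classes[c] == "high") for c in cells
    ]
    return float(np.mean(ok))


def score_against_truth(predicted, truth: TissueBundle, **kwargs):
    """Dispatch a prediction to the matching metric for its type."""
    from .assign import AssignmentResult

    if isinstance(predicted, AssignmentResult):
        channel = predicted.spots.channel
        key = channel if channel in truth.truth_spots else next(iter(truth.truth_spots))
        return assignment_accuracy(predicted.spots, truth.truth_spots[key], **kwargs)
    if isinstance(predicted, SpotSet):
        key = predicted.channel if predicted.channel in truth.truth_spots else next(
            iter(truth.truth_spots)
        )
        return spot_detection_scores(
            predicted.coords, truth.truth_spots[key].coords, **kwargs
        )
    if isinstance(predicted, NucleiLabels):
        return nucleus_detection_scores(predicted, truth.truth_nuclei, **kwargs)
    if isinstance(predicted, ApicalCellMap):
        return segmentation_jaccard(predicted.labels2d, truth.truth_cells.labels2d)
    if isinstance(predicted, np.ndarray) and predicted.ndim == 2:
        return segmentation_jaccard(predicted, truth.truth_cells.labels2d)
    if isinstance(predicted, pd.Series):
        return classification_agreement(predicted, truth.truth_classes)
    raise TypeError(f"no metric for type {type(predicted).__name__}")


# --------------------------------------------------------------- bundle I/O


def write_bundle(bundle: TissueBundle, outdir) -> None:
    """Write channels, truth labels, truth tables and params to a directory."""
    import yaml
    from pathlib import Path

    from . import io as eqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, im in bundle.channels.items():
        eqio.write_volume(im, outdir / f"channel_{name}.tif")
    eqio.write_labels(bundle.truth_cells.labels2d, outdir / "truth_cells.tif")
    eqio.write_cell_z(bundle.truth_cells.cell_z, outdir / "truth_cells_z.csv")
    eqio.write_labels(bundle.truth_nuclei.labels3d, outdir / "truth_nuclei.tif")
    bundle.truth_nuclei.props.to_csv(
        outdir / "truth_nuclei_props.csv", index=False, float_format="%.6g"
    )
    for name, ss in bundle.truth_spots.items():
        eqio.write_spots(ss, outdir / f"truth_spots_{name}.csv")
    pd.DataFrame(
        {
            "cell": sorted(bundle.truth_classes),
            "class": [bundle.truth_classes[c] for c in sorted(bundle.truth_classes)],
        }
    ).to_csv(outdir / "truth_classes.csv", index=False)
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(bundle.params), fh, sort_keys=True)
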