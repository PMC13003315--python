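"""3D detection of diffraction-limited RNA spots (smFISH).

Single transcripts appear as near-Gaussian dots.  Detection is a scale-
matched Laplacian-of-Gaussian filter whose strict 3D local maxima are the
candidates; a threshold on the response (manual, or an automatic knee
criterion on the candidate responses) retains spots, which are then refined
to sub-voxel coordinates by a separable quadratic fit.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from .core import SpotSet, VolumeImage


def log_response(channel: VolumeImage, spot_radius: tuple[float, float]) -> np.ndarray:
    """Negated anisotropy-aware LoG response (bright blobs positive).

    ``spot_radius`` is (axial, lateral) in µm; sigma per axis is
    radius / sqrt(3) / spacing (3D blob scale matching).
    """
    r_ax, r_lat = spot_radius
    if r_ax <= 0 or r_lat <= 0:
        raise ValueError("spot radii must be > 0")
    dz, dy, dx = channel.grid.spacing
    sigma = (
        r_ax / np.sqrt(3.0) / dz,
        r_lat / np.sqrt(3.0) / dy,
        r_lat / np.sqrt(3.0) / dx,
    )
    data = channel.data.astype(float)
    # anchor at the image minimum: the truncated discrete kernel does not
    # exactly annihilate constants, this makes additive shifts exact no-ops
    return -ndi.gaussian_laplace(data - data.min(), sigma)


def _local_maxima(resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates and values of 3³-neighbourhood maxima, borders excluded.

    A plateau (equal-valued tie within the neighbourhood) keeps only its
    lexicographically smallest coordinate, so noise-free symmetric fixtures
    detect deterministically.
    """
    maxf = ndi.maximum_filter(resp, size=3, mode="constant", cval=-np.inf)
    cand = resp >= maxf
    cand[:1] = cand[-1:] = False
    cand[:, :1] = cand[:, -1:] = False
    cand[:, :, :1] = cand[:, :, -1:] = False
    coords = np.argwhere(cand)  # argwhere is lexicographic in (z, y, x)
    if len(coords) == 0:
        return coords, np.zeros(0)
    vals = resp[tuple(coords.T)]
    kept_idx: list[int] = []
    kept: set[tuple[int, int, int]] = set()
    for i, (c, v) in enumerate(zip(coords, vals)):
        cz, cy, cx = (int(a) for a in c)
        tie = False
        for oz in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for ox in (-1, 0, 1):
                    if (cz + oz, cy + oy, cx + ox) in kept and resp[
                        cz + oz, cy + oy, cx + ox
                    ] == v:
                        tie = True
                        break
                if tie:
                    break
            if tie:
                break
        if not tie:
            kept_idx.append(i)
            kept.add((cz, cy, cx))
    return coords[kept_idx], vals[kept_idx]


def _knee(vals: np.ndarray) -> float:
    """Knee of the count-surviving-vs-threshold curve (unit-square chord)."""
    vmin, vmax = vals[0], vals[-1]
    ts = np.linspace(vmin, vmax, 100)
    counts = len(vals) - np.searchsorted(vals, ts, side="left")
    x = (ts - vmin) / (vmax - vmin)
    y = counts / counts[0]
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((x1 - x0) * (y0 - y) - (x0 - x) * (y1 - y0)) / chord
    return float(ts[int(np.argmax(dist))])


def auto_threshold(response_maxima: np.ndarray) -> float:
    """Automatic response threshold from the count-vs-threshold curve.

    100 evenly spaced thresholds between the candidates' min and max give a
    survival-count curve.  Real spots reveal themselves as a *stability
    plateau*: once the noise maxima (which outnumber spots by orders of
    magnitude in a 3D volume) are cut away, the count stays nearly constant
    over a wide threshold range before the true spots themselves start to
    disappear.  The knee of the normalised curve (maximum distance to the
    chord joining its endpoints) locates the end of the noise bulk; the
    returned threshold is the start of the first run of at least 5
    consecutive grid steps at or beyond the knee that each remove less than
    2% of the surviving candidates, or the knee itself when no such plateau
    exists.  Requires >= 10 candidates.
    """
    vals = np.sort(np.asarray(response_maxima, dtype=float))
    if len(vals) < 10:
        raise ValueError(
            "auto threshold needs >= 10 candidates; set a manual threshold"
        )
    if vals[-1] == vals[0]:
        return float(vals[0])
    knee = _knee(vals)
    ts = np.linspace(vals[0], vals[-1], 100)
    counts = len(vals) - np.searchsorted(vals, ts, side="left")
    rel_drop = (counts[:-1] - counts[1:]) / np.maximum(counts[:-1], 1)
    stable = rel_drop < 0.02
    start = int(np.searchsorted(ts, knee, side="left"))
    i = start
    while i < len(stable):
        if stable[i]:
            j = i
            while j < len(stable) and stable[j]:
                j += 1
            if j - i >= 5:
                return float(ts[i])
            i = j
        else:
            i += 1
    return float(knee)


def _refine_subvoxel(resp: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Per-axis quadratic refinement; offsets clipped to ±0.5 voxel."""
    refined = coords.astype(float)
    for axis in range(3):
        step = np.zeros(3, dtype=int)
        step[axis] = 1
        f0 = resp[tuple(coords.T)]
        fm = resp[tuple((coords - step).T)]
        fp = resp[tuple((coords + step).T)]
        denom = fm - 2 * f0 + fp
        with np.errstate(divide="ignore", invalid="ignore"):
            off = 0.5 * (fm - fp) / denom
        off = np.where(np.isfinite(off), off, 0.0)
        refined[:, axis] += np.clip(off, -0.5, 0.5)
    return refined


def detect_spots(
    channel: VolumeImage,
    spot_radius: tuple[float, float],
    threshold="auto",
) -> SpotSet:
    """Detect spots of (axial, lateral) radius ``spot_radius`` µm.

    ``threshold`` applies to the LoG response values of candidate maxima;
    ``"auto"`` uses :func:`auto_threshold` on all candidates.  Spot
    intensity is the raw image value at the maximum voxel; the cell field
    starts at 0 (unassigned).
    """
    resp = log_response(channel, spot_radius)
    coords, vals = _local_maxima(resp)
    if len(coords) == 0:
        return SpotSet(np.zeros((0, 3)), channel.channel_name)
    thr = auto_threshold(vals) if threshold == "auto" else float(threshold)
    keep = vals >= thr
    coords = coords[keep]
    if len(coords) == 0:
        return SpotSet(np.zeros((0, 3)), channel.channel_name)
    refined = _refine_subvoxel(resp, coords)
    intensity = channel.data[tuple(coords.T)].astype(float)
    return SpotSet(refined, channel.channel_name, intensity)


def edit_spots(
    spots: SpotSet,
    add: np.ndarray | list | None = None,
    remove: list[int] | None = None,
    image: VolumeImage | None = None,
) -> SpotSet:
    """Batch spot editing: removals (by index) applied before additions.

    Added spots take their intensity from ``image`` at the nearest voxel
    when given (NaN otherwise) and start unassigned (cell 0).
    """
    n = len(spots)
    remove = list(remove or [])
    for i in remove:
        if not (0 <= i < n):
            raise IndexError(f"spot index {i} out of range [0, {n})")
    keep = np.setdiff1d(np.arange(n), np.asarray(remove, dtype=int))
    coords = spots.coords[keep]
    intensity = spots.intensity[keep]
    cell = spots.cell[keep]
    add = np.asarray(add if add is not None else np.zeros((0, 3)), dtype=float)
    add = add.reshape(-1, 3)
    if len(add):
        if image is not None:
            vox = np.clip(
                np.round(add).astype(int),
                0,
                np.asarray(image.grid.shape) - 1,
            )
            add_int = image.data[tuple(vox.T)].astype(float)
        else:
            add_int = np.full(len(add), np.nan)
        coords = np.vstack([coords, add])
        intensity = np.concatenate([intensity, add_int])
        cell = np.concatenate([cell, np.zeros(len(add), dtype=int)])
    return SpotSet(coords, spots.channel, intensity, cell)
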