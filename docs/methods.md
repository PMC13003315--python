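# Methods

This note records the models, parameter choices and numerical conventions
behind epiquant, and what the built-in simulator does and does not
demonstrate.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based; voxel spacing `(dz, dy, dx)` is in
µm and every distance, area and volume the package reports is physical
(µm, µm², µm³). Distances are never computed in voxel counts because the
axial sampling is typically 3–5× coarser than lateral. Label 0 is
background everywhere; labels need not be consecutive, and a
`relabel_sequential` utility exists but is never applied implicitly.
Missing values (a cell without a nucleus, a class not called) serialize as
empty CSV fields — 0 is a legal count and is never a missing sentinel.

## 2.5D cell maps

Epithelial cells are outlined only at their apical junctions, so a cell is
modelled as a 2D polygon plus one Z coordinate ("2D labels with 3D
coordinates"). The projection stage records, per pixel, the argmax-Z of the
junction channel (ties break to the smallest Z, for determinism); the
`local_peak` variant smooths along Z first (σ in µm, converted through dz)
but returns the unsmoothed intensity, which suppresses single-voxel noise
peaks without biasing intensities. Cell Z is estimated from a one-pixel
dilated band around each cell's boundary, not from the interior, because
only junction pixels carry apical signal; the statistic is configurable
(median default — robust to stray argmax values in noisy pixels; mean
available). The built-in 2D segmentation is a classical seeded watershed
(seeds = connected h-minima of the projection, depth `seed_h` in intensity
units; ridges become background; areas outside `[min_area, max_area]` µm²
are removed after the watershed, before Z estimation). It is a deliberately
dependency-light baseline: label images produced by learned segmenters are
accepted as first-class input through `io.read_labels` plus the
`(label, z)` CSV sidecar.

## Nucleus segmentation and filtering

Blob detection uses the 3D scale-space relation between a ball of radius r
and the Laplacian of Gaussian: the response is extremal at σ = r/√3, so
each axis uses σ = r/√3 ÷ spacing. Candidate maxima above the threshold
(Otsu on the response by default) are pruned by non-maximum suppression at
the nucleus scale (greedy, highest response first, min separation = r in
µm) and seed a watershed on the inverted smoothed intensity restricted to
an Otsu foreground mask, which separates touching nuclei. Any label that
ends up 26-disconnected is split so that one label is always one connected
object. Default radius 2.3 µm matches the simulator's nuclei (2.5 µm axial
× 2.2 µm lateral half-axes); volume filters default to [20, 1000] µm³
(a nucleus of those radii has ≈ 50 µm³, so the band removes speckles and
fused giants without touching plausible nuclei).

## Nucleus–cell pairing

Matching cost between a cell's apical anchor (2D centroid placed at its
apical plane) and a nucleus centroid is Euclidean in µm with the axial term
down-weighted: cost = √(Δx² + Δy² + (w_z Δz)²), w_z = 0.25. The depth of a
nucleus below its apex varies with cell height and pseudostratification,
so lateral proximity is the informative term; w_z > 0 still breaks lateral
ties in favour of shallower nuclei. Both w_z and the admissibility gate
`max_dist` (default 10 µm) are config keys. The objective is
maximum-cardinality minimum-cost matching: "minimum cost over partial
matchings" alone is degenerate (the empty matching costs 0), so
inadmissible entries receive one uniform large cost and the Hungarian
solver then pairs as many admissible cell–nucleus pairs as possible,
minimising total cost among those; inadmissible pairs are dropped from the
solution. Tests verify optimality against exhaustive enumeration on all
instance shapes up to 7×7. Ties between equal-cost optima resolve by the
solver's deterministic order; exact lexicographic canonicalisation over
the optimal set is not implemented (ties have measure zero for continuous
costs).

## Spot detection and the automatic threshold

Detection is a scale-matched LoG (radius = σ√3 convention; the pipeline
default spot radius (1.3, 0.43) µm is matched to the simulator's PSF σ of
(0.75, 0.25) µm), strict 3³-neighbourhood maxima with plateau ties broken
to the lexicographically smallest coordinate, border voxels excluded (the
quadratic refinement needs both neighbours), and per-axis quadratic
refinement clipped to ±0.5 voxel. The image minimum is subtracted before
filtering: the truncated discrete LoG kernel does not exactly annihilate
constants, and anchoring at the minimum makes detection exactly invariant
to additive intensity offsets.

The automatic threshold works on the survival curve (candidate count vs
threshold, 100 even steps between the extremes). In a 3D volume, noise
maxima outnumber true spots by orders of magnitude, which flattens the
signal plateau against the x-axis; the knee of the normalised curve
(maximum distance to the chord between its endpoints) therefore only
locates the end of the noise bulk. The returned threshold is the start of
the first *stability plateau* at or beyond the knee — ≥ 5 consecutive grid
steps each removing < 2% of survivors — falling back to the knee itself
when no plateau exists. The 2%/step and 5-step constants are the curve's
grid resolution speaking: a plateau must be wide and flat relative to the
100-step grid to be distinguishable from the signal's own decay.

## Spot-to-cell assignment

All five strategies operate in µm. `projection` rounds the spot's (y, x)
to a pixel of the 2D label image. `nearest_nucleus` measures the distance
to the nucleus *surface* by default (nearest labeled voxel; distance 0
inside a nucleus) so large nuclei do not lose nearby spots — centroid
distance is available via config; exact ties go to the smaller nucleus
label. `mixed` computes each spot's depth below the apical plane of its
projection cell (background ⇒ +∞) and switches from projection to nearest
nucleus at `depth_cut` (default 5 µm: roughly the apex-to-nucleus-centre
distance in the simulated tissue — above it the apical footprint is the
better witness, below it the nucleus is). `hull` builds, per cell, the
convex hull of the boundary pixels of its apical polygon placed at its
apical plane plus the six axis-extreme voxels of its paired nucleus; a
spot is inside if every facet inequality holds within `pad` (default
0.5 µm, absorbing voxelisation), with multi-hull ties resolved by nearest
hull centroid; a cell with no paired nucleus has a coplanar (degenerate)
support set and assigns nothing. `iterative` propagates any base
strategy's labels to unassigned spots from their k nearest assigned
neighbours under a strict-majority (unique plurality) rule, synchronous
updates, assigned spots frozen — the unassigned count is non-increasing,
so the iteration terminates.

By construction the hull reaches only `pad` below the nucleus bottom,
while transcripts occur below that; hull assignment therefore trades
coverage for precision (high accuracy on the spots it does assign, a
substantial unassigned fraction). Accuracy against simulation truth is
accordingly reported over matched-and-assigned spots, with the unassigned
fraction surfaced separately in the comparison table — the same shape the
strategy-agreement table uses.

## Per-cell features

Cytoplasmic intensity of cell c is measured in the prism
{labels2d = c, z_c ≤ z ≤ z_c + depth/dz} clipped to the volume (the 2.5D
scheme extrudes the apical footprint straight down; no lateral shrinking
toward the basal side). Nucleus voxels are included by default
(`exclude_nucleus` flag available). The perimeter is the crack length
(boundary edge count × pixel pitch, each edge weighted by its own axis
pitch), which makes a digital square's circularity come out at the
closed-form 4πA/P². Neighbour counts tolerate the one-pixel watershed
ridge: adjacency is evaluated across gaps of up to three pixels.
Classification pre-fill is binary (positive/negative) by Otsu (256 bins)
or a manual threshold; multi-class labels enter via CSV import. Clustering
z-scores the chosen columns (making it invariant to per-column affine
transforms), uses Euclidean distance with Ward/average/complete linkage,
cuts at k, and leaves rows with missing features uncounted rather than
imputed.

## Channel unmixing

The co-stained junction + nuclei channel is split by a grayscale opening
with an ellipsoidal structuring element whose per-axis voxel radii come
from one physical radius (half the nucleus radius — large enough to erase
the thin junction sheet, small enough to survive inside nuclei). The
junction estimate is the white top-hat, so junctions + nuclei = mixed
exactly and both parts are non-negative; opening is anti-extensive, so the
nuclei estimate never exceeds the input. A caveat the acceptance run
quantifies: the top-hat necessarily leaves the acquisition noise in the
junction residual, so *voxelwise* Pearson correlation between the junction
estimate and the true junction channel is noise-limited even though the
operator itself is accurate (on the noise-free component sum the same
correlation is ≈ 0.96); the blob component, carrying most of the variance,
is recovered well in both regimes.

## The synthetic tissue

The generator is the package's study-condition definition, not a fixture:
50 cells on a (40, 256, 256) grid at (1.0, 0.2, 0.2) µm spacing, flat by
default, all runs completing in seconds on one CPU. Cells are a raster
Voronoi tessellation of uniform seeds after one Lloyd relaxation step; the
apical surface is a cosine dome of peak height `curvature` (0 = flat). One
ellipsoidal nucleus per cell (half-axes 2.5 × 2.2 µm) sits `nucleus_depth`
= 4 µm below the apex *along the local inward surface normal*, laterally
jittered within 20% of the cell's inradius; transcripts are drawn per cell
from Poisson(λ_high = 30) or Poisson(λ_low = 3) (class Bernoulli 0.5),
placed uniformly in the cell's cytoplasm (footprint minus the junction
zone) between the apical surface and 2 µm below the nucleus bottom, again
displaced along the normal, and rendered as 3D Gaussians of σ
(0.75, 0.25) µm with amplitude 100 over background 100 and Gaussian read
noise σ = 20 (spot SNR 5; shot noise optional). Placement along the
normal, rather than vertically, is what makes Z-projection assignment fail
on curved tissue — cells in a dome are perpendicular to the surface, so
their basal content is laterally offset from the apical footprint; a flat
sheet is exactly the vertical-prism limit.

What the simulator does **not** emulate: realistic optics (the PSF is an
axis-aligned Gaussian, no aberrations or depth-dependent blur),
photobleaching, autofluorescence texture, multi-layer or pseudostratified
epithelia, dividing cells or multi-nucleated cells, transcription-site
clusters or dense overlapping spot aggregates, and segmentation-quality
variation of external tools. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under controlled
geometry and noise — not performance on any particular microscope's data,
where parameter defaults (radii, thresholds, depth cut) will need
adjusting to the acquisition.

Two known accuracy floors, visible in the acceptance measurements and
deliberately not tuned away: (1) on flat tissue the nucleus-based
strategies misassign ~1–2% of spots — those lying within a few hundred nm
of a shared cell edge, where detection localisation noise and off-centre
nuclei make the nearest-nucleus relation genuinely ambiguous (this
ambiguity is the very reason several strategies exist); (2) the junction
component of the unmixing correlates below the blob component for the
noise reason above.

## Determinism and the CLI

Every random choice flows from one integer seed:
`np.random.default_rng(seed)` drives the generator sequentially, and
pipeline stages derive sub-seeds as `(seed·1000003 + crc32(stage)) mod
2³¹`. The staged CLI writes stable filenames into one working directory,
skips stages whose outputs are newer than their inputs (`--force`
overrides), rejects unknown config keys outright, and re-runs reproduce
CSV outputs byte-identically (timestamps live only in `run.log`).
Floats in CSVs are written at 6 significant digits.

## Problem sizes used in validation

Unit tests use 25-cell (32, 160, 160) tissues; acceptance checks use the
default 50-cell (40, 256, 256) conditions, a 10 µm dome for the curvature
comparison, a 400-spot SNR-5 field for detection, 200 random ≤ 7×7
instances against the exhaustive matching oracle, and two full pipeline
runs for reproducibility. These sizes were chosen so the entire validation
is a desk-scale computation while every statistic still has a three-digit
sample behind it.
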