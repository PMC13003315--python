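import numpy as np
import pandas as pd
import pytest

from epiquant.assign import AssignmentResult, assign_projection
from epiquant.core import (
    ApicalCellMap,
    CellNucleusPairing,
    NucleiLabels,
    SpotSet,
    VolumeImage,
    VoxelGrid,
)
from epiquant.features import (
    build_cell_table,
    cluster_cells,
    measure_cytoplasmic_intensity,
    measure_nuclear_intensity,
    morphometrics,
    prefill_classification,
)

SPACING = (1.0, 0.2, 0.2)


def _two_cell_map(nz=30):
    g = VoxelGrid((nz, 20, 20), SPACING)
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[:, :10] = 1
    labels[:, 10:] = 2
    return ApicalCellMap(labels, {1: 4.0, 2: 4.0}, g)


class TestCytoplasmicIntensity:
    def test_constant_image_gives_constant_mean(self):
        cells = _two_cell_map()
        img = VolumeImage(cells.grid, np.full(cells.grid.shape, 7.0))
        for depth in (1.0, 3.0, 10.0):
            out = measure_cytoplasmic_intensity(img, cells, depth)
            assert (out["mean"] == 7.0).all()

    def test_single_plane_depth_sums_that_plane(self):
        cells = _two_cell_map()
        data = np.zeros(cells.grid.shape)
        data[4] = 3.0  # the apical plane itself
        data[5] = 100.0
        img = VolumeImage(cells.grid, data)
        out = measure_cytoplasmic_intensity(img, cells, depth=0.5)  # < dz
        assert out.loc[1, "sum"] == 3.0 * 200  # 200 pixels per cell
        assert out.loc[1, "mean"] == 3.0

    def test_depth_must_be_positive(self):
        cells = _two_cell_map()
        img = VolumeImage(cells.grid, np.zeros(cells.grid.shape))
        with pytest.raises(ValueError):
            measure_cytoplasmic_intensity(img, cells, 0.0)

    def test_nucleus_exclusion_flag(self):
        cells = _two_cell_map()
        data = np.full(cells.grid.shape, 1.0)
        labels3d = np.zeros(cells.grid.shape, dtype=np.int32)
        labels3d[5:7, 2:5, 2:5] = 1
        data[labels3d > 0] = 100.0
        img = VolumeImage(cells.grid, data)
        nuclei = NucleiLabels.from_labels(labels3d, cells.grid)
        with_nuc = measure_cytoplasmic_intensity(img, cells, 5.0)
        without = measure_cytoplasmic_intensity(img, cells, 5.0, exclude_nucleus=nuclei)
        assert without.loc[1, "mean"] == 1.0
        assert with_nuc.loc[1, "mean"] > 1.0

    def test_reporter_levels_recovered(self, flat_bundle):
        """High/low cytoplasmic reporter cells separate into two modes and
        per-cell means sit near the generated levels."""
        b = flat_bundle
        out = measure_cytoplasmic_intensity(
            b.channels["ihc"], b.truth_cells, depth=b.params.cyto_depth
        )
        high = [c for c, k in b.truth_classes.items() if k == "high"]
        low = [c for c, k in b.truth_classes.items() if k == "low"]
        mean_high = out.loc[high, "mean"].mean()
        mean_low = out.loc[low, "mean"].mean()
        exp_high = b.params.ihc_high + b.params.background
        exp_low = b.params.ihc_low + b.params.background
        assert abs(mean_high - exp_high) <= 0.1 * exp_high
        assert abs(mean_low - exp_low) <= 0.1 * exp_low


class TestNuclearIntensity:
    def test_constant_and_sum(self):
        g = VoxelGrid((10, 10, 10), (1, 1, 1))
        labels = np.zeros(g.shape, dtype=np.int32)
        labels[2, 2, :10] = 4  # 10 voxels
        nuclei = NucleiLabels.from_labels(labels, g)
        img = VolumeImage(g, np.full(g.shape, 3.0))
        out = measure_nuclear_intensity(img, nuclei)
        assert out.loc[4, "mean"] == 3.0
        assert out.loc[4, "sum"] == 30.0


class TestMorphometrics:
    def test_square_cell_area_perimeter_circularity(self):
        g = VoxelGrid((5, 20, 20), (1.0, 0.2, 0.2))
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1  # 10x10 square
        m = morphometrics(ApicalCellMap(labels, {1: 0.0}, g)).iloc[0]
        assert m["area_um2"] == pytest.approx(4.0)
        assert m["perimeter_um"] == pytest.approx(8.0)  # 40 steps x 0.2
        assert m["circularity"] == pytest.approx(4 * np.pi * 100 / 40**2, rel=1e-6)

    def test_voronoi_mean_neighbor_count_near_six(self, flat_bundle):
        """Planar tessellation: interior cells average ~6 neighbours
        (cells clipped by the image border have fewer and are excluded)."""
        labels = flat_bundle.truth_cells.labels2d
        border = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(
            labels[:, -1]
        )
        m = morphometrics(flat_bundle.truth_cells)
        interior = m[~m["cell"].isin(border)]
        assert len(interior) >= 10
        assert 5.5 <= interior["n_neighbors"].mean() <= 6.5

    def test_nucleus_fields_missing_when_unpaired(self):
        cells = _two_cell_map()
        m = morphometrics(cells)
        assert m["nucleus"].isna().all()


class TestPrefill:
    def test_manual_threshold(self):
        vals = pd.Series([1, 1, 1, 9, 9], index=[1, 2, 3, 4, 5])
        out = prefill_classification(vals, method="threshold", threshold=5)
        assert list(out) == ["negative"] * 3 + ["positive"] * 2

    def test_all_below_threshold(self):
        vals = pd.Series([1, 2, 3], index=[1, 2, 3])
        out = prefill_classification(vals, method="threshold", threshold=10)
        assert (out == "negative").all()

    def test_otsu_constant_values_error(self):
        with pytest.raises(ValueError, match="manual"):
            prefill_classification(pd.Series([5.0, 5.0, 5.0]), method="otsu")

    def test_otsu_agrees_with_generated_classes(self, flat_bundle):
        b = flat_bundle
        out = measure_cytoplasmic_intensity(
            b.channels["ihc"], b.truth_cells, depth=b.params.cyto_depth
        )
        calls = prefill_classification(out["mean"], method="otsu", name="ihc")
        agree = np.mean(
            [
                (calls[c] == "positive") == (b.truth_classes[c] == "high")
                for c in calls.index
            ]
        )
        assert agree >= 0.95


class TestBuildCellTable:
    def _assignment(self, cells, counts):
        coords, owners = [], []
        for c, n in counts.items():
            ys, xs = np.nonzero(cells.labels2d == c)
            for i in range(n):
                coords.append([5.0, ys[i], xs[i]])
                owners.append(c)
        spots = SpotSet(np.asarray(coords).reshape(-1, 3), "rna0", None, owners)
        return AssignmentResult(spots, "projection")

    def test_count_column_sums(self):
        cells = _two_cell_map()
        res = self._assignment(cells, {1: 5, 2: 2})
        table = build_cell_table(cells, assignments=[res])
        assert table["count_rna0"].sum() == 7
        assert table.loc[table.cell == 1, "count_rna0"].iloc[0] == 5

    def test_unknown_cell_in_assignment_is_an_error(self):
        cells = _two_cell_map()
        spots = SpotSet(np.zeros((1, 3)), "rna0", None, [99])
        with pytest.raises(ValueError, match="99"):
            build_cell_table(cells, assignments=[AssignmentResult(spots, "p")])

    def test_missing_blocks_keep_rows(self):
        cells = _two_cell_map()
        table = build_cell_table(cells)
        assert len(table) == 2
        assert table["nucleus"].isna().all()

    def test_end_to_end_counts_track_poisson_means(self, flat_bundle):
        """Per-cell counts in the table correlate with the generated Poisson
        means (r >= 0.8 at lambda 30 vs 3)."""
        b = flat_bundle
        truth = b.truth_spots["rna0"]
        res = assign_projection(truth.copy(), b.truth_cells)
        table = build_cell_table(b.truth_cells, assignments=[res])
        lam = np.array(
            [
                b.params.lambda_high
                if b.truth_classes[c] == "high"
                else b.params.lambda_low
                for c in table["cell"]
            ]
        )
        r = np.corrcoef(lam, table["count_rna0"])[0, 1]
        assert r >= 0.8


class TestClusterCells:
    def _blob_table(self, sep=4.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 2))
        b = rng.normal(sep, 1, (n, 2))
        X = np.vstack([a, b])
        return pd.DataFrame({"cell": np.arange(len(X)), "f1": X[:, 0], "f2": X[:, 1]})

    def test_two_separated_blobs_recovered(self):
        table = self._blob_table()
        ids = cluster_cells(table, ["f1", "f2"], k=2, linkage="ward")
        first, second = ids[:20], ids[20:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(ids) == {1, 2}

    def test_k_one_puts_everything_together(self):
        table = self._blob_table()
        ids = cluster_cells(table, ["f1"], k=1)
        assert (ids == 1).all()

    def test_duplicated_feature_column_invariant_for_ward(self):
        table = self._blob_table()
        table["f1_copy"] = table["f1"]
        a = cluster_cells(table, ["f1"], k=2, linkage="ward")
        b = cluster_cells(table, ["f1", "f1_copy"], k=2, linkage="ward")
        same = (a == b).mean()
        assert same in (0.0, 1.0) or same == 1.0  # identical up to label swap
        agree = max((a == b).mean(), (a == (3 - b)).mean())
        assert agree == 1.0

    def test_affine_transform_invariance(self):
        table = self._blob_table()
        base = cluster_cells(table, ["f1", "f2"], k=2)
        table2 = table.assign(f1=table.f1 * 100 + 3, f2=table.f2 * 0.01 - 7)
        moved = cluster_cells(table2, ["f1", "f2"], k=2)
        agree = max((base == moved).mean(), (base == (3 - moved)).mean())
        assert agree == 1.0

    def test_rows_with_missing_values_excluded(self):
        table = self._blob_table()
        table.loc[3, "f2"] = np.nan
        ids = cluster_cells(table, ["f1", "f2"], k=2)
        assert np.isnan(ids[3])
        assert ids.drop(3).notna().all()

    def test_k_larger_than_usable_rows_error(self):
        table = self._blob_table(n=2)
        with pytest.raises(ValueError):
            cluster_cells(table, ["f1"], k=10)
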