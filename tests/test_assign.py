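import numpy as np
import pytest

from epiquant.assign import (
    assign_hull,
    assign_iterative,
    assign_mixed,
    assign_nearest_nucleus,
    assign_projection,
    cell_hull_points_um,
    compare_strategies,
)
from epiquant.core import (
    ApicalCellMap,
    CellNucleusPairing,
    NucleiLabels,
    SpotSet,
    VoxelGrid,
)

SPACING = (1.0, 0.2, 0.2)


@pytest.fixture
def toy_scene():
    """Two square cells side by side, one nucleus below each."""
    g = VoxelGrid((30, 40, 40), SPACING)
    labels2d = np.zeros((40, 40), dtype=np.int32)
    labels2d[:, 1:19] = 3
    labels2d[:, 21:39] = 5
    cells = ApicalCellMap(labels2d, {3: 4.0, 5: 4.0}, g)
    labels3d = np.zeros(g.shape, dtype=np.int32)
    labels3d[8:13, 16:25, 6:14] = 1  # nucleus of cell 3
    labels3d[8:13, 16:25, 26:34] = 2  # nucleus of cell 5
    nuclei = NucleiLabels.from_labels(labels3d, g)
    pairing = CellNucleusPairing({3: 1, 5: 2})
    return cells, nuclei, pairing


class TestProjection:
    def test_interior_spot_any_z(self, toy_scene):
        cells, _, _ = toy_scene
        spots = SpotSet([[25.0, 10.0, 10.0], [2.0, 10.0, 10.0]])
        res = assign_projection(spots, cells)
        assert list(res.spots.cell) == [3, 3]  # Z-invariant

    def test_background_stays_unassigned(self, toy_scene):
        cells, _, _ = toy_scene
        spots = SpotSet([[5.0, 10.0, 20.0]])  # over the ridge (label 0)
        res = assign_projection(spots, cells)
        assert res.spots.cell[0] == 0
        assert res.unassigned_count == 1

    def test_flat_tissue_exact(self, flat_bundle):
        truth = flat_bundle.truth_spots["rna0"]
        res = assign_projection(truth.copy(), flat_bundle.truth_cells)
        assert np.mean(res.spots.cell == truth.cell) == 1.0


class TestNearestNucleus:
    def test_inside_nucleus_wins(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[10.0, 20.0, 10.0]])
        res = assign_nearest_nucleus(spots, nuclei, pairing)
        assert res.spots.cell[0] == 3

    def test_equidistant_breaks_to_lower_nucleus_label(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        # x=19.5 is exactly midway between the surfaces at x=13 and x=26
        spots = SpotSet([[10.0, 20.0, 19.5]])
        res = assign_nearest_nucleus(spots, nuclei, pairing)
        assert res.spots.cell[0] == 3  # nucleus 1 < nucleus 2

    def test_unpaired_nucleus_leaves_unassigned(self, toy_scene):
        cells, nuclei, _ = toy_scene
        pairing = CellNucleusPairing({3: 1})  # nucleus 2 unpaired
        spots = SpotSet([[10.0, 20.0, 30.0]])
        res = assign_nearest_nucleus(spots, nuclei, pairing)
        assert res.spots.cell[0] == 0

    def test_empty_nuclei_all_unassigned(self, toy_scene):
        cells, nuclei, _ = toy_scene
        empty = NucleiLabels.from_labels(
            np.zeros(nuclei.grid.shape, dtype=np.int32), nuclei.grid
        )
        spots = SpotSet([[10.0, 20.0, 30.0]])
        res = assign_nearest_nucleus(spots, empty, CellNucleusPairing({}))
        assert res.unassigned_count == 1

    def test_centroid_mode(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[10.0, 20.0, 8.0]])
        res = assign_nearest_nucleus(
            spots, nuclei, pairing, nucleus_distance="centroid"
        )
        assert res.spots.cell[0] == 3


class TestMixed:
    def test_infinite_cut_equals_projection_on_hits(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        rng = np.random.default_rng(0)
        spots = SpotSet(rng.uniform((5, 1, 1), (25, 39, 39), (40, 3)))
        proj = assign_projection(spots, cells)
        mixed = assign_mixed(spots, cells, nuclei, pairing, depth_cut=1e9)
        hit = proj.spots.cell > 0
        np.testing.assert_array_equal(mixed.spots.cell[hit], proj.spots.cell[hit])

    def test_zero_cut_equals_nearest_nucleus_below_apex(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[10.0, 10.0, 10.0], [20.0, 30.0, 30.0]])  # below z=4
        near = assign_nearest_nucleus(spots, nuclei, pairing)
        mixed = assign_mixed(spots, cells, nuclei, pairing, depth_cut=0.0)
        np.testing.assert_array_equal(mixed.spots.cell, near.spots.cell)

    def test_negative_cut_rejected(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        with pytest.raises(ValueError):
            assign_mixed(SpotSet(np.zeros((0, 3))), cells, nuclei, pairing, -1.0)

    def test_depth_cut_sweep_on_curved_tissue(self, curved_bundle):
        """Best mixed accuracy over a small sweep is within 0.02 of the best
        pure strategy."""
        from epiquant.simulate import assignment_accuracy

        b = curved_bundle
        cells, nuclei = b.truth_cells, b.truth_nuclei
        pairing = CellNucleusPairing(b.truth_pairing)
        truth = b.truth_spots["rna0"]
        spots = truth.copy()
        spots.cell = np.zeros(len(spots), dtype=int)
        pure = [
            assign_projection(spots, cells),
            assign_nearest_nucleus(spots, nuclei, pairing),
        ]
        pure_acc = max(
            assignment_accuracy(r.spots, truth)["accuracy"] for r in pure
        )
        mixed_acc = [
            assignment_accuracy(
                assign_mixed(spots, cells, nuclei, pairing, d).spots, truth
            )["accuracy"]
            for d in (2.0, 5.0, 10.0)
        ]
        assert max(mixed_acc) >= pure_acc - 0.02


def _hull_oracle_inside(points_um, spot_um, pad):
    """Independent half-space check: for every hull facet, build the
    outward normal from vertex cross products and test normal·(s - v) <= pad."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points_um)
    interior = points_um[hull.vertices].mean(axis=0)
    for simplex in hull.simplices:
        a, b, c = points_um[simplex]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm == 0:
            continue
        n = n / norm
        if np.dot(n, interior - a) > 0:
            n = -n  # orient outward
        if np.dot(n, spot_um - a) > pad:
            return False
    return True


class TestHull:
    def test_spot_between_apex_and_nucleus(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[6.0, 20.0, 10.0]])
        res = assign_hull(spots, cells, nuclei, pairing, pad=0.5)
        assert res.spots.cell[0] == 3

    def test_spot_far_below_everything_unassigned(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[28.0, 20.0, 10.0]])
        res = assign_hull(spots, cells, nuclei, pairing, pad=0.5)
        assert res.spots.cell[0] == 0

    def test_degenerate_hull_warns_and_skips(self, toy_scene):
        cells, nuclei, _ = toy_scene
        spots = SpotSet([[6.0, 20.0, 10.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            res = assign_hull(spots, cells, nuclei, CellNucleusPairing({}), pad=0.5)
        assert res.unassigned_count == 1

    def test_containment_matches_halfspace_oracle(self, small_bundle):
        """Implementation containment equals the independent facet-normal
        oracle on every (spot, cell) pair."""
        b = small_bundle
        cells, nuclei = b.truth_cells, b.truth_nuclei
        pairing = CellNucleusPairing(b.truth_pairing)
        spots = b.truth_spots["rna0"]
        spacing = np.asarray(SPACING)
        from scipy.spatial import ConvexHull

        from epiquant.assign import QhullError

        pad = 0.5
        for c in cells.labels:
            pts = cell_hull_points_um(cells, nuclei, pairing, c)
            try:
                hull = ConvexHull(pts)
            except QhullError:
                continue
            impl = (
                spots.coords * spacing @ hull.equations[:, :3].T
                + hull.equations[:, 3]
            ).max(axis=1) <= pad
            for i in range(0, len(spots), 7):  # subsample for speed
                oracle = _hull_oracle_inside(pts, spots.coords[i] * spacing, pad)
                assert impl[i] == oracle


class TestIterative:
    def _seeded(self, coords, cells_assigned):
        spots = SpotSet(coords, "rna0", None, np.asarray(cells_assigned))
        from epiquant.assign import AssignmentResult

        return AssignmentResult(spots, "seed")

    def test_unanimous_neighbors_adopt(self):
        coords = [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]]
        init = self._seeded(coords, [4, 4, 4, 0])
        res = assign_iterative(init, (1, 1, 1), k=3)
        assert res.spots.cell[3] == 4

    def test_two_two_tie_stays_unassigned(self):
        coords = [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1], [0, 0.5, 0.5]]
        init = self._seeded(coords, [4, 4, 7, 7, 0])
        res = assign_iterative(init, (1, 1, 1), k=4, max_iter=3)
        assert res.spots.cell[4] == 0

    def test_no_assigned_spots_returns_unchanged(self):
        init = self._seeded([[0, 0, 0], [1, 1, 1]], [0, 0])
        res = assign_iterative(init, (1, 1, 1), k=3)
        assert res.unassigned_count == 2

    def test_assigned_spots_never_change_and_count_monotone(self, flat_bundle):
        b = flat_bundle
        truth = b.truth_spots["rna0"]
        rng = np.random.default_rng(0)
        hidden = rng.random(len(truth)) < 0.2
        spots = truth.copy()
        spots.cell = np.where(hidden, 0, truth.cell)
        from epiquant.assign import AssignmentResult

        init = AssignmentResult(spots, "truth-minus-20%")
        res = assign_iterative(init, SPACING, k=5, max_iter=10)
        kept = ~hidden
        np.testing.assert_array_equal(res.spots.cell[kept], truth.cell[kept])
        assert res.unassigned_count <= int(hidden.sum())
        recovered = res.spots.cell[hidden] == truth.cell[hidden]
        assigned = res.spots.cell[hidden] > 0
        assert np.mean(recovered[assigned]) >= 0.9


class TestCompareStrategies:
    def test_self_agreement_is_one(self, toy_scene):
        cells, nuclei, pairing = toy_scene
        spots = SpotSet([[6.0, 20.0, 10.0], [6.0, 20.0, 30.0]])
        res = assign_projection(spots, cells)
        df = compare_strategies([res, res])
        assert df.iloc[0, 0] == 1.0

    def test_disjoint_assignments_agree_zero(self):
        from epiquant.assign import AssignmentResult

        coords = np.zeros((10, 3))
        a = AssignmentResult(SpotSet(coords, "r", None, np.full(10, 1)), "a")
        b = AssignmentResult(SpotSet(coords, "r", None, np.full(10, 2)), "b")
        df = compare_strategies([a, b])
        assert df.loc["a", "b"] == 0.0

    def test_mismatched_spot_counts_error(self):
        from epiquant.assign import AssignmentResult

        a = AssignmentResult(SpotSet(np.zeros((3, 3))), "a")
        b = AssignmentResult(SpotSet(np.zeros((4, 3))), "b")
        with pytest.raises(ValueError):
            compare_strategies([a, b])

    def test_matrix_symmetric_entries_bounded(self, flat_bundle):
        b = flat_bundle
        cells, nuclei = b.truth_cells, b.truth_nuclei
        pairing = CellNucleusPairing(b.truth_pairing)
        spots = b.truth_spots["rna0"].copy()
        spots.cell = np.zeros(len(spots), dtype=int)
        results = [
            assign_projection(spots, cells),
            assign_nearest_nucleus(spots, nuclei, pairing),
            assign_mixed(spots, cells, nuclei, pairing, 5.0),
            assign_hull(spots, cells, nuclei, pairing, 0.5),
        ]
        results.append(assign_iterative(results[2], SPACING))
        df = compare_strategies(results, truth=b.truth_spots["rna0"])
        names = [r.strategy for r in results]
        mat = df[names].to_numpy()
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert np.nanmin(mat) >= 0 and np.nanmax(mat) <= 1
        assert df["accuracy"].notna().all()


def test_count_conservation_every_strategy(flat_bundle):
    """assigned + unassigned = total spots, for every strategy."""
    b = flat_bundle
    cells, nuclei = b.truth_cells, b.truth_nuclei
    pairing = CellNucleusPairing(b.truth_pairing)
    spots = b.truth_spots["rna0"].copy()
    spots.cell = np.zeros(len(spots), dtype=int)
    for res in [
        assign_projection(spots, cells),
        assign_nearest_nucleus(spots, nuclei, pairing),
        assign_mixed(spots, cells, nuclei, pairing, 5.0),
        assign_hull(spots, cells, nuclei, pairing, 0.5),
    ]:
        per_cell = sum(np.sum(res.spots.cell == c) for c in cells.labels)
        assert per_cell + res.unassigned_count == len(spots)
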