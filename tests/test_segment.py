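import numpy as np
import pandas as pd
import pytest

from spotmap import (
    BinSpec,
    SpotTable,
    assign_spots,
    overlapping_bins,
    qc_filter,
    segment_dapi,
    spot_environment_bins,
)
from spotmap import simulate as sim


def _spots(xy, genes):
    xy = np.asarray(xy, float)
    return SpotTable(pd.DataFrame({
        "gene": list(genes), "x": xy[:, 0], "y": xy[:, 1]
    }))


class TestSegmentDapi:
    def test_two_separated_nuclei_two_labels(self):
        img, centers, _ = sim.make_nuclei_image(
            centers=np.array([[60.0, 80.0], [120.0, 80.0]]),
            nucleus_sd=10, size=(180, 180), seed=0,
        )
        mask = segment_dapi(img, tophat_radius=25)
        assert mask.max() == 2
        lab = {mask[int(cy), int(cx)] for cx, cy in centers}
        assert lab == {1, 2}

    def test_touching_nuclei_split_by_watershed(self):
        img, _, _ = sim.make_nuclei_image(
            centers=np.array([[80.0, 80.0], [105.0, 80.0]]),
            nucleus_sd=10, size=(180, 180), seed=0,
        )
        mask = segment_dapi(img, tophat_radius=25)
        assert mask.max() == 2

    def test_expansion_grows_label_area_monotonically(self):
        img, _, _ = sim.make_nuclei_image(
            centers=np.array([[90.0, 90.0]]), nucleus_sd=10,
            size=(180, 180), seed=0,
        )
        areas = [
            (segment_dapi(img, tophat_radius=25, expansion_distance=d) > 0).sum()
            for d in (0, 5, 15, 30)
        ]
        assert areas == sorted(areas)
        assert areas[0] < areas[-1]

    def test_constant_offset_invariance(self):
        """The top-hat removes a constant background, so an intensity
        offset below the threshold margin leaves the label count fixed."""
        centers = np.array([[60.0, 60.0], [130.0, 110.0]])
        img0, _, _ = sim.make_nuclei_image(centers=centers, nucleus_sd=10,
                                           size=(190, 190), seed=0)
        img1, _, _ = sim.make_nuclei_image(centers=centers, nucleus_sd=10,
                                           offset=30.0, size=(190, 190), seed=0)
        m0 = segment_dapi(img0, tophat_radius=25)
        m1 = segment_dapi(img1, tophat_radius=25)
        assert m0.max() == m1.max()

    def test_empty_threshold_raises(self):
        img = sim.NuclearImage(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            segment_dapi(img, tophat_radius=10, intensity_threshold=100.0)


class TestAssignSpots:
    def test_read_contributes_to_its_cell(self):
        mask = np.zeros((20, 20), int)
        mask[5:10, 5:10] = 3
        seg, rep = assign_spots(_spots([[7.0, 7.0]], ["G"]), mask)
        assert seg.counts.loc[3, "G"] == 1
        assert rep["n_assigned"] == 1

    def test_conservation_with_background_and_out_of_extent(self):
        mask = np.zeros((20, 20), int)
        mask[0:10, 0:10] = 1
        spots = _spots([[5, 5], [15, 15], [50, 50]], "GGG")
        seg, rep = assign_spots(spots, mask)
        assert rep["n_assigned"] + rep["n_background"] + rep["n_out_of_extent"] == 3
        assert rep["n_background"] == 1 and rep["n_out_of_extent"] == 1

    def test_reads_in_generated_cells_assigned_back(self, five_class_ref):
        spots, mask, truth = sim.make_typed_cells(
            five_class_ref, 80, depth=1.5, size=(420, 420), seed=1
        )
        seg, rep = assign_spots(spots, mask)
        labels = rep["read_labels"]
        # reconstruct each read's generating cell (nearest truth center:
        # exact, since footprints are disjoint and reads stay inside them)
        from scipy.spatial import cKDTree

        _, gen_cell = cKDTree(truth[["x", "y"]].to_numpy()).query(spots.xy)
        frac = (labels == gen_cell + 1).mean()
        assert frac >= 0.99


class TestOverlappingBins:
    def test_tiling_is_a_partition(self):
        rng = np.random.default_rng(0)
        spots = _spots(
            np.column_stack([rng.uniform(0.1, 99.9, 500),
                             rng.uniform(0.1, 99.9, 500)]),
            ["G"] * 500,
        )
        seg = overlapping_bins(spots, BinSpec(radius=10, spacing=20))
        assert seg.counts.to_numpy().sum() == 500

    def test_half_spacing_puts_interior_read_in_four_bins(self):
        # surround with far-corner reads so the lattice extends past the
        # focal read on all sides
        spots = _spots([[55.0, 55.0], [0.0, 0.0], [100.0, 100.0]], "GGG")
        seg = overlapping_bins(spots, BinSpec(radius=10, spacing=10))
        covering = 0
        for idx in seg.counts.index:
            cx, cy = seg.centroids[list(seg.counts.index).index(idx)]
            if abs(55 - cx) <= 10 and abs(55 - cy) <= 10:
                covering += 1
        assert covering == 4

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(1)
        xy = np.column_stack([rng.uniform(0, 200, 300), rng.uniform(0, 200, 300)])
        spots = _spots(xy, ["G"] * 300)
        r, s = 25.0, 25.0
        seg = overlapping_bins(spots, BinSpec(radius=r, spacing=s))
        for pos, (cx, cy) in zip(seg.counts.index, seg.centroids):
            expected = int(
                ((np.abs(xy[:, 0] - cx) <= r) & (np.abs(xy[:, 1] - cy) <= r)).sum()
            )
            assert seg.counts.loc[pos, "G"] == expected

    def test_single_read_counted_once_per_covering_bin(self):
        spots = _spots([[10.0, 10.0]], ["G"])
        seg = overlapping_bins(spots, BinSpec(radius=5, spacing=5))
        assert (seg.counts["G"] == 1).all()


class TestSpotEnvironment:
    def test_isolated_read_one_hot(self):
        spots = _spots([[0, 0], [100, 100]], "AB")
        seg = spot_environment_bins(spots, radius=5)
        assert seg.counts.loc[0].tolist() == [1, 0]
        assert seg.counts.loc[1].tolist() == [0, 1]

    def test_two_close_reads_both_rows_sum_two(self):
        spots = _spots([[0, 0], [1, 0]], "AB")
        seg = spot_environment_bins(spots, radius=5)
        assert (seg.counts.sum(axis=1) == 2).all()

    def test_matches_pairwise_distance_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        xy = np.column_stack([rng.uniform(0, 300, n), rng.uniform(0, 300, n)])
        genes = rng.choice(["A", "B", "C"], n)
        spots = _spots(xy, genes)
        seg = spot_environment_bins(spots, radius=20)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        panel = ["A", "B", "C"]
        for i in range(n):
            within = d[i] <= 20
            expected = [int((genes[within] == g).sum()) for g in panel]
            assert seg.counts.iloc[i].tolist() == expected


class TestQcFilter:
    def test_no_thresholds_is_identity(self):
        from spotmap import SegmentedMap

        seg = SegmentedMap(
            counts=pd.DataFrame([[3, 1], [0, 7]], columns=["a", "b"]),
            unit_kind="bin", centroids=np.zeros((2, 2)),
        )
        out, rep = qc_filter(seg)
        pd.testing.assert_frame_equal(out.counts, seg.counts)
        assert rep == {"n_units_dropped": 0, "n_genes_dropped": 0}

    def test_low_count_unit_dropped(self):
        from spotmap import SegmentedMap

        seg = SegmentedMap(
            counts=pd.DataFrame([[3, 0], [5, 5]], columns=["a", "b"]),
            unit_kind="bin", centroids=np.zeros((2, 2)),
        )
        out, rep = qc_filter(seg, min_reads_per_unit=5)
        assert rep["n_units_dropped"] == 1
        assert list(out.counts.index) == [1]

    def test_planted_low_units_and_genes_removed_exactly(self):
        from spotmap import SegmentedMap

        rng = np.random.default_rng(3)
        counts = rng.integers(20, 40, (30, 6))
        counts[[4, 11], :] = 0  # planted empty units
        counts[:, 5] = 0
        counts[4, 0] = 2  # low-count unit
        seg = SegmentedMap(
            counts=pd.DataFrame(counts, columns=[f"g{i}" for i in range(6)]),
            unit_kind="bin", centroids=np.zeros((30, 2)),
        )
        out, rep = qc_filter(seg, min_reads_per_unit=10, min_reads_per_gene=10)
        assert rep["n_units_dropped"] == 2
        assert rep["n_genes_dropped"] == 1
        assert "g5" not in out.counts.columns

    def test_idempotence(self):
        from spotmap import SegmentedMap

        rng = np.random.default_rng(4)
        seg = SegmentedMap(
            counts=pd.DataFrame(rng.integers(0, 30, (20, 4)),
                                columns=list("abcd")),
            unit_kind="spot_env", centroids=np.zeros((20, 2)),
        )
        once, _ = qc_filter(seg, min_reads_per_unit=40, min_reads_per_gene=100)
        twice, rep = qc_filter(once, min_reads_per_unit=40, min_reads_per_gene=100)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert rep == {"n_units_dropped": 0, "n_genes_dropped": 0}

    def test_everything_filtered_raises(self):
        from spotmap import SegmentedMap

        seg = SegmentedMap(
            counts=pd.DataFrame([[1]], columns=["a"]),
            unit_kind="bin", centroids=np.zeros((1, 2)),
        )
        with pytest.raises(ValueError):
            qc_filter(seg, min_reads_per_unit=100)
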