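"""Aggregate clustering, ring decomposition, interior counting."""
import numpy as np
import pytest

from nanosorb import (
    MolecularConfiguration,
    aggregate_stats,
    analyze_trajectory,
    cluster_molecules,
    count_inside,
    decompose_rings,
    fraction_on_cnt,
)
from nanosorb.cnt import NanotubeSpec, build_zigzag
from nanosorb.synthetic import plant_configuration
from nanosorb.trajectory import minimum_image

BOX = (8.0, 8.0, 8.0)


def bfs_components(pos, box, cutoff):
    """Independent oracle: BFS connected components of the thresholded
    minimum-image distance graph, labelled by first occurrence."""
    n = len(pos)
    delta = pos[:, None, :] - pos[None, :, :]
    delta = minimum_image(delta, box)
    adj = np.sqrt((delta**2).sum(-1)) < cutoff
    labels = -np.ones(n, dtype=int)
    next_label = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = next_label
        while queue:
            i = queue.pop()
            for j in np.nonzero(adj[i])[0]:
                if labels[j] < 0:
                    labels[j] = next_label
                    queue.append(j)
        next_label += 1
    return labels


class TestClustering:
    def test_close_pair_forms_one_aggregate(self):
        cfg = MolecularConfiguration(np.array([[1.0, 1, 1], [1.4, 1, 1]]), box=BOX)
        part = cluster_molecules(cfg, cutoff=1.0)
        assert part.n_aggregates == 1
        assert aggregate_stats(part) == (1, 2.0)

    def test_distant_molecules_stay_singletons(self):
        pos = np.array([[1.0, 1, 1], [4, 1, 1], [1, 4, 1], [4, 4, 4]])
        part = cluster_molecules(MolecularConfiguration(pos, box=BOX), cutoff=1.0)
        assert part.n_aggregates == 4
        assert aggregate_stats(part) == (4, 1.0)

    def test_minimum_image_links_across_the_boundary(self):
        pos = np.array([[0.2, 1, 1], [7.9, 1, 1]])  # 0.3 nm apart through the wall
        part = cluster_molecules(MolecularConfiguration(pos, box=BOX), cutoff=1.0)
        assert part.n_aggregates == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_equals_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 1, (200, 3)) * np.asarray(BOX)
        cfg = MolecularConfiguration(pos, box=BOX)
        part = cluster_molecules(cfg, cutoff=1.0)
        assert np.array_equal(part.labels, bfs_components(pos, BOX, 1.0))

    def test_cutoff_limits(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 1, (40, 3)) * np.asarray(BOX)
        cfg = MolecularConfiguration(pos, box=BOX)
        assert cluster_molecules(cfg, cutoff=1e-9).n_aggregates == 40
        diagonal = float(np.linalg.norm(BOX))
        assert cluster_molecules(cfg, cutoff=diagonal).n_aggregates == 1

    def test_aggregate_count_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 1, (100, 3)) * np.asarray(BOX)
        cfg = MolecularConfiguration(pos, box=BOX)
        counts = [cluster_molecules(cfg, cutoff=c).n_aggregates
                  for c in (0.3, 0.6, 1.0, 1.5, 2.5, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_partition_covers_every_molecule_exactly_once(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 1, (80, 3)) * np.asarray(BOX)
        part = cluster_molecules(MolecularConfiguration(pos, box=BOX), cutoff=1.0)
        assert part.labels.size == 80
        assert sum(part.sizes().values()) == 80

    def test_empty_configuration_gives_empty_partition(self):
        part = cluster_molecules(MolecularConfiguration(np.empty((0, 3)), box=BOX))
        assert part.n_aggregates == 0 and part.labels.size == 0

    def test_stats_on_known_partitions(self):
        from nanosorb.trajectory import Partition
        assert aggregate_stats(Partition(labels=np.zeros(6, dtype=int))) == (1, 6.0)
        assert aggregate_stats(Partition(labels=np.array([0, 0, 0, 1]))) == (2, 2.0)
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 7, 60)
        dense = np.unique(labels, return_inverse=True)[1]
        k, mean = aggregate_stats(Partition(labels=dense))
        assert k == np.unique(labels).size
        assert mean == pytest.approx(60 / k)


class TestFractionOnCnt:
    def test_far_molecules_zero_contact_fraction(self, swcnt_wall):
        pos = np.array([[1.0, 5.0, 1.0], [18.0, 70.0, 18.0]])
        cfg = MolecularConfiguration(pos, cnt_walls=(swcnt_wall,))
        assert fraction_on_cnt(cfg, mode="contact") == 0.0
        part = cluster_molecules(cfg)
        assert fraction_on_cnt(cfg, part, mode="cluster") == 0.0

    def test_contact_placed_molecules_count_fully(self, swcnt_wall):
        atoms = swcnt_wall.positions[[0, 500, 1000]]
        center = np.array([10.0, 40.0, 10.0])
        pos = []
        for a in atoms:
            radial = a - center
            radial[1] = 0.0
            radial /= np.linalg.norm(radial)
            pos.append(a + 0.2 * radial)
        cfg = MolecularConfiguration(np.array(pos), cnt_walls=(swcnt_wall,))
        assert fraction_on_cnt(cfg, mode="contact", contact_cutoff=0.5) == 100.0

    def test_contact_fraction_non_decreasing_in_cutoff(self, swcnt_wall):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 1, (60, 3)) * np.array([20.0, 80.0, 20.0])
        cfg = MolecularConfiguration(pos, cnt_walls=(swcnt_wall,))
        fracs = [fraction_on_cnt(cfg, mode="contact", contact_cutoff=c)
                 for c in (0.3, 0.7, 1.5, 3.0, 6.0)]
        assert fracs == sorted(fracs)

    def test_contact_mode_equals_exhaustive_distance_scan(self, swcnt_wall):
        rng = np.random.default_rng(17)
        pos = rng.uniform(0, 1, (50, 3)) * np.array([20.0, 80.0, 20.0])
        cfg = MolecularConfiguration(pos, cnt_walls=(swcnt_wall,))
        got = fraction_on_cnt(cfg, mode="contact", contact_cutoff=1.0)
        count = 0
        box = np.array(cfg.box)
        for p in pos:
            d = minimum_image(swcnt_wall.positions - p, box)
            if np.sqrt((d**2).sum(1)).min() < 1.0:
                count += 1
        assert got == pytest.approx(100.0 * count / 50)


class TestRings:
    def test_generated_wall_rings_have_axis_centroids(self, swcnt_wall):
        rings = decompose_rings(swcnt_wall)
        assert len(rings) == swcnt_wall.n_rings
        centroids = np.array([r.centroid for r in rings])
        # tube axis is y through (10, *, 10)
        assert np.abs(centroids[:, [0, 2]] - 10.0).max() < 1e-6
        ys = centroids[:, 1]
        assert np.all(np.diff(ys) > 0)  # ordered along the axis

    def test_raw_coordinates_grouped_by_axial_position(self):
        wall = build_zigzag(NanotubeSpec(chirality_n=12, length=2.0, axis=(0, 0, 1)))
        rings = decompose_rings(wall.positions, axis=(0, 0, 1))
        # raw grouping resolves single atom rows (n per row, two rows per ring)
        assert len(rings) == 2 * wall.n_rings
        for ring in rings:
            assert len(ring.members) == 12
            assert np.abs(ring.centroid[:2]).max() < 1e-9

    def test_displaced_atom_raises_with_diagnostic(self):
        wall = build_zigzag(NanotubeSpec(chirality_n=12, length=2.0, axis=(0, 0, 1)))
        pos = wall.positions.copy()
        pos[0, 2] += 0.03  # beyond the 0.05/2 row gap pattern: bridges two rows
        pos[5, 2] -= 0.2   # isolated well beyond tolerance
        with pytest.raises(ValueError, match="axial"):
            decompose_rings(pos, axis=(0, 0, 1))


class TestInterior:
    def test_axis_molecule_counted_wall_molecule_not(self, swcnt_wall):
        rings = decompose_rings(swcnt_wall)
        pos = np.array([
            [10.0, 40.0, 10.0],   # on the axis at mid-length
            [10.0, 40.0, 16.0],   # radially outside the tube
        ])
        cfg = MolecularConfiguration(pos, cnt_walls=(swcnt_wall,))
        count, members = count_inside(cfg, rings, sphere_radius=0.9 * swcnt_wall.radius)
        assert count == 1
        assert members.tolist() == [0]

    @pytest.mark.parametrize("seed", range(10))
    def test_union_of_spheres_oracle(self, swcnt_wall, seed):
        rings = decompose_rings(swcnt_wall)
        sr = 0.9 * swcnt_wall.radius
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 1, (100, 3)) * np.array([20.0, 80.0, 20.0])
        cfg = MolecularConfiguration(pos, cnt_walls=(swcnt_wall,))
        count, members = count_inside(cfg, rings, sr)
        # oracle: per-ring membership sets, union, no dedup shortcuts
        box = np.array(cfg.box)
        inside = set()
        for ring in rings:
            for i, p in enumerate(pos):
                d = minimum_image(ring.centroid - p, box)
                if float(np.sqrt((d**2).sum())) < sr:
                    inside.add(i)
        assert count == len(inside)
        assert set(members.tolist()) == inside

    def test_sphere_radius_must_be_smaller_than_tube(self, swcnt_wall):
        rings = decompose_rings(swcnt_wall)
        cfg = MolecularConfiguration(np.array([[10.0, 40.0, 10.0]]),
                                     cnt_walls=(swcnt_wall,))
        with pytest.raises(ValueError, match="sphere_radius"):
            count_inside(cfg, rings, sphere_radius=swcnt_wall.radius * 1.1)


class TestTrajectory:
    def test_constant_trajectory_gives_constant_reports(self, swcnt_wall):
        cfg, _ = plant_configuration((swcnt_wall,), n_inside=3, surface_clusters=[5],
                                     free_clusters=[4], seed=0)
        frames = [
            MolecularConfiguration(cfg.dox_positions, cfg.cnt_walls, cfg.box, time=float(i))
            for i in range(3)
        ]
        reports = analyze_trajectory(frames)
        assert len(reports) == 3
        first = reports[0]
        for r in reports[1:]:
            assert r.n_aggregates == first.n_aggregates
            assert r.aggregate_membership == first.aggregate_membership

    def test_planted_ground_truth_recovered(self, swcnt_wall):
        cfg, truth = plant_configuration(
            (swcnt_wall,), n_inside=5, surface_clusters=[10, 10],
            free_clusters=[4, 4, 4], seed=42)
        [report] = analyze_trajectory([cfg])
        assert report.n_aggregates == truth.n_aggregates == 4
        assert report.mean_aggregate_size == pytest.approx(truth.mean_aggregate_size)
        assert report.fraction_on_cnt == pytest.approx(truth.fraction_on_cnt)
        assert report.fraction_inside_cnt == pytest.approx(truth.fraction_inside_cnt)
        assert report.aggregate_membership == truth.aggregate_membership

    def test_interior_set_subset_of_tube_aggregate(self, swcnt_wall):
        cfg, truth = plant_configuration(
            (swcnt_wall,), n_inside=4, surface_clusters=[6], free_clusters=[3], seed=7)
        [report] = analyze_trajectory([cfg])
        # tube aggregate is label 0 by construction; the first 4 molecules
        # are the interior ones
        assert all(report.aggregate_membership[i] == 0 for i in range(4))
        assert report.fraction_inside_cnt <= report.fraction_on_cnt

    def test_empty_frame_list_gives_empty_output(self):
        assert analyze_trajectory([]) == []

    def test_csv_time_series_written(self, swcnt_wall, tmp_path):
        cfg, _ = plant_configuration((swcnt_wall,), n_inside=2, surface_clusters=[3],
                                     free_clusters=[2], seed=1)
        out = tmp_path / "agg.csv"
        analyze_trajectory([cfg], csv_path=out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns) == ["time", "n_aggregates", "mean_aggregate_size",
                                    "fraction_on_cnt", "fraction_inside_cnt"]
        assert len(df) == 1
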