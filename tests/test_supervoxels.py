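import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

import gifdemons as gd
from gifdemons.supervoxels import (
    SlicParams,
    SupervoxelLabeling,
    build_multiscale_guidance,
    build_random_guidance,
    enforce_connectivity,
    render_channel,
    slic_cluster,
    slic_distance,
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _two_region_volume(n=32, axis=2):
    data = np.zeros((n, n, n))
    idx = [slice(None)] * 3
    idx[axis] = slice(n // 2, None)
    data[tuple(idx)] = 1.0
    return gd.Volume(data)


def _labels_straddling_regions(labeling, data):
    count = 0
    for li in range(labeling.n_labels):
        vals = data[labeling.labels == li]
        if vals.min() != vals.max():
            count += 1
    return count


class TestSlicDistance:
    def test_spatial_3_4_5_triangle(self):
        d = np.linalg.norm(np.array([3.0, 4.0, 0.0]))
        assert d == pytest.approx(5.0)
        assert slic_distance(d, 0.0, S=5.0, m=1.0) == pytest.approx(1.0)

    def test_intensity_distance(self):
        assert slic_distance(0.0, abs(10 - 14), S=1.0, m=2.0) == pytest.approx(2.0)

    def test_joint_distance(self):
        # d_xw=5, d_I=4, S=5, m=2 -> sqrt(1 + 4) = sqrt(5)
        assert slic_distance(5, 4, S=5, m=2) == pytest.approx(np.sqrt(5.0))

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            slic_distance(1, 1, S=0, m=1)


class TestSlicCluster:
    def test_grid_partition_on_constant_volume(self):
        vol = gd.Volume(np.zeros((24, 24, 24)))
        lab = slic_cluster(vol, SlicParams(K=8, m=1e6, sigma_z=0.0))
        sizes = np.bincount(lab.labels.ravel())
        assert lab.n_labels == 8
        # pure spatial Voronoi of the seed grid: 2x2x2 blocks of 12^3
        np.testing.assert_allclose(sizes, 1728, rtol=0.10)

    def test_partition_property(self, rng):
        vol = gd.Volume(rng.random((20, 20, 20)))
        lab = slic_cluster(vol, SlicParams(K=27, rng_seed=5))
        assert lab.labels.min() == 0
        assert np.all(np.bincount(lab.labels.ravel()) > 0)
        assert lab.labels.shape == vol.shape

    def test_compactness_bound_with_intensity_disabled(self, rng):
        vol = gd.Volume(rng.random((32, 32, 32)))
        lab = slic_cluster(vol, SlicParams(K=64, m=1e9, sigma_z=0.0))
        S = lab.S
        assert S == pytest.approx(8.0)
        for sl in ndimage.find_objects(lab.labels + 1):
            for s in sl:
                assert s.stop - s.start <= 2 * int(np.ceil(S)) + 1

    def test_strong_edge_boundary_recall(self):
        vol = _two_region_volume()
        lab = slic_cluster(vol, SlicParams(K=64, m=24, sigma_z=0.0))
        # no supervoxel contains voxels from both regions, hence every
        # interface voxel lies on a supervoxel boundary (recall 1.0)
        assert _labels_straddling_regions(lab, vol.data) == 0

    def test_seeded_determinism_bit_exact(self, rng):
        vol = gd.Volume(rng.random((20, 20, 20)))
        params = SlicParams(K=27, rng_seed=11)
        a = slic_cluster(vol, params)
        b = slic_cluster(vol, params)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_k_exceeding_voxels_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            slic_cluster(gd.Volume(np.zeros((4, 4, 4))), SlicParams(K=100))

    def test_label_convergence_on_structured_input(self):
        """On strongly structured input the labeling reaches a fixed point
        well before i_max and further iterations change nothing."""
        vol = _two_region_volume(24)
        lab = slic_cluster(vol, SlicParams(K=27, m=24, sigma_z=0.0, i_max=30))
        assert lab.converged
        assert lab.n_iter < 30
        more = slic_cluster(vol, SlicParams(K=27, m=24, sigma_z=0.0, i_max=60))
        np.testing.assert_array_equal(lab.labels, more.labels)


class TestEnforceConnectivity:
    def _labeling(self, labels, S=3.0):
        n = int(labels.max()) + 1
        centers = np.zeros((n, 3))
        return SupervoxelLabeling(labels.astype(np.int32), centers, np.zeros(n), S)

    def test_idempotent_on_connected_labeling(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[4:] = 1
        out = enforce_connectivity(self._labeling(labels))
        np.testing.assert_array_equal(out.labels, labels)
        again = enforce_connectivity(out)
        np.testing.assert_array_equal(again.labels, out.labels)

    def test_orphan_island_absorbed(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[4:] = 1
        labels[1, 1, 1:3] = 1  # 2-voxel island of label 1 inside label 0
        out = enforce_connectivity(self._labeling(labels))
        assert np.all(out.labels[1, 1, 1:3] == out.labels[1, 1, 0])
        # partition restored: two 26-connected labels
        assert out.n_labels == 2

    def test_flood_fill_oracle_on_random_labeling(self, rng):
        labels = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int32)
        out = enforce_connectivity(self._labeling(labels, S=3.0))
        for li in range(out.n_labels):
            mask = out.labels == li
            assert mask.any()
            _, n_comp = ndimage.label(mask, structure=_CONN26)
            assert n_comp == 1


class TestRenderChannel:
    def test_single_cluster_constant(self, rng):
        vol = gd.Volume(rng.random((6, 6, 6)))
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        lab = SupervoxelLabeling(labels, np.zeros((1, 3)), np.zeros(1), 6.0)
        out = render_channel(vol, lab)
        np.testing.assert_allclose(out.data, 0.0)  # constant renders as zeros

    def test_perfectly_clustered_two_regions(self):
        vol = _two_region_volume(8)
        labels = (vol.data > 0.5).astype(np.int32)
        lab = SupervoxelLabeling(labels, np.zeros((2, 3)), np.zeros(2), 4.0)
        out = render_channel(vol, lab)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_group_by_mean_oracle(self, rng):
        vol = gd.Volume(rng.random((10, 10, 10)))
        labels = rng.integers(0, 5, (10, 10, 10)).astype(np.int32)
        lab = SupervoxelLabeling(labels, np.zeros((5, 3)), np.zeros(5), 4.0)
        out = render_channel(vol, lab)
        means = np.array([vol.data[labels == li].mean() for li in range(5)])
        expected = (means - means.min()) / np.ptp(means)
        np.testing.assert_allclose(out.data, expected[labels], atol=1e-10)


class TestGuidanceConstruction:
    def test_no_perturbation_gives_identical_channels(self, rng):
        vol = gd.Volume(rng.random((16, 16, 16)))
        gi = build_random_guidance(vol, SlicParams(K=27, sigma_z=0.0), M=3)
        assert gi.n_channels == 3
        np.testing.assert_array_equal(gi.data[..., 0], gi.data[..., 1])
        np.testing.assert_array_equal(gi.data[..., 0], gi.data[..., 2])

    def test_perturbed_channels_differ_on_noise_but_agree_on_edges(self, rng):
        noise = gd.Volume(rng.random((24, 24, 24)))
        params = SlicParams(K=27, rng_seed=2)  # sigma_z defaults to S/4
        gi = build_random_guidance(noise, params, M=2)
        assert not np.array_equal(gi.data[..., 0], gi.data[..., 1])
        edge = _two_region_volume(24)
        for seed in (2, 3):
            lab = slic_cluster(edge, replace(params, rng_seed=seed))
            assert _labels_straddling_regions(lab, edge.data) == 0

    def test_multiscale_single_entry_reduction(self, rng):
        vol = gd.Volume(rng.random((16, 16, 16)))
        gi = build_multiscale_guidance(vol, SlicParams(K=64), [27])
        lab = slic_cluster(vol, SlicParams(K=27, sigma_z=0.0))
        np.testing.assert_array_equal(
            gi.data[..., 0], render_channel(vol, lab).data
        )

    def test_multiscale_label_counts_decrease(self, rng):
        vol = gd.Volume(rng.random((24, 24, 24)))
        ladder = [216, 64, 27]
        counts = [
            slic_cluster(vol, SlicParams(K=K, sigma_z=0.0)).n_labels
            for K in ladder
        ]
        assert counts[0] > counts[1] > counts[2]

    def test_multiscale_constant_volume_constant_channels(self):
        vol = gd.Volume(np.full((16, 16, 16), 0.5))
        gi = build_multiscale_guidance(vol, SlicParams(K=64), [64, 27])
        assert np.ptp(gi.data[..., 0]) == 0
        assert np.ptp(gi.data[..., 1]) == 0

    def test_non_monotone_ladder_rejected(self, rng):
        vol = gd.Volume(rng.random((12, 12, 12)))
        with pytest.raises(ValueError, match="monotone"):
            build_multiscale_guidance(vol, SlicParams(), [64, 8, 27])
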