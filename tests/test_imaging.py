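"""Puncta segmentation, density and opposed-puncta colocalization."""

import numpy as np
import pytest

from synprot.errors import ConfigError, SchemaError
from synprot.imaging import (
    ImageStack,
    Punctum,
    colocalize,
    group_percent_change,
    puncta_density,
    puncta_table,
    segment_puncta,
)
from synprot.simulate import generate_image_stack

VOX = (70.0, 100.0, 100.0)


def punctum(z, y, x, channel="A"):
    return Punctum(channel=channel, centroid_nm=(z, y, x), n_voxels=8,
                   volume_um3=8 * 70 * 100 * 100 * 1e-9, slice_span=2)


class TestImageStack:
    def test_shape_and_voxel_validation(self):
        with pytest.raises(SchemaError):
            ImageStack(np.zeros((4, 4)))
        with pytest.raises(ConfigError):
            ImageStack(np.zeros((3, 4, 4)), voxel_size_nm=(70.0, -1.0, 100.0))

    def test_volume(self):
        stack = ImageStack(np.zeros((10, 10, 10)), voxel_size_nm=(1000.0, 1000.0, 1000.0))
        assert stack.volume_um3 == pytest.approx(1000.0)

    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.uniform(size=(5, 8, 8)), voxel_size_nm=VOX)
        path = tmp_path / "c.tif"
        stack.to_tiff(str(path))
        back = ImageStack.from_tiff(str(path), VOX)
        assert np.allclose(back.data, stack.data, atol=1e-6)


class TestSegmentPuncta:
    def test_background_only_stack_yields_no_puncta(self):
        stack = ImageStack(np.zeros((5, 16, 16)), VOX)
        assert segment_puncta(stack) == []
        flat = ImageStack(np.full((5, 16, 16), 7.0), VOX)
        assert segment_puncta(flat) == []

    def test_exact_recovery_on_noiseless_planted_stack(self):
        stacks, truth = generate_image_stack(n_puncta=(50, 40), coloc_fraction=0.0, seed=19)
        for channel, n_expected in (("A", 50), ("B", 40)):
            puncta = segment_puncta(stacks[channel], channel)
            assert len(puncta) == n_expected
            planted = truth[truth["channel"] == channel][["z_nm", "y_nm", "x_nm"]].to_numpy()
            found = np.array([p.centroid_nm for p in puncta])
            # every planted centroid matched within one voxel
            for row in planted:
                dists = np.abs(found - row)
                best = np.argmin((dists**2).sum(axis=1))
                assert np.all(dists[best] <= np.array(VOX))

    def test_single_voxel_speck_removed_by_size_filter(self):
        arr = np.zeros((5, 16, 16))
        arr[2, 8, 8] = 100.0
        stack = ImageStack(arr, VOX)
        assert segment_puncta(stack, min_voxels=2) == []
        assert len(segment_puncta(stack, min_voxels=1)) == 1

    def test_max_voxels_and_min_slices_bounds(self):
        arr = np.zeros((6, 16, 16))
        arr[2:4, 4:6, 4:6] = 100.0  # 8 voxels over 2 slices
        arr[1, 10:12, 10:12] = 100.0  # 4 voxels on one slice
        stack = ImageStack(arr, VOX)
        assert len(segment_puncta(stack)) == 2
        assert len(segment_puncta(stack, max_voxels=5)) == 1
        assert len(segment_puncta(stack, min_slices=2)) == 1

    def test_intensity_scale_invariance(self):
        stacks, _ = generate_image_stack(
            n_puncta=(20, 0), noise_sd=2.0, psf_sigma_nm=60.0, seed=21
        )
        base = segment_puncta(stacks["A"])
        scaled = segment_puncta(
            ImageStack(stacks["A"].data * 137.0, stacks["A"].voxel_size_nm)
        )
        assert [p.centroid_nm for p in base] == [p.centroid_nm for p in scaled]
        assert [p.n_voxels for p in base] == [p.n_voxels for p in scaled]


class TestDensityAndChange:
    def test_forced_density_arithmetic(self):
        stack = ImageStack(np.zeros((10, 10, 10)), voxel_size_nm=(1000.0, 1000.0, 1000.0))
        puncta = [punctum(0, 0, 0)] * 100
        assert puncta_density(puncta, stack) == pytest.approx(0.1)
        assert puncta_density([], stack) == 0.0

    def test_halving_depth_doubles_density(self):
        full = ImageStack(np.zeros((10, 10, 10)), voxel_size_nm=(1000.0, 1000.0, 1000.0))
        half = ImageStack(np.zeros((5, 10, 10)), voxel_size_nm=(1000.0, 1000.0, 1000.0))
        puncta = [punctum(0, 0, 0)] * 10
        assert puncta_density(puncta, half) == pytest.approx(2 * puncta_density(puncta, full))

    def test_group_percent_change(self):
        assert group_percent_change([1.0, 1.0], [1.0]) == pytest.approx(0.0)
        assert group_percent_change([1.0], [1.27]) == pytest.approx(27.0)
        fwd = group_percent_change([1.0], [1.05])
        back = group_percent_change([1.05], [1.0])
        assert fwd == pytest.approx(-back, rel=0.06)  # approximate for small changes
        with pytest.raises(ConfigError):
            group_percent_change([], [1.0])
        with pytest.raises(ConfigError):
            group_percent_change([0.0], [1.0])


class TestColocalize:
    def test_identical_lists_fully_colocalized(self):
        puncta = [punctum(100, 200, 300), punctum(5000, 6000, 7000)]
        assert colocalize(puncta, puncta) == 1.0

    def test_empty_reference_channel(self):
        assert colocalize([], [punctum(0, 0, 0)]) == 0.0
        assert colocalize([punctum(0, 0, 0)], []) == 0.0

    def test_anisotropic_distance_respected(self):
        a = [punctum(0.0, 0.0, 0.0)]
        b_near = [punctum(450.0, 0.0, 0.0, "B")]
        b_far = [punctum(0.0, 600.0, 0.0, "B")]
        assert colocalize(a, b_near, max_distance_nm=500) == 1.0
        assert colocalize(a, b_far, max_distance_nm=500) == 0.0

    def test_planted_fraction_recovered(self):
        stacks, truth = generate_image_stack(n_puncta=(30, 30), coloc_fraction=0.6, seed=23)
        pa = segment_puncta(stacks["A"], "A")
        pb = segment_puncta(stacks["B"], "B")
        assert colocalize(pa, pb, 500.0) == pytest.approx(0.6, abs=1 / 30)

    def test_fully_colocalized_generator(self):
        stacks, _ = generate_image_stack(n_puncta=(25, 25), coloc_fraction=1.0, seed=25)
        pa = segment_puncta(stacks["A"], "A")
        pb = segment_puncta(stacks["B"], "B")
        assert colocalize(pa, pb, 500.0) == 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ConfigError):
            colocalize([punctum(0, 0, 0)], [punctum(0, 0, 0)], max_distance_nm=-1)


def test_puncta_table_columns():
    tab = puncta_table([punctum(70, 100, 100), punctum(140, 200, 200, "B")])
    assert list(tab["channel"]) == ["A", "B"]
    assert set(tab.columns) == {
        "channel", "z_nm", "y_nm", "x_nm", "n_voxels", "volume_um3", "slice_span"
    }
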