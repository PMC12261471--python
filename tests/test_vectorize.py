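"""Betti curves, landscapes and the 1200-D feature vector."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from topolink.topology import (
    ChannelImage,
    PersistenceDiagram,
    ThresholdGrid,
    cubical_persistence,
    euler_characteristic,
)
from topolink.vectorize import (
    TOPO_VECTOR_LENGTH,
    betti_curve,
    block_slices,
    channel_vector,
    image_vector,
    landscape_level1,
    read_feature_table,
    restrict_blocks,
    split_channels,
    triangle_function,
    write_feature_table,
)

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def count_components(mask: np.ndarray) -> int:
    """Independent beta0: 4-connected component labelling."""
    return int(ndimage.label(mask, structure=FOUR_CONN)[1])


def diagram_of(bars, dims, essential=None):
    bars = np.asarray(bars, dtype=np.float64).reshape(-1, 2)
    dims = np.asarray(dims)
    ess = np.zeros(len(bars), bool) if essential is None else np.asarray(essential)
    return PersistenceDiagram(bars[:, 0], bars[:, 1], dims, ess)


class TestTriangleFunction:
    @pytest.mark.parametrize("pair,x,expected", [
        ((100, 200), 150, 50),   # peak = (d-b)/2 at the midpoint
        ((0, 2), 3, 0),          # outside (b, d)
        ((0, 100), 75, 25),      # falling branch: d - x
        ((0, 100), 25, 25),      # rising branch: x - b
        ((50, 50), 50, 0),       # degenerate pair is identically zero
        ((10, 20), 10, 0),       # open at the birth endpoint
    ])
    def test_closed_forms(self, pair, x, expected):
        assert triangle_function(pair, x) == pytest.approx(expected)

    def test_rejects_inverted_pair(self):
        with pytest.raises(ValueError):
            triangle_function((10, 5), 7)

    @given(b=st.floats(0, 250), length=st.floats(0.1, 255), x=st.floats(-10, 300))
    def test_nonnegative_and_bounded_by_half_persistence(self, b, length, x):
        d = min(b + length, 255.0)
        val = triangle_function((b, d), x)
        assert 0.0 <= val <= (d - b) / 2 + 1e-12


class TestBettiCurve:
    def test_empty_diagram_is_zero(self, default_grid):
        d = diagram_of(np.empty((0, 2)), np.empty(0, int))
        assert betti_curve(d, default_grid, 0).tolist() == [0] * 50

    def test_essential_bar_alive_everywhere(self, default_grid):
        d = diagram_of([(0, 255)], [0], [True])
        assert betti_curve(d, default_grid, 0).tolist() == [1] * 50

    def test_nonessential_death_at_255_not_alive_at_endpoint(self, default_grid):
        d = diagram_of([(0, 255)], [1])
        curve = betti_curve(d, default_grid, 1)
        assert curve[0] == 1 and curve[-1] == 0

    def test_rejects_bad_dim(self, default_grid):
        with pytest.raises(ValueError):
            betti_curve(diagram_of(np.empty((0, 2)), np.empty(0, int)),
                        default_grid, 2)

    def test_matches_component_counting_and_euler_identity(self, rng, coarse_grid):
        """beta0 equals independent labelling; beta1 equals beta0 - chi."""
        for _ in range(25):
            vals = rng.integers(0, 256, (8, 8))
            img = ChannelImage(vals)
            d = cubical_persistence(img, coarse_grid)
            b0 = betti_curve(d, coarse_grid, 0)
            b1 = betti_curve(d, coarse_grid, 1)
            for m, t in enumerate(coarse_grid.thresholds):
                mask = vals <= t
                assert b0[m] == count_components(mask)
                assert b1[m] == b0[m] - euler_characteristic(mask)

    def test_full_rectangle_property(self, rng, default_grid):
        vals = rng.integers(0, 256, (10, 10))
        d = cubical_persistence(ChannelImage(vals), default_grid)
        assert betti_curve(d, default_grid, 0)[-1] == 1
        assert betti_curve(d, default_grid, 1)[-1] == 0


class TestLandscape:
    def test_empty_diagram_zero_vector(self):
        d = diagram_of(np.empty((0, 2)), np.empty(0, int))
        assert landscape_level1(d, 0, bins=100).tolist() == [0.0] * 100

    def test_single_pair_peak_near_midpoint(self):
        d = diagram_of([(100, 200)], [0])
        vec = landscape_level1(d, 0, bins=100)
        centers = (np.arange(100) + 0.5) * 2.55
        peak_bin = np.argmin(np.abs(centers - 150))
        assert vec.max() == vec[peak_bin]
        # one bin is at most 2.55 wide, so the sampled peak is within one slope-step
        assert vec[peak_bin] == pytest.approx(50.0, abs=2.55)

    def test_pointwise_max_of_two_tents(self):
        d = diagram_of([(0, 100), (50, 150)], [0, 0])
        xs = np.linspace(0, 255, 1000)
        brute = np.maximum(triangle_function((0, 100), xs),
                           triangle_function((50, 150), xs))
        vec = landscape_level1(d, 0, bins=100)
        centers = (np.arange(100) + 0.5) * 2.55
        expected = np.maximum(triangle_function((0, 100), centers),
                              triangle_function((50, 150), centers))
        assert np.allclose(vec, expected)
        assert vec.max() <= brute.max() + 1e-9
        # lambda1(75) = 25: both tents evaluate to 25 there
        assert triangle_function((0, 100), 75) == triangle_function((50, 150), 75) == 25

    def test_dominates_every_single_tent(self, rng):
        bars = np.sort(rng.uniform(0, 255, (20, 2)), axis=1)
        d = diagram_of(bars, [0] * 20)
        vec = landscape_level1(d, 0, bins=100)
        centers = (np.arange(100) + 0.5) * 2.55
        for b, dd in bars:
            assert np.all(vec >= triangle_function((b, dd), centers) - 1e-12)

    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            landscape_level1(diagram_of(np.empty((0, 2)), np.empty(0, int)), 0, bins=1)


class TestVectors:
    def test_channel_vector_layout(self, default_grid):
        d = diagram_of([(0, 255)], [0], [True])
        vec = channel_vector(d, default_grid)
        assert vec.shape == (300,)
        assert vec[:50].tolist() == [1.0] * 50          # Betti H0 block
        assert vec[50:100].tolist() == [0.0] * 50       # Betti H1 block
        assert vec[100:200].max() > 0                   # landscape H0 block

    def test_image_vector_length_and_identical_channels(self, rng):
        rgb = np.repeat(rng.integers(0, 256, (12, 12, 1)), 3, axis=2).astype(np.uint8)
        vec = image_vector(rgb)
        assert vec.shape == (TOPO_VECTOR_LENGTH,)
        blocks = vec.reshape(4, 300)
        # gray of an achromatic image equals each color channel
        assert np.allclose(blocks[0], blocks[1])
        assert np.allclose(blocks[1], blocks[2])
        assert np.allclose(blocks[2], blocks[3])

    def test_image_vector_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            image_vector(np.zeros((8, 8)))

    def test_grayscale_is_itu601_luminance(self):
        rgb = np.zeros((4, 4, 3), np.uint8)
        rgb[..., 0], rgb[..., 1], rgb[..., 2] = 100, 50, 200
        chans = split_channels(rgb)
        lum = int(np.floor(0.299 * 100 + 0.587 * 50 + 0.114 * 200 + 0.5))
        assert int(chans["gray"].values[0, 0]) == lum

    def test_block_restriction_widths(self, rng):
        full = rng.standard_normal((3, TOPO_VECTOR_LENGTH))
        assert restrict_blocks(full, "betti").shape == (3, 400)
        assert restrict_blocks(full, "landscape").shape == (3, 800)
        assert restrict_blocks(full, "all") is full
        with pytest.raises(ValueError):
            restrict_blocks(full, "fourier")

    def test_block_slices_partition_the_vector(self):
        sl = block_slices()
        covered = np.zeros(TOPO_VECTOR_LENGTH, int)
        for s in sl["betti"] + sl["landscape"]:
            covered[s] += 1
        assert (covered == 1).all()

    def test_feature_table_round_trip(self, tmp_path, rng):
        table = {f"e{i}": rng.standard_normal(TOPO_VECTOR_LENGTH) for i in range(4)}
        path = tmp_path / "features.tsv"
        write_feature_table(path, table)
        loaded = read_feature_table(path)
        assert set(loaded) == set(table)
        for k in table:
            assert np.allclose(loaded[k], table[k])
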