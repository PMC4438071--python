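"""LBP-TOP, LBP-SIP and LBP-MOP on video volumes."""

import numpy as np
import pytest

from stlbp import (
    BlockGrid,
    DegenerateBlockError,
    MOPParams,
    NeighborSpec,
    SIPParams,
    TemporalExtentError,
    TOPParams,
    comparison_count,
    lbp_histogram,
    lbp_mop,
    lbp_sip,
    lbp_top,
    mean_planes,
)

from reference import naive_mop, naive_sip, naive_top


@pytest.fixture
def constant_video():
    return np.full((10, 10, 9), 37.0)


class TestDimensionality:
    @pytest.mark.parametrize(
        "grid,expected", [(BlockGrid(1, 1), 48), (BlockGrid(5, 5), 1200)]
    )
    def test_top_length_is_48_per_block(self, small_video, grid, expected):
        h = lbp_top(small_video, TOPParams(R_t=3, grid=grid))
        assert len(h) == expected

    @pytest.mark.parametrize(
        "grid,expected", [(BlockGrid(1, 1), 20), (BlockGrid(5, 5), 500)]
    )
    def test_sip_length_is_20_per_block(self, small_video, grid, expected):
        h = lbp_sip(small_video, SIPParams(R_t=3, grid=grid))
        assert len(h) == expected

    def test_mop_default_length_matches_top(self, small_video):
        assert len(lbp_mop(small_video, MOPParams())) == 48

    def test_mop_coarse_grid_length(self, rng):
        # 3x3 + 3x2 + 3x2 blocks of 16 bins -> 16 * (9 + 6 + 6) = 336
        video = rng.integers(0, 256, size=(24, 24, 10)).astype(float)
        params = MOPParams(
            grid_xy=BlockGrid(3, 3), grid_xt=BlockGrid(3, 2), grid_yt=BlockGrid(3, 2)
        )
        assert len(lbp_mop(video, params)) == 336


class TestConstantVideo:
    def test_top_all_mass_at_full_code(self, constant_video):
        h = lbp_top(constant_video, TOPParams(R_t=3))
        for plane in ("XY", "XT", "YT"):
            seg = h.segment(f"{plane}.b0_0")
            assert seg[15] == pytest.approx(1.0)

    def test_sip_mass_at_bins_15_and_3(self, constant_video):
        h = lbp_sip(constant_video, SIPParams(R_t=3))
        assert h.segment("XY.b0_0")[15] == pytest.approx(1.0)
        assert h.segment("T.b0_0")[3] == pytest.approx(1.0)


class TestOracleEquivalence:
    """Vectorized descriptors equal naive triple-loop references."""

    @pytest.mark.parametrize("grid", [(1, 1), (2, 2), (3, 2)])
    def test_top(self, small_video, grid):
        got = lbp_top(small_video, TOPParams(R_t=3, grid=BlockGrid(*grid)))
        expected = naive_top(small_video, R_t=3, rows=grid[0], cols=grid[1])
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    @pytest.mark.parametrize("grid", [(1, 1), (2, 2), (3, 2)])
    def test_sip(self, small_video, grid):
        got = lbp_sip(small_video, SIPParams(R_t=3, grid=BlockGrid(*grid)))
        expected = naive_sip(small_video, R_t=3, rows=grid[0], cols=grid[1])
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    def test_mop(self, small_video):
        params = MOPParams(
            grid_xy=BlockGrid(2, 2), grid_xt=BlockGrid(2, 1), grid_yt=BlockGrid(1, 2)
        )
        got = lbp_mop(small_video, params)
        expected = naive_mop(small_video, grids=((2, 2), (2, 1), (1, 2)))
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    def test_top_nonunit_temporal_radius(self, small_video):
        got = lbp_top(small_video, TOPParams(R_t=4))
        expected = naive_top(small_video, R_t=4)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)


def test_sip_spatial_equals_per_frame_lbp(small_video):
    """SIP's spatial neighbor set is exactly the P=4 XY neighborhood, so its
    spatial histogram equals core 2-D LBP accumulated over interior frames."""
    R_t = 3
    h = lbp_sip(small_video, SIPParams(R_t=R_t))
    counts = np.zeros(16)
    for t in range(R_t, small_video.shape[2] - R_t):
        frame_hist = lbp_histogram(
            small_video[:, :, t], NeighborSpec(4, 1), normalize=False
        )
        counts += frame_hist.values
    np.testing.assert_allclose(h.segment("XY.b0_0"), counts / counts.sum(), atol=1e-12)


def test_top_neighbor_union_is_six_intersection_points():
    """At equal radii the union of TOP's three 4-neighbor sets has exactly six
    unique members — SIP's intersection points on the three axes."""
    plane_axes = {"XY": (0, 1), "XT": (1, 2), "YT": (0, 2)}  # (dy,dx,dt) indices
    union = set()
    per_plane = {}
    for plane, (a, b) in plane_axes.items():
        pts = set()
        for drow, dcol in NeighborSpec(4, 1).offsets():
            off = [0, 0, 0]
            off[b], off[a] = int(dcol), int(drow)
            pts.add(tuple(off))
        per_plane[plane] = pts
        union |= pts
    expected = {
        (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1)
    }
    assert union == expected
    # every point is shared by exactly two planes ("computed twice")
    for pt in union:
        assert sum(pt in pts for pts in per_plane.values()) == 2


def test_temporal_reversal_permutes_sip_temporal_bins(small_video):
    """Reversing frame order swaps past/future bits: bins map 0->0, 1<->2, 3->3;
    the spatial segment is unchanged."""
    params = SIPParams(R_t=3)
    fwd = lbp_sip(small_video, params)
    rev = lbp_sip(small_video[:, :, ::-1], params)
    np.testing.assert_allclose(
        rev.segment("XY.b0_0"), fwd.segment("XY.b0_0"), atol=1e-12
    )
    np.testing.assert_allclose(
        rev.segment("T.b0_0"), fwd.segment("T.b0_0")[[0, 2, 1, 3]], atol=1e-12
    )


class TestMeanPlanes:
    def test_static_video_xy_mean_is_the_frame(self, random_image):
        video = np.repeat(random_image[:, :, None], 7, axis=2)
        planes = mean_planes(video)
        np.testing.assert_allclose(planes.xy_mean, random_image, atol=1e-9)

    def test_ramp_video_closed_form(self):
        h, w, l = 6, 5, 8
        video = np.broadcast_to(np.arange(l, dtype=float), (h, w, l)).copy()
        planes = mean_planes(video)
        np.testing.assert_allclose(planes.xy_mean, (l - 1) / 2, atol=1e-9)
        np.testing.assert_allclose(
            planes.xt_mean, np.broadcast_to(np.arange(l, dtype=float), (w, l)), atol=1e-9
        )

    def test_shape_contract(self, rng):
        video = rng.random((6, 5, 8))
        planes = mean_planes(video)
        assert planes.xy_mean.shape == (6, 5)
        assert planes.xt_mean.shape == (5, 8)
        assert planes.yt_mean.shape == (6, 8)


def test_mop_xy_segment_invariant_to_frame_permutation(small_video, rng):
    params = MOPParams()
    base = lbp_mop(small_video, params)
    shuffled = lbp_mop(small_video[:, :, rng.permutation(small_video.shape[2])], params)
    np.testing.assert_allclose(
        shuffled.segment("XY.b0_0"), base.segment("XY.b0_0"), atol=1e-12
    )


def test_mop_static_video_xy_equals_single_frame_histogram(random_image):
    video = np.repeat(random_image[:, :, None], 7, axis=2)
    h = lbp_mop(video, MOPParams())
    frame = lbp_histogram(random_image, NeighborSpec(4, 1))
    np.testing.assert_allclose(h.segment("XY.b0_0"), frame.values, atol=1e-12)


@pytest.mark.parametrize("descriptor,params", [
    (lbp_top, TOPParams(R_t=3)),
    (lbp_sip, SIPParams(R_t=3)),
    (lbp_mop, MOPParams()),
])
def test_gray_shift_invariance(small_video, descriptor, params):
    base = descriptor(small_video, params)
    shifted = descriptor(small_video + 41.0, params)
    np.testing.assert_allclose(shifted.values, base.values, atol=1e-12)


class TestComplexity:
    @pytest.mark.parametrize("w,h,l", [(10, 10, 10), (7, 9, 11)])
    def test_closed_forms(self, w, h, l):
        assert comparison_count("top", w, h, l) == 12 * w * h * l
        assert comparison_count("sip", w, h, l) == 6 * w * h * l
        assert comparison_count("mop", w, h, l) == 4 * (w * h + w * l + h * l)

    def test_instrumented_counts_match_closed_forms(self, small_video):
        h, w, l = small_video.shape
        top = lbp_top(small_video, TOPParams(R_t=3), full_volume=True)
        sip = lbp_sip(small_video, SIPParams(R_t=3), full_volume=True)
        mop = lbp_mop(small_video, MOPParams(), full_volume=True)
        assert top.meta["comparisons"] == comparison_count("top", w, h, l)
        assert sip.meta["comparisons"] == comparison_count("sip", w, h, l)
        assert mop.meta["comparisons"] == comparison_count("mop", w, h, l)

    def test_sip_costs_exactly_half_of_top(self, small_video):
        top = lbp_top(small_video, TOPParams(R_t=3), full_volume=True)
        sip = lbp_sip(small_video, SIPParams(R_t=3), full_volume=True)
        assert 2 * sip.meta["comparisons"] == top.meta["comparisons"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            comparison_count("vlbp", 5, 5, 5)


class TestErrors:
    def test_short_video_raises_temporal_extent(self, rng):
        video = rng.random((10, 10, 5))
        with pytest.raises(TemporalExtentError):
            lbp_top(video, TOPParams(R_t=3))

    def test_mop_degenerate_block_names_plane(self, rng):
        video = rng.random((20, 20, 9))
        params = MOPParams(grid_yt=BlockGrid(3, 9))  # YT plane is 20x9, interior 18x7
        with pytest.raises(DegenerateBlockError, match="YT"):
            lbp_mop(video, params)

    def test_fractional_sip_temporal_radius_rejected(self, small_video):
        with pytest.raises(ValueError):
            lbp_sip(small_video, SIPParams(R_t=2.5))
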