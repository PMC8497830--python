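"""Tests for the tile-triage signal-detection procedure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.morphology import disk

from mlsfm import triage as tri
from mlsfm.acquisition import TileStack


def brute_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening straight from the definition: minimum then maximum
    over the disc structuring element, ignoring out-of-image positions."""
    fp = disk(radius).astype(bool)
    offs = np.argwhere(fp) - radius
    h, w = img.shape

    def scan(a, reducer, pad_value):
        p = np.pad(a.astype(float), radius, constant_values=pad_value)
        stack = [
            p[radius + di : radius + di + h, radius + dj : radius + dj + w]
            for di, dj in offs
        ]
        return reducer(stack, axis=0)

    return scan(scan(img, np.min, np.inf), np.max, -np.inf)


class TestMip:
    def test_single_plane_identity(self):
        plane = np.arange(12, dtype=np.uint16).reshape(1, 3, 4)
        np.testing.assert_array_equal(tri.mip_z(plane), plane[0])

    def test_pixelwise_maximum(self, rng):
        stack = rng.integers(0, 1000, size=(7, 10, 11)).astype(np.uint16)
        mip = tri.mip_z(stack)
        for z in range(7):
            assert (mip >= stack[z]).all()
        np.testing.assert_array_equal(mip, stack.max(axis=0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tri.mip_z(np.empty((0, 4, 4)))


class TestRollingBall:
    def test_constant_image(self):
        img = np.full((32, 32), 13.0)
        bg = tri.rolling_ball_background(img, 5)
        np.testing.assert_array_equal(bg, img)

    def test_spike_isolated(self):
        img = np.full((40, 40), 10.0)
        img[20, 20] = 110.0
        bg = tri.rolling_ball_background(img, 5)
        np.testing.assert_array_equal(bg, np.full((40, 40), 10.0))
        residual = img - bg
        assert residual[20, 20] == 100.0 and residual.sum() == 100.0

    def test_broad_plateau_preserved(self):
        img = np.full((48, 48), 5.0)
        img[10:40, 10:40] = 50.0  # plateau much wider than the ball
        bg = tri.rolling_ball_background(img, 5)
        assert bg[24, 24] == 50.0

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            tri.rolling_ball_background(np.zeros((10, 10)), 20)

    @given(
        seed=st.integers(0, 10_000),
        radius=st.integers(1, 7),
    )
    def test_equals_brute_force_opening(self, seed, radius):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2 * radius + 1, 64, size=2))
        img = rng.integers(0, 4096, size=shape).astype(float)
        got = tri.rolling_ball_background(img, radius)
        np.testing.assert_array_equal(got, brute_opening(img, radius))
        assert (got <= img).all()


class TestSubdivide:
    def test_single_window(self):
        assert tri.subdivide((100, 80), (1, 1)) == [
            (slice(0, 100), slice(0, 80))
        ]

    def test_grid_count_and_documented_geometry(self):
        wins = tri.subdivide((400, 400), (4, 4), 0.10)
        assert len(wins) == 16
        ry, rx = wins[0]
        assert rx.stop - rx.start == 109  # ceil(400 / 3.7)
        starts = sorted({w[1].start for w in wins})
        assert starts == [0, 97, 194, 291]

    @given(
        h=st.integers(40, 300),
        w=st.integers(40, 300),
        g=st.integers(1, 5),
        v=st.floats(0.0, 0.5),
    )
    def test_union_covers_every_pixel(self, h, w, g, v):
        wins = tri.subdivide((h, w), (g, g), v)
        assert len(wins) == g * g
        covered = np.zeros((h, w), dtype=bool)
        for ry, rx in wins:
            covered[ry, rx] = True
        assert covered.all()

    def test_overlap_one_rejected(self):
        with pytest.raises(ValueError):
            tri.subdivide((100, 100), (4, 4), 1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "statistic, expected",
        [(125.0, "signal"), (103.0, "no_signal"), (110.0, "uncertain")],
    )
    def test_stated_thresholds(self, statistic, expected):
        stats = tri.SubregionStats(bg_mean=100.0, bg_sd=10.0, signal_statistic=statistic)
        cfg = tri.TriageConfig(high_k=2.0, low_k=0.5)
        assert tri.classify_subregion(stats, cfg) == expected

    def test_snr_arithmetic(self):
        assert tri.SubregionStats(100.0, 10.0, 445.0).snr == pytest.approx(34.5)
        assert tri.SubregionStats(100.0, 10.0, 145.0).snr == pytest.approx(4.5)
        assert tri.SubregionStats(100.0, 10.0, 100.0).snr == 0.0

    def test_zero_sd_snr_is_undefined(self):
        with pytest.raises(ValueError):
            tri.snr_of(np.full((8, 8), 3.0))

    @given(
        mean=st.floats(0.0, 200.0),
        sd=st.floats(0.1, 50.0),
        stat=st.floats(0.0, 500.0),
        bump=st.floats(0.0, 100.0),
    )
    def test_monotone_in_statistic(self, mean, sd, stat, bump):
        """Raising the statistic never demotes the class."""
        order = {"no_signal": 0, "uncertain": 1, "signal": 2}
        cfg = tri.TriageConfig()
        lo = tri.classify_subregion(tri.SubregionStats(mean, sd, stat), cfg)
        hi = tri.classify_subregion(tri.SubregionStats(mean, sd, stat + bump), cfg)
        assert order[hi] >= order[lo]

    @given(
        high_k=st.floats(1.0, 3.0),
        tighter=st.floats(0.0, 3.0),
        seed=st.integers(0, 1000),
    )
    def test_raising_high_k_never_adds_rescans(self, high_k, tighter, seed):
        stats = [
            tri.SubregionStats(100.0, 10.0, float(s))
            for s in np.random.default_rng(seed).uniform(90, 160, size=16)
        ]
        def rescan(k):
            cfg = tri.TriageConfig(high_k=k, low_k=0.5)
            d = tri.TriageDecision(
                "t", [tri.classify_subregion(s, cfg) for s in stats], stats,
                [], k, 0.5,
            )
            return tri.select_rescan_tiles([d], "any_signal")

        assert set(rescan(high_k + tighter)) <= set(rescan(high_k))


class TestRescanSelection:
    def make_decision(self, tile_id, classes):
        stats = [tri.SubregionStats(0.0, 1.0, 0.0)] * len(classes)
        return tri.TriageDecision(tile_id, classes, stats, [], 2.0, 0.5)

    def test_all_clear_gives_empty_list(self):
        ds = [self.make_decision(f"t{i}", ["no_signal"] * 4) for i in range(3)]
        assert tri.select_rescan_tiles(ds) == []

    def test_single_signal_subregion_flags_exactly_that_tile(self):
        ds = [
            self.make_decision("t0", ["no_signal"] * 4),
            self.make_decision("t1", ["no_signal", "signal", "no_signal", "no_signal"]),
        ]
        assert tri.select_rescan_tiles(ds, "any_signal") == ["t1"]

    def test_policy_containment(self, rng):
        classes = ["no_signal", "uncertain", "signal"]
        ds = [
            self.make_decision(f"t{i}", list(rng.choice(classes, size=4)))
            for i in range(20)
        ]
        strict = set(tri.select_rescan_tiles(ds, "any_signal"))
        loose = set(tri.select_rescan_tiles(ds, "signal_or_uncertain"))
        assert strict <= loose


class TestEvaluate:
    def test_perfect_detection(self):
        truth = {"a": True, "b": False, "c": True}
        m = tri.evaluate(["a", "c"], truth)
        assert m.fp_rate == 0.0 and m.fn_rate == 0.0

    def test_fp_counts_rescanned_without_truth(self):
        truth = {f"t{i}": i < 7 for i in range(10)}
        rescan = [f"t{i}" for i in range(8)]  # t7 has no true signal
        m = tri.evaluate(rescan, truth)
        assert m.fp_rate == pytest.approx(0.125)

    def test_fn_denominator_is_all_tiles(self):
        truth = {f"t{i}": i < 5 for i in range(2000)}
        m = tri.evaluate([], truth)
        assert m.fn_rate == pytest.approx(0.0025)  # 5 of 2000 tiles
        assert m.fp_rate is None  # nothing rescanned

    def test_permutation_invariant(self, rng):
        tiles = [f"t{i}" for i in range(50)]
        truth = {t: bool(rng.integers(0, 2)) for t in tiles}
        rescan = [t for t in tiles if rng.random() < 0.4]
        m1 = tri.evaluate(rescan, truth)
        m2 = tri.evaluate(rescan[::-1], dict(reversed(list(truth.items()))))
        assert (m1.fp_rate, m1.fn_rate) == (m2.fp_rate, m2.fn_rate)


class TestTriageTile:
    def test_noise_only_tile_not_flagged(self, rng):
        stack = (rng.normal(100, 2, size=(5, 128, 128))).astype(np.uint16)
        d = tri.triage_tile(stack, tile_id="noise")
        assert not d.has_signal

    def test_bright_structure_flagged(self, rng):
        vol = rng.normal(100, 2, size=(5, 128, 128))
        vol[2, 40:42, 20:100] += 200.0  # a bright axon-like line
        d = tri.triage_tile(vol.astype(np.uint16), tile_id="sig")
        assert d.has_signal
        assert d.tile_snr() > 2.0
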