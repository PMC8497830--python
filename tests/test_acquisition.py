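"""Tests for acquisition planning and the forward imaging simulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mlsfm import acquisition as acq
from mlsfm import phantom as ph
from mlsfm.optics import SheetModel
from mlsfm.pipeline import default_detection_path


def brute_force_tile_count(width, fov, overlap):
    """Place tiles at stride (1-v)F until the bound is covered."""
    n, pos = 1, 0.0
    while pos + fov < width - 1e-9:
        pos += (1.0 - overlap) * fov
        n += 1
    return n


def brute_force_section_count(L, D, o):
    """Image D, cut back to the overlap, repeat until L is covered."""
    n, top = 1, D
    while top < L - 1e-9:
        top += D - o
        n += 1
    return n


class TestMosaicPlanning:
    @pytest.mark.parametrize(
        "width_mm, fov_mm, overlap, expected",
        [
            (4.0, 4.0, 0.05, 1),
            (11.6, 4.0, 0.05, 3),
            (8.0, 4.0, 0.05, 3),
        ],
    )
    def test_tile_counts(self, width_mm, fov_mm, overlap, expected):
        plans = acq.plan_mosaic(
            ((0, width_mm * 1000), (0, width_mm * 1000)),
            (fov_mm * 1000, fov_mm * 1000),
            overlap,
        )
        per_axis = int(math.isqrt(len(plans)))
        assert per_axis**2 == len(plans)
        assert per_axis == expected

    @given(
        width=st.floats(100.0, 5000.0),
        fov=st.floats(50.0, 1500.0),
        overlap=st.floats(0.0, 0.5),
    )
    def test_coverage_and_overlap(self, width, fov, overlap):
        plans = acq.plan_mosaic(((0, width), (0, 100.0)), (fov, fov), overlap)
        ys = sorted({p.y_um for p in plans})
        # union covers the requested bounds
        assert ys[0] <= 0.0 and ys[-1] + fov >= width - 1e-6
        # adjacent tiles overlap by at least the requested fraction
        for a, b in zip(ys, ys[1:]):
            assert (a + fov) - b >= overlap * fov - 1e-6

    def test_matches_brute_force_enumeration(self):
        for width in np.linspace(120, 2400, 25):
            for fov in (100.0, 240.0, 730.0):
                for v in (0.0, 0.05, 0.1, 0.3):
                    plans = acq.plan_mosaic(((0, width), (0, fov)), (fov, fov), v)
                    ys = {p.y_um for p in plans}
                    assert len(ys) == brute_force_tile_count(width, fov, v)

    def test_invalid_fov_rejected(self):
        with pytest.raises(ValueError):
            acq.plan_mosaic(((0, 100), (0, 100)), (0.0, 10.0), 0.05)


class TestSectioning:
    @pytest.mark.parametrize(
        "L, D, o, expected",
        [(1000, 1000, 100, 1), (10000, 1000, 100, 11), (5800, 2000, 100, 3)],
    )
    def test_section_counts(self, L, D, o, expected):
        sched = acq.plan_sections(L, D, o)
        assert sched.n_sections == expected

    def test_matches_brute_force_enumeration(self):
        for L in np.linspace(500, 15000, 30):
            for D in (800.0, 1000.0, 2500.0):
                for o in (0.0, 100.0, 300.0):
                    got = acq.plan_sections(L, D, o).n_sections
                    assert got == brute_force_section_count(L, D, o)

    def test_no_forward_progress_rejected(self):
        with pytest.raises(ValueError):
            acq.plan_sections(5000, 100, 100)


class TestZStacksAndTrigger:
    def test_z_stack_overlap_fraction(self):
        stacks = acq.plan_z_stacks(3000.0, 1000.0, 0.10, z_step_um=2.0)
        for (a0, a1), (b0, b1) in zip(stacks, stacks[1:]):
            assert a1 - b0 == pytest.approx(100.0)  # 10% of stack depth
        assert stacks[-1][1] >= 3000.0 - 1e-9

    @pytest.mark.parametrize(
        "speed, interval, period",
        [(0.08, 2.0, 25.0), (0.1, 2.0, 20.0)],
    )
    def test_trigger_period(self, speed, interval, period):
        got, _ = acq.trigger_schedule(speed, interval)
        assert got == pytest.approx(period)

    def test_motion_blur_length(self):
        # 0.1 mm/s at 30 ms exposure blurs 3 um along z
        _, blur = acq.trigger_schedule(0.1, 2.0, exposure_ms=30.0)
        assert blur == pytest.approx(3.0)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            acq.trigger_schedule(0.0, 2.0)


@pytest.fixture(scope="module")
def bead_grid_stacks(sheet):
    """Noiseless bead-lattice stacks in both illumination modes."""
    grid = ph.generate_bead_grid(
        (40.0, 40.0, 30.0), (40.0, 520.0, 60.0), (1.0, 1.0, 1.0),
        amplitude=2000.0, margin_um=15.0,
    )
    det = default_detection_path(zoom=6.3, sensor_px=64)
    cfg = acq.AcquisitionConfig(
        shot_noise=False, read_noise_sd=0.0, camera_offset=0.0,
        photon_scale=300.0,
    )
    plan = acq.TilePlan(
        "t", 0, x_um=10, y_um=0, fov_y_um=520.0, fov_x_um=40.0,
        z_min_um=2.0, z_max_um=38.0, z_step_um=1.0, zoom=6.3,
    )
    return {
        mode: acq.simulate_stack(grid, plan, det, sheet, mode=mode, config=cfg)
        for mode in ("tiled", "stationary")
    }


@pytest.fixture(scope="module")
def brightness_table(sheet):
    from mlsfm.optics import DetectionPath, ObjectiveSpec

    settings = [
        DetectionPath(
            objective=ObjectiveSpec("o", na, mag), zoom=1.0,
            zoom_range=(0.5, 10.0), sensor_shape_px=(48, 48),
        )
        for na, mag in [
            (0.3, 2.0), (0.4, 2.0), (0.5, 2.0),
            (0.5, 4.0), (0.5, 8.0), (0.4, 6.0), (0.45, 3.0),
        ]
    ]
    return acq.measure_dye_pool_brightness(settings, sheet, level=50.0)


class TestForwardSimulation:
    def test_camera_noise_model_on_empty_phantom(self, sheet):
        """Offset and read noise dominate an empty field: mean ~ offset,
        SD ~ read noise over >= 1e5 pixels."""
        empty = ph.PhantomVolume(
            intensity=np.zeros((5, 120, 120)), voxel_size_um=(2.0, 2.0, 2.0)
        )
        det = default_detection_path(zoom=1.6, sensor_px=320)
        cfg = acq.AcquisitionConfig(camera_offset=100.0, read_noise_sd=2.0)
        plan = acq.TilePlan(
            "t", 0, x_um=0, y_um=0, fov_y_um=det.fov_um[0], fov_x_um=det.fov_um[1],
            z_min_um=2, z_max_um=6, z_step_um=4, zoom=1.6,
        )
        stack = acq.simulate_stack(
            empty, plan, det, sheet, config=cfg, rng=np.random.default_rng(0)
        )
        v = stack.voxels.astype(float)
        assert v.size >= 1e5
        assert v.mean() == pytest.approx(100.0, abs=0.1)
        assert v.std() == pytest.approx(2.0, rel=0.10)

    @staticmethod
    def axial_fwhms(stack):
        from skimage.feature import peak_local_max

        from mlsfm.psf import fit_fwhm

        vol = stack.voxels.astype(float)
        mip = vol.max(axis=0)
        peaks = peak_local_max(mip, min_distance=10, threshold_abs=vol.max() * 0.05)
        rows, fwhms = [], []
        for py, px in peaks:
            f, _ = fit_fwhm(vol[:, py, px], spacing=1.0)
            rows.append(py)
            fwhms.append(f)
        order = np.argsort(rows)
        return np.array(rows)[order], np.array(fwhms)[order]

    def test_axial_fwhm_uniform_in_tiled_mode(self, bead_grid_stacks):
        _, fwhms = self.axial_fwhms(bead_grid_stacks["tiled"])
        assert len(fwhms) >= 8
        assert np.std(fwhms) / np.mean(fwhms) < 0.05

    def test_stationary_mode_degrades_at_fov_edge(self, bead_grid_stacks):
        rows, fwhms = self.axial_fwhms(bead_grid_stacks["stationary"])
        center = fwhms[np.argmin(np.abs(rows - rows.mean()))]
        edge = max(fwhms[0], fwhms[-1])
        assert edge > 1.5 * center

    def test_modes_agree_at_fov_center(self, bead_grid_stacks):
        rows_t, fw_t = self.axial_fwhms(bead_grid_stacks["tiled"])
        rows_s, fw_s = self.axial_fwhms(bead_grid_stacks["stationary"])
        ct = fw_t[np.argmin(np.abs(rows_t - rows_t.mean()))]
        cs = fw_s[np.argmin(np.abs(rows_s - rows_s.mean()))]
        assert cs == pytest.approx(ct, rel=0.05)

    def test_signal_linear_in_exposure_and_intensity(self, sheet):
        pool_1 = ph.generate_dye_pool(50.0, (20.0, 80.0, 80.0))
        pool_2 = ph.generate_dye_pool(100.0, (20.0, 80.0, 80.0))
        det = default_detection_path(zoom=1.6, sensor_px=24)
        cfg = acq.AcquisitionConfig(
            shot_noise=False, read_noise_sd=0.0, camera_offset=0.0,
            photon_scale=10.0,
        )
        plan = acq.TilePlan(
            "t", 0, x_um=10, y_um=10, fov_y_um=det.fov_um[0] / 2,
            fov_x_um=det.fov_um[1] / 2, z_min_um=6, z_max_um=10, z_step_um=4,
            zoom=1.6,
        )
        m1 = acq.simulate_stack(pool_1, plan, det, sheet, config=cfg).voxels.mean()
        m2 = acq.simulate_stack(pool_2, plan, det, sheet, config=cfg).voxels.mean()
        assert m2 / m1 == pytest.approx(2.0, rel=0.01)

    def test_fully_outside_plan_rejected_by_default(self, sheet):
        pool = ph.generate_dye_pool(50.0, (20.0, 80.0, 80.0))
        det = default_detection_path(zoom=1.6, sensor_px=24)
        plan = acq.TilePlan(
            "t", 0, x_um=500.0, y_um=500.0, fov_y_um=40, fov_x_um=40,
            z_min_um=2, z_max_um=6, z_step_um=4, zoom=1.6,
        )
        with pytest.raises(ValueError, match="outside"):
            acq.simulate_stack(pool, plan, det, sheet)


class TestDyePoolBrightness:
    def test_equal_na_over_mag_gives_equal_brightness(self, brightness_table):
        df = brightness_table
        a = df[(df.na == 0.3) & (df.mag == 2.0)].mean_intensity.iloc[0]
        b = df[(df.na == 0.45) & (df.mag == 3.0)].mean_intensity.iloc[0]
        assert a == pytest.approx(b, rel=0.02)  # same NA/Mag ratio
        # brightness depends on the optics only through NA/Mag
        ratio = df.mean_intensity / (df.na / df.mag) ** 2
        assert ratio.std() / ratio.mean() < 0.02

    def test_loglog_slope_is_two(self, brightness_table):
        df = brightness_table
        slope = np.polyfit(np.log(df.na / df.mag), np.log(df.mean_intensity), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)


class TestCostModel:
    def make_plan(self, tile_id="t", n_z=100):
        return acq.TilePlan(
            tile_id, 0, x_um=0, y_um=0, fov_y_um=100, fov_x_um=100,
            z_min_um=0.0, z_max_um=(n_z - 1) * 2.0, z_step_um=2.0, zoom=1.6,
        )

    def test_byte_accounting(self):
        cfg = acq.AcquisitionConfig()
        est = acq.cost_model([self.make_plan()], cfg, (2048, 2048))
        assert est.n_frames == 100
        assert est.n_bytes == 838_860_800

    def test_empty_plan_zero_cost(self):
        est = acq.cost_model([], acq.AcquisitionConfig(), (2048, 2048))
        assert est.n_frames == est.n_bytes == est.n_tiles == 0
        assert est.stage_time_s == est.exposure_time_s == 0.0

    def test_additive_over_disjoint_subsets(self):
        cfg = acq.AcquisitionConfig()
        plans = [self.make_plan(f"t{i}", n_z=10 + i) for i in range(6)]
        whole = acq.cost_model(plans, cfg, (256, 256))
        parts = acq.cost_model(plans[:2], cfg, (256, 256)) + acq.cost_model(
            plans[2:], cfg, (256, 256)
        )
        assert whole == parts

    def test_restricted_pass_proportional_frames(self):
        cfg = acq.AcquisitionConfig()
        plans = [self.make_plan(f"t{i}") for i in range(9)]
        full = acq.cost_model(plans, cfg, (256, 256))
        third = acq.cost_model(plans[:3], cfg, (256, 256))
        assert third.n_frames * 3 == full.n_frames

    def test_sectioning_time_calibration(self):
        est = acq.cost_model([], acq.AcquisitionConfig(), (16, 16), n_cuts=10)
        assert est.sectioning_time_s == pytest.approx(1800.0)  # ~30 min


class TestBoundaryDetection:
    def test_uniform_image_is_empty_field(self):
        assert acq.detect_sample_boundary(np.full((64, 64), 7.0)) is None

    def test_disc_bounding_box(self):
        img = np.zeros((100, 120))
        yy, xx = np.mgrid[:100, :120]
        disc = (yy - 40) ** 2 + (xx - 70) ** 2 <= 20**2
        img[disc] = 100.0
        box = acq.detect_sample_boundary(img, margin_px=0)
        assert abs(box.row_min - 20) <= 1 and abs(box.row_max - 61) <= 1
        assert abs(box.col_min - 50) <= 1 and abs(box.col_max - 91) <= 1

    def test_margin_grows_box_and_clips(self):
        img = np.zeros((50, 50))
        img[20:30, 20:30] = 10.0
        b0 = acq.detect_sample_boundary(img, margin_px=0)
        b5 = acq.detect_sample_boundary(img, margin_px=5)
        assert (b5.row_min, b5.col_min) == (b0.row_min - 5, b0.col_min - 5)
        b100 = acq.detect_sample_boundary(img, margin_px=100)
        assert (b100.row_min, b100.row_max) == (0, 50)
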