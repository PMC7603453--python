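import numpy as np
import pytest

from taskcbct.detectability import (
    DetectabilityConfig,
    DetectabilityMap,
    LocalTransfer,
    TaskFunction,
    build_targets,
    default_task_voxel,
    detectability_index,
    detectability_map,
    local_fisher,
    mtf_nps,
    penalty_grid,
    thread_task_function,
)
from taskcbct.geometry import ViewPose, grid_views
from taskcbct.phantom import MaterialPhantom
from taskcbct.projector import Spectrum, spectrum_preset


@pytest.fixture(scope="module")
def air_cfg():
    return DetectabilityConfig(task_voxel=(32, 32, 32))


@pytest.fixture(scope="module")
def grids(air_cfg):
    n = air_cfg.fft_n
    task = thread_task_function((n, n, n), (0.5, 0.5, 0.5))
    penalty = penalty_grid((n, n, n), neighbor_stride=air_cfg.supersample)
    return task, penalty


class TestMtfNps:
    def test_beta_zero_gives_unit_mtf_and_reciprocal_nps(self):
        rng = np.random.default_rng(0)
        f = rng.random((8, 8, 8)) + 0.1
        r = penalty_grid((8, 8, 8))
        tr = mtf_nps(f, r, beta=0.0)
        assert np.allclose(tr.mtf, 1.0)
        assert np.allclose(tr.nps, 1.0 / f)

    def test_mtf_decreases_monotonically_with_beta(self):
        rng = np.random.default_rng(1)
        f = rng.random((8, 8, 8)) * 10
        r = penalty_grid((8, 8, 8))
        nondc = r > 0
        prev = None
        for beta in (0.0, 1.0, 10.0, 100.0):
            mtf = mtf_nps(f, r, beta).mtf
            if prev is not None:
                assert np.all(mtf[nondc] <= prev[nondc] + 1e-12)
            prev = mtf

    def test_zero_transfer_convention(self):
        f = np.zeros((4, 4, 4))
        tr = mtf_nps(f, penalty_grid((4, 4, 4)), beta=0.0)
        assert np.all(tr.mtf == 0) and np.all(tr.nps == 0)

    def test_mtf_bounded(self):
        rng = np.random.default_rng(2)
        f = rng.random((6, 6, 6)) * 1e4
        tr = mtf_nps(f, penalty_grid((6, 6, 6)), beta=3.0)
        assert tr.mtf.min() >= 0 and tr.mtf.max() <= 1


class TestDetectabilityIndex:
    def _task(self, shape=(8, 8, 8), spacing=1.0):
        axes = [np.fft.fftfreq(n, d=spacing) for n in shape]
        fx, fy, fz = np.meshgrid(*axes, indexing="ij")
        mag = np.exp(-((np.sqrt(fx**2 + fy**2 + fz**2) - 0.25) ** 2) / 0.02)
        mag[0, 0, 0] = 0
        return TaskFunction(mag, *axes)

    def test_constant_nps_closed_form(self):
        """MTF=1, NPS=c: d2 = (sum W^2 df^3) / c exactly."""
        task = self._task()
        c = 0.37
        tr = LocalTransfer(np.ones((8, 8, 8)), np.full((8, 8, 8), c), (0, 0, 0))
        expected = (task.magnitude**2).sum() * task.df3 / c
        assert detectability_index(tr, task) == pytest.approx(expected, rel=1e-10)

    def test_task_scaling_homogeneity(self):
        task = self._task()
        rng = np.random.default_rng(3)
        f = rng.random((8, 8, 8)) + 0.5
        tr = mtf_nps(f, penalty_grid((8, 8, 8)), beta=2.0)
        d2 = detectability_index(tr, task)
        scaled = TaskFunction(3.0 * task.magnitude, task.f_x, task.f_y, task.f_z)
        assert detectability_index(tr, scaled) == pytest.approx(9.0 * d2, rel=1e-10)

    def test_matches_triple_sum_oracle(self):
        """Random 8^3 grids agree with an explicit elementwise triple sum."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            f = rng.random((8, 8, 8)) * 10 + 0.01
            r = penalty_grid((8, 8, 8))
            beta = rng.uniform(0, 5)
            task = self._task()
            tr = mtf_nps(f, r, beta)
            num = den = 0.0
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        core = tr.mtf[i, j, k] ** 2 * task.magnitude[i, j, k] ** 2
                        num += core * task.df3
                        den += tr.nps[i, j, k] * core * task.df3
            expected = num**2 / den
            assert detectability_index(tr, task) == pytest.approx(expected, rel=1e-10)

    def test_zero_task_returns_zero(self):
        task = self._task()
        zero_task = TaskFunction(np.zeros_like(task.magnitude), task.f_x, task.f_y, task.f_z)
        tr = LocalTransfer(np.ones((8, 8, 8)), np.ones((8, 8, 8)), (0, 0, 0))
        assert detectability_index(tr, zero_task) == 0.0


class TestLocalFisher:
    def test_zero_fluence_gives_zero_information(self, geom, air_phantom, air_cfg):
        sp = Spectrum((60.0,), (1e-30,))  # vanishing fluence
        f = local_fisher(air_phantom, geom, [ViewPose(0, 90)], air_cfg, sp)
        assert f.max() < 1e-12

    def test_linear_in_fluence(self, geom, air_phantom, air_cfg):
        f1 = local_fisher(air_phantom, geom, [ViewPose(40, 90)], air_cfg,
                          spectrum_preset("mono60", 1e5))
        f2 = local_fisher(air_phantom, geom, [ViewPose(40, 90)], air_cfg,
                          spectrum_preset("mono60", 2e5))
        assert np.allclose(f2, 2 * f1, rtol=1e-9)

    def test_single_view_matches_per_pixel_oracle(self, geom, air_phantom, air_cfg):
        """The accumulated patch equals an explicit per-pixel loop over the
        analytic blob footprint/backprojection, so its DFT matches too."""
        from taskcbct.detectability import BLOB_SIGMA_VOX
        from taskcbct.geometry import pose_to_matrix
        from taskcbct.projector import pixel_rays

        pose = ViewPose(25, 95)
        sp = spectrum_preset("mono60", 1e5)
        f_impl = local_fisher(air_phantom, geom, [pose], air_cfg, sp)

        # oracle: loop over every detector pixel, analytic Gaussian line
        # integrals, Gaussian window (independent code path, plain loops)
        matrix = pose_to_matrix(geom, pose)
        h = air_cfg.roi_halfwidth_vox
        sub = air_cfg.supersample
        sigma = BLOB_SIGMA_VOX
        j_center = air_phantom.voxel_center(np.array(air_cfg.task_voxel))
        n = 2 * h * sub + 1
        offs = (np.arange(n) - h * sub) / sub
        patch = np.zeros((n, n, n))
        line = np.sqrt(2 * np.pi) * sigma
        src, dirs = pixel_rays(matrix, geom.detector_rows, geom.detector_cols)
        rel = j_center - src
        foot = []
        for d in dirs:
            t = d @ rel
            rho2 = rel @ rel - t * t
            foot.append(line * np.exp(-0.5 * rho2 / sigma**2))
        a_max = max(foot)
        for d, a in zip(dirs, foot):
            if a <= a_max * 1e-4:  # footprint truncation rule
                continue
            w = 1e5  # air: expected counts = total fluence
            for ix, ox in enumerate(offs):
                for iy, oy in enumerate(offs):
                    for iz, oz in enumerate(offs):
                        r = np.sqrt(ox * ox + oy * oy + oz * oz)
                        if r > h:
                            continue
                        c = j_center + np.array([ox, oy, oz])
                        relc = c - src
                        tc = d @ relc
                        rc2 = relc @ relc - tc * tc
                        if rc2 >= (4.5 * sigma) ** 2:  # ridge truncation rule
                            continue
                        ridge = line * np.exp(-0.5 * rc2 / sigma**2)
                        win = np.exp(-0.5 * (r / (h / 2.5)) ** 2)
                        patch[ix, iy, iz] += win * ridge * w * a
        n_fft = air_cfg.fft_n
        f_oracle = np.abs(np.fft.fftn(patch, s=(n_fft,) * 3, axes=(0, 1, 2)))
        assert np.allclose(f_impl, f_oracle, rtol=1e-6, atol=1e-6 * f_oracle.max())

    def test_roi_must_fit(self, geom, air_phantom, spectrum):
        cfg = DetectabilityConfig(task_voxel=(2, 32, 32))
        with pytest.raises(ValueError):
            local_fisher(air_phantom, geom, [ViewPose(0, 90)], cfg, spectrum)


class TestDetectabilityMapOps:
    def test_air_map_rotationally_symmetric(self, geom, air_phantom, air_cfg, grids):
        """Per-view d2 of an all-air scene is phi-constant at fixed theta."""
        task, penalty = grids
        sp = spectrum_preset("poly5", 1e5)
        vals = []
        for phi in [0, 18, 45, 77, 130, 222, 301]:
            f = local_fisher(air_phantom, geom, [ViewPose(phi, 90)], air_cfg, sp)
            tr = mtf_nps(f, penalty, air_cfg.beta * sp.total_fluence)
            vals.append(detectability_index(tr, task))
        vals = np.array(vals)
        assert (vals.max() - vals.min()) / vals.mean() < 0.01

    def test_screw_axis_views_score_lowest(self, geom, phantom, grids):
        """d2 along the screws' long axes is far below the orthogonal view:
        the mechanism that makes the planner avoid metal-heavy views."""
        task, penalty = grids
        sp = spectrum_preset("poly5", 1e5)
        cfg = DetectabilityConfig()
        d2 = {}
        for name, pose in [("parallel", ViewPose(90, 90)),
                           ("orthogonal", ViewPose(0, 90))]:
            f = local_fisher(phantom, geom, [pose], cfg, sp)
            tr = mtf_nps(f, penalty, cfg.beta * sp.total_fluence)
            d2[name] = detectability_index(tr, task)
        assert d2["parallel"] < d2["orthogonal"]

    def test_fluence_monotonicity(self, geom, phantom, grids):
        """More photons never reduce detectability (beta > 0)."""
        task, penalty = grids
        cfg = DetectabilityConfig()
        vals = []
        for fluence in (5e4, 1e5, 4e5):
            sp = spectrum_preset("poly5", fluence)
            f = local_fisher(phantom, geom, [ViewPose(30, 90)], cfg, sp)
            tr = mtf_nps(f, penalty, cfg.beta * sp.total_fluence)
            vals.append(detectability_index(tr, task))
        assert vals[0] < vals[1] < vals[2]

    def test_cumulative_mode_with_empty_acquired_equals_per_view(
        self, geom, air_phantom, air_cfg
    ):
        sp = spectrum_preset("mono60", 1e5)
        views = [ViewPose(0, 90), ViewPose(10, 90)]
        import dataclasses

        per = detectability_map(air_phantom, geom, views, sp, air_cfg)
        cum = detectability_map(
            air_phantom, geom, views, sp,
            dataclasses.replace(air_cfg, mode="cumulative"), acquired_views=(),
        )
        assert np.allclose(per.d2, cum.d2, rtol=1e-12)

    def test_default_task_voxel_sits_on_first_screw(self, phantom):
        j = default_task_voxel(phantom)
        assert phantom.labels[j] == 3  # titanium


class TestBuildTargets:
    def _map(self):
        phis = np.arange(0.0, 360.0, 5.0)
        thetas = np.arange(45.0, 140.0, 5.0)
        rng = np.random.default_rng(9)
        return DetectabilityMap(rng.random((len(phis), len(thetas))), phis, thetas)

    def test_vector_length_is_eleven(self):
        assert len(build_targets(self._map(), ViewPose(0, 90))) == 11

    def test_constant_map_gives_constant_vector(self):
        phis = np.arange(0.0, 360.0, 5.0)
        thetas = np.arange(45.0, 140.0, 5.0)
        m = DetectabilityMap(np.full((len(phis), len(thetas)), 0.7), phis, thetas)
        assert np.allclose(build_targets(m, ViewPose(10, 90)), 0.7)

    def test_exact_row_extraction(self):
        """Hand-built map: targets are exactly the (phi+5) row at the 11
        theta offsets in ascending order."""
        m = self._map()
        pose = ViewPose(30, 90)
        got = build_targets(m, pose)
        i = list(m.phi_deg).index(35.0)
        for k, delta in enumerate(range(-25, 30, 5)):
            j = list(m.theta_deg).index(90.0 + delta)
            assert got[k] == m.d2[i, j]

    def test_off_grid_target_raises(self):
        with pytest.raises(KeyError):
            build_targets(self._map(), ViewPose(0, 47))  # theta off-grid

    def test_wraps_phi_across_360(self):
        m = self._map()
        got = build_targets(m, ViewPose(355, 90))
        i = list(m.phi_deg).index(0.0)
        j = list(m.theta_deg).index(65.0)
        assert got[0] == m.d2[i, j]


def test_task_function_invariants():
    t = thread_task_function((16, 16, 16), (1.0, 1.0, 1.0))
    assert t.magnitude[0, 0, 0] == 0.0
    assert t.magnitude.min() >= 0
    # peak near the thread frequency 1/3 cycles/mm
    fx = np.fft.fftfreq(16, d=1.0)
    radial = t.magnitude[:, 0, 0]
    assert abs(abs(fx[np.argmax(radial)]) - 1 / 3) < 0.07
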