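import math

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad

from shgqpm.optics import OpticalConfig, beam_geometry
from shgqpm.spectral import (
    DFFTConfig,
    SpectralComponents,
    analytic_components,
    analytic_prism_lattice,
    analytic_square_wave,
    dfft_1d,
    dfft_3d,
    dft_1d_reference,
    dft_3d_reference,
    gaussian_piece_integral,
    prune,
    select_index_ranges,
)
from shgqpm.structure import (
    FibrilModel,
    PrismLattice,
    SquareWave1D,
    VoxelVolume,
    apply_focal_window,
    prism_lattice_volume,
    square_wave_volume,
    voxelize,
)

SMALL_BOX = (400.0, 400.0, 800.0)


def adaptive_quad_transform(f, lo, hi, k, points):
    """Independent oracle: scipy adaptive quadrature of f(u) e^{-iku}."""
    pts = [p for p in points if lo < p < hi]
    re = quad(lambda u: f(u) * math.cos(k * u), lo, hi, points=pts, limit=400)[0]
    im = quad(lambda u: -f(u) * math.sin(k * u), lo, hi, points=pts, limit=400)[0]
    return re + 1j * im


@pytest.fixture(scope="module")
def periodic_wave():
    """Square wave spanning exactly 20 periods (harmonics on the grid)."""
    return SquareWave1D(width=200.0, period=400.0, length=8000.0)


@pytest.fixture(scope="module")
def windowed_1d(geom800):
    """The windowed validation profile: samples, boundaries, domain."""
    wave = SquareWave1D(length=6.0 * geom800.w_z)
    vol = square_wave_volume(wave, 300)
    z = vol.axis_coords(2)
    samples = vol.values[0, 0, :] * np.exp(-(z**2) / geom800.w_z**2)
    return wave, samples


class TestDFFT1D:
    def test_constant_profile_zero_frequency(self):
        c = 0.7
        out = dfft_1d(np.full(64, c), [], DFFTConfig(), np.array([0.0]),
                      domain=(0.0, 512.0))
        assert out[0] == pytest.approx(c * 512.0, rel=1e-12)

    def test_square_wave_matches_sinc_series_harmonics(self, periodic_wave):
        # 20 exact periods: harmonic q_j lands on grid index l = 20 j
        H = periodic_wave.length
        vol = square_wave_volume(periodic_wave, 320)
        j = np.arange(1, 11)
        freqs = 2.0 * math.pi * j / periodic_wave.period
        out = dfft_1d(vol.values[0, 0, :], periodic_wave.boundaries(),
                      DFFTConfig(), freqs, domain=(-H / 2, H / 2)) / H
        expected = 2.0 * np.sin(math.pi * j / 2.0) / (math.pi * j)
        mask = j % 2 == 1
        assert np.allclose(out[mask].real, expected[mask], rtol=5e-3)
        assert np.all(np.abs(out[~mask]) < 5e-3)

    def test_matches_adaptive_quadrature_on_windowed_profile(
        self, geom800, windowed_1d
    ):
        wave, samples = windowed_1d
        H = wave.length
        freqs = np.array([-0.05, -0.0157, -0.002, 0.0, 0.008])
        out = dfft_1d(samples, wave.boundaries(), DFFTConfig(), freqs,
                      domain=(-H / 2, H / 2))

        def f(z):
            return float(wave.sample(np.array(z))) * math.exp(
                -(z**2) / geom800.w_z**2
            )

        scale = np.max(np.abs(out))
        for i, k in enumerate(freqs):
            oracle = adaptive_quad_transform(f, -H / 2, H / 2, k,
                                             wave.boundaries())
            assert abs(out[i] - oracle) / scale < 1e-3

    def test_quadrature_order_convergence(self, windowed_1d, geom800):
        wave, samples = windowed_1d
        H = wave.length
        freqs = np.array([-0.0157, -0.0471])
        _, ana = analytic_square_wave(wave, window=(geom800.w_z, 1.0), freqs=freqs)

        def err(q):
            out = dfft_1d(samples, wave.boundaries(), DFFTConfig(quad_order=q),
                          freqs, domain=(-H / 2, H / 2)) / H
            return float(np.max(np.abs(out - ana)) / np.max(np.abs(ana)))

        # error falls with quadrature order until the interpolation floor
        assert err(2) > 10.0 * err(128)
        assert err(128) < 1e-3

    def test_linearity(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=80)
        g = rng.normal(size=80)
        freqs = np.array([0.0, 0.01, 0.03])
        bnds = [250.0, 700.0]
        cfg = DFFTConfig()
        dom = (0.0, 2000.0)
        lhs = dfft_1d(2.0 * f - 3.0 * g, bnds, cfg, freqs, domain=dom)
        rhs = 2.0 * dfft_1d(f, bnds, cfg, freqs, domain=dom) - 3.0 * dfft_1d(
            g, bnds, cfg, freqs, domain=dom
        )
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_batched_application(self):
        rng = np.random.default_rng(1)
        batch = rng.normal(size=(5, 64))
        freqs = np.array([0.0, 0.02])
        out = dfft_1d(batch, [], DFFTConfig(), freqs, domain=(0.0, 640.0))
        for i in range(5):
            row = dfft_1d(batch[i], [], DFFTConfig(), freqs, domain=(0.0, 640.0))
            assert np.allclose(out[i], row)


class TestDFFT3D:
    def test_empty_volume_gives_zero_components(self):
        vol = VoxelVolume(values=np.zeros((8, 8, 16)), box=(100.0, 100.0, 200.0))
        comps = dfft_3d(vol, None, DFFTConfig(), ((-2, 2), (-2, 2), (-4, 4)))
        assert np.all(comps.G == 0)

    def test_negated_volume_negates_components(self, small_model, geom800):
        vol = voxelize(small_model, (8, 16, 32))
        w = apply_focal_window(vol, geom800)
        neg = VoxelVolume(values=-w.values, box=w.box, windowed=True,
                          window_a=w.window_a, lambda_window=w.lambda_window)
        r = ((-2, 2), (-2, 2), (-4, 4))
        a = dfft_3d(w, small_model, DFFTConfig(), r)
        b = dfft_3d(neg, small_model, DFFTConfig(), r)
        assert np.allclose(b.G, -a.G, rtol=1e-12, atol=1e-15)

    def test_conjugate_symmetry_for_real_structure(self, small_model, geom800):
        vol = voxelize(small_model, (16, 16, 32))
        w = apply_focal_window(vol, geom800)
        comps = dfft_3d(w, small_model, DFFTConfig(), ((-8, 8), (-8, 8), (-16, 16)))
        assert comps.conjugate_symmetry_error() < 1e-10

    def test_zero_component_is_structure_mean(self, small_model):
        vol = voxelize(small_model, (16, 16, 32))
        comps = dfft_3d(vol, small_model, DFFTConfig(), ((-1, 1), (-1, 1), (-1, 1)))
        # integral of the exact geometry, not the rasterized mean
        area = sum(
            pol * math.pi * r**2 for _, _, r, pol in small_model.fibrils
        )
        _, W, H = small_model.box
        # coarse 25 nm pitch leaves sub-pitch chord slivers unsampled, so
        # the agreement is a few percent at this resolution
        assert comps.get(0, 0, 0) == pytest.approx(area / (W * H), rel=0.05)

    def test_prism_instance_matches_quadrature_oracle(self, geom800):
        lattice = PrismLattice(
            box=SMALL_BOX, motif=(120.0, 120.0, 120.0),
            periods=(200.0, 200.0, 250.0)
        )
        vol = prism_lattice_volume(lattice, (16, 16, 32))
        w = apply_focal_window(vol, geom800)
        comps = dfft_3d(w, lattice, DFFTConfig(), ((-8, 8), (-8, 8), (-16, 16)))
        mag = np.abs(comps.G)
        top = np.argsort(mag.ravel())[::-1][:50]
        waists = (geom800.w_rho, geom800.w_rho, geom800.w_z)
        cache = [{}, {}, {}]

        def axis_factor(axis, m):
            if m not in cache[axis]:
                k = 2.0 * math.pi * m / SMALL_BOX[axis]
                waist = waists[axis]
                half = lattice.motif[axis] / 2.0
                val = 0.0 + 0.0j
                for c in lattice.centers(axis):
                    val += adaptive_quad_transform(
                        lambda u: math.exp(-(u**2) / waist**2),
                        c - half, c + half, k, [],
                    )
                cache[axis][m] = val / SMALL_BOX[axis]
            return cache[axis][m]

        for ix in top:
            i, j, k = np.unravel_index(ix, mag.shape)
            oracle = (
                axis_factor(0, i + comps.m_start)
                * axis_factor(1, j + comps.n_start)
                * axis_factor(2, k + comps.l_start)
            )
            assert abs(comps.G[i, j, k] - oracle) / mag.max() < 5e-3

    def test_cylinder_instance_converges_to_quadrature_oracle(
        self, small_model, geom800
    ):
        """Chord profiles have sqrt kinks at disk tangent points, so the
        separable DFFT converges first-order in the voxel pitch; at the
        refined grid it agrees with the polar-quadrature oracle to <0.5%."""
        L, W, H = small_model.box
        xr, wr = leggauss(64)
        xa, wa = leggauss(128)

        def oracle(m, n, l):
            km = 2 * math.pi * m / L
            kn = 2 * math.pi * n / W
            kl = 2 * math.pi * l / H
            tx = adaptive_quad_transform(
                lambda x: math.exp(-(x**2) / geom800.w_rho**2),
                -L / 2, L / 2, km, [],
            )
            tot = 0.0 + 0.0j
            for cy, cz, r, pol in small_model.fibrils:
                rho = 0.5 * r * (xr + 1.0)
                wrho = 0.5 * r * wr
                ang = math.pi * (xa + 1.0)
                wang = math.pi * wa
                RR, AA = np.meshgrid(rho, ang, indexing="ij")
                Y = cy + RR * np.cos(AA)
                Z = cz + RR * np.sin(AA)
                f = (
                    np.exp(-(Y**2) / geom800.w_rho**2 - Z**2 / geom800.w_z**2)
                    * np.exp(-1j * (kn * Y + kl * Z))
                    * RR
                )
                tot += pol * np.einsum("ij,i,j->", f, wrho, wang)
            return tx * tot / (L * W * H)

        errs = {}
        for dims in [(16, 16, 32), (64, 64, 128)]:
            vol = voxelize(small_model, dims)
            w = apply_focal_window(vol, geom800)
            comps = dfft_3d(w, small_model, DFFTConfig(),
                            ((-8, 8), (-8, 8), (-16, 16)))
            mag = np.abs(comps.G)
            top = np.argsort(mag.ravel())[::-1][:50]
            worst = 0.0
            for ix in top:
                i, j, k = np.unravel_index(ix, mag.shape)
                o = oracle(i + comps.m_start, j + comps.n_start,
                           k + comps.l_start)
                worst = max(worst, abs(comps.G[i, j, k] - o) / mag.max())
            errs[dims] = worst
        assert errs[(64, 64, 128)] < 5e-3
        assert errs[(16, 16, 32)] > 2.0 * errs[(64, 64, 128)]

    def test_box_mismatch_rejected(self, small_model):
        vol = VoxelVolume(values=np.zeros((8, 8, 8)), box=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            dfft_3d(vol, small_model, DFFTConfig())


class TestReferenceDFT:
    def test_constant_volume_single_component(self):
        vol = VoxelVolume(values=np.full((8, 8, 8), 2.0), box=(80.0,) * 3)
        comps = dft_3d_reference(vol)
        assert comps.get(0, 0, 0) == pytest.approx(2.0)
        G = comps.G.copy()
        G[4, 4, 4] = 0.0
        assert np.max(np.abs(G)) < 1e-12

    def test_magnitudes_match_dfft_on_smooth_volume(self, geom800):
        # centred Gaussian blob: smooth, so both transforms see the same
        # spectrum up to the corner-vs-centre phase reference
        dims = (16, 16, 32)
        box = SMALL_BOX
        vol = VoxelVolume(values=np.zeros(dims), box=box)
        x = vol.axis_coords(0)[:, None, None]
        y = vol.axis_coords(1)[None, :, None]
        z = vol.axis_coords(2)[None, None, :]
        vol.values[:] = np.exp(
            -(x**2 + y**2) / 120.0**2 - z**2 / 240.0**2
        )
        ref = dft_3d_reference(vol)
        r = ((-3, 3), (-3, 3), (-3, 3))
        comps = dfft_3d(vol, None, DFFTConfig(), r)
        # align index blocks
        i0 = -3 - ref.m_start
        j0 = -3 - ref.n_start
        k0 = -3 - ref.l_start
        ref_block = ref.G[i0 : i0 + 7, j0 : j0 + 7, k0 : k0 + 7]
        scale = np.max(np.abs(comps.G))
        assert np.max(np.abs(np.abs(ref_block) - np.abs(comps.G))) / scale < 0.01

    def test_corner_phase_reference_alternates_sign(self, windowed_1d):
        # undoing the (-1)^l corner factor recovers the centre-referenced
        # transform; without it the components ring at every harmonic
        wave, samples = windowed_1d
        H = wave.length
        G_fft, l0 = dft_1d_reference(samples)
        l = np.arange(l0, l0 + samples.size)
        k = 2.0 * math.pi * l / H
        sel = (np.abs(k) < 0.06) & (np.abs(G_fft) > 1e-4)
        G_dfft = dfft_1d(samples, wave.boundaries(), DFFTConfig(), k[sel],
                         domain=(-H / 2, H / 2)) / H
        pitch = H / samples.size
        aligned = G_fft[sel] * (-1.0) ** l[sel] * np.exp(-1j * k[sel] * pitch / 2)
        raw_err = np.max(np.abs(G_fft[sel] - G_dfft))
        fixed_err = np.max(np.abs(aligned - G_dfft))
        assert fixed_err < 0.1 * raw_err


class TestAnalyticComponents:
    def test_half_duty_square_wave_has_no_even_harmonics(self):
        wave = SquareWave1D(width=200.0, period=400.0, length=8000.0)
        q, c = analytic_components("square_wave_1d", {"wave": wave}, None, None)
        j = np.round(q * 400.0 / (2 * math.pi)).astype(int)
        even = (j % 2 == 0) & (j != 0)
        fundamental = np.max(np.abs(c))
        assert fundamental == pytest.approx(2.0 / math.pi, rel=1e-12)
        assert np.all(np.abs(c[even]) < 1e-10 * fundamental)

    def test_motif_filling_period_leaves_only_zero_order(self):
        lattice = PrismLattice(
            box=(700.0, 700.0, 700.0),
            motif=(350.0, 350.0, 350.0),
            periods=(350.0, 350.0, 350.0),
        )
        freqs = tuple(
            2.0 * math.pi * np.arange(-3, 4) / 700.0 for _ in range(3)
        )
        comps = analytic_prism_lattice(lattice, None, freqs)
        assert comps.get(0, 0, 0) == pytest.approx(1.0, rel=1e-10)
        G = comps.G.copy()
        G[3, 3, 3] = 0.0
        assert np.max(np.abs(G)) < 1e-10

    def test_wide_window_converges_to_unwindowed_series(self):
        wave = SquareWave1D(width=200.0, period=400.0, length=8000.0)
        j = np.array([1, 3, 5])
        freqs = 2.0 * math.pi * j / 400.0
        exact = 2.0 * np.sin(math.pi * j / 2.0) / (math.pi * j)

        def err(waist):
            _, c = analytic_square_wave(wave, window=(waist, 1.0), freqs=freqs)
            return float(np.max(np.abs(c - exact)))

        assert err(100.0 * 400.0) < err(10.0 * 400.0)
        # residual ~ mean window deficit over the finite structure (~0.2%)
        assert err(100.0 * 400.0) < 5e-3

    def test_gaussian_piece_integral_against_quadrature(self):
        for k in (0.0, 0.01, 0.06):
            val = gaussian_piece_integral(np.array([k]), -120.0, 250.0, 300.0, 1.0)[0]
            oracle = adaptive_quad_transform(
                lambda u: math.exp(-(u**2) / 300.0**2), -120.0, 250.0, k, []
            )
            assert val == pytest.approx(oracle, rel=1e-10)


class TestPrune:
    @pytest.fixture()
    def comps_and_geom(self, small_model, geom800):
        vol = voxelize(small_model, (16, 16, 32))
        w = apply_focal_window(vol, geom800)
        comps = dfft_3d(w, small_model, DFFTConfig(),
                        ((-8, 8), (-8, 8), (-16, 16)))
        return comps, geom800

    def test_zero_epsilon_is_identity(self, comps_and_geom):
        comps, geom = comps_and_geom
        out = prune(comps, geom, 1.0, DFFTConfig(prune_epsilon=0.0))
        assert out is comps

    def test_retained_set_shrinks_with_epsilon(self, comps_and_geom):
        comps, geom = comps_and_geom
        sizes = []
        for eps in (1e-10, 1e-6, 1e-2):
            out = prune(comps, geom, 1.0, DFFTConfig(prune_epsilon=eps))
            sizes.append(int(np.count_nonzero(out.G)))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_pruned_pattern_matches_full_sum(self, comps_and_geom):
        from shgqpm.emission import AngularGrid, second_harmonic_field

        comps, geom = comps_and_geom
        opt = OpticalConfig(lambda_fund=800.0)
        grid = AngularGrid(n_theta=80, n_phi=80)
        full = second_harmonic_field(comps, geom, opt, grid)
        pruned = second_harmonic_field(
            prune(comps, geom, 1.0, DFFTConfig(prune_epsilon=1e-6)),
            geom, opt, grid,
        )
        rel = abs(pruned.peak_intensity - full.peak_intensity) / full.peak_intensity
        assert rel < 1e-3

    def test_select_index_ranges_cover_emission_sphere(self, geom800):
        r = select_index_ranges(geom800, 1.0, SMALL_BOX, (16, 16, 32), 1e-6)
        # the backward-matched axial momentum must be inside the z range
        k_back = -(2.0 * geom800.k_omega + geom800.k_2omega)
        l_back = k_back * SMALL_BOX[2] / (2 * math.pi)
        assert r[2][0] <= l_back <= r[2][1]
        assert r[0][0] == -r[0][1]
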