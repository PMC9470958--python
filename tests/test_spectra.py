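"""Green-Kubo estimator: grids, currents, correlation, transform, smoothing."""

import numpy as np
import pytest

from memdiel import units
from memdiel.spectra import (
    CurrentSeries,
    DielectricSpectrum,
    PhysicalContext,
    collect_currents,
    flux_autocorrelation,
    frequency_grid,
    imag_permittivity,
    moving_average,
    net_current,
    smooth_spectrum,
    spectrum_from_current,
)
from memdiel.trajectory_io import Frame


CTX = PhysicalContext(temperature_K=310.0, volume_m3=1e-26)


class TestFrequencyGrid:
    def test_paper_run_parameters(self):
        grid = frequency_grid(1e-9, 1.5e-15)
        assert grid[0] == pytest.approx(0.002)            # 2/T in THz
        assert grid[-1] == pytest.approx(1e3 / 3.0, rel=1e-4)  # 1/(2 dt)
        assert np.allclose(np.diff(grid), 0.002)

    def test_unusable_run_is_error(self):
        with pytest.raises(ValueError):
            frequency_grid(1.0, 0.25)

    def test_doubling_t_halves_resolution_keeps_nyquist(self):
        g1 = frequency_grid(1e-9, 2e-15)
        g2 = frequency_grid(2e-9, 2e-15)
        assert g2[0] == pytest.approx(g1[0] / 2)
        assert g2[-1] == pytest.approx(g1[-1], rel=1e-6)

    def test_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            frequency_grid(-1.0, 1e-15)


def _frame(vel, box=None):
    n = len(vel)
    return Frame(time=0.0, box=box if box is not None else np.ones(3),
                 positions=np.zeros((n, 3)), velocities=np.asarray(vel, float))


class TestNetCurrent:
    def test_single_atom_unit_conversion(self):
        frame = _frame([[1.0, 0.0, 0.0]])
        J = net_current(frame, np.array([0]), np.array([1.0]))
        assert J[0] == pytest.approx(units.E_CHARGE * 1e3)
        assert J[1] == J[2] == 0.0

    def test_neutral_pair_cancels(self):
        frame = _frame([[0.3, -0.2, 0.9], [0.3, -0.2, 0.9]])
        J = net_current(frame, np.array([0, 1]), np.array([0.417, -0.417]))
        np.testing.assert_allclose(J, 0.0, atol=1e-30)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(42)
        vel = rng.normal(size=(5, 3))
        q = rng.normal(size=5)
        frame = _frame(vel)
        J = net_current(frame, np.arange(5), q)
        brute = np.zeros(3)
        for j in range(5):
            brute += q[j] * vel[j] * units.E_CHARGE * units.NM_PER_PS
        np.testing.assert_allclose(J, brute, rtol=1e-14)


class TestFluxAutocorrelation:
    def test_constant_current(self):
        J = np.tile([1.0, 2.0, -1.0], (64, 1))
        C = flux_autocorrelation(J, 8)
        # biased estimator: C(k) = (n-k)/n |J|^2
        expect = (64 - np.arange(8)) / 64 * 6.0
        np.testing.assert_allclose(C, expect, rtol=1e-12)

    def test_cosine_closed_form(self):
        n, periods = 256, 8
        t = np.arange(n)
        w0 = 2 * np.pi * periods / n
        J = np.zeros((n, 3))
        J[:, 0] = np.cos(w0 * t)
        C = flux_autocorrelation(J, n // 4)
        k = np.arange(n // 4)
        # integer periods: biased estimator gives (n-k)/n * cos(w0 k)/2
        # plus a boundary term; compare against the direct-sum oracle instead
        direct = np.array([np.dot(J[: n - ki, 0], J[ki:, 0]) / n for ki in k])
        np.testing.assert_allclose(C, direct, atol=1e-10)
        # and the closed form holds to the truncation correction
        np.testing.assert_allclose(C[: 10], 0.5 * np.cos(w0 * k[:10]), atol=0.06)

    def test_fft_equals_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        J = rng.normal(size=(200, 3))
        C = flux_autocorrelation(J, 50)
        for k in (0, 1, 7, 49):
            direct = sum(np.dot(J[t], J[t + k]) for t in range(200 - k)) / 200
            assert C[k] == pytest.approx(direct, rel=1e-12)

    def test_lag_bound(self):
        with pytest.raises(ValueError):
            flux_autocorrelation(np.zeros((16, 3)), 16)

    def test_slab_additivity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4096, 3))
        b = rng.normal(size=(4096, 3))
        Ca = flux_autocorrelation(a, 16)
        Cb = flux_autocorrelation(b, 16)
        Cw = flux_autocorrelation(a + b, 16)
        # independent slabs: whole = sum of parts up to cross-term noise
        scale = Ca[0] + Cb[0]
        np.testing.assert_allclose(Cw, Ca + Cb, atol=0.1 * scale)


class TestImagPermittivity:
    def test_zero_charges_give_zero(self):
        frames = [_frame(np.random.default_rng(k).normal(size=(4, 3))) for k in range(6)]
        from memdiel.trajectory_io import AtomRecord, Topology

        atoms = [AtomRecord(atom_id=i, name="C1", element="C", residue_id=1,
                            residue_name="DMPC", molecule_id=0, charge=0.0, mass=12.0)
                 for i in range(4)]
        top = Topology(atoms=atoms)
        cur = collect_currents(frames, top, np.zeros(4, dtype=int), 1, dt_s=1e-15)
        spec = spectrum_from_current(cur, CTX)[0]
        np.testing.assert_allclose(spec.eps_imag, 0.0, atol=1e-30)

    def test_static_atoms_give_zero(self):
        C = np.zeros(64)
        grid = np.linspace(1.0, 10.0, 16)
        eps = imag_permittivity(C, 1e-15, CTX, grid)
        np.testing.assert_allclose(eps, 0.0, atol=1e-30)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            imag_permittivity(np.ones(8), 1e-15, CTX, np.array([0.0, 1.0]))

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            PhysicalContext(temperature_K=-1.0, volume_m3=1.0)
        with pytest.raises(ValueError):
            PhysicalContext(temperature_K=300.0, volume_m3=0.0)

    def test_white_noise_level(self):
        # iid Gaussian J: C(0)=3 sigma^2, C(k>0)=0, so
        # eps'' = 3 sigma^2 dt / (6 eps0 V kB T w)
        rng = np.random.default_rng(7)
        sigma = 1e-22
        J = rng.normal(scale=sigma, size=(200_000, 3))
        series = CurrentSeries(data=J[None], dt_s=1e-15)
        spec = spectrum_from_current(series, CTX)[0]
        w = 2 * np.pi * spec.f_thz * 1e12
        expect = 3 * sigma**2 * 1e-15 / (6 * CTX.eps0 * CTX.volume_m3 * CTX.kB
                                         * CTX.temperature_K * w)
        band = spec.f_thz > 1.0
        ratio = np.mean(spec.eps_imag[band] / expect[band])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_fft_path_matches_direct_cosine_sum(self):
        rng = np.random.default_rng(11)
        J = rng.normal(size=(512, 3))
        series = CurrentSeries(data=J[None], dt_s=2e-15)
        spec = spectrum_from_current(series, CTX)[0]
        C = flux_autocorrelation(J, 256)
        direct = imag_permittivity(C, 2e-15, CTX, spec.f_thz)
        np.testing.assert_allclose(spec.eps_imag, direct, rtol=1e-9, atol=1e-12)


class TestSmoothing:
    def _spec(self, values, step=0.1):
        f = (np.arange(len(values)) + 1) * step
        return DielectricSpectrum(f_thz=f, eps_imag=np.asarray(values, float))

    def test_window_of_one_step_is_identity(self):
        spec = self._spec(np.random.default_rng(0).normal(size=50))
        out = smooth_spectrum(spec, 0.1)
        np.testing.assert_array_equal(out.eps_imag, spec.eps_imag)

    def test_constant_is_unchanged(self):
        spec = self._spec(np.full(40, 3.3))
        out = smooth_spectrum(spec, 0.5)
        np.testing.assert_allclose(out.eps_imag, 3.3, rtol=1e-14)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(5)
        spec = self._spec(rng.normal(size=20_000))
        w = 9
        out = smooth_spectrum(spec, 0.9)
        inner = slice(50, -50)
        ratio = out.eps_imag[inner].var() / spec.eps_imag[inner].var()
        assert ratio == pytest.approx(1.0 / w, rel=0.15)

    def test_raw_data_retained(self):
        spec = self._spec(np.arange(30.0))
        out = smooth_spectrum(spec, 0.5)
        np.testing.assert_array_equal(out.eps_imag_raw, spec.eps_imag)
        assert out.window_thz == 0.5

    def test_subgrid_window_rejected(self):
        spec = self._spec(np.ones(10))
        with pytest.raises(ValueError):
            smoo_ = smooth_spectrum(spec, 0.01)

    def test_edges_use_shrinking_windows(self):
        vals = np.arange(10.0)
        out = moving_average(vals, 5)
        assert out[0] == pytest.approx(np.mean(vals[:3]))
        assert out[-1] == pytest.approx(np.mean(vals[-3:]))
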