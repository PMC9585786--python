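"""Coil combination, SNR maps, field mapping, and intensity corrections."""

import numpy as np
import pytest

from natriq.phantom import AcquisitionSeries, PROTOCOLS
from natriq.recon import (
    adaptive_combine,
    b0_map_dual_echo,
    b1_map_phase_sensitive,
    composite_pulse_phase,
    correct_off_resonance,
    derive_correction_factors,
    derive_and_apply_correction,
    multiple_replica_snr,
    _b1_lookup,
)
from natriq.trajectory import build_da3dpr_trajectory, forward_sample, grid_reconstruct


def _series(volumes, noise_only, seed=0):
    return AcquisitionSeries(volumes=volumes, contrast_values=np.array([0.55]),
                             contrast_kind="te", noise_only=noise_only,
                             protocol=PROTOCOLS["sodium"], seed=seed)


class TestAdaptiveCombine:
    def test_single_coil_identity_up_to_phase(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((1, 8, 8, 8)) + 1j * rng.standard_normal((1, 8, 8, 8))
        out = adaptive_combine(v)
        assert np.allclose(np.abs(out), np.abs(v[0]))

    def test_two_coils_recover_rsos(self):
        ax = np.linspace(-1, 1, 32)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        s1 = np.exp(-((x - 0.4) ** 2 + y**2 + z**2) / 2.0)
        s2 = np.exp(-((x + 0.4) ** 2 + y**2 + z**2) / 2.0) * np.exp(0.4j)
        obj = 1.0 + 0.3 * np.exp(-(x**2 + y**2 + z**2) / 0.5)
        combined = adaptive_combine(np.stack([obj * s1, obj * s2]))
        rsos = obj * np.sqrt(np.abs(s1) ** 2 + np.abs(s2) ** 2)
        rel = np.abs(np.abs(combined) - rsos) / rsos
        assert rel.mean() < 0.01

    def test_combination_improves_snr(self):
        rng = np.random.default_rng(1)
        obj = np.ones((16, 16, 16))
        sens = np.stack([0.9 * obj, 0.7 * obj])
        noisy = sens * obj + 0.2 * (rng.standard_normal((2, 16, 16, 16))
                                    + 1j * rng.standard_normal((2, 16, 16, 16)))
        combined = adaptive_combine(noisy)

        def snr(im):
            m = np.abs(im)
            return m.mean() / m.std()

        best_single = max(snr(noisy[0]), snr(noisy[1]))
        assert snr(combined) >= best_single

    def test_block_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            adaptive_combine(np.ones((2, 4, 4, 4), complex), block_overlap=8)


class TestMultipleReplicaSNR:
    def test_uniform_signal_analytic_ratio(self):
        rng = np.random.default_rng(2)
        vol = np.full((1, 12, 12, 12), 5.0, dtype=complex)[None]
        noise = 0.5 * (rng.standard_normal((2, 12, 12, 12))
                       + 1j * rng.standard_normal((2, 12, 12, 12)))
        snr = multiple_replica_snr(_series(vol, noise), n_replicas=100, seed=3)
        assert abs(snr.snr.mean() - 10.0) / 10.0 < 0.10

    def test_zero_signal_gives_near_zero_snr(self):
        rng = np.random.default_rng(3)
        vol = np.zeros((1, 1, 10, 10, 10), dtype=complex)
        noise = 1.0 * (rng.standard_normal((2, 10, 10, 10))
                       + 1j * rng.standard_normal((2, 10, 10, 10)))
        snr = multiple_replica_snr(_series(vol, noise), n_replicas=60, seed=4)
        # magnitude of pure noise has mean/sd ~ 1.91 (Rayleigh), far below
        # any real signal SNR; median stays at that floor
        assert np.median(snr.snr) < 3.0

    def test_doubling_sigma_halves_snr(self):
        rng = np.random.default_rng(4)
        vol = np.full((1, 1, 10, 10, 10), 8.0, dtype=complex)
        n1 = 0.4 * (rng.standard_normal((2, 10, 10, 10))
                    + 1j * rng.standard_normal((2, 10, 10, 10)))
        s1 = multiple_replica_snr(_series(vol, n1), n_replicas=100, seed=5)
        s2 = multiple_replica_snr(_series(vol, 2 * n1), n_replicas=100, seed=5)
        ratio = np.median(s1.snr) / np.median(s2.snr)
        assert abs(ratio - 2.0) / 2.0 < 0.10

    def test_missing_noise_scans_rejected(self):
        vol = np.ones((1, 1, 8, 8, 8), dtype=complex)
        with pytest.raises(ValueError):
            multiple_replica_snr(_series(vol, np.empty((0, 8, 8, 8))), n_replicas=10)


class TestB0Map:
    def test_identical_phases_give_zero(self):
        e = np.ones((8, 8, 8), complex)
        fm = b0_map_dual_echo(e, e, 0.60, 1.60)
        assert np.allclose(fm.b0, 0.0)

    def test_recovers_synthetic_offset(self):
        obj = np.ones((8, 8, 8))
        b0 = 50.0
        e1 = obj * np.exp(2j * np.pi * b0 * 0.60e-3)
        e2 = obj * np.exp(2j * np.pi * b0 * 1.60e-3)
        fm = b0_map_dual_echo(e1, e2, 0.60, 1.60)
        assert np.abs(fm.b0 - 50.0).max() < 0.1

    def test_wrap_beyond_half_bandwidth(self):
        # dTE = 1 ms -> unambiguous range +-500 Hz; 600 Hz aliases to -400
        obj = np.ones((4, 4, 4))
        e1 = obj * np.exp(2j * np.pi * 600.0 * 0.60e-3)
        e2 = obj * np.exp(2j * np.pi * 600.0 * 1.60e-3)
        fm = b0_map_dual_echo(e1, e2, 0.60, 1.60)
        assert np.allclose(fm.b0, -400.0, atol=1e-6)

    def test_equal_tes_rejected(self):
        e = np.ones((4, 4, 4), complex)
        with pytest.raises(ValueError):
            b0_map_dual_echo(e, e, 1.0, 1.0)


class TestB1Map:
    def test_lookup_strictly_monotone(self):
        _, phases = _b1_lookup()
        d = np.diff(phases)
        assert np.all(d < 0) or np.all(d > 0)

    def test_unit_scale_recovered(self):
        ref = np.ones((6, 6, 6), complex)
        prep = ref * np.exp(1j * composite_pulse_phase(np.full((6, 6, 6), 90.0)))
        fm = b1_map_phase_sensitive(prep, ref)
        assert np.allclose(fm.b1, 1.0, atol=1e-6)

    @pytest.mark.parametrize("scale", [0.7, 0.9, 1.1])
    def test_bloch_forward_recovery(self, scale):
        # independent closed-form oracle for the composite rotation phase
        def oracle_phase(alpha_deg):
            a = np.deg2rad(alpha_deg)
            return np.angle(np.sin(a) * np.cos(2 * a) - 1j * np.sin(2 * a))

        ref = np.ones((5, 5, 5), complex)
        prep = ref * np.exp(1j * oracle_phase(90.0 * scale))
        fm = b1_map_phase_sensitive(prep, ref)
        assert abs(np.nanmean(fm.b1) - scale) / scale < 0.01

    def test_out_of_domain_flagged_invalid(self):
        ref = np.ones((4, 4, 4), complex)
        prep = ref * np.exp(1j * composite_pulse_phase(np.full((4, 4, 4), 5.0)))
        fm = b1_map_phase_sensitive(prep, ref)
        assert not fm.support_mask.all() or np.isnan(fm.b1).any()


class TestOffResonanceCorrection:
    @pytest.fixture(scope="class")
    def setup(self):
        n = 24
        traj = build_da3dpr_trajectory(2000, n, 2.5, readout_duration=20.0)
        ax = np.arange(n) - n // 2
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        obj = (r <= 8).astype(complex)
        return n, traj, obj, r

    def test_zero_b0_equals_plain_recon(self, setup):
        n, traj, obj, _ = setup
        ks = forward_sample(obj, traj)
        plain = grid_reconstruct(ks, traj, n, kspace_filter="hann")
        corrected = correct_off_resonance(ks, np.zeros((n, n, n)), traj, n)
        assert np.allclose(corrected, plain)

    def test_single_bin_undoes_constant_offset(self, setup):
        n, traj, obj, _ = setup
        f0 = 40.0
        times = traj.flat_times()
        ks = forward_sample(obj, traj) * np.exp(2j * np.pi * f0 * times * 1e-3)
        plain = grid_reconstruct(forward_sample(obj, traj), traj, n,
                                 kspace_filter="hann")
        corrected = correct_off_resonance(ks, np.full((n, n, n), f0), traj, n,
                                          n_freq_bins=1)
        assert np.allclose(corrected, plain, atol=1e-9 * np.abs(plain).max())

    def test_gradient_field_cv_improves(self, setup):
        n, traj, obj, r = setup
        b0 = 300.0 * (np.arange(n) / (n - 1) - 0.5)[:, None, None] * np.ones((n, n, n))
        times = traj.flat_times()
        nb = 16
        edges = np.linspace(b0.min(), b0.max(), nb + 1)
        ks = np.zeros(traj.n_samples, complex)
        for i in range(nb):
            m = (b0 >= edges[i]) & (b0 < edges[i + 1] if i < nb - 1 else b0 <= edges[i + 1])
            if m.any():
                f = 0.5 * (edges[i] + edges[i + 1])
                ks += forward_sample(obj * m, traj) * np.exp(2j * np.pi * f * times * 1e-3)
        unc = grid_reconstruct(ks, traj, n, kspace_filter="hann")
        cor = correct_off_resonance(ks, b0, traj, n, n_freq_bins=15)
        interior = r <= 6

        def cv(im):
            v = np.abs(im[interior])
            return v.std() / v.mean()

        assert cv(cor) < cv(unc)


class TestIntensityCorrection:
    def test_homogeneous_observation_noop(self):
        cyl = np.zeros((16, 16, 16))
        cyl[4:12, 4:12, 4:12] = 3.0
        factors = derive_correction_factors(cyl)
        inside = cyl > 0
        assert np.allclose(factors.intensity_gain[inside], 1.0, atol=1e-9)
        assert np.allclose(factors.intensity_gain[~inside], 1.0)

    def test_inverts_known_smooth_shading(self):
        n = 32
        ax = np.linspace(-1, 1, n)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        shading = 1.0 + 0.2 * x + 0.1 * y * y
        mask = (x**2 + y**2 + z**2) <= 0.8
        observed = 5.0 * shading * mask
        corrected, _ = derive_and_apply_correction(observed, observed)
        interior = (x**2 + y**2 + z**2) <= 0.5
        vals = corrected[interior]
        assert vals.std() / vals.mean() < 0.02

    def test_factors_independent_of_invivo_content(self):
        n = 24
        ax = np.linspace(-1, 1, n)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        shading = 1.0 + 0.15 * x
        mask = (x**2 + y**2) <= 0.9
        cyl = 4.0 * shading * mask
        f1 = derive_correction_factors(cyl)
        f2 = derive_correction_factors(cyl)   # same cylinder, any subject
        assert np.array_equal(f1.intensity_gain, f2.intensity_gain)
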