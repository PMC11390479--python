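"""Geometry and Fourier primitives: rotations, wedges, filters, FSC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapsta import phantoms as ph
from chapsta.volumes import (
    EulerAngles,
    FSCCurve,
    Volume,
    WedgeSpec,
    apply_transform,
    bandpass_filter,
    constrained_cc,
    euler_from_matrix,
    flip_z,
    fsc,
    full_mask,
    make_wedge_mask,
    resolution_at_threshold,
    spherical_mask,
    symmetrize,
)
from conftest import central_sphere, masked_corr


class TestWedgeMask:
    def test_full_tilt_range_passes_everything(self):
        m = make_wedge_mask(16, 7.04, WedgeSpec(90, 0.0))
        assert np.all(m.grid == 1.0)

    # (45 degrees is skipped: its boundary coincides with the lattice
    # diagonal and the tie voxels bias the discrete count by ~3%)
    @pytest.mark.parametrize("theta", [30.0, 50.0, 60.0, 75.0])
    def test_sampled_fraction_matches_tilt_range(self, theta):
        # brute-force oracle: among Fourier voxels inside the Nyquist
        # sphere the sampled fraction must be 2*theta/180
        n = 32
        m = make_wedge_mask(n, 7.04, WedgeSpec(theta, 0.0))
        k = np.fft.fftfreq(n) * n
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        inside = np.sqrt(kz**2 + ky**2 + kx**2) <= n / 2
        angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
        oracle = float((angle[inside] <= theta).mean())
        assert oracle == pytest.approx(2 * theta / 180, abs=0.02)
        assert float(m.grid[inside].mean()) == pytest.approx(oracle, abs=1e-6)

    def test_friedel_symmetry(self):
        g = make_wedge_mask(16, 7.04, WedgeSpec(60, 3.0)).grid
        flipped = g[(-np.arange(16)) % 16][:, (-np.arange(16)) % 16][
            :, :, (-np.arange(16)) % 16
        ]
        assert np.allclose(g, flipped)

    def test_default_theta_is_60(self):
        assert WedgeSpec().theta_max == 60.0

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            WedgeSpec(theta_max=0.0)
        with pytest.raises(ValueError):
            WedgeSpec(theta_max=91.0)


class TestApplyTransform:
    def test_identity_is_exact(self, smooth_bullet):
        out = apply_transform(smooth_bullet, EulerAngles(), (0, 0, 0))
        assert np.array_equal(out.data, smooth_bullet.data)

    def test_round_trip_preserves_smooth_phantom(self, smooth_bullet):
        e = EulerAngles(33.0, 50.0, -70.0)
        back = apply_transform(apply_transform(smooth_bullet, e), e.inverse())
        m = central_sphere(48, 20)
        assert masked_corr(back.data, smooth_bullet.data, m) >= 0.99

    def test_c7_symmetrized_map_invariant_under_c7_rotation(self, smooth_bullet):
        s = symmetrize(smooth_bullet, "C7")
        r = apply_transform(s, EulerAngles(360.0 / 7, 0.0, 0.0))
        assert masked_corr(r.data, s.data, central_sphere(48, 20)) >= 0.999

    def test_pure_shift(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.standard_normal((16, 16, 16)), 1.0)
        out = apply_transform(v, EulerAngles(), (3, 0, 0))
        assert np.allclose(out.data[:, :, 4:], v.data[:, :, 1:-3], atol=1e-5)

    def test_non_cubic_rejected(self):
        v = Volume(np.zeros((8, 8, 16), dtype=np.float32), 1.0)
        with pytest.raises(ValueError):
            apply_transform(v, EulerAngles(10, 0, 0))


class TestEulerAngles:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(-179, 179), st.floats(1, 179), st.floats(-179, 179)
    )
    def test_matrix_round_trip(self, rot, tilt, psi):
        e = EulerAngles(rot, tilt, psi)
        e2 = euler_from_matrix(e.matrix())
        assert np.allclose(e2.matrix(), e.matrix(), atol=1e-8)

    def test_inverse_composes_to_identity(self):
        e = EulerAngles(20.0, 70.0, -10.0)
        assert np.allclose(e.compose(e.inverse()).matrix(), np.eye(3),
                           atol=1e-10)


class TestBandpass:
    def test_no_cutoffs_is_identity(self, bullet_map):
        out = bandpass_filter(bullet_map)
        assert np.array_equal(out.data, bullet_map.data)

    def test_lowpass_removes_high_frequency_power(self):
        rng = np.random.default_rng(1)
        v = Volume(rng.standard_normal((32, 32, 32)), 7.04)
        out = bandpass_filter(v, high_res=40.0)
        f = np.fft.fftn(out.data)
        k = np.fft.fftfreq(32, d=7.04)
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        above = np.sqrt(kz**2 + ky**2 + kx**2) > 1 / 40.0 + 2 / (32 * 7.04)
        frac = (np.abs(f[above]) ** 2).sum() / (np.abs(f) ** 2).sum()
        assert frac < 0.01

    def test_mean_preserved_without_highpass(self, bullet_map):
        out = bandpass_filter(bullet_map, high_res=30.0)
        assert out.data.mean() == pytest.approx(bullet_map.data.mean(),
                                                rel=1e-4, abs=1e-6)

    def test_invalid_band_rejected(self, bullet_map):
        with pytest.raises(ValueError):
            bandpass_filter(bullet_map, low_res=20.0, high_res=40.0)


class TestSymmetrize:
    def test_c1_is_identity(self, smooth_bullet):
        assert np.array_equal(symmetrize(smooth_bullet, "C1").data,
                              smooth_bullet.data)

    def test_idempotence(self, smooth_bullet):
        s1 = symmetrize(smooth_bullet, "C7")
        s2 = symmetrize(s1, "C7")
        m = central_sphere(48, 20)
        rel = np.sqrt(((s2.data - s1.data)[m] ** 2).mean()) / np.sqrt(
            (s1.data[m] ** 2).mean()
        )
        assert rel < 0.04  # trilinear resampling noise on a smooth map

    def test_group_invariance_every_element(self, smooth_bullet):
        s = symmetrize(smooth_bullet, "C7")
        m = central_sphere(48, 20)
        for k in range(1, 7):
            ang = k * 360.0 / 7
            ang = ang - 360 if ang >= 180 else ang
            r = apply_transform(s, EulerAngles(ang, 0, 0))
            assert masked_corr(r.data, s.data, m) >= 0.999

    def test_d7_football_invariant_under_z_flip(self, football_map):
        smooth = bandpass_filter(football_map, high_res=25.0)
        s = symmetrize(smooth, "D7")
        m = central_sphere(48, 20)
        assert masked_corr(flip_z(s).data, s.data, m) >= 0.999


def _brute_force_cc(ref, sub, wedge_ref, wedge_sub, mask, max_shift):
    """Direct-space oracle: filter, mask-normalize, then exhaustively
    correlate over circular shifts with nested loops."""
    shared = wedge_ref.grid * wedge_sub.grid
    a = np.fft.ifftn(np.fft.fftn(ref.data) * shared).real
    b = np.fft.ifftn(np.fft.fftn(sub.data) * shared).real
    m = mask.data

    def norm(x):
        mu = (m * x).sum() / m.sum()
        c = m * (x - mu)
        return c / np.sqrt((c**2).sum())

    ah, bh = norm(a), norm(b)
    n = ah.shape[0]
    best, best_shift = -np.inf, None
    for dz in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                shifted = np.roll(ah, (dz, dy, dx), axis=(0, 1, 2))
                s = float((shifted * bh).sum())
                if s > best:
                    best, best_shift = s, (dx, dy, dz)
    return best, best_shift


class TestConstrainedCC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        v = Volume(rng.standard_normal((16, 16, 16)), 7.04)
        sc, sh = constrained_cc(v, v, full_mask(16), full_mask(16),
                                spherical_mask(16), 0)
        assert sc == pytest.approx(1.0, abs=1e-6)
        assert sh == (0, 0, 0)

    def test_translation_equivariance(self, smooth_bullet):
        shifted = Volume(np.roll(smooth_bullet.data, 2, axis=2), 7.04)
        sc, sh = constrained_cc(smooth_bullet, shifted, full_mask(48),
                                full_mask(48), spherical_mask(48), 3)
        assert sh == (2, 0, 0)
        assert sc >= 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = Volume(rng.standard_normal((8, 8, 8)), 7.04)
        sub = Volume(rng.standard_normal((8, 8, 8)), 7.04)
        wa = make_wedge_mask(8, 7.04, WedgeSpec(60, 0.0))
        wb = make_wedge_mask(8, 7.04, WedgeSpec(45, 0.0))
        mask = spherical_mask(8, radius=3, soft_edge=1)
        got_s, got_sh = constrained_cc(ref, sub, wa, wb, mask, 2)
        exp_s, exp_sh = _brute_force_cc(ref, sub, wa, wb, mask, 2)
        assert got_s == pytest.approx(exp_s, abs=1e-6)
        assert got_sh == exp_sh

    def test_zero_volume_rejected(self):
        z = Volume(np.zeros((8, 8, 8), dtype=np.float32), 1.0)
        v = Volume(np.ones((8, 8, 8), dtype=np.float32), 1.0)
        with pytest.raises(ValueError):
            constrained_cc(z, v, full_mask(8), full_mask(8),
                           spherical_mask(8), 0)


class TestFSC:
    def test_self_fsc_is_one(self, bullet_map):
        curve = fsc(bullet_map, bullet_map)
        assert np.all(curve.corr[curve.n_voxels > 0] >= 1 - 1e-6)

    def test_independent_noise_stays_within_null_bound(self):
        rng = np.random.default_rng(3)
        a = Volume(rng.standard_normal((32, 32, 32)), 7.04)
        b = Volume(rng.standard_normal((32, 32, 32)), 7.04)
        curve = fsc(a, b)
        pop = curve.n_voxels > 0
        bound = 3 / np.sqrt(np.maximum(curve.n_voxels[pop], 1))
        frac_ok = (np.abs(curve.corr[pop]) <= bound).mean()
        assert frac_ok >= 0.95

    def test_shared_signal_with_noise_decays_near_filter_cutoff(self):
        rng = np.random.default_rng(4)
        base = ph.build_species_map(ph.SpeciesGeometry(), ph.BULLET_WIDE,
                                    48, 7.04)
        base = bandpass_filter(base, high_res=20.0)
        a = Volume(base.data + 0.08 * rng.standard_normal(base.data.shape),
                   7.04)
        b = Volume(base.data + 0.08 * rng.standard_normal(base.data.shape),
                   7.04)
        res = resolution_at_threshold(fsc(a, b), 0.143)
        assert not res.is_bound
        assert 15.0 <= res.angstrom <= 28.0

    def test_frequencies_strictly_increasing(self, bullet_map):
        curve = fsc(bullet_map, bullet_map)
        assert np.all(np.diff(curve.shell_freq) > 0)


class TestResolutionAtThreshold:
    def test_all_one_curve_reports_nyquist_bound(self):
        curve = FSCCurve(np.array([0.01, 0.02, 0.03]), np.ones(3),
                         np.array([10, 10, 10]))
        res = resolution_at_threshold(curve)
        assert res.is_bound
        assert res.angstrom == pytest.approx(1 / 0.03)

    def test_hand_computed_linear_interpolation(self):
        # crossing of 0.143 between (0.02, 0.5) and (0.025, 0.0)
        curve = FSCCurve(np.array([0.02, 0.025]), np.array([0.5, 0.0]),
                         np.array([10, 10]))
        res = resolution_at_threshold(curve, 0.143)
        expected = 1.0 / (0.02 + 0.005 * (0.5 - 0.143) / 0.5)
        assert res.angstrom == pytest.approx(expected, rel=1e-9)
        assert not res.is_bound

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        corr = np.clip(np.linspace(1.0, -0.1, 20)
                       + 0.05 * rng.standard_normal(20), -1, 1)
        corr[0] = 1.0
        curve = FSCCurve(np.linspace(0.005, 0.07, 20), corr,
                         np.full(20, 50))
        prev = None
        for thr in (0.1, 0.143, 0.3, 0.5, 0.8):
            r = resolution_at_threshold(curve, thr).angstrom
            if prev is not None:
                assert r >= prev - 1e-9
            prev = r
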