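"""Reflection-core numerics: d-spacings, amplitude conversion, scaling,
FFT synthesis against brute-force summation, Patterson properties and
sphere integration against a naive voxel loop."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trxmap.reflections import (
    MapGrid,
    ReflectionSet,
    d_spacing,
    fit_scale,
    integrate_density,
    intensities_to_amplitudes,
    patterson_map,
    synthesize_map,
    _frac_matrix,
    _orth_matrix,
)
from trxmap.synthetic import (
    intensities_from_amplitudes,
    make_toy_crystal,
    structure_factors,
)

CUBIC = gemmi.UnitCell(10, 10, 10, 90, 90, 90)


class TestDSpacing:
    def test_cubic_axis(self):
        assert d_spacing((1, 0, 0), CUBIC) == pytest.approx(10.0)

    def test_orthorhombic_oracle(self):
        cell = gemmi.UnitCell(10, 20, 30, 90, 90, 90)
        oracle = 1.0 / np.sqrt(1 / 100 + 1 / 400 + 1 / 900)
        assert d_spacing((1, 1, 1), cell) == pytest.approx(oracle, rel=1e-12)
        assert d_spacing((1, 1, 1), cell) == pytest.approx(8.571, abs=5e-4)

    @given(st.integers(-8, 8), st.integers(-8, 8), st.integers(-8, 8))
    @settings(max_examples=30, deadline=None)
    def test_friedel_invariance(self, h, k, l):
        if (h, k, l) == (0, 0, 0):
            return
        cell = gemmi.UnitCell(12, 17, 23, 90, 103, 90)
        assert d_spacing((h, k, l), cell) == pytest.approx(
            d_spacing((-h, -k, -l), cell), rel=1e-12)

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            d_spacing((0, 0, 0), CUBIC)


def _iset(values, sigmas, hkl=None):
    n = len(values)
    if hkl is None:
        hkl = [(i + 1, 0, 0) for i in range(n)]
    return ReflectionSet(CUBIC, "P1", np.array(hkl), np.array(values, float),
                         np.array(sigmas, float), "I")


class TestIntensityToAmplitude:
    def test_sqrt_truncate_basics(self):
        rs = _iset([4.0, -1.0], [0.0, 0.5])
        out = intensities_to_amplitudes(rs, "sqrt_truncate")
        assert out.value[0] == pytest.approx(2.0)
        assert out.value[1] == 0.0

    def test_french_wilson_strong_limit(self, i_dark):
        strong = i_dark.copy()
        strong.sigma = 1e-3 * np.abs(strong.value) + 1e-9
        out = intensities_to_amplitudes(strong, "french_wilson")
        ref = np.sqrt(strong.value)
        assert np.allclose(out.value, ref, rtol=0.01)

    def test_french_wilson_keeps_negatives_positive(self, i_dark):
        noisy = i_dark.copy()
        noisy.sigma = np.full(noisy.n, float(np.mean(noisy.value)))
        noisy.value = noisy.value.copy()
        noisy.value[:5] = -0.5 * noisy.sigma[:5]
        out = intensities_to_amplitudes(noisy, "french_wilson")
        assert np.all(out.value[:5] > 0)

    def test_thin_shells_fall_back_with_warning(self):
        rs = _iset([4.0, 9.0, 16.0], [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="sqrt_truncate"):
            out = intensities_to_amplitudes(rs, "french_wilson")
        assert out.value[0] == pytest.approx(2.0)

    def test_empty_set_rejected(self):
        rs = _iset([1.0], [0.1]).select(np.array([False]))
        with pytest.raises(ValueError):
            intensities_to_amplitudes(rs, "sqrt_truncate")


class TestFitScale:
    def test_identity_and_factor_two(self, f_dark):
        same = fit_scale(f_dark, f_dark)
        assert same.k == pytest.approx(1.0, abs=1e-9)
        assert same.B == pytest.approx(0.0, abs=1e-9)
        double = f_dark.copy()
        double.value = 2.0 * f_dark.value
        halved = fit_scale(double, f_dark)
        assert halved.k == pytest.approx(2.0, abs=1e-9)

    def test_recovers_k_and_b_roundtrip(self, f_dark):
        s2 = 1.0 / f_dark.d_spacings() ** 2
        moving = f_dark.copy()
        moving.value = f_dark.value / 0.7 * np.exp(5.0 * s2 / 4.0)
        model = fit_scale(f_dark, moving)
        assert model.k == pytest.approx(0.7, abs=1e-6)
        assert model.B == pytest.approx(5.0, abs=1e-6)

    def test_insufficient_overlap_rejected(self, f_dark):
        tiny = f_dark.select(np.arange(f_dark.n) < 5)
        with pytest.raises(ValueError, match="overlap"):
            fit_scale(f_dark, tiny)


class TestSynthesizeMap:
    def test_zero_coefficients_give_zero_map(self, f_dark):
        silent = f_dark.copy()
        silent.value = np.zeros(f_dark.n)
        grid = synthesize_map(silent, 0.6)
        assert np.allclose(grid.values, 0.0)
        assert grid.rms_sigma == 0.0

    def test_single_coefficient_is_cosine_wave(self):
        rs = ReflectionSet(CUBIC, "P1", np.array([[1, 0, 0]]), np.array([1.0]),
                           np.array([0.0]), "F", phase=np.array([0.0]))
        grid = synthesize_map(rs, 1.0)
        na = grid.shape[0]
        profile = grid.values[:, 0, 0]
        x = np.arange(na) / na
        expect = 2.0 / CUBIC.volume * np.cos(2 * np.pi * x)
        assert np.allclose(profile, expect, atol=1e-12)
        assert np.argmax(profile) == 0

    def test_density_maxima_at_atom_positions(self, toy_crystal, f_dark):
        grid = synthesize_map(f_dark, 0.5)
        frac_step = 1.0 / np.array(grid.shape)
        orth = _orth_matrix(toy_crystal.cell)
        step = np.linalg.norm(orth @ frac_step)
        for atom in toy_crystal.atoms_dark:
            idx = np.round(atom.frac_xyz * grid.shape).astype(int) % grid.shape
            window = grid.rms_sigma * 3
            assert grid.values[tuple(idx)] > window, (
                f"no density peak within one grid step of {atom.frac_xyz}")

    def test_matches_bruteforce_sum(self):
        xtal = make_toy_crystal(seed=9, n_atoms=4)
        fs = structure_factors(xtal.atoms_dark, xtal.cell, "P1", 3.0)
        grid = synthesize_map(fs, 1.2)
        coeff = fs.value * np.exp(1j * np.deg2rad(fs.phase))
        na, nb, nc = grid.shape
        for point in [(0, 0, 0), (1, 2, 3), (na - 1, nb // 2, 1)]:
            x = np.array(point) / np.array(grid.shape)
            total = 0.0
            for h, c in zip(fs.hkl, coeff):
                total += 2.0 * np.real(c * np.exp(-2j * np.pi * float(h @ x)))
            total /= xtal.cell.volume
            assert grid.values[point] == pytest.approx(total, rel=1e-8, abs=1e-12)

    def test_missing_phases_rejected(self, f_dark):
        rs = f_dark.copy()
        rs.phase = None
        with pytest.raises(ValueError, match="phase"):
            synthesize_map(rs)

    def test_rms_scales_linearly_with_amplitudes(self, f_dark):
        base = synthesize_map(f_dark, 0.6).rms_sigma
        scaled = f_dark.copy()
        scaled.value = 3.0 * f_dark.value
        assert synthesize_map(scaled, 0.6).rms_sigma == pytest.approx(
            3.0 * base, rel=1e-10)

    def test_forward_fft_returns_input_coefficients(self, f_dark):
        grid = synthesize_map(f_dark, 0.6)
        c_grid = np.fft.ifftn(grid.values) * f_dark.cell.volume
        coeff = f_dark.value * np.exp(1j * np.deg2rad(f_dark.phase))
        for i in (0, f_dark.n // 3, f_dark.n - 1):
            h = tuple(f_dark.hkl[i] % grid.shape)
            assert abs(c_grid[h] - coeff[i]) <= 1e-8 * max(abs(coeff[i]), 1.0)


class TestPattersonMap:
    def test_single_atom_has_only_origin_peak(self):
        from trxmap.synthetic import Atom

        fs = structure_factors([Atom("C", np.array([0.3, 0.6, 0.1]))],
                               (12, 12, 12, 90, 90, 90), "P1", 2.5)
        pat = patterson_map(intensities_from_amplitudes(fs), 0.8)
        rms = pat.rms_sigma
        peak = pat.values[0, 0, 0]
        assert peak == pat.values.max()
        interior = pat.values.copy()
        # mask voxels within 2 A of the origin (periodic)
        fa, fb, fc = pat.frac_coords()
        frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1)
        delta = (frac + 0.5) % 1.0 - 0.5
        cart = delta @ _orth_matrix(pat.cell).T
        near = np.sqrt((cart**2).sum(-1)) < 2.0
        interior[near] = 0.0
        assert interior.max() < 3.0 * rms

    def test_two_atom_peaks_at_separation_vector(self):
        from trxmap.synthetic import Atom

        u = np.array([0.25, 0.0, 0.0])
        atoms = [Atom("C", np.array([0.1, 0.2, 0.3]), b_factor=5.0),
                 Atom("C", np.array([0.1, 0.2, 0.3]) + u, b_factor=5.0)]
        fs = structure_factors(atoms, (16, 16, 16, 90, 90, 90), "P1", 2.0)
        pat = patterson_map(intensities_from_amplitudes(fs), 0.7)
        origin = pat.values[0, 0, 0]
        at_u = pat.value_at_frac(u)
        at_minus_u = pat.value_at_frac(-u)
        assert at_u == pytest.approx(origin / 2, rel=0.05)
        assert at_minus_u == pytest.approx(at_u, rel=1e-9)

    def test_depends_only_on_magnitudes(self, f_dark):
        rng = np.random.default_rng(1)
        scrambled = f_dark.copy()
        scrambled.phase = rng.uniform(0, 360, f_dark.n)
        a = patterson_map(f_dark, 0.7)
        b = patterson_map(scrambled, 0.7)
        assert np.allclose(a.values, b.values)


class TestIntegrateDensity:
    @staticmethod
    def _bruteforce(grid, centers, radius, threshold, sign):
        rms = grid.rms_sigma
        frac_mat = _frac_matrix(grid.cell)
        orth = _orth_matrix(grid.cell)
        na, nb, nc = grid.shape
        per = np.zeros(len(centers))
        union = 0.0
        counted = set()
        for ci, center in enumerate(centers):
            cf = frac_mat @ np.asarray(center, float)
            for ia in range(na):
                for ib in range(nb):
                    for ic in range(nc):
                        f = np.array([ia / na, ib / nb, ic / nc])
                        delta = (f - cf + 0.5) % 1.0 - 0.5
                        if np.linalg.norm(orth @ delta) > radius:
                            continue
                        v = grid.values[ia, ib, ic] / rms
                        if sign == "positive" and v > threshold:
                            contrib = v
                        elif sign == "negative" and v < -threshold:
                            contrib = -v
                        else:
                            continue
                        per[ci] += contrib * grid.voxel_volume
                        if (ia, ib, ic) not in counted:
                            counted.add((ia, ib, ic))
                            union += contrib * grid.voxel_volume
        return per, union

    def test_zero_map_integrates_to_zero(self):
        grid = MapGrid(np.zeros((6, 6, 6)), CUBIC)
        per, total = integrate_density(grid, np.array([[1.0, 1.0, 1.0]]), 2.0)
        assert total == 0.0 and np.all(per == 0.0)

    def test_sign_filter_excludes_opposite_features(self):
        values = np.random.default_rng(4).normal(size=(8, 8, 8)) * 0.01
        values[2, 2, 2] = 5.0
        grid = MapGrid(values, CUBIC)
        center = np.array([[2 / 8 * 10, 2 / 8 * 10, 2 / 8 * 10]])
        _, neg = integrate_density(grid, center, 1.0, 1.0, sign="negative")
        _, pos = integrate_density(grid, center, 1.0, 1.0, sign="positive")
        assert neg == 0.0
        assert pos > 0.0

    def test_matches_naive_voxel_loop(self):
        rng = np.random.default_rng(8)
        grid = MapGrid(rng.normal(size=(9, 10, 11)), CUBIC)
        centers = np.array([[2.0, 3.0, 4.0], [8.0, 9.0, 1.0]])
        for sign, threshold in (("positive", 0.0), ("negative", 1.5)):
            per, total = integrate_density(grid, centers, 3.0, threshold, sign)
            per_ref, total_ref = self._bruteforce(grid, centers, 3.0,
                                                  threshold, sign)
            assert np.allclose(per, per_ref, rtol=1e-8)
            assert total == pytest.approx(total_ref, rel=1e-8)

    @given(st.floats(0.0, 3.0), st.floats(0.5, 4.0))
    @settings(max_examples=15, deadline=None)
    def test_monotone_in_threshold_and_radius(self, threshold, radius):
        rng = np.random.default_rng(12)
        grid = MapGrid(rng.normal(size=(8, 8, 8)), CUBIC)
        center = np.array([[5.0, 5.0, 5.0]])
        _, base = integrate_density(grid, center, radius, threshold)
        _, lower_thresh = integrate_density(grid, center, radius,
                                            threshold / 2.0)
        _, bigger_radius = integrate_density(grid, center, radius + 1.0,
                                             threshold)
        assert lower_thresh >= base - 1e-12
        assert bigger_radius >= base - 1e-12
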