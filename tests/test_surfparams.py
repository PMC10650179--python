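"""Surface-parameter computations against closed forms and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from afmtex import (
    AdhesionMap,
    SpectralSurfaceSpec,
    compute_all,
    compute_bearing_curve,
    compute_fractal_dimensions,
    compute_radial_spectrum,
    compute_sdq,
    compute_sdr,
    compute_spk,
    extract_features,
    fit_power_law,
    fourier_transform,
    generate_map,
)
from afmtex.surfparams import ParameterError, RadialSpectrum

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# independent brute-force oracles (double loops over the printed formulas)


def sdr_oracle(z, dx, dy):
    n_rows, n_cols = z.shape
    total = 0.0
    for l in range(n_rows - 1):
        for k in range(n_cols - 1):
            t1 = math.sqrt(dy**2 + (z[l, k] - z[l + 1, k]) ** 2)
            t2 = math.sqrt(dy**2 + (z[l, k + 1] - z[l + 1, k + 1]) ** 2)
            t3 = math.sqrt(dx**2 + (z[l, k] - z[l, k + 1]) ** 2)
            t4 = math.sqrt(dx**2 + (z[l + 1, k] - z[l + 1, k + 1]) ** 2)
            total += 0.25 * (t1 + t2) * (t3 + t4)
    flat = (n_rows - 1) * (n_cols - 1) * dx * dy
    return (total - flat) / flat * 100.0


def sdq_oracle(z, dx, dy):
    n_rows, n_cols = z.shape
    acc = 0.0
    for l in range(1, n_rows):
        for k in range(1, n_cols):
            acc += ((z[l, k] - z[l, k - 1]) / dx) ** 2
            acc += ((z[l, k] - z[l - 1, k]) / dy) ** 2
    return math.sqrt(acc / ((n_rows - 1) * (n_cols - 1)))


def spk_oracle(values, step=0.001):
    """Direct geometric construction on a densely tabulated bearing curve.

    Independent of the package implementation: brute-force window search
    with per-window polyfit and fine-grid numeric integration of the
    peak area.
    """
    v = np.sort(np.asarray(values, dtype=float), axis=None)[::-1]
    p = np.arange(0.0, 100.0 + step / 2, step)
    h = np.interp(p, np.arange(1, v.size + 1) / v.size * 100.0, v)
    width = int(round(40.0 / step)) + 1
    best = None
    for s in range(0, p.size - width + 1):
        slope, intercept = np.polyfit(p[s:s + width], h[s:s + width], 1)
        if best is None or abs(slope) < best[0] - 1e-15:
            best = (abs(slope), slope, intercept)
    h_upper = best[2]
    if h[0] <= h_upper:
        return 0.0
    above = h - h_upper
    j = int(np.argmax(above <= 0))
    p_cross = np.interp(0.0, -above[j - 1:j + 1], p[j - 1:j + 1])
    grid = np.linspace(0.0, p_cross, 20001)
    area = np.trapezoid(np.clip(np.interp(grid, p, h) - h_upper, 0, None), grid)
    return 2.0 * area / p_cross if p_cross > 0 else 0.0


# ---------------------------------------------------------------------------
# Sdr / Sdq


class TestSdrSdq:
    def test_flat_map_zero(self, flat_map):
        assert compute_sdr(flat_map) == 0.0
        assert compute_sdq(flat_map) == 0.0

    def test_tilted_plane_closed_forms(self, plane_map):
        assert compute_sdr(plane_map) == pytest.approx((SQRT2 - 1) * 100, rel=1e-12)
        assert compute_sdq(plane_map) == pytest.approx(1.0, rel=1e-12)

    def test_diagonal_plane_sdq(self):
        n = 16
        x = np.arange(n, dtype=float)
        m = AdhesionMap(x[None, :] + x[:, None], dx=1.0, dy=1.0)
        assert compute_sdq(m) == pytest.approx(SQRT2, rel=1e-12)

    @given(
        z=arrays(np.float64, array_shapes(min_dims=2, max_dims=2,
                                          min_side=2, max_side=8),
                 elements=st.floats(-5, 5)),
        dx=st.floats(0.5, 3.0),
        dy=st.floats(0.5, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_double_loop_oracle(self, z, dx, dy):
        m = AdhesionMap(z, dx=dx, dy=dy)
        assert compute_sdr(m) == pytest.approx(sdr_oracle(z, dx, dy),
                                               rel=1e-12, abs=1e-12)
        assert compute_sdq(m) == pytest.approx(sdq_oracle(z, dx, dy),
                                               rel=1e-12, abs=1e-12)

    def test_sdr_nonnegative(self, rough_map):
        assert compute_sdr(rough_map) >= 0.0


# ---------------------------------------------------------------------------
# bearing curve / Spk


class TestBearingCurve:
    def test_constant_map_is_horizontal(self, flat_map):
        curve = compute_bearing_curve(flat_map)
        assert np.all(curve.heights == 2.5)

    def test_two_level_map(self):
        vals = np.concatenate([np.ones(32), np.zeros(32)])
        m = AdhesionMap(vals.reshape(8, 8), dx=1, dy=1)
        curve = compute_bearing_curve(m)
        assert curve.evaluate(25.0) == 1.0
        assert curve.evaluate(75.0) == 0.0

    def test_heights_are_permutation_of_values(self, rough_map):
        curve = compute_bearing_curve(rough_map)
        np.testing.assert_array_equal(
            np.sort(curve.heights), np.sort(rough_map.values, axis=None)
        )

    def test_monotone_non_increasing(self, rough_map):
        curve = compute_bearing_curve(rough_map)
        assert np.all(np.diff(curve.heights) <= 0)
        assert curve.ratios[0] > 0 and curve.ratios[-1] == pytest.approx(100.0)


class TestSpk:
    def test_constant_map_zero_with_warning(self, flat_map):
        with pytest.warns(UserWarning, match="single level"):
            assert compute_spk(flat_map) == 0.0

    def test_sparse_peaks_give_positive_spk(self):
        vals = np.zeros(10_000)
        vals[:100] = 1.0  # 1 % of pixels form a peak population
        m = AdhesionMap(vals.reshape(100, 100), dx=1, dy=1)
        assert compute_spk(m) > 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_geometry_oracle(self, seed):
        """Staircase surfaces with known bearing curves match the
        brute-force equal-area construction."""
        rng = np.random.default_rng(seed)
        levels = np.sort(rng.uniform(0, 2, size=6))[::-1]
        weights = rng.integers(1, 6, size=6)
        vals = np.repeat(levels, weights * 8)
        side = int(np.floor(np.sqrt(vals.size)))
        vals = vals[: side * side]
        m = AdhesionMap(rng.permutation(vals).reshape(side, side), dx=1, dy=1)
        expected = spk_oracle(m.values, step=0.1)
        assert compute_spk(m, step=0.1) == pytest.approx(expected, abs=1e-6)

    def test_translation_invariant(self, rough_map):
        shifted = rough_map.with_values(rough_map.values + 3.7)
        assert compute_spk(shifted) == pytest.approx(compute_spk(rough_map),
                                                     rel=1e-9)


# ---------------------------------------------------------------------------
# spectrum / power law


class TestRadialSpectrum:
    def test_constant_map_all_zero(self, flat_map):
        spec = compute_radial_spectrum(flat_map)
        assert np.all(spec.A == pytest.approx(0.0, abs=1e-15))

    def test_pure_cosine_peaks_in_right_bin(self):
        n, dx, k = 64, 1.0, 8
        x = np.arange(n)
        z = np.cos(2 * np.pi * k * x / n)[None, :].repeat(n, axis=0)
        spec = compute_radial_spectrum(AdhesionMap(z, dx=dx, dy=dx))
        peak_bin = int(np.argmax(spec.A))
        f_expected = k / (n * dx)
        df = 1.0 / (n * dx)  # annular bin width
        assert abs(spec.Q[peak_bin] - f_expected) < df / 2

    def test_parseval_normalization(self, rng):
        """sum |F|^2 equals the grid variance under the 1/(NxNy) convention."""
        vals = rng.normal(size=(32, 32))
        m = AdhesionMap(vals, dx=1, dy=1)
        f = fourier_transform(m, subtract_mean=True)
        zc = vals - vals.mean()
        assert np.sum(np.abs(f) ** 2) == pytest.approx(np.mean(zc**2), rel=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ParameterError):
            compute_radial_spectrum(AdhesionMap(np.ones((8, 16)), dx=1, dy=1))

    def test_zero_frequency_excluded(self, rough_map):
        spec = compute_radial_spectrum(rough_map)
        assert np.all(spec.Q > 0)
        assert np.all(np.diff(spec.Q) > 0)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        q = np.linspace(0.01, 1.0, 50)
        spec = RadialSpectrum(Q=q, A=q**-0.5, nyquist=1.0)
        fit = fit_power_law(spec, q[0], q[-1] * 1.01)
        assert fit.b == pytest.approx(-0.5, abs=1e-12)
        assert fit.fd == pytest.approx(2.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_is_flat(self):
        fitted = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = AdhesionMap(rng.normal(size=(128, 128)), dx=1.0, dy=1.0)
            spec = compute_radial_spectrum(m)
            fitted.append(fit_power_law(spec, spec.Q[1], 0.8 * spec.nyquist).b)
        assert np.mean(fitted) == pytest.approx(0.0, abs=0.15)

    def test_fd_is_two_minus_b(self):
        q = np.linspace(0.01, 1.0, 20)
        spec = RadialSpectrum(Q=q, A=q**-0.73, nyquist=1.0)
        fit = fit_power_law(spec, q[0], 2.0)
        assert fit.fd == 2.0 - fit.b

    def test_too_few_bins_rejected(self):
        spec = RadialSpectrum(Q=np.array([0.1, 0.2, 0.3]),
                              A=np.array([1.0, 0.0, 0.0]), nyquist=1.0)
        with pytest.raises(ParameterError, match=">= 3 bins"):
            fit_power_law(spec, 0.05, 0.4)


class TestFractalDimensions:
    def test_single_exponent_bands_agree(self):
        vals = []
        for seed in range(5):
            m = generate_map(SpectralSurfaceSpec(grid_n=256, b_low=-0.5,
                                                 b_high=-0.5, seed=seed))
            vals.append(compute_fractal_dimensions(m))
        sfd, top, bottom = np.mean(vals, axis=0)
        assert top == pytest.approx(sfd, abs=0.15)
        assert bottom == pytest.approx(sfd, abs=0.15)

    def test_two_exponent_bands_recovered(self):
        vals = []
        for seed in range(5):
            m = generate_map(SpectralSurfaceSpec(grid_n=512, b_low=-0.3,
                                                 b_high=-0.9, seed=seed))
            vals.append(compute_fractal_dimensions(m))
        _, top, bottom = np.mean(vals, axis=0)
        assert top == pytest.approx(2.3, abs=0.15)
        assert bottom == pytest.approx(2.9, abs=0.15)

    def test_split_outside_band_rejected(self):
        # 16 px over 10 um: quadrature band far below 1/300 nm^-1
        m = generate_map(SpectralSurfaceSpec(grid_n=16))
        with pytest.raises(ParameterError, match="band"):
            compute_fractal_dimensions(m)


# ---------------------------------------------------------------------------
# compute_all / extraction


class TestComputeAll:
    def test_constant_map_degenerate(self, flat_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = compute_all(flat_map)
        assert (params.sdr, params.sdq, params.spk) == (0.0, 0.0, 0.0)
        assert math.isnan(params.sfd)
        assert set(params.failed) == {"sfd", "sfd_top", "sfd_bottom"}

    @pytest.mark.parametrize("seed", range(8))
    def test_synthetic_maps_give_finite_parameters(self, seed):
        m = generate_map(SpectralSurfaceSpec(grid_n=128, seed=seed))
        params = compute_all(m)
        assert all(np.isfinite(v) for v in params.as_dict().values())
        assert params.sdr >= 0 and params.sdq >= 0 and params.spk >= 0

    def test_translation_invariance(self, rough_map):
        base = compute_all(rough_map)
        shifted = compute_all(rough_map.with_values(rough_map.values + 2.0))
        for name in ("sdr", "sdq", "spk", "sfd", "sfd_top", "sfd_bottom"):
            assert getattr(shifted, name) == pytest.approx(
                getattr(base, name), rel=1e-6, abs=1e-9
            ), name

    def test_scale_covariance(self, rough_map):
        c = 3.0
        base = compute_all(rough_map)
        scaled = compute_all(rough_map.with_values(rough_map.values * c))
        assert scaled.spk == pytest.approx(c * base.spk, rel=1e-6)
        assert scaled.sdr > base.sdr
        assert scaled.sdq == pytest.approx(c * base.sdq, rel=1e-9)

    def test_unit_sensitivity(self, rough_map):
        """Expressing adhesion in different units changes Sdr/Sdq/Spk."""
        micro = compute_all(rough_map.with_values(rough_map.values / 1000.0))
        base = compute_all(rough_map)
        assert micro.sdr != base.sdr
        assert micro.sdq != base.sdq
        assert micro.spk != base.spk


class TestExtraction:
    def test_one_row_per_cell_with_labels(self, separated_table):
        assert len(separated_table) == 32
        assert set(separated_table["class"]) == {"precancerous", "cancerous"}
        assert separated_table["n_quadrants"].between(1, 4).all()
        feats = separated_table[
            ["sdr", "sdq", "spk", "sfd", "sfd_top", "sfd_bottom"]
        ]
        assert np.isfinite(feats.to_numpy()).all()

    def test_classes_differ_in_fractal_dimension(self, separated_table):
        by_class = separated_table.groupby("class")["sfd"].mean()
        assert by_class["cancerous"] > by_class["precancerous"] + 0.1

    def test_whole_map_mode(self):
        m = generate_map(SpectralSurfaceSpec(grid_n=128, seed=3),
                         cell_id="whole")
        table, _ = extract_features([m], use_quadrants=False)
        assert len(table) == 1
        assert table.loc[0, "n_quadrants"] == 1
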