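"""Lattice dose model: amplitudes, theta sums, PVDR, profiles, beam fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minibeam import (
    INFINITE,
    BeamSpec,
    DoseField,
    GeometryError,
    InvalidGeometryError,
    ProfileCut,
    ResolutionError,
    amplitude_from_mean,
    dose_at,
    extract_diagonal_profile,
    fit_beam_sigma,
    pvdr_analytic,
    pvdr_from_profile,
    pvdr_of_ratio,
    read_dose_map,
    read_profile,
    render_dose_map,
    tophat_peak,
    write_dose_map,
    write_profile,
)
from minibeam.grid_dose import _theta

from conftest import STUDY_RATIOS, brute_force_dose


class TestAmplitude:
    @pytest.mark.parametrize(
        "mean,sigma,ctc,expected",
        [
            (60.0, 95.0, 1800.0, 3428.2),
            (0.0, 95.0, 1800.0, 0.0),
            (60.0, 180.0, 1800.0, 954.9),
        ],
    )
    def test_closed_form(self, mean, sigma, ctc, expected):
        assert amplitude_from_mean(mean, sigma, ctc) == pytest.approx(expected, rel=1e-4)

    def test_mean_dose_roundtrip(self):
        """Analytic lattice mean A*2*pi*sigma^2/ctc^2 recovers the field mean."""
        a = amplitude_from_mean(60.0, 306.0, 1800.0)
        assert a * 2 * math.pi * 306.0**2 / 1800.0**2 == pytest.approx(60.0, rel=1e-12)

    @pytest.mark.parametrize("sigma,ctc", [(0.0, 1800.0), (-5.0, 1800.0), (95.0, 0.0)])
    def test_invalid_geometry(self, sigma, ctc):
        with pytest.raises(InvalidGeometryError):
            amplitude_from_mean(60.0, sigma, ctc)


class TestDoseAt:
    def test_beam_center_isolated_limit(self, spec_small):
        """At sigma/ctc = 0.053 the neighbour contribution is negligible."""
        a = amplitude_from_mean(60.0, 95.0, 1800.0)
        assert dose_at(spec_small, 0.0, 0.0) == pytest.approx(a, rel=1e-12)

    def test_valley_matches_theta_oracle(self, spec_large):
        """Valley dose from the separable theta-sum oracle (~57.9 Gy)."""
        d = float(dose_at(spec_large, 900.0, 900.0))
        assert d == pytest.approx(57.9, abs=0.1)

    def test_matches_brute_force_sum(self):
        spec = BeamSpec(sigma=411.0, ctc=1800.0, mean_dose=60.0)
        xs = np.array([0.0, 250.0, 900.0, -640.0])
        ys = np.array([100.0, 900.0, 900.0, 333.0])
        expected = brute_force_dose(xs, ys, 411.0, 1800.0, 60.0)
        assert dose_at(spec, xs, ys) == pytest.approx(expected, rel=1e-9)

    def test_single_beam_grid_is_gaussian(self):
        spec = BeamSpec(sigma=200.0, ctc=1800.0, mean_dose=60.0, grid_n=1)
        a = amplitude_from_mean(60.0, 200.0, 1800.0)
        r2 = 150.0**2 + 90.0**2
        assert float(dose_at(spec, 150.0, 90.0)) == pytest.approx(
            a * math.exp(-r2 / (2 * 200.0**2)), rel=1e-12
        )

    def test_separability(self, spec_large):
        """D(x,y) * D(0,0) = D(x,0) * D(0,y) for the infinite lattice."""
        x, y = 412.0, -731.0
        lhs = float(dose_at(spec_large, x, y)) * float(dose_at(spec_large, 0.0, 0.0))
        rhs = float(dose_at(spec_large, x, 0.0)) * float(dose_at(spec_large, 0.0, y))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @pytest.mark.parametrize("ratio", STUDY_RATIOS)
    def test_truncation_convergence(self, ratio):
        """Doubling the truncation order changes nothing (< 1e-6 relative)."""
        x = np.linspace(-0.9, 0.9, 7)
        k = math.ceil(6 * ratio) + 1
        t1 = _theta(x, ratio, 1.0, order=k)
        t2 = _theta(x, ratio, 1.0, order=2 * k)
        assert t1 == pytest.approx(t2, rel=1e-6)


class TestTophat:
    @pytest.mark.parametrize(
        "mean,width,ctc,expected",
        [(60.0, 180.0, 1800.0, 6000.0), (60.0, 1800.0, 1800.0, 60.0), (30.0, 600.0, 1800.0, 270.0)],
    )
    def test_peak(self, mean, width, ctc, expected):
        assert tophat_peak(mean, width, ctc) == pytest.approx(expected, rel=1e-12)

    def test_width_exceeding_ctc_rejected(self):
        with pytest.raises(InvalidGeometryError):
            tophat_peak(60.0, 2000.0, 1800.0)

    @given(
        mean=st.floats(0.1, 100.0),
        width=st.floats(10.0, 1800.0),
        ctc=st.floats(1800.0, 5000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_peak_at_least_mean(self, mean, width, ctc):
        assert tophat_peak(mean, width, ctc) >= mean * (1 - 1e-12)


class TestRenderDoseMap:
    def test_unit_cell_mean_conserved(self):
        spec = BeamSpec(sigma=0.11 * 1800.0, ctc=1800.0, mean_dose=60.0)
        field = render_dose_map(spec, (-900.0, 900.0, -900.0, 900.0), 1800.0 / 256)
        assert field.values.mean() == pytest.approx(60.0, rel=1e-3)

    @pytest.mark.parametrize("ratio", STUDY_RATIOS)
    def test_mean_conservation_all_ratios(self, ratio):
        spec = BeamSpec(sigma=ratio * 1800.0, ctc=1800.0, mean_dose=60.0)
        field = render_dose_map(spec, (-900.0, 900.0, -900.0, 900.0), 1800.0 / 128)
        assert field.values.mean() == pytest.approx(60.0, rel=1e-3)

    def test_richardson_resolution_check(self):
        spec = BeamSpec(sigma=306.0, ctc=1800.0, mean_dose=60.0)
        m1 = render_dose_map(spec, (-900.0, 900.0, -900.0, 900.0), 1800 / 256).values.mean()
        m2 = render_dose_map(spec, (-900.0, 900.0, -900.0, 900.0), 1800 / 512).values.mean()
        assert abs(m2 - m1) / m2 < 1e-4

    def test_experimental_field_geometry(self):
        """4x4 grid over 7.2 x 7.2 mm² mimics the irradiated pattern."""
        spec = BeamSpec(sigma=95.0, ctc=1800.0, mean_dose=60.0, grid_n=4)
        field = render_dose_map(spec, (-3600.0, 3600.0, -3600.0, 3600.0), 1800 / 64)
        # 16 beams at ±0.5, ±1.5 ctc: hottest pixel within half a pixel of
        # a beam center, so within a few percent of the amplitude
        a = amplitude_from_mean(60.0, 95.0, 1800.0)
        assert field.values.max() == pytest.approx(a, rel=0.05)
        assert float(dose_at(spec, 900.0, 900.0)) == pytest.approx(a, rel=1e-6)

    def test_too_coarse_pixel_rejected(self, spec_small):
        with pytest.raises(ResolutionError):
            render_dose_map(spec_small, (-900, 900, -900, 900), 100.0)

    def test_roundtrip_io(self, tmp_path, spec_large):
        field = render_dose_map(spec_large, (-900, 900, -900, 900), 1800 / 64)
        path = tmp_path / "map.csv"
        write_dose_map(field, path, spec=spec_large)
        back = read_dose_map(path)
        assert back.values == pytest.approx(field.values, rel=1e-6)
        assert back.pixel_size == field.pixel_size
        assert back.origin == pytest.approx(field.origin)


class TestPvdrAnalytic:
    def test_near_homogeneous(self):
        assert pvdr_of_ratio(0.491) == pytest.approx(1.071, abs=0.005)

    def test_strong_modulation(self):
        """theta(ctc/2) = 2 exp(-12.5)-dominated at ratio 0.1."""
        assert pvdr_of_ratio(0.1) == pytest.approx(1.8e10, rel=0.01)

    def test_flat_field_limit(self):
        assert pvdr_of_ratio(50.0) == pytest.approx(1.0, abs=1e-9)

    def test_underflow_ratio_reported_infinite(self):
        assert pvdr_of_ratio(0.01) == math.inf

    def test_monotone_decreasing_and_ge_one(self):
        values = [pvdr_of_ratio(r) for r in STUDY_RATIOS]
        assert all(v >= 1.0 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_spec_wrapper_requires_infinite_gaussian(self, spec_large):
        assert pvdr_analytic(spec_large) == pytest.approx(pvdr_of_ratio(883 / 1800))
        with pytest.raises(InvalidGeometryError):
            pvdr_analytic(BeamSpec(sigma=95, ctc=1800, grid_n=4))


class TestDiagonalProfile:
    def _field(self, ratio, n_cells=4, px_per_ctc=128):
        spec = BeamSpec(sigma=ratio * 1800.0, ctc=1800.0, mean_dose=60.0)
        half = n_cells / 2 * 1800.0
        return spec, render_dose_map(spec, (-half, half, -half, half), 1800.0 / px_per_ctc)

    def test_peak_spacing_is_ctc_sqrt2(self):
        _, field = self._field(0.23)
        cut = extract_diagonal_profile(field)
        d = np.asarray(cut.doses)
        from scipy.signal import find_peaks

        peaks_idx, _ = find_peaks(d, prominence=0.001 * (d.max() - d.min()))
        spacings = np.diff(cut.positions[peaks_idx])
        assert spacings == pytest.approx(
            np.full(len(spacings), 1800.0 * math.sqrt(2)), rel=0.02
        )

    def test_constant_field_flat_profile(self):
        field = DoseField(values=np.full((64, 64), 60.0), pixel_size=100.0, origin=(0, 0))
        cut = extract_diagonal_profile(field)
        assert np.ptp(cut.doses) < 1e-9
        assert pvdr_from_profile(cut).value == 1.0

    def test_profile_extrema_match_map_extrema(self):
        """Dense-sampling: profile max/min equal the diagonal's analytic max/min."""
        spec, field = self._field(0.312, px_per_ctc=256)
        cut = extract_diagonal_profile(field)
        assert cut.doses.max() == pytest.approx(float(dose_at(spec, 0, 0)), rel=5e-3)
        assert cut.doses.min() == pytest.approx(float(dose_at(spec, 900, 900)), rel=5e-3)

    def test_diagonal_outside_extent(self):
        field = DoseField(values=np.ones((8, 8)), pixel_size=10.0, origin=(0.0, 1000.0))
        with pytest.raises(GeometryError):
            extract_diagonal_profile(field)

    def test_profile_io_roundtrip(self, tmp_path):
        _, field = self._field(0.17)
        cut = extract_diagonal_profile(field)
        path = tmp_path / "profile.csv"
        write_profile(cut, path)
        back = read_profile(path)
        assert back.doses == pytest.approx(cut.doses, rel=1e-6)


class TestPvdrFromProfile:
    @pytest.mark.parametrize("ratio", [0.228, 0.312, 0.491])
    def test_agrees_with_analytic_on_noiseless_maps(self, ratio):
        spec = BeamSpec(sigma=ratio * 1800.0, ctc=1800.0, mean_dose=60.0)
        field = render_dose_map(spec, (-3600, 3600, -3600, 3600), 1800 / 256)
        res = pvdr_from_profile(extract_diagonal_profile(field))
        assert not res.is_lower_bound
        assert res.value == pytest.approx(pvdr_of_ratio(ratio), rel=0.01)

    def test_unresolvable_valley_reported_as_lower_bound(self):
        """At ratio 0.053 the valleys drown in a 0.5% noise floor."""
        spec = BeamSpec(sigma=95.0, ctc=1800.0, mean_dose=60.0)
        field = render_dose_map(spec, (-3600, 3600, -3600, 3600), 1800 / 256)
        res = pvdr_from_profile(extract_diagonal_profile(field), noise_floor_frac=0.005)
        assert res.is_lower_bound
        assert res.value == pytest.approx(1 / 0.005, rel=0.05)


class TestFitBeamSigma:
    def _single_beam(self, sigma, noise_sd=0.0, rng=None):
        x = np.linspace(-600.0, 600.0, 241)
        d = 100.0 * np.exp(-(x**2) / (2 * sigma**2))
        if noise_sd:
            d = d * rng.normal(1.0, noise_sd, d.shape)
        return ProfileCut(positions=x, doses=np.clip(d, 0, None), cut_kind="axis")

    def test_noiseless_self_consistency(self):
        fit = fit_beam_sigma(self._single_beam(95.3))
        assert fit.sigma == pytest.approx(95.3, abs=0.1)
        assert fit.sigma_stderr < 0.1

    def test_noisy_recovery_within_three_stderr(self):
        """2% multiplicative noise: 100-seed recovery within 3 SE (>=95%)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_beam_sigma(self._single_beam(95.3, 0.02, rng), relative_noise=True)
            se = max(fit.sigma_stderr, 1e-6)
            hits += abs(fit.sigma - 95.3) <= 3 * se
        assert hits >= 95

    def test_fit_on_rendered_field(self):
        spec = BeamSpec(sigma=306.0, ctc=1800.0, mean_dose=60.0, grid_n=1)
        field = render_dose_map(spec, (-900, 900, -900, 900), 1800 / 128)
        fit = fit_beam_sigma(field)
        assert fit.sigma == pytest.approx(306.0, rel=1e-3)
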