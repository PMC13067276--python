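"""1D quantification: normalization, integration, index, conversion, deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignintrace import (
    Spectrum1D,
    deconvolve_gs,
    incorporation_index,
    integrate_region,
    labeling_percentage,
    normalize_to_reference,
    simulate_1d,
)
from lignintrace.lineshapes import gaussian, pseudo_voigt
from lignintrace.shifts import SpectralRegion, named_regions

AROMATIC = named_regions()["aromatic"]


def _two_peak_spectrum(split, noise=0.0, seed=None, fwhm=4.0, eta=0.3):
    ppm = 135.0 + 0.05 * np.arange(601)
    clean = split[0] * pseudo_voigt(ppm, 147.0, fwhm, eta)
    clean = clean + split[1] * pseudo_voigt(ppm, 153.0, fwhm, eta)
    y = clean
    if noise:
        rng = np.random.default_rng(seed)
        y = clean + rng.normal(0.0, noise * clean.max(), clean.shape)
    return Spectrum1D(ppm, y)


class TestNormalization:
    def test_reference_peak_scaled_to_one(self):
        ppm = np.linspace(0, 200, 2001)
        spec = Spectrum1D(ppm, 2.0 * gaussian(ppm, 73.0, 2.0) / gaussian(np.array([73.0]), 73.0, 2.0)[0])
        scaled, n = normalize_to_reference(spec)
        assert n == pytest.approx(2.0, rel=1e-6)
        window = named_regions()["carbohydrate_ref"]
        mask = (scaled.ppm >= window.lo_ppm) & (scaled.ppm <= window.hi_ppm)
        assert scaled.intensity[mask].max() == pytest.approx(1.0)

    def test_scale_invariance(self, wt_phe):
        spec = simulate_1d(wt_phe)
        s1, _ = normalize_to_reference(spec)
        s2, _ = normalize_to_reference(spec.scaled(5.0))
        assert np.allclose(s1.intensity, s2.intensity)

    def test_reference_found_at_73(self, wt_phe):
        spec = simulate_1d(wt_phe)
        window = named_regions()["carbohydrate_ref"]
        mask = (spec.ppm >= window.lo_ppm) & (spec.ppm <= window.hi_ppm)
        argmax = spec.ppm[mask][np.argmax(spec.intensity[mask])]
        assert argmax == pytest.approx(73.0, abs=0.5)

    def test_errors(self, wt_phe):
        spec = simulate_1d(wt_phe)
        with pytest.raises(ValueError):
            normalize_to_reference(spec, SpectralRegion("out", 300.0, 310.0))


class TestIntegration:
    def test_unit_area_gaussian(self):
        ppm = np.linspace(100, 180, 8001)
        spec = Spectrum1D(ppm, gaussian(ppm, 140.0, 1.0))
        region = SpectralRegion("r", 120.0, 160.0)
        assert integrate_region(spec, region) == pytest.approx(1.0, abs=1e-4)

    def test_additivity_of_adjacent_regions(self, wt_phe):
        spec = simulate_1d(wt_phe)
        a = integrate_region(spec, SpectralRegion("a", 108.0, 140.0))
        b = integrate_region(spec, SpectralRegion("b", 140.0, 165.0))
        ab = integrate_region(spec, SpectralRegion("ab", 108.0, 165.0))
        assert a + b == pytest.approx(ab, rel=1e-12)

    def test_matches_riemann_oracle(self, wt_phe):
        """Fine-grid midpoint Riemann sum as independent oracle."""
        spec = simulate_1d(wt_phe, axis=(0.0, 200.0, 0.005))
        region = AROMATIC
        value = integrate_region(spec, region)
        centers = np.arange(region.lo_ppm + 0.0005, region.hi_ppm, 0.001)
        oracle = np.interp(centers, spec.ppm, spec.intensity).sum() * 0.001
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_region_outside_axis_raises(self, wt_phe):
        spec = simulate_1d(wt_phe)
        with pytest.raises(ValueError):
            integrate_region(spec, SpectralRegion("bad", 150.0, 250.0))


class TestIncorporationIndex:
    def test_identical_spectra_give_unity(self, control):
        spec = simulate_1d(control)
        assert incorporation_index(spec, spec) == pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance(self, wt_phe, control):
        lab = simulate_1d(wt_phe)
        unl = simulate_1d(control)
        i1 = incorporation_index(lab, unl)
        i2 = incorporation_index(lab.scaled(7.0), unl.scaled(0.2))
        assert i1 == pytest.approx(i2, rel=1e-12)

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.2, 0.31, 0.5])
    def test_closed_form_recovery(self, control, p):
        """Index then conversion recovers the generator's labeling fraction
        within 0.5 percentage points (noise-free)."""
        labeled = control.model_copy(update={"labeling_fraction": p})
        index = incorporation_index(simulate_1d(labeled), simulate_1d(control))
        a = control.natural_abundance
        assert index == pytest.approx(1.0 + p * (1 - a) / a, rel=0.02)
        assert labeling_percentage(index, a) == pytest.approx(100 * p, abs=0.5)


class TestLabelingPercentage:
    @pytest.mark.parametrize("p", np.linspace(0.0, 1.0, 10).tolist())
    def test_exact_inverse_of_index_form(self, p):
        a = 0.011
        index = 1.0 + p * (1.0 - a) / a
        assert labeling_percentage(index, a) == pytest.approx(100.0 * p, abs=1e-9)

    def test_printed_pairings(self):
        # index 29 corresponds to ~31% labeling; an unlabeled control to 0%
        assert round(labeling_percentage(29.0)) == 31
        assert labeling_percentage(1.0) == 0.0
        assert labeling_percentage(12.0) == pytest.approx(12.2, abs=0.05)

    def test_subunity_index_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert labeling_percentage(0.8) == 0.0

    def test_invalid_abundance(self):
        with pytest.raises(ValueError):
            labeling_percentage(5.0, a=0.1)


class TestDeconvolution:
    @pytest.mark.parametrize("split", [(87.0, 13.0), (71.0, 29.0), (50.0, 50.0)])
    def test_noise_free_recovery(self, split):
        res = deconvolve_gs(_two_peak_spectrum(split))
        assert res.converged
        assert res.percent["G/FA"] == pytest.approx(split[0], abs=0.1)
        assert res.percent["S"] == pytest.approx(split[1], abs=0.1)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)

    @pytest.mark.parametrize("split", [(90, 10), (80, 20), (70, 30), (60, 40)])
    @pytest.mark.parametrize("noise", [0.0, 0.01])
    def test_recovery_under_noise(self, split, noise):
        res = deconvolve_gs(_two_peak_spectrum(split, noise=noise, seed=3))
        assert res.percent["G/FA"] == pytest.approx(split[0], abs=2.0)

    def test_fitted_centers_near_initialization(self):
        res = deconvolve_gs(_two_peak_spectrum((70.0, 30.0)))
        assert res.components["G/FA"]["center"] == pytest.approx(147.0, abs=0.2)
        assert res.components["S"]["center"] == pytest.approx(153.0, abs=0.2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(0.0, 1.0), a=st.floats(0.001, 0.049))
def test_conversion_inverts_index_closed_form(p, a):
    """labeling_percentage is the exact inverse of I = 1 + p(1-a)/a for any
    admissible natural abundance."""
    index = 1.0 + p * (1 - a) / a
    assert labeling_percentage(index, a) == pytest.approx(100 * p, abs=1e-8)
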