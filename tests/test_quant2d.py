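"""2D volumetrics: box integration, composition, fold changes, DNP."""

import numpy as np
import pytest

from lignintrace import (
    SampleModel,
    Spectrum2D,
    composition,
    dnp_enhancement,
    fold_changes,
    integrate_crosspeak,
    simulate_1d,
    simulate_2d,
    simulate_dnp_pair,
)
from lignintrace.lineshapes import LineShape, profile_2d
from lignintrace.presets import STUDY_COMPOSITIONS, study_model
from lignintrace.quant2d import CompositionResult
from lignintrace.shifts import CrossPeakDef, quantification_probes


def _peak_spectrum(peaks, axis=(90.0, 180.0, 0.25), fwhm=0.4):
    """Synthetic plane with narrow Gaussians of given (f1, f2, volume)."""
    lo, hi, step = axis
    f = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    shape = LineShape("gaussian", fwhm_ppm=fwhm)
    z = np.zeros((f.size, f.size))
    for c1, c2, vol in peaks:
        z += vol * profile_2d(f, f, c1, c2, shape)
        if c1 != c2:
            z += vol * profile_2d(f, f, c2, c1, shape)
    return Spectrum2D(f, f, z, {})


class TestBoxIntegration:
    def test_unit_volume_peak_fully_inside(self):
        spec = _peak_spectrum([(111.0, 168.0, 1.0)])
        peak = CrossPeakDef("FA", "C2", "C9", 111.0, 168.0, "FA2/5/8-9")
        assert integrate_crosspeak(spec, peak) == pytest.approx(1.0, abs=1e-3)

    def test_matches_brute_force_oracle(self, wt_phe):
        spec = simulate_2d(wt_phe)
        peak = CrossPeakDef("S", "C2/6", "C3/5", 104.0, 153.0, "S2/6-3/5")
        value = integrate_crosspeak(spec, peak)
        # explicit double loop over both twin boxes
        d = 0.25
        def brute(c1, c2):
            acc = 0.0
            for i, x1 in enumerate(spec.f1_ppm):
                if abs(x1 - c1) > 1.5:
                    continue
                for j, x2 in enumerate(spec.f2_ppm):
                    if abs(x2 - c2) <= 1.5:
                        acc += spec.intensity[i, j]
            return acc * d * d
        oracle = 0.5 * (brute(104.0, 153.0) + brute(153.0, 104.0))
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_empty_region_is_zero(self):
        spec = _peak_spectrum([(111.0, 168.0, 1.0)])
        quiet = CrossPeakDef("H", "C2/6", "C4", 128.0, 160.0, "H2/6-4")
        assert integrate_crosspeak(spec, quiet) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_band_rejected(self):
        spec = _peak_spectrum([(130.0, 132.0, 1.0)])
        near_diag = CrossPeakDef("X", "a", "b", 130.0, 132.0, "near")
        with pytest.raises(ValueError):
            integrate_crosspeak(spec, near_diag)
        # diagonal peaks themselves are allowed when requested explicitly
        diag = CrossPeakDef("X", "a", "a", 130.0, 130.0, "diag")
        integrate_crosspeak(spec, diag, allow_diagonal=True)

    def test_box_outside_window_rejected(self):
        spec = _peak_spectrum([(111.0, 168.0, 1.0)], axis=(100.0, 120.0, 0.25))
        peak = CrossPeakDef("FA", "C2", "C9", 111.0, 168.0, "FA2/5/8-9")
        with pytest.raises(ValueError):
            integrate_crosspeak(spec, peak)


class TestComposition:
    def test_equal_weighted_volumes_give_quarters(self, table):
        probes = quantification_probes(table)
        peaks = []
        for unit, plist in probes.items():
            for p in plist:
                w = (table.lookup(unit, p.site_a).n_carbons
                     * table.lookup(unit, p.site_b).n_carbons)
                peaks.append((p.f1_ppm, p.f2_ppm, float(w)))
        spec = _peak_spectrum(peaks)
        result = composition(spec, probes=probes, table=table)
        for unit in ("G", "S", "H", "FA"):
            assert result.percent[unit] == pytest.approx(25.0, abs=0.1)

    def test_percentages_sum_to_100(self, wt_phe):
        result = composition(simulate_2d(wt_phe))
        assert sum(result.percent.values()) == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("key", sorted(STUDY_COMPOSITIONS))
    def test_recovers_study_compositions(self, key):
        truth = STUDY_COMPOSITIONS[key]
        result = composition(simulate_2d(study_model(*key)))
        for unit, pct in result.percent.items():
            assert pct == pytest.approx(100.0 * truth[unit], abs=1.0)

    def test_random_composition_recovery_within_one_point(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            f = rng.dirichlet([3.0, 3.0, 3.0, 3.0])
            comp = {u: float(v) for u, v in zip(("G", "S", "H", "FA"), f)}
            comp["pCA"] = 0.0
            model = SampleModel(composition=comp, labeling_fraction=0.31)
            result = composition(simulate_2d(model))
            for unit, pct in result.percent.items():
                assert pct == pytest.approx(100.0 * comp[unit], abs=1.0)

    def test_pca_probe_empty_without_pca(self, wt_phe):
        """With no p-coumarate in the sample, the (160, 168) ppm probe box
        holds no volume (the empty dashed-box observation)."""
        spec = simulate_2d(wt_phe)
        pca = CrossPeakDef("pCA", "C4", "C9", 160.0, 168.0, "pCA4-9")
        v = integrate_crosspeak(spec, pca)
        strongest = max(r["volume"] for r in composition(spec).peak_table)
        assert abs(v) < 0.01 * strongest


class TestFoldChanges:
    def test_identical_samples_give_unity(self, wt_phe):
        c = composition(simulate_2d(wt_phe))
        fc = fold_changes(c, c)
        for r in fc.ratios.values():
            assert r == pytest.approx(1.0, rel=1e-12)

    def test_equal_total_reduces_to_percent_ratio(self):
        mut = composition(simulate_2d(study_model("C3H", "Tyr")))
        wt = composition(simulate_2d(study_model("WT", "Tyr")))
        fc = fold_changes(mut, wt)
        for unit in fc.ratios:
            assert fc.ratios[unit] == pytest.approx(
                mut.percent[unit] / wt.percent[unit], rel=1e-12
            )

    def test_h_lignin_increase_in_tyr_mutant(self):
        mut = composition(simulate_2d(study_model("C3H", "Tyr")))
        wt = composition(simulate_2d(study_model("WT", "Tyr")))
        assert fold_changes(mut, wt).ratios["H"] == pytest.approx(2.6, abs=0.1)

    def test_zero_wt_volume_flagged_infinite(self):
        mut = CompositionResult(
            volumes={"G": 1.0, "H": 1.0}, total=2.0,
            percent={"G": 50.0, "H": 50.0},
        )
        wt = CompositionResult(
            volumes={"G": 2.0, "H": 0.0}, total=2.0,
            percent={"G": 100.0, "H": 0.0},
        )
        fc = fold_changes(mut, wt)
        assert np.isinf(fc.ratios["H"])
        assert fc.flags["H"] == "zero WT volume"


class TestDNP:
    def test_epsilon_recovered_from_pair(self, wt_phe):
        spec = simulate_1d(wt_phe)
        on, off = simulate_dnp_pair(spec, 11.0, noise=0.005, seed=8)
        res = dnp_enhancement(on, off)
        assert res.epsilon == pytest.approx(11.0, abs=0.5)
        assert res.time_saving == pytest.approx(res.epsilon**2)

    def test_epsilon_forty_saves_1600(self, wt_phe):
        spec = simulate_1d(wt_phe)
        on, off = simulate_dnp_pair(spec, 40.0)
        res = dnp_enhancement(on, off)
        assert res.time_saving == pytest.approx(1600.0, rel=1e-9)

    def test_on_equals_off_gives_unity(self, wt_phe):
        spec = simulate_1d(wt_phe)
        res = dnp_enhancement(spec, spec)
        assert res.epsilon == 1.0 and res.time_saving == 1.0

    def test_noise_floor_guard(self, wt_phe):
        spec = simulate_1d(wt_phe)
        with pytest.raises(ValueError):
            dnp_enhancement(spec, spec.scaled(0.0), noise_floor=0.0)
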