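"""XIC extraction, S/N estimation, product matching, detection calls."""

import math

import numpy as np
import pytest

import glycotarget as gt
from glycotarget.detection import Chromatogram, _peak_area
from glycotarget.fragments import FragmentIon
from glycotarget.run import Run, Spectrum


def brute_force_xic(run, mz, ppm_tol, rt_window):
    """Independent per-scan filter oracle."""
    rts, vals = [], []
    for scan in run.ms1:
        if rt_window and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        total = 0.0
        for m, i in zip(scan.mz, scan.intensity):
            if abs(m - mz) * 1e6 <= ppm_tol * mz:
                total += i
        rts.append(scan.rt)
        vals.append(total)
    return np.array(rts), np.array(vals)


class TestXIC:
    def test_agrees_exactly_with_brute_force_oracle(self, target_transition):
        for seed in range(5):
            run = gt.simulate_run(
                gt.SyntheticRunConfig(transition=target_transition,
                                      concentration=3.0, seed=seed)
            )
            ch = gt.extract_xic(run, target_transition.precursor_mz, 10.0, (10, 14))
            rts, vals = brute_force_xic(run, target_transition.precursor_mz, 10.0, (10, 14))
            np.testing.assert_array_equal(ch.rt, rts)
            np.testing.assert_array_equal(ch.intensity, vals)

    def test_apex_at_injected_rt(self, target_transition):
        cfg = gt.SyntheticRunConfig(transition=target_transition, concentration=50.0,
                                    peak_rt=12.3, seed=2)
        run = gt.simulate_run(cfg)
        ch = gt.extract_xic(run, target_transition.precursor_mz, 10.0, (10, 14))
        apex_rt = ch.rt[np.argmax(ch.intensity)]
        assert apex_rt == pytest.approx(12.3, abs=0.05)

    def test_offset_mz_gives_zero_xic(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=50.0,
                                  n_noise_points=0, seed=3)
        )
        off = target_transition.precursor_mz * (1 + 50e-6)
        ch = gt.extract_xic(run, off, 10.0, (11.8, 12.2))
        assert np.all(ch.intensity == 0)

    def test_linearity_in_intensity(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=5.0, seed=4)
        )
        doubled = Run(
            ms1=[Spectrum(s.rt, s.mz, 2 * s.intensity) for s in run.ms1],
            ms2=run.ms2,
        )
        ch1 = gt.extract_xic(run, target_transition.precursor_mz, 10.0)
        ch2 = gt.extract_xic(doubled, target_transition.precursor_mz, 10.0)
        np.testing.assert_allclose(ch2.intensity, 2 * ch1.intensity, rtol=1e-12)

    def test_empty_window(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=5.0, seed=5)
        )
        ch = gt.extract_xic(run, target_transition.precursor_mz, 10.0, (20.0, 21.0))
        assert len(ch) == 0

    def test_nonpositive_tolerance_rejected(self, target_transition):
        run = Run()
        with pytest.raises(ValueError):
            gt.extract_xic(run, 500.0, 0.0)


class TestSNR:
    def test_known_truth_recovery(self):
        """Injected apex over N(floor, sigma) background: the estimator must
        land within 25% of the analytic S/N = (floor+apex)/(floor+sigma)."""
        floor, sigma, apex = 50.0, 10.0, 300.0
        truth = (floor + apex) / (floor + sigma)
        rt = np.arange(0.0, 4.0, 0.02)
        center = rt[len(rt) // 2]
        for seed in range(30):
            rng = np.random.default_rng(seed)
            intensity = floor + rng.normal(0, sigma, rt.size)
            intensity = np.clip(intensity, 0, None)
            peak = apex * np.exp(-0.5 * ((rt - center) / 0.05) ** 2)
            chrom = Chromatogram(rt, intensity + peak)
            snr = gt.estimate_snr(chrom, (center - 0.15, center + 0.15))
            assert snr == pytest.approx(truth, rel=0.25)

    def test_flat_zero_chromatogram(self):
        chrom = Chromatogram(np.arange(10.0), np.zeros(10))
        assert gt.estimate_snr(chrom, (4.0, 6.0)) == 0.0

    def test_zero_background_with_peak_is_infinite(self):
        intensity = np.zeros(20)
        intensity[10] = 100.0
        chrom = Chromatogram(np.arange(20.0), intensity)
        assert math.isinf(gt.estimate_snr(chrom, (9.0, 11.0)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        rt = np.arange(100.0)
        intensity = np.abs(30 + rng.normal(0, 8, 100))
        intensity[50] = 400.0
        chrom = Chromatogram(rt, intensity)
        scaled = Chromatogram(rt, 7.5 * intensity)
        region = (47.0, 53.0)
        assert gt.estimate_snr(scaled, region) == pytest.approx(
            gt.estimate_snr(chrom, region), rel=1e-12
        )

    def test_empty_chromatogram_rejected(self):
        with pytest.raises(ValueError):
            gt.estimate_snr(Chromatogram(np.array([]), np.array([])), (0, 1))


class TestMatchProducts:
    def test_all_published_products_match(self, target_transition):
        mz = np.array(sorted(p.mz for p in target_transition.products))
        spec = Spectrum(rt=12.0, mz=mz, intensity=np.full(mz.size, 100.0), ms_level=2)
        matches = gt.match_products(spec, list(target_transition.products), 0.01)
        assert len(matches) == len(target_transition.products)
        assert all(abs(m.ppm_error) < 1 for m in matches)

    def test_empty_spectrum(self, target_transition):
        spec = Spectrum(rt=1.0, mz=np.array([]), intensity=np.array([]), ms_level=2)
        assert gt.match_products(spec, list(target_transition.products), 0.01) == []

    def test_degenerate_one_centroid_two_ions(self):
        """Two expected ions within tolerance of a single centroid: the
        closer wins; an exact tie goes to the lower expected m/z."""
        spec = Spectrum(rt=1.0, mz=np.array([100.000]), intensity=np.array([50.0]),
                        ms_level=2)
        near = FragmentIon(kind="oxonium", label="near", mz=100.002)
        far = FragmentIon(kind="oxonium", label="far", mz=100.006)
        matches = gt.match_products(spec, [far, near], tol=0.01)
        assert [m.label for m in matches] == ["near"]
        lo = FragmentIon(kind="oxonium", label="lo", mz=99.996)
        hi = FragmentIon(kind="oxonium", label="hi", mz=100.004)
        matches = gt.match_products(spec, [hi, lo], tol=0.01)
        assert [m.label for m in matches] == ["lo"]

    def test_ppm_tolerance_mode(self, target_transition):
        ion = list(target_transition.products)[0]
        spec = Spectrum(rt=1.0, mz=np.array([ion.mz * (1 + 4e-6)]),
                        intensity=np.array([10.0]), ms_level=2)
        assert gt.match_products(spec, [ion], tol=5.0, tol_is_ppm=True)
        assert not gt.match_products(spec, [ion], tol=2.0, tol_is_ppm=True)


class TestDetectTarget:
    def test_positive_run_detected(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=20.0, seed=6)
        )
        res = gt.detect_target(run, target_transition)
        assert res.detected
        assert res.signal_to_noise > 3
        assert len(res.matched_products) >= 4
        assert res.peak_rt == pytest.approx(12.0, abs=0.1)

    def test_blank_not_detected(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=0.0, seed=6)
        )
        assert not gt.detect_target(run, target_transition).detected

    def test_no_ms2_coverage_forces_negative(self, target_transition):
        run = gt.simulate_run(
            gt.SyntheticRunConfig(transition=target_transition, concentration=20.0, seed=6)
        )
        stripped = Run(ms1=run.ms1, ms2=[])
        res = gt.detect_target(stripped, target_transition)
        assert not res.detected
        assert res.diagnostics["reason"] == "no MS2 coverage"
        assert res.signal_to_noise > 3  # S/N alone would have passed

    def test_detected_implies_thresholds(self, target_transition):
        policy = gt.DetectionPolicy()
        for seed in range(5):
            for conc in (0.0, 0.3, 1.0, 10.0):
                run = gt.simulate_run(
                    gt.SyntheticRunConfig(transition=target_transition,
                                          concentration=conc, seed=seed)
                )
                res = gt.detect_target(run, target_transition, policy)
                if res.detected:
                    assert res.signal_to_noise > policy.snr_threshold
                    assert len(res.matched_products) >= policy.min_products


class TestPeakArea:
    def test_single_scan_spike_excluded_from_area(self):
        rt = np.arange(0.0, 4.0, 0.02)
        peak = 500.0 * np.exp(-0.5 * ((rt - 2.0) / 0.085) ** 2)
        spiked = peak.copy()
        spiked[30] += 5000.0  # single-scan spike far from the peak
        a_clean = _peak_area(Chromatogram(rt, peak), 2.0, 0.3)
        a_spiked = _peak_area(Chromatogram(rt, spiked), 2.0, 0.3)
        assert a_spiked == pytest.approx(a_clean, rel=0.01)
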