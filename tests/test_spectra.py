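"""1D spectrum synthesis, peak picking, deconvolution and assignment."""

import numpy as np
import pytest

from fluornmr.datasets import StudyFixture
from fluornmr.spectra import (
    AssignmentTable,
    Peak,
    Spectrum1D,
    assign_by_difference,
    estimate_noise_sigma,
    fit_lorentzians,
    pick_peaks,
    simulate_spectrum,
)

FIELD = 658.780


class TestSimulate:
    def test_no_peaks_no_noise_is_zero(self):
        s = simulate_spectrum([], noise_sigma=0.0)
        assert np.all(s.intensity == 0.0)

    def test_axis_is_downfield_to_upfield(self):
        s = simulate_spectrum([], noise_sigma=0.0)
        assert s.ppm[0] > s.ppm[-1]

    def test_deterministic_for_fixed_seed(self):
        a = simulate_spectrum([Peak(-47.0, 50.0)], noise_sigma=0.02, seed=3)
        b = simulate_spectrum([Peak(-47.0, 50.0)], noise_sigma=0.02, seed=3)
        assert np.array_equal(a.intensity, b.intensity)

    def test_peak_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectrum([Peak(-20.0, 50.0)])

    def test_width_read_back(self):
        # 52.7 Hz at 658.780 MHz is 0.08 ppm; no extra broadening applied
        s = simulate_spectrum([Peak(-47.0, 52.7)], field_mhz=FIELD,
                              noise_sigma=0.0, lb_hz=0.0)
        (p,) = pick_peaks(s)
        assert p.fwhm_hz / FIELD == pytest.approx(0.08, abs=s.dppm)

    def test_thrombin_most_downfield_maximum(self, study):
        s = simulate_spectrum(study.peaks("thrombin"), field_mhz=FIELD,
                              noise_sigma=0.0, lb_hz=study.lb_hz)
        assert s.ppm[np.argmax(s.intensity >= 0.5)] is not None
        peaks = pick_peaks(s)
        assert peaks[0].center_ppm == pytest.approx(-43.5, abs=0.01)


class TestPickPeaks:
    def test_zero_spectrum_gives_no_peaks(self):
        s = simulate_spectrum([], noise_sigma=0.0)
        assert pick_peaks(s) == []

    @pytest.mark.parametrize("protein,n_expected", [("thrombin", 7), ("prethrombin-2", 4)])
    def test_reported_peak_counts(self, study, protein, n_expected):
        s = simulate_spectrum(study.peaks(protein), field_mhz=FIELD,
                              noise_sigma=0.0, lb_hz=study.lb_hz)
        assert len(pick_peaks(s)) == n_expected

    @pytest.mark.parametrize("protein,n_expected", [("thrombin", 7), ("prethrombin-2", 4)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_peak_counts_survive_study_noise(self, study, protein, n_expected, seed):
        s = simulate_spectrum(study.peaks(protein), field_mhz=FIELD,
                              noise_sigma=study.noise_sigma, lb_hz=study.lb_hz,
                              seed=seed)
        assert len(pick_peaks(s)) == n_expected

    def test_round_trip_recovers_separated_centers(self):
        """pick o simulate recovers centers within one grid step when
        pairwise separations are at least twice the FWHM and noise is 0."""
        rng = np.random.default_rng(5)
        fwhm_hz, lb = 40.0, 0.0
        fwhm_ppm = fwhm_hz / FIELD
        for _ in range(10):
            centers = np.sort(rng.uniform(-53.0, -41.0, size=6))
            while np.any(np.diff(centers) < 2 * fwhm_ppm):
                centers = np.sort(rng.uniform(-53.0, -41.0, size=6))
            s = simulate_spectrum([Peak(c, fwhm_hz) for c in centers],
                                  field_mhz=FIELD, noise_sigma=0.0, lb_hz=lb)
            got = sorted(p.center_ppm for p in pick_peaks(s))
            assert len(got) == 6
            assert np.allclose(got, centers, atol=s.dppm)


class TestFitLorentzians:
    def test_exact_recovery_single_peak(self):
        truth = Peak(-47.3, 60.0, amplitude=2.5)
        s = simulate_spectrum([truth], noise_sigma=0.0, lb_hz=0.0, field_mhz=FIELD)
        init = [Peak(-47.25, 50.0, amplitude=1.0)]
        peaks, diag = fit_lorentzians(s, init)
        assert diag.converged
        assert peaks[0].center_ppm == pytest.approx(truth.center_ppm, rel=1e-4)
        assert peaks[0].fwhm_hz == pytest.approx(truth.fwhm_hz, rel=1e-4)
        assert peaks[0].amplitude == pytest.approx(truth.amplitude, rel=1e-4)

    def test_two_close_peaks_with_noise(self):
        truths = [Peak(-47.4, 0.08 * FIELD), Peak(-47.6, 0.08 * FIELD)]
        s = simulate_spectrum(truths, noise_sigma=0.01, lb_hz=0.0,
                              field_mhz=FIELD, seed=11)
        init = [Peak(-47.38, 50.0), Peak(-47.63, 50.0)]
        peaks, _ = fit_lorentzians(s, init)
        got = sorted(p.center_ppm for p in peaks)
        assert got[0] == pytest.approx(-47.6, abs=0.01)
        assert got[1] == pytest.approx(-47.4, abs=0.01)

    def test_overlapped_cluster_fits_broad(self, study):
        """A single component forced through the prethrombin-2 cluster near
        -47.9 ppm comes out broader than any isolated line."""
        s = simulate_spectrum(study.peaks("prethrombin-2"), field_mhz=FIELD,
                              noise_sigma=0.0, lb_hz=study.lb_hz)
        window = (s.ppm < -47.0) & (s.ppm > -49.2)
        sub = Spectrum1D(s.ppm[window], s.intensity[window], s.field_mhz, s.lb_hz)
        peaks, _ = fit_lorentzians(sub, [Peak(-47.9, 80.0, amplitude=5.0)])
        isolated_fwhm = study.fwhm_ppm * FIELD + study.lb_hz
        assert peaks[0].fwhm_hz > isolated_fwhm

    def test_initial_center_outside_axis_rejected(self):
        s = simulate_spectrum([Peak(-47.0, 50.0)], noise_sigma=0.0)
        with pytest.raises(ValueError):
            fit_lorentzians(s, [Peak(-20.0, 50.0)])

    def test_apodization_monotonicity(self):
        """Larger applied line broadening never narrows the fitted line."""
        widths = []
        for lb in (0.0, 10.0, 20.0, 40.0):
            s = simulate_spectrum([Peak(-47.0, 50.0)], noise_sigma=0.0,
                                  lb_hz=lb, field_mhz=FIELD)
            peaks, _ = fit_lorentzians(s, [Peak(-47.0, 50.0 + lb)])
            widths.append(peaks[0].fwhm_hz)
        assert np.all(np.diff(widths) >= -1e-9)


class TestAssignByDifference:
    def test_identical_spectra_no_regions(self, study):
        s = simulate_spectrum(study.peaks("thrombin"), noise_sigma=0.0,
                              lb_hz=study.lb_hz, field_mhz=FIELD)
        assert assign_by_difference(s, s) == []

    def test_w215f_perturbs_both_trp215_peaks(self, study):
        wt = simulate_spectrum(study.peaks("prethrombin-2"), noise_sigma=0.0,
                               lb_hz=study.lb_hz, field_mhz=FIELD)
        mut = simulate_spectrum(study.peaks("prethrombin-2", omit=("215",)),
                                noise_sigma=0.0, lb_hz=study.lb_hz, field_mhz=FIELD)
        regions = assign_by_difference(wt, mut)
        assert len(regions) == 2
        assert regions[0].extremum_ppm == pytest.approx(-47.9, abs=0.01)
        assert regions[1].extremum_ppm == pytest.approx(-49.8, abs=0.01)

    def test_w141f_thrombin_single_region(self, study):
        wt = simulate_spectrum(study.peaks("thrombin"), noise_sigma=0.0,
                               lb_hz=study.lb_hz, field_mhz=FIELD)
        mut = simulate_spectrum(study.peaks("thrombin", omit=("141",)),
                                noise_sigma=0.0, lb_hz=study.lb_hz, field_mhz=FIELD)
        regions = assign_by_difference(wt, mut)
        assert len(regions) == 1
        assert regions[0].extremum_ppm == pytest.approx(-43.5, abs=0.01)

    def test_symmetric_in_magnitude(self, study):
        wt = simulate_spectrum(study.peaks("prethrombin-2"), noise_sigma=0.01,
                               lb_hz=study.lb_hz, field_mhz=FIELD, seed=1)
        mut = simulate_spectrum(study.peaks("prethrombin-2", omit=("215",)),
                                noise_sigma=0.01, lb_hz=study.lb_hz,
                                field_mhz=FIELD, seed=2)
        fwd = assign_by_difference(wt, mut)
        rev = assign_by_difference(mut, wt)
        assert [r.extremum_ppm for r in fwd] == [r.extremum_ppm for r in rev]
        assert [r.max_abs_diff for r in fwd] == [r.max_abs_diff for r in rev]

    def test_mismatched_axes_rejected(self):
        a = simulate_spectrum([Peak(-47.0, 50.0)], n_points=1024, noise_sigma=0.0)
        b = simulate_spectrum([Peak(-47.0, 50.0)], n_points=2048, noise_sigma=0.0)
        with pytest.raises(ValueError):
            assign_by_difference(a, b)


class TestIO:
    def test_spectrum_csv_round_trip(self, tmp_path):
        s = simulate_spectrum([Peak(-47.0, 50.0)], n_points=512,
                              noise_sigma=0.01, seed=4)
        path = tmp_path / "spec.csv"
        s.to_csv(path)
        back = Spectrum1D.from_csv(path)
        assert np.array_equal(back.ppm, s.ppm)
        assert np.array_equal(back.intensity, s.intensity)
        assert back.field_mhz == s.field_mhz
        assert back.lb_hz == s.lb_hz

    def test_assignment_table_round_trip(self, tmp_path, study):
        table = study.assignment("thrombin")
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = AssignmentTable.from_csv(path)
        assert back.protein == "thrombin"
        assert back.entries["29"] is None
        assert back.entries["60d"] == [-48.5, -48.7]

    def test_noise_estimate_matches_generator(self):
        s = simulate_spectrum([Peak(-44.0, 50.0)], noise_sigma=0.05, seed=9)
        assert estimate_noise_sigma(s) == pytest.approx(0.05, rel=0.15)
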