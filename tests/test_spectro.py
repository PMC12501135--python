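"""Spectral processing: differencing, alignment, fitting, quantification, QC."""

import numpy as np
import pandas as pd
import pytest

from eibdyn import spectro
from eibdyn.spectro import (AlignmentError, FitResult, Spectrum,
                            TissueFractions, align_spectra,
                            difference_spectrum, fit_diff_spectrum,
                            qc_exclusion, quantify_concentration)


def make_axis(dppm=0.002):
    return np.arange(0.5, 10.5, dppm)


def gaussian(ppm, amp, center, sigma):
    return amp * np.exp(-0.5 * ((ppm - center) / sigma) ** 2)


class TestDifference:
    def test_identical_spectra_zero_diff(self):
        ppm = make_axis()
        s = Spectrum(ppm, np.sin(ppm), kind="ON")
        d = difference_spectrum(s, Spectrum(ppm, np.sin(ppm), kind="OFF"))
        assert d.kind == "DIFF"
        assert np.all(d.intensity == 0)

    def test_unit_gaussian_minus_flat(self):
        ppm = make_axis()
        peak = gaussian(ppm, 1.0, 3.0, 0.05)
        d = difference_spectrum(Spectrum(ppm, peak, "ON"),
                                Spectrum(ppm, np.zeros_like(ppm), "OFF"))
        assert np.allclose(d.intensity, peak)

    def test_axis_mismatch_raises(self):
        a = Spectrum(make_axis(), np.zeros(5000), "ON")
        b = Spectrum(make_axis()[::-1], np.zeros(5000), "OFF")
        with pytest.raises(AlignmentError):
            difference_spectrum(a, b)

    def test_nonmonotone_axis_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))


class TestAlignment:
    def test_already_aligned_zero_shifts(self):
        ppm = make_axis()
        specs = [Spectrum(ppm, gaussian(ppm, 1, 3.0, 0.05)) for _ in range(4)]
        _, shifts = align_spectra(specs)
        assert np.all(shifts == 0)

    def test_grid_aligned_displacement_recovered(self):
        ppm = make_axis(dppm=0.002)
        ref = Spectrum(ppm, gaussian(ppm, 1, 3.0, 0.05))
        shifted = Spectrum(ppm, gaussian(ppm, 1, 3.02, 0.05))
        aligned, shifts = align_spectra([ref, shifted])
        assert shifts[1] == pytest.approx(-0.02, abs=1e-9)
        mask = np.abs(ppm - 3.0) < 0.2
        assert np.allclose(aligned[1].intensity[mask], ref.intensity[mask],
                           atol=1e-6)

    def test_idempotent(self):
        ppm = make_axis()
        specs = [Spectrum(ppm, gaussian(ppm, 1, 3.0, 0.05)),
                 Spectrum(ppm, gaussian(ppm, 1, 3.01, 0.05))]
        aligned, _ = align_spectra(specs)
        again, shifts2 = align_spectra(aligned)
        assert np.all(shifts2 == 0)
        for a, b in zip(aligned, again):
            assert np.array_equal(a.intensity, b.intensity)

    def test_no_peak_warns_zero_shift(self):
        rng = np.random.default_rng(0)
        ppm = make_axis()
        ref = Spectrum(ppm, gaussian(ppm, 1, 3.0, 0.05)
                       + rng.normal(0, 0.01, ppm.size))
        peakless = rng.normal(0, 0.01, ppm.size)
        peakless[np.abs(ppm - 3.0) < 0.35] = 0.0
        flat = Spectrum(ppm, peakless)
        with pytest.warns(UserWarning, match="reference peak"):
            _, shifts = align_spectra([ref, flat])
        assert shifts[1] == 0.0


class TestFitting:
    def test_noiseless_gaussian_area_closed_form(self):
        ppm = make_axis()
        amp, sigma = 2.0, 0.04
        diff = Spectrum(ppm, gaussian(ppm, amp, 3.0, sigma), "DIFF")
        fit = fit_diff_spectrum(diff)
        expected = amp * sigma * np.sqrt(2 * np.pi)
        assert fit.gaba_area == pytest.approx(expected, rel=1e-3)
        assert fit.gaba_fit_error_pct < 0.1

    def test_doublet_area_closed_form(self):
        ppm = make_axis()
        amp, sigma = 1.5, 0.035
        doublet = gaussian(ppm, amp, 3.71, sigma) + gaussian(ppm, amp, 3.79, sigma)
        fit = fit_diff_spectrum(Spectrum(ppm, doublet, "DIFF"))
        expected = 2 * amp * sigma * np.sqrt(2 * np.pi)
        assert fit.glx_area == pytest.approx(expected, rel=1e-3)

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(1)
        ppm = make_axis()
        fit = fit_diff_spectrum(Spectrum(ppm, rng.normal(0, 1.0, ppm.size), "DIFF"))
        # fitted amplitude is on the order of the noise SD against a 2xSD
        # denominator, so SNR sits near 0.5-2, far below a real peak's
        assert fit.gaba_snr < 3.0
        assert fit.gaba_fit_error_pct > 10.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        ppm = make_axis()
        y = (gaussian(ppm, 1.0, 3.0, 0.04)
             + gaussian(ppm, 0.8, 3.71, 0.035) + gaussian(ppm, 0.8, 3.79, 0.035)
             + rng.normal(0, 0.02, ppm.size))
        f1 = fit_diff_spectrum(Spectrum(ppm, y, "DIFF"))
        f3 = fit_diff_spectrum(Spectrum(ppm, 3.0 * y, "DIFF"))
        assert f3.gaba_area == pytest.approx(3 * f1.gaba_area, rel=1e-4)
        assert f3.glx_area == pytest.approx(3 * f1.glx_area, rel=1e-4)
        assert f3.gaba_fit_error_pct == pytest.approx(f1.gaba_fit_error_pct, rel=1e-3)

    def test_short_axis_rejected(self):
        ppm = np.linspace(2.9, 3.1, 100)
        with pytest.raises(ValueError, match="2.6"):
            fit_diff_spectrum(Spectrum(ppm, np.zeros(100), "DIFF"))


class TestQuantification:
    def fit(self, gaba=1.0, glx=1.0):
        return FitResult(gaba_area=gaba, glx_area=glx, gaba_fit_error_pct=1,
                         glx_fit_error_pct=1, gaba_snr=10, glx_snr=10)

    def test_equal_areas_unit_eib(self):
        frac = TissueFractions(0.7, 0.3, 0.0)
        c = quantify_concentration(self.fit(2.5, 2.5), water_area=123.0,
                                   fractions=frac)
        assert c.eib == pytest.approx(1.0)

    def test_linearity_and_eib_invariance(self):
        frac = TissueFractions(0.6, 0.3, 0.1)
        c1 = quantify_concentration(self.fit(1.0, 2.0), 100.0, frac)
        c2 = quantify_concentration(self.fit(2.0, 4.0), 100.0, frac)
        assert c2.gaba_plus == pytest.approx(2 * c1.gaba_plus)
        assert c2.glx == pytest.approx(2 * c1.glx)
        assert c2.eib == pytest.approx(c1.eib)

    def test_water_homogeneity_degree_minus_one(self):
        frac = TissueFractions(0.6, 0.3, 0.1)
        c1 = quantify_concentration(self.fit(), 100.0, frac)
        c2 = quantify_concentration(self.fit(), 200.0, frac)
        assert c2.gaba_plus == pytest.approx(c1.gaba_plus / 2)

    def test_mm_correction_is_55_percent(self):
        frac = TissueFractions(0.6, 0.3, 0.1)
        c = quantify_concentration(self.fit(), 100.0, frac, mm_correct=True)
        assert c.mm_corrected_gaba == pytest.approx(0.55 * c.gaba_plus)

    def test_nonpositive_gaba_area_rejected(self):
        with pytest.raises(ValueError, match="EIB undefined"):
            quantify_concentration(self.fit(gaba=0.0), 100.0,
                                   TissueFractions(0.6, 0.3, 0.1))

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            TissueFractions(0.6, 0.3, 0.2)


class TestQcExclusion:
    @staticmethod
    def table(cells):
        """Build a 6-subject metrics table, zero everywhere except ``cells``:
        {(subject, session, metric): value}."""
        rows = []
        for subj in "ABCDEF":
            for ses in ("rest", "0back"):
                for metric in ("gaba_snr", "gaba_fit_error"):
                    # constant background: cells with zero spread never flag,
                    # so only the injected extremes drive the rule
                    rows.append({"subject": subj, "session": ses,
                                 "metric": metric,
                                 "value": cells.get((subj, ses, metric), 0.0)})
        return pd.DataFrame(rows)

    def test_two_metrics_one_session_excluded(self):
        t = self.table({("A", "rest", "gaba_snr"): 5.0,
                        ("A", "rest", "gaba_fit_error"): 5.0})
        out = qc_exclusion(t).set_index("subject")
        assert out.loc["A", "exclude"]

    def test_single_flag_retained(self):
        t = self.table({("B", "rest", "gaba_snr"): 5.0})
        out = qc_exclusion(t).set_index("subject")
        assert not out.loc["B", "exclude"]

    def test_same_metric_two_sessions_excluded(self):
        t = self.table({("C", "rest", "gaba_snr"): 5.0,
                        ("C", "0back", "gaba_snr"): 5.0})
        out = qc_exclusion(t).set_index("subject")
        assert out.loc["C", "exclude"]

    def test_order_invariance(self):
        t = self.table({("A", "rest", "gaba_snr"): 5.0,
                        ("A", "0back", "gaba_fit_error"): 5.0})
        out1 = qc_exclusion(t)
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out2 = qc_exclusion(shuffled)
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_subjects(self):
        t = self.table({}).query("subject in ['A', 'B']")
        with pytest.raises(ValueError, match="3 subjects"):
            qc_exclusion(t)
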