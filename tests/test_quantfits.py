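"""Hill binding, FRAP recovery, sedimentation and calibration fits."""

import math

import numpy as np
import pytest

from flipper.quantfits import (
    AVOGADRO,
    FrapTrace,
    TitrationCurve,
    calibration_quantify,
    fit_frap,
    fit_hill,
    normalize_frap,
    pellet_fraction,
    titration_series,
)

K_TRUE = math.log(2.0) / 131.0  # half-recovery at 131 s


def _frap_data(a=0.8, k=K_TRUE, n=40, t_max=600.0):
    t = np.linspace(0.0, t_max, n)
    return t, a * (1.0 - np.exp(-k * t))


def _hill_data(kd=1.21, bmax=100.0, n=12):
    x = np.geomspace(0.03, 40.0, n)
    return x, bmax * x / (kd + x)


class TestNormalizeFrap:
    def test_constant_trace_flat_one(self):
        n = 30
        t = tuple(np.arange(-10.0, n - 10.0))
        trace = FrapTrace(t, (100.0,) * n, (100.0,) * n, (10.0,) * n)
        assert normalize_frap(trace) == pytest.approx(np.ones(n))

    def test_photobleach_drift_removed(self):
        """A 20% reference drift over the acquisition cancels out and the
        recovered rate stays within 1% of truth."""
        t = np.arange(-15.0, 300.0, 3.0)
        drift = np.exp(np.log(0.8) * (t - t[0]) / (t[-1] - t[0]))
        true = np.where(t < 0, 1.0, 0.25 + 0.6 * (1 - np.exp(-K_TRUE * np.maximum(t, 0))))
        bg = 12.0
        trace = FrapTrace(tuple(t), tuple(500 * true * drift + bg),
                          tuple(500 * drift + bg), tuple(np.full(t.size, bg)))
        norm = normalize_frap(trace)
        assert norm[t < 0].mean() == pytest.approx(1.0, abs=1e-9)
        post = t >= 0
        res = fit_frap(t[post], norm[post] - norm[post][0], n_boot=0)
        assert res.params["k"] == pytest.approx(K_TRUE, rel=0.01)

    def test_zero_background_constant_reference(self):
        t = tuple(np.arange(-6.0, 6.0))
        ble = (4.0,) * 6 + (1.0, 2.0, 3.0, 3.5, 3.8, 4.0)
        trace = FrapTrace(t, ble, (8.0,) * 12, (0.0,) * 12)
        norm = normalize_frap(trace)
        assert norm == pytest.approx(np.array(ble) / 4.0)

    def test_bad_reference_and_missing_prebleach(self):
        t = tuple(np.arange(-6.0, 6.0))
        with pytest.raises(ValueError, match="unbleached"):
            normalize_frap(FrapTrace(t, (5.0,) * 12, (1.0,) * 12, (2.0,) * 12))
        with pytest.warns(UserWarning):
            post_only = FrapTrace(tuple(np.arange(12.0)), (5.0,) * 12,
                                  (8.0,) * 12, (0.0,) * 12)
        with pytest.raises(ValueError, match="pre-bleach"):
            normalize_frap(post_only)


class TestFitFrap:
    def test_noiseless_recovery_of_half_time(self):
        t, y = _frap_data()
        res = fit_frap(t, y, n_boot=0)
        assert res.derived["T_0.5"] == pytest.approx(131.0, rel=1e-4)
        assert res.params["A"] == pytest.approx(0.8, rel=1e-4)

    def test_half_recovery_definition(self):
        t, y = _frap_data()
        res = fit_frap(t, y, n_boot=0)
        a, k = res.params["A"], res.params["k"]
        t_half = res.derived["T_0.5"]
        assert a * (1 - math.exp(-k * t_half)) == pytest.approx(a / 2.0)

    def test_noisy_replicates_median_error_small(self):
        errors = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            t, y = _frap_data(n=30)
            noisy = y + rng.normal(0.0, 0.02 * 0.8, y.size)
            res = fit_frap(t, noisy, n_boot=0)
            errors.append(abs(res.params["k"] - K_TRUE) / K_TRUE)
        assert np.median(errors) < 0.05

    def test_flat_data_unidentifiable(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="flat"):
            fit_frap(t, np.full(10, 0.5), n_boot=0)

    def test_scale_equivariance(self):
        t, y = _frap_data()
        base = fit_frap(t, y, n_boot=0)
        scaled = fit_frap(t, 7.0 * y, n_boot=0)
        assert scaled.params["A"] == pytest.approx(7.0 * base.params["A"], rel=1e-6)
        assert scaled.params["k"] == pytest.approx(base.params["k"], rel=1e-6)

    def test_bootstrap_reproducible_and_tight_without_noise(self):
        t, y = _frap_data(n=20)
        a = fit_frap(t, y, n_boot=50, seed=3)
        b = fit_frap(t, y, n_boot=50, seed=3)
        assert a.se == b.se
        assert a.se["k"] < 1e-8  # zero residuals, zero spread


class TestFitHill:
    def test_noiseless_recovery_of_kd(self):
        x, y = _hill_data()
        res = fit_hill(TitrationCurve(tuple(x), tuple(y)), n_boot=0)
        assert res.params["K_D"] == pytest.approx(1.21, rel=1e-6)
        assert res.params["Bmax"] == pytest.approx(100.0, rel=1e-6)
        assert res.derived["K_0.5"] == res.params["K_D"]

    def test_half_occupancy_at_kd(self):
        x, y = _hill_data()
        res = fit_hill(TitrationCurve(tuple(x), tuple(y)), n_boot=0)
        bmax, kd = res.params["Bmax"], res.params["K_D"]
        assert bmax * kd / (kd + kd) == pytest.approx(bmax / 2.0)

    def test_noisy_replicates_low_bias_and_coverage(self):
        """3% multiplicative-scale noise: small median K_D error and the
        bootstrap interval covers the generating value most of the time."""
        errors, covered = [], 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            x, y = _hill_data()
            noisy = y + rng.normal(0.0, 3.0, y.size)
            res = fit_hill(TitrationCurve(tuple(x), tuple(noisy)),
                           n_boot=199, seed=rep)
            errors.append(abs(res.params["K_D"] - 1.21) / 1.21)
            lo, hi = res.ci95["K_D"]
            covered += lo <= 1.21 <= hi
        assert np.median(errors) < 0.10
        assert covered >= 0.85 * n_rep

    def test_rss_not_worse_than_initialization(self):
        rng = np.random.default_rng(5)
        x, y = _hill_data()
        noisy = y + rng.normal(0, 5.0, y.size)
        res = fit_hill(TitrationCurve(tuple(x), tuple(noisy)), n_boot=0)
        b0, kd0 = np.max(noisy), x[np.argmin(np.abs(noisy - np.max(noisy) / 2))]
        rss0 = np.sum((noisy - b0 * x / (kd0 + x)) ** 2)
        assert res.rss <= rss0 + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_hill(TitrationCurve((0.0, 1.0, 2.0), (0.0, 1.0, 2.0)), n_boot=0)
        with pytest.raises(ValueError):
            fit_hill(TitrationCurve((1.0, 2.0, 3.0), (0.0, 0.0, 0.0)), n_boot=0)
        with pytest.raises(ValueError):
            TitrationCurve((1.0, 2.0), (0.5, 0.6))  # < 3 points


class TestPelletFraction:
    @pytest.mark.parametrize("p,s,expected", [(1.0, 1.0, 0.5), (1.0, 0.0, 1.0),
                                              (30.0, 70.0, 0.3)])
    def test_values(self, p, s, expected):
        assert pellet_fraction(p, s) == pytest.approx(expected)

    def test_complement(self):
        assert pellet_fraction(3.0, 11.0) + pellet_fraction(11.0, 3.0) == \
            pytest.approx(1.0)

    def test_both_zero(self):
        with pytest.raises(ValueError):
            pellet_fraction(0.0, 0.0)


class TestTitrationSeries:
    def test_saturation_point_recovered(self):
        kd = 0.9
        x = np.array([0.1, 0.3, 0.6, 1.0, 2.0, 4.0, 8.0, 16.0])
        y = 0.95 * x / (kd + x)
        _, sat = titration_series(x, y, n_boot=0)
        assert sat == pytest.approx(19.0 * kd, rel=0.05)

    def test_flat_series_errors(self):
        with pytest.raises(ValueError, match="flat"):
            titration_series(np.arange(1.0, 6.0), np.full(5, 0.4), n_boot=0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            titration_series(np.array([1.0, 2.0]), np.array([0.2, 0.6]), n_boot=0)

    def test_non_monotone_warns(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = np.array([0.2, 0.6, 0.3, 0.7, 0.8])
        with pytest.warns(UserWarning, match="decreases"):
            titration_series(x, y, n_boot=0)


class TestCalibrationQuantify:
    VOL_FL = 50.0
    CELLS = 6e6
    MW = 5.5e5

    def _intensity_for(self, conc_um, slope=7.3, intercept=2.0):
        copies = conc_um * 1e-6 * AVOGADRO * self.VOL_FL * 1e-15
        ng = copies * self.MW / AVOGADRO * self.CELLS * 1e9
        return ng * slope + intercept

    def test_exact_interpolation_on_a_line(self):
        amt = np.array([1.0, 5.0, 10.0, 50.0, 100.0])
        inten = amt * 3.0 + 1.0
        res = calibration_quantify(amt, inten, [inten[2]], self.CELLS,
                                   self.VOL_FL, self.MW)
        assert res.amounts_ng[0] == pytest.approx(10.0)

    def test_planted_concentration_recovered(self):
        amt = np.geomspace(1.0, 2000.0, 6)
        inten = amt * 7.3 + 2.0
        sample = self._intensity_for(2.95)
        res = calibration_quantify(amt, inten, [sample], self.CELLS,
                                   self.VOL_FL, self.MW)
        assert res.concentrations_uM[0] == pytest.approx(2.95, rel=1e-9)

    def test_planted_two_to_one_molar_ratio(self):
        amt = np.geomspace(1.0, 4000.0, 6)
        inten = amt * 7.3 + 2.0
        samples = [self._intensity_for(5.90), self._intensity_for(2.95)]
        res = calibration_quantify(amt, inten, samples, self.CELLS,
                                   self.VOL_FL, self.MW)
        ratio = res.concentrations_uM[0] / res.concentrations_uM[1]
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_extrapolation_flagged_and_blocked(self):
        amt = np.array([1.0, 5.0, 10.0])
        inten = amt * 2.0
        with pytest.raises(ValueError, match="outside"):
            calibration_quantify(amt, inten, [100.0], self.CELLS,
                                 self.VOL_FL, self.MW)
        res = calibration_quantify(amt, inten, [100.0], self.CELLS,
                                   self.VOL_FL, self.MW,
                                   allow_extrapolation=True)
        assert res.extrapolated == (True,)

    def test_singular_standards_rejected(self):
        amt = np.array([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="singular|one amount"):
            calibration_quantify(amt, amt * 2, [10.0], self.CELLS,
                                 self.VOL_FL, self.MW)
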