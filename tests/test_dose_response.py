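import numpy as np
import pytest

from streammix import dose_response as dr


def logistic_data(y0=100.0, ec50=50.0, b=4.0, concs=(2, 5, 12, 30, 75, 190, 470)):
    """Noise-free responses on the logistic curve, with the four controls
    evaluated at the pseudo-log-concentration they enter the regression at
    (2 decades below the lowest treatment), so the fixture lies exactly on
    the fitted model."""
    concs = np.asarray(concs, dtype=float)
    x = np.log10(concs)
    curve = lambda xx: y0 / (1 + np.exp(b * (xx - np.log10(ec50))))  # noqa: E731
    responses = curve(x)
    controls = np.full(4, curve(x.min() - dr.CONTROL_OFFSET_DECADES))
    return concs, responses, controls


class TestFitLogistic3:
    def test_noise_free_recovery(self):
        concs, responses, controls = logistic_data()
        fit = dr.fit_logistic3(concs, responses, controls)
        assert fit.y0 == pytest.approx(100.0, rel=1e-6)
        assert 10**fit.x50 == pytest.approx(50.0, rel=1e-6)
        assert fit.b == pytest.approx(4.0, rel=1e-6)
        assert not fit.censored

    def test_flat_responses_censored_above_highest(self):
        concs = np.array([26.0, 80.0, 240.0, 1100.0])
        responses = np.array([100.0, 95.0, 102.0, 88.0])
        fit = dr.fit_logistic3(concs, responses, np.full(4, 100.0))
        assert fit.censored
        assert fit.censored_above == 1100.0
        with pytest.raises(ValueError, match="censored"):
            dr.ecp(fit, 0.5)

    def test_censoring_threshold_uses_control_mean(self):
        # weakest response dips below 80% of control -> a fit is attempted
        concs, responses, controls = logistic_data(ec50=400.0)
        fit = dr.fit_logistic3(concs, responses, controls)
        assert not fit.censored

    def test_requires_positive_concentrations(self):
        with pytest.raises(ValueError):
            dr.fit_logistic3([0.0, 1.0, 2.0, 4.0], [1, 1, 1, 1], [1, 1])


class TestEcp:
    def test_midpoint_identity(self):
        concs, responses, controls = logistic_data()
        fit = dr.fit_logistic3(concs, responses, controls)
        assert dr.ecp(fit, 0.5) == pytest.approx(10**fit.x50)

    def test_ec20_hand_value(self):
        concs, responses, controls = logistic_data(ec50=50.0, b=4.0)
        fit = dr.fit_logistic3(concs, responses, controls)
        expected = 10 ** (np.log10(50.0) + np.log(0.25) / 4.0)
        assert dr.ecp(fit, 0.2) == pytest.approx(expected, rel=1e-6)
        assert dr.ecp(fit, 0.2) == pytest.approx(22.5, abs=0.05)

    def test_strictly_increasing_in_p(self):
        concs, responses, controls = logistic_data()
        fit = dr.fit_logistic3(concs, responses, controls)
        ps = np.linspace(0.05, 0.95, 19)
        ecs = [dr.ecp(fit, p) for p in ps]
        assert np.all(np.diff(ecs) > 0)

    def test_invalid_p(self):
        concs, responses, controls = logistic_data()
        fit = dr.fit_logistic3(concs, responses, controls)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                dr.ecp(fit, bad)


class TestEcpConfidence:
    def test_noise_free_bootstrap_collapses_to_point(self):
        concs, responses, controls = logistic_data()
        fit = dr.fit_logistic3(concs, responses, controls)
        est = dr.ecp_confidence(fit, 0.5, n_boot=200, seed=0)
        assert est.ci_method == "bootstrap"
        assert est.ci_low == pytest.approx(est.conc, rel=1e-4)
        assert est.ci_high == pytest.approx(est.conc, rel=1e-4)

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(5)
        concs, responses, controls = logistic_data()
        responses = responses * np.exp(rng.normal(0, 0.1, responses.size))
        fit = dr.fit_logistic3(concs, responses, controls)
        a = dr.ecp_confidence(fit, 0.5, n_boot=100, seed=7)
        b = dr.ecp_confidence(fit, 0.5, n_boot=100, seed=7)
        c = dr.ecp_confidence(fit, 0.5, n_boot=100, seed=8)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_all_or_nothing_uses_bracketing(self):
        # no effect up to 26, total loss at 82 and above
        concs = np.array([8.0, 26.0, 82.0, 250.0])
        responses = np.array([100.0, 98.0, 0.0, 0.0])
        fit = dr.fit_logistic3(concs, responses, np.full(4, 100.0))
        est = dr.ecp_confidence(fit, 0.5, seed=0)
        assert est.ci_method == "bracketing"
        assert est.ci_low == 26.0
        assert est.ci_high == 82.0
        assert est.ci_low <= est.conc <= est.ci_high


class TestFitPiecewise:
    @staticmethod
    def _piecewise_data(y0=100.0, x0=1.25, m=-80.0):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        y = y0 + m * np.maximum(x - x0, 0.0)
        return 10**x, y

    def test_noise_free_breakpoint_recovery(self):
        # true breakpoint sits on the candidate grid (midpoint of 1.0 and 1.5)
        concs, responses = self._piecewise_data()
        fit = dr.fit_piecewise(concs, responses)
        assert fit.x0 == pytest.approx(1.25, abs=1e-12)
        assert fit.y0 == pytest.approx(100.0, rel=1e-9)
        assert fit.m == pytest.approx(-80.0, rel=1e-9)
        assert fit.ec0 == pytest.approx(10**1.25, rel=1e-9)
        assert not fit.censored_above

    def test_flat_data_censored(self):
        concs = 10 ** np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        fit = dr.fit_piecewise(concs, np.full(5, 50.0))
        assert fit.censored_above == pytest.approx(100.0)

    def test_ec0_below_ec10_below_ec50(self):
        concs, responses = self._piecewise_data()
        pw = dr.fit_piecewise(concs, responses)
        lfit = dr.fit_logistic3(concs[1:], responses[1:], np.full(4, 100.0))
        assert pw.ec0 <= dr.ecp(lfit, 0.1) <= dr.ecp(lfit, 0.5)

    def test_needs_five_points(self):
        with pytest.raises(ValueError):
            dr.fit_piecewise([1, 10, 100, 1000], [9, 9, 5, 1])


class TestNormalizeToControl:
    def test_fractions(self):
        out = dr.normalize_to_control([197.0, 0.0, 250.0], 197.0)
        assert out[0] == 1.0
        assert out[1] == 0.0
        assert out[2] > 1.0  # may exceed 1

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            dr.normalize_to_control([1.0], 0.0)
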