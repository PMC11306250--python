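import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actotrap import dwells as dw
from actotrap.detection import BindingEvent
from actotrap.params import ParameterError


def hypo_sample(rng, n, k_fast, k_slow):
    """Sequential two-exponential dwells (the generator truth)."""
    return rng.exponential(1 / k_fast, n) + rng.exponential(1 / k_slow, n)


class TestCumulativeDwellFit:
    def test_minimum_events(self):
        with pytest.raises(ParameterError):
            dw.cumulative_dwell_fit(np.ones(10))

    def test_single_exponential_degenerate_case(self, rng):
        k = 7.0
        fit = dw.cumulative_dwell_fit(rng.exponential(1 / k, 1000))
        # the dominant component carries the rate; the other is spurious
        dom = fit.k1 if abs(fit.A1) > abs(fit.A2) else fit.k2_obs
        spur_amp = min(abs(fit.A1), abs(fit.A2))
        assert dom == pytest.approx(k, rel=0.10)
        assert spur_amp < 0.15

    def test_hypoexponential_recovery(self, rng):
        fit = dw.cumulative_dwell_fit(hypo_sample(rng, 2000, 19.4, 5.5))
        assert fit.k1 == pytest.approx(5.5, rel=0.10)
        assert fit.k2_obs == pytest.approx(19.4, rel=0.10)
        assert fit.n_events == 2000
        assert fit.R2 > 0.99

    def test_component_ordering(self, rng):
        fit = dw.cumulative_dwell_fit(hypo_sample(rng, 500, 12.0, 1.0))
        assert fit.k1 < fit.k2_obs

    def test_estimator_consistency(self):
        # slow-rate bias shrinks as n grows (averaged over seeds)
        biases = []
        for n in (250, 1000, 4000):
            errs = []
            for seed in range(4):
                rng = np.random.default_rng(1000 + seed)
                fit = dw.cumulative_dwell_fit(hypo_sample(rng, n, 19.4, 5.5))
                errs.append(fit.k1 - 5.5)
            biases.append(abs(np.mean(errs)))
        assert biases[2] < biases[0]

    def test_y0_fixed_by_default(self, rng):
        fit = dw.cumulative_dwell_fit(hypo_sample(rng, 300, 10.0, 2.0))
        assert fit.y0 == 0.0
        fit2 = dw.cumulative_dwell_fit(hypo_sample(rng, 300, 10.0, 2.0),
                                       free_y0=True)
        assert abs(fit2.y0) < 0.1


def _mkfit(k_slow, k_fast, se_slow=0.05, se_fast=0.5):
    return dw.DwellFit(A1=1.0, k1=k_slow, A2=-0.3, k2_obs=k_fast, y0=0.0,
                       stderr={"A1": 0.01, "k1": se_slow, "A2": 0.01,
                               "k2_obs": se_fast, "y0": 0.0},
                       n_events=1000, R2=0.999)


class TestClassifyRates:
    def test_exact_slope_example(self):
        # ATP-dependent components 0.55 and 5.5 at 0.01 / 0.1 mM -> 55
        fits = [_mkfit(0.55, 19.4, 0.01, 1.0), _mkfit(5.5, 19.4, 0.1, 1.0)]
        cls = dw.classify_rates(fits, [0.01, 0.1])
        assert cls.k2_0 == pytest.approx(55.0, rel=1e-6)
        assert cls.k1_0 == pytest.approx(19.4, rel=1e-6)

    def test_invariant_component_average(self):
        fits = [_mkfit(0.5, 8.0, 0.01, 0.2), _mkfit(5.0, 8.0, 0.1, 0.2)]
        cls = dw.classify_rates(fits, [0.01, 0.1])
        assert cls.k1_0 == pytest.approx(8.0, rel=1e-6)

    def test_permutation_invariance(self):
        f1 = _mkfit(0.55, 19.4, 0.01, 1.0)
        # swap the component order inside the record
        f1_swapped = dw.DwellFit(
            A1=f1.A2, k1=f1.k2_obs, A2=f1.A1, k2_obs=f1.k1, y0=0.0,
            stderr={"A1": 0.01, "k1": 1.0, "A2": 0.01, "k2_obs": 0.01,
                    "y0": 0.0}, n_events=1000, R2=0.999)
        f2 = _mkfit(5.5, 19.4, 0.1, 1.0)
        a = dw.classify_rates([f1, f2], [0.01, 0.1])
        b = dw.classify_rates([f1_swapped, f2], [0.01, 0.1])
        assert a.k1_0 == pytest.approx(b.k1_0, rel=1e-9)
        assert a.k2_0 == pytest.approx(b.k2_0, rel=1e-9)

    def test_no_invariant_component_fails(self):
        # both components scale with ATP
        fits = [_mkfit(0.5, 1.0, 0.005, 0.01),
                _mkfit(5.0, 10.0, 0.05, 0.1)]
        with pytest.raises(dw.ClassificationError):
            dw.classify_rates(fits, [0.01, 0.1])

    def test_needs_two_levels(self):
        with pytest.raises(ParameterError):
            dw.classify_rates([_mkfit(1.0, 5.0)], [0.1])

    def test_end_to_end_recovery_s267e(self):
        # simulation truths from the measured table: 19.4 / 55
        rng = np.random.default_rng(30)
        fits = [dw.cumulative_dwell_fit(hypo_sample(rng, 3000, 19.4, kb),
                                        n_boot=40, seed=5)
                for kb in (0.55, 5.5)]
        cls = dw.classify_rates(fits, [0.01, 0.1])
        assert abs(cls.k1_0 - 19.4) < 2 * cls.k1_se
        assert abs(cls.k2_0 - 55.0) < 2 * cls.k2_se

    def test_end_to_end_recovery_s267a(self):
        # k1 = 4.7 also recovered when the 100 uM level is degenerate
        rng = np.random.default_rng(40)
        fits = [dw.cumulative_dwell_fit(hypo_sample(rng, 3000, 4.7, kb),
                                        n_boot=40, seed=6)
                for kb in (0.46, 4.6)]
        cls = dw.classify_rates(fits, [0.01, 0.1])
        assert abs(cls.k1_0 - 4.7) < 2 * cls.k1_se


class TestGaussianFit:
    def test_exact_gaussian_sample(self, rng):
        x = rng.normal(18.2, 4.0, 2000)
        fit = dw.displacement_gaussian_fit(x)
        assert abs(fit.xc - 18.2) < 2 * max(fit.stderr["xc"],
                                            4.0 / np.sqrt(2000))
        assert fit.w == pytest.approx(8.0, rel=0.1)  # w = 2 sigma

    def test_min_events(self, rng):
        with pytest.raises(ParameterError):
            dw.displacement_gaussian_fit(rng.normal(0, 1, 50))

    def test_narrow_sample_auto_bins(self, rng):
        # sample tighter than the default 2-nm bin still fits
        x = rng.normal(15.3, 0.6, 400)
        fit = dw.displacement_gaussian_fit(x)
        assert fit.xc == pytest.approx(15.3, abs=0.15)

    def test_bimodal_warning(self, rng):
        x = np.concatenate([rng.normal(-8, 1.0, 300),
                            rng.normal(8, 1.0, 300)])
        with pytest.warns(UserWarning, match="bimodal"):
            fit = dw.displacement_gaussian_fit(x)
        assert fit is not None

    @given(shift=st.floats(-30, 30))
    @settings(max_examples=10, deadline=None)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(7)
        x = rng.normal(10.0, 3.0, 500)
        f0 = dw.displacement_gaussian_fit(x)
        f1 = dw.displacement_gaussian_fit(x + shift)
        assert f1.xc - shift == pytest.approx(f0.xc, abs=0.02)


def _events(dwells, gaps, t0=1.0):
    out, t = [], t0
    for d, g in zip(dwells, gaps):
        out.append(BindingEvent(t, t + d, d, 10.0, 0.5, 10.0, 100.0))
        t += d + g
    return out


class TestDutyAndOnRate:
    def test_values(self):
        ev = _events([0.5] * 20, [1.5] * 20, t0=0.0)
        total = 40.0
        res = dw.apparent_duty_and_onrate(ev, total)
        assert res["duty"] == pytest.approx(10.0 / 40.0)
        assert res["on_rate"] == pytest.approx(20 / 30.0)

    def test_full_coverage_errors(self):
        ev = _events([1.0] * 20, [0.0] * 20, t0=0.0)
        with pytest.raises(ParameterError):
            dw.apparent_duty_and_onrate(ev, 20.0)

    def test_near_full_coverage_duty_is_one(self):
        ev = _events([1.0] * 20, [1e-6] * 20, t0=0.0)
        res = dw.apparent_duty_and_onrate(ev, 20.0 + 20e-6)
        assert res["duty"] == pytest.approx(1.0, abs=1e-4)

    def test_min_events(self):
        with pytest.raises(ParameterError):
            dw.apparent_duty_and_onrate(_events([0.1] * 5, [1.0] * 5), 10.0)

    def test_on_rate_recovers_attachment_rate(self, s267e, cond_100um):
        from actotrap import synthetics as sy

        traj = sy.simulate_state_sequence(s267e.rates, cond_100um, 600.0, 55)
        periods = traj.attached_periods()
        ev = [BindingEvent(a, b, b - a, 10.0, 0.5, 10.0, 100.0)
              for a, b in periods]
        res = dw.apparent_duty_and_onrate(ev, traj.duration)
        se = s267e.rates.k_att / np.sqrt(len(ev))
        assert abs(res["on_rate"] - s267e.rates.k_att) < 2.5 * se

    def test_duty_quotient_between_variants(self, s267e, cond_100um):
        # equal attachment rates: quotient ~ attached-time ratio ~ 1.85
        from actotrap import synthetics as sy
        from actotrap.params import variant

        a = variant("S267A")
        duties = {}
        for v, seed in ((a, 81), (s267e, 82)):
            traj = sy.simulate_state_sequence(v.rates, cond_100um, 3000.0,
                                              seed)
            ev = [BindingEvent(x, y, y - x, 10.0, 0.5, 10.0, 100.0)
                  for x, y in traj.attached_periods()]
            duties[v.name] = dw.apparent_duty_and_onrate(
                ev, traj.duration)["duty"]
        q = duties["S267A"] / duties["S267E"]
        # finite t_off = 2 s compresses the ideal 1.85 somewhat
        ideal = (0.43016 / 2.43016) / (0.23337 / 2.23337)
        assert q == pytest.approx(ideal, rel=0.10)
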