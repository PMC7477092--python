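"""Induction kinetics: PI, crossing times, WUEi, integrals, curvature, dip."""

import numpy as np
import pandas as pd
import pytest

from leafdyn.core import InductionTrace
from leafdyn.errors import (DomainError, NoInductionError,
                            UndefinedMetricError)
from leafdyn.induction import (InductionAnalyzer, detect_dip, gross_vs_j,
                               induction_fraction, integrate_window,
                               stomatal_opening, time_to_fraction, wue_i)

TAU_S = 240.0  # 4 min


def exp_trace(ai=2.0, af=26.0, tau=TAU_S, dt=2.0, dur=3600.0, notch=None):
    t = np.arange(-300.0, dur + dt / 2, dt)
    a = np.where(t < 0, ai, ai + (af - ai) * (1.0 - np.exp(-np.maximum(t, 0) / tau)))
    if notch is not None:
        # V-shaped excursion below the frozen pre-notch level, so the
        # realized peak-to-trough drawdown equals the nominal depth
        t0, depth, width = notch
        inside = np.abs(t - t0) <= width
        base = a[np.searchsorted(t, t0 - width)]
        a[inside] = base - depth * (1.0 - np.abs(t[inside] - t0) / width)
    gs = np.where(t < 0, 0.22, 0.22 + 0.38 * (1.0 - np.exp(-np.maximum(t, 0) / 360.0)))
    return InductionTrace(pd.DataFrame({
        "time_s": t, "PAR": np.where(t < 0, 50.0, 1500.0), "A": a, "gs": gs,
        "Ci": np.full_like(t, 320.0), "Ca": 400.0, "VPD": 7.0, "O2": 21.0,
    }))


class TestInductionFraction:
    def test_endpoints_map_to_0_and_100(self):
        tr = exp_trace()
        pi = induction_fraction(tr, ai=2.0, af=26.0)
        assert pi.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert pi.iloc[-1] == pytest.approx(100.0, abs=0.1)

    def test_midpoint_with_measured_steady_values(self):
        # Ai = 2.0, Af = 26.0 (control wildtype steady states), A = 14.0
        assert (14.0 - 2.0) / (26.0 - 2.0) * 100.0 == pytest.approx(50.0)
        tr = exp_trace()
        pi = induction_fraction(tr, ai=2.0, af=26.0)
        k = int(np.argmin(np.abs(pi.values - 50.0)))
        a_at_k = tr.data.loc[tr.data["time_s"] >= 0, "A"].iloc[k]
        assert a_at_k == pytest.approx(14.0, abs=0.1)

    def test_affine_invariance(self):
        tr = exp_trace()
        pi1 = induction_fraction(tr, ai=2.0, af=26.0)
        shifted = exp_trace(ai=7.0, af=31.0)  # +5 to everything
        pi2 = induction_fraction(shifted, ai=7.0, af=31.0)
        np.testing.assert_allclose(pi1.values, pi2.values, atol=1e-9)

    def test_no_induction_error(self):
        tr = exp_trace()
        with pytest.raises(NoInductionError):
            induction_fraction(tr, ai=26.0, af=2.0)


class TestTimeToFraction:
    def test_closed_form_exponential(self):
        """tau = 4 min: t50 = tau ln2 = 2.773 min, t90 = tau ln10 = 9.210 min."""
        tr = exp_trace()
        pi = induction_fraction(tr, ai=2.0, af=26.0)
        t50 = time_to_fraction(pi, 50.0)
        t90 = time_to_fraction(pi, 90.0)
        assert t50 == pytest.approx(4.0 * np.log(2.0), abs=0.02)
        assert t90 == pytest.approx(4.0 * np.log(10.0), abs=0.02)
        assert t90 / t50 == pytest.approx(np.log(10.0) / np.log(2.0), abs=0.02)
        assert t50 < t90

    def test_step_crossing_interpolated_within_bracket(self):
        pi = pd.Series([0.0, 0.0, 100.0, 100.0], index=[0.0, 2.0, 4.0, 6.0])
        t = time_to_fraction(pi, 50.0, smooth_width=1)
        assert 2.0 / 60.0 < t < 4.0 / 60.0

    def test_never_crossing_raises(self):
        pi = pd.Series([0.0, 10.0, 20.0], index=[0.0, 2.0, 4.0])
        with pytest.raises(UndefinedMetricError):
            time_to_fraction(pi, 90.0)

    def test_agrees_with_brute_force_fine_grid(self):
        """Crossing times match a 10x-resampled brute-force scan to within
        one raw sampling interval."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            tau = rng.uniform(120.0, 600.0)
            tr = exp_trace(tau=tau)
            noisy = tr.data.copy()
            noisy["A"] += rng.normal(0.0, 0.3, len(noisy))
            tr2 = InductionTrace(noisy)
            pi = induction_fraction(tr2, ai=2.0, af=26.0)
            for target in (50.0, 90.0):
                t = time_to_fraction(pi, target)
                # oracle: same smoothing, then linear resample at 0.2 s
                s = pi.rolling(5, center=True, min_periods=1).median()
                tf = np.arange(s.index[0], s.index[-1], 0.2)
                vf = np.interp(tf, s.index.to_numpy(), s.to_numpy())
                t_oracle = tf[np.argmax(vf >= target)] / 60.0
                assert abs(t - t_oracle) <= 2.0 / 60.0 + 1e-9


class TestWUE:
    @pytest.mark.parametrize("a, gs, expected", [
        (26.0, 0.60, 43.33),   # control wildtype at high irradiance
        (28.4, 1.03, 27.57),   # control flacca: ratio ~ 1.6
        (0.0, 0.5, 0.0),
    ])
    def test_quotients(self, a, gs, expected):
        assert wue_i(a, gs) == pytest.approx(expected, abs=0.01)

    def test_genotype_ratio(self):
        assert wue_i(26.0, 0.60) / wue_i(28.4, 1.03) == pytest.approx(1.57, abs=0.01)

    def test_nonpositive_gs_rejected(self):
        with pytest.raises(DomainError):
            wue_i(5.0, 0.0)


class TestIntegrals:
    def test_constant_field(self):
        tr = exp_trace(ai=10.0, af=10.0001, tau=1e9)
        tr.data["A"] = 10.0
        assert integrate_window(tr, "A") == pytest.approx(50.0, rel=1e-6)

    def test_linear_ramp_triangle_area(self):
        t = np.arange(-300.0, 302.0, 2.0)
        df = pd.DataFrame({
            "time_s": t, "PAR": np.where(t < 0, 50.0, 1500.0),
            "A": np.where(t < 0, 0.0, t / 30.0),  # 0 -> 10 over 5 min
            "gs": 0.3, "Ci": 300.0, "Ca": 400.0, "VPD": 7.0, "O2": 21.0,
        })
        assert integrate_window(InductionTrace(df), "A") == pytest.approx(25.0, rel=1e-6)

    def test_coverage_gap_warns_but_returns(self):
        tr = exp_trace()
        thinned = tr.data[(tr.data["time_s"] < 100) | (tr.data["time_s"] > 130)]
        tr2 = InductionTrace(thinned)
        with pytest.warns(UserWarning, match="gap"):
            val = integrate_window(tr2, "A")
        assert np.isfinite(val)


class TestStomatalOpening:
    def test_constant_gs_zero_delta(self):
        tr = exp_trace()
        tr.data["gs"] = 0.4
        gsi, gsf, d = stomatal_opening(tr)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_exponential_opening(self):
        tr = exp_trace()
        gsi, gsf, d = stomatal_opening(tr)
        assert gsi == pytest.approx(0.22, abs=1e-6)
        assert d == pytest.approx(0.38, abs=0.01)


class TestGrossVsJ:
    J = np.linspace(40.0, 180.0, 15)

    def test_linear_data(self):
        rep = gross_vs_j(2.0 + 0.22 * self.J, self.J)
        assert rep.c == pytest.approx(0.0, abs=1e-10)
        assert rep.r2_linear == pytest.approx(1.0)
        assert not rep.curved

    def test_quadratic_coefficient_recovered(self):
        rep = gross_vs_j(0.1 * self.J + 0.001 * self.J ** 2, self.J)
        assert rep.c == pytest.approx(0.001, rel=1e-6)
        assert rep.curved

    def test_requires_enough_points(self):
        with pytest.raises(DomainError):
            gross_vs_j(np.ones(5), np.arange(5.0) + 1)


class TestDip:
    def test_monotone_trace_has_no_dip(self):
        assert not detect_dip(exp_trace()).present

    def test_injected_notch_detected(self):
        tr = exp_trace(notch=(108.0, 1.0, 24.0))  # 1 umol dip at 1.8 min
        dip = detect_dip(tr)
        assert dip.present
        assert dip.time_min == pytest.approx(1.8, abs=0.4)
        assert dip.depth == pytest.approx(1.0, abs=0.4)

    def test_subthreshold_notch_absent(self):
        tr = exp_trace(notch=(108.0, 0.3, 24.0))
        assert not detect_dip(tr).present


def test_analyzer_end_to_end_on_synthetic_trace(wt_control_clean):
    trace, truth = wt_control_clean
    m = InductionAnalyzer().analyze(trace)
    assert m.t50_min == pytest.approx(truth.t50_min, abs=2.0 / 60.0)
    assert m.t90_min == pytest.approx(truth.t90_min, abs=2.0 / 60.0)
    assert m.ai == pytest.approx(truth.ai, abs=1e-9)
    assert 0 < m.t50_min < m.t90_min
    assert m.delta_gs == pytest.approx(0.38, abs=0.02)
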