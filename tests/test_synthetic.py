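"""Generator fidelity: steady-state anchors, determinism, round trips."""

import numpy as np
import pytest

from leafdyn.calibration import fit_rd_s
from leafdyn.errors import ScenarioError
from leafdyn.fvcb import fit_aci
from leafdyn.induction import induction_fraction, time_to_fraction
from leafdyn.io import write_trace
from leafdyn.synthetic import (preset, simulate_induction,
                               simulate_response_curve)
from tests.conftest import clean_preset


class TestSteadyStateAnchors:
    def test_wt_control_endpoints_match_measured_table(self, wt_control_clean):
        """Wildtype control steady states: A 2.0 -> 26.0, gs 0.22 -> 0.60,
        Ci 379 -> 311, all within 5 %."""
        trace, truth = wt_control_clean
        df = truth.clean_trace.data
        pre, post = df[df["time_s"] < 0], df[df["time_s"] >= 3300.0]
        assert truth.ai == pytest.approx(2.0, rel=0.05)
        assert truth.af == pytest.approx(26.0, rel=0.05)
        assert pre["gs"].mean() == pytest.approx(0.22, rel=0.05)
        assert post["gs"].mean() == pytest.approx(0.60, rel=0.05)
        assert pre["Ci"].mean() == pytest.approx(379.0, rel=0.05)
        assert post["Ci"].mean() == pytest.approx(311.0, rel=0.05)

    def test_flacca_control_gs_endpoints(self, flacca_control_clean):
        trace, truth = flacca_control_clean
        df = truth.clean_trace.data
        assert df[df["time_s"] < 0]["gs"].mean() == pytest.approx(0.62, rel=0.05)
        assert df[df["time_s"] >= 3300.0]["gs"].mean() == pytest.approx(1.03, rel=0.05)

    @pytest.mark.parametrize("genotype, treatment, gs_i", [
        ("WT", "high_vpd", 0.14),
        ("WT", "low_co2", 0.34),
        ("flacca", "high_vpd", 0.58),
        ("flacca", "low_co2", 0.58),
    ])
    def test_preset_initial_gs(self, genotype, treatment, gs_i):
        assert preset(genotype, treatment).gs_i == pytest.approx(gs_i, abs=1e-9)

    def test_flacca_initial_gs_insensitive_to_environment(self):
        vals = [preset("flacca", tr).gs_i for tr in ("control", "low_co2", "high_vpd")]
        assert max(vals) - min(vals) < 0.05

    def test_unknown_preset_rejected(self):
        with pytest.raises(ScenarioError):
            preset("WT", "drought")


class TestDynamics:
    def test_no_dynamics_when_everything_pre_activated(self):
        sc = clean_preset("WT", "control",
                          gs_f=0.22, act0_r=1.0, act0_j=1.0, lag_min=1e-6)
        trace, _ = simulate_induction(sc)
        post = trace.data[trace.data["time_s"] >= 0]["A"]
        assert post.max() - post.min() < 1e-6

    def test_determinism_byte_identical(self, tmp_path):
        sc = preset("WT", "control", seed=11)
        t1, _ = simulate_induction(sc)
        t2, _ = simulate_induction(sc)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trace(t1, p1)
        write_trace(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        t3, _ = simulate_induction(preset("WT", "control", seed=12))
        assert not np.allclose(t3.data["A"], t1.data["A"])

    def test_ground_truth_metrics_recompute_exactly(self, wt_control_clean):
        _, truth = wt_control_clean
        pi = induction_fraction(truth.clean_trace, ai=truth.ai, af=truth.af)
        assert time_to_fraction(pi, 50.0) == truth.t50_min
        assert time_to_fraction(pi, 90.0) == truth.t90_min

    def test_optional_dip_injection(self):
        sc = clean_preset("flacca", "control", dip_enabled=True)
        from leafdyn.induction import detect_dip
        trace, _ = simulate_induction(sc)
        dip = detect_dip(trace)
        assert dip.present
        assert 1.0 < dip.time_min < 3.0


class TestResponseCurves:
    def test_a_nondecreasing_in_ca_below_tpu(self, wt_calibration_curves):
        _, _, aci21 = wt_calibration_curves
        df = aci21.data
        sub = df[df["Ca"] <= 900.0].sort_values("Ca")
        assert np.all(np.diff(sub["A"]) > -1e-9)

    def test_aci_round_trip_recovers_scenario_biochemistry(self, wt_calibration_curves):
        sc, _, aci21 = wt_calibration_curves
        res = fit_aci(aci21, rd=sc.rd, cc_source="cc", gm=sc.gm)
        assert res.params.vcmax == pytest.approx(sc.vcmax, rel=1e-3)
        assert res.params.j == pytest.approx(sc.j1500, rel=1e-3)
        assert res.params.tpu == pytest.approx(sc.tpu, rel=1e-3)

    def test_apar_round_trip_recovers_rd_and_s(self, wt_calibration_curves):
        sc, apar, _ = wt_calibration_curves
        rd, s, r2 = fit_rd_s(apar)
        assert rd == pytest.approx(sc.rd, rel=0.05)
        assert s == pytest.approx(sc.s, rel=0.05)
        assert r2 > 0.999

    def test_low_o2_suppresses_photorespiration(self):
        sc = clean_preset("WT", "control")
        c21 = simulate_response_curve(sc, "ACI", levels=[150.0], o2=21.0)
        c2 = simulate_response_curve(sc, "ACI", levels=[150.0], o2=2.0)
        assert c2.data["A"].iloc[0] > c21.data["A"].iloc[0]
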