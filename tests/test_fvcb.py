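"""FvCB demand model, A/Ci fitting and the supply-demand intersection."""

import numpy as np
import pandas as pd
import pytest

from leafdyn.core import ResponseCurve
from leafdyn.errors import DomainError, UnderDeterminedError
from leafdyn.fvcb import (FvCBModel, FvCBParams, aci_with_supply, demand_a,
                          fit_aci, regimes)

# chosen so that all three regimes appear on CC_GRID (Rubisco below
# ~290 ubar, RuBP in between, TPU above ~980 ubar)
P = FvCBParams(vcmax=100.0, j=150.0, tpu=11.0, rd=1.0)


def synth_curve(p: FvCBParams, cc, noise=0.0, rng=None):
    cc = np.asarray(cc, dtype=float)
    a = demand_a(cc, p)
    if noise:
        a = a + rng.normal(0.0, noise, len(cc))
    df = pd.DataFrame({
        "time_s": np.arange(len(cc), dtype=float), "PAR": 1500.0, "A": a,
        "gs": 0.5, "Ci": cc, "Ca": cc / 0.8, "VPD": 7.0, "O2": 21.0,
    })
    return ResponseCurve(df, mode="ACI")


CC_GRID = np.array([50, 80, 120, 160, 200, 250, 300, 400, 550, 700,
                    900, 1100, 1400, 1800], dtype=float)


class TestDemand:
    def test_compensation_point_gives_minus_rd(self):
        assert demand_a(P.gamma_star, P) == pytest.approx(-P.rd, abs=1e-12)

    def test_rubp_limited_asymptote(self):
        p = FvCBParams(vcmax=1e4, j=180.0, tpu=1e4, rd=1.0)
        assert demand_a(1e7, p) == pytest.approx(180.0 / 4.0 - 1.0, rel=1e-4)

    def test_hand_evaluated_rubisco_limited_point(self):
        # Km = 405 (1 + 210/278); Ac = 100*160/910.93 = 17.5645
        p = FvCBParams(vcmax=100.0, j=1e3, tpu=1e3, rd=1.0,
                       gamma_star=40.0, kc=405.0, ko=278.0, o=210.0)
        assert demand_a(200.0, p) == pytest.approx(16.5645, abs=1e-3)

    def test_rejects_nonpositive_cc(self):
        with pytest.raises(DomainError):
            demand_a(0.0, P)

    def test_nondecreasing_in_cc_up_to_plateau(self):
        cc = np.linspace(P.gamma_star + 1.0, 2500.0, 400)
        a = demand_a(cc, P)
        assert np.all(np.diff(a) >= -1e-10)

    def test_regime_order_follows_cc(self):
        labels = regimes(CC_GRID, P)
        order = {"Rubisco": 0, "RuBP": 1, "TPU": 2}
        idx = [order[l] for l in labels]
        assert idx == sorted(idx)


class TestFit:
    def test_noise_free_recovery_within_01_percent(self):
        res = fit_aci(synth_curve(P, CC_GRID), rd=P.rd)
        for got, true in [(res.params.vcmax, P.vcmax), (res.params.j, P.j),
                          (res.params.tpu, P.tpu)]:
            assert abs(got - true) / true < 1e-3
        assert res.converged
        assert set(res.regimes) == {"Rubisco", "RuBP", "TPU"}

    def test_under_determined(self):
        with pytest.raises(UnderDeterminedError):
            fit_aci(synth_curve(P, CC_GRID[:4]), rd=P.rd)

    def test_single_regime_flags_unidentifiable(self):
        low_cc = np.array([60.0, 90, 120, 150, 180, 210])  # Rubisco only
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = fit_aci(synth_curve(P, low_cc), rd=P.rd)
        assert not res.identifiable["tpu"]
        assert not res.identifiable["j"]
        assert res.identifiable["vcmax"]

    def test_optimum_beats_every_multistart_seed(self):
        curve = synth_curve(P, CC_GRID)
        model = FvCBModel(rd=P.rd)
        x, y = curve.data["Ci"].to_numpy(), curve.data["A"].to_numpy()
        model.fit(x, y)
        for v0 in model.vcmax_grid:
            for j0 in model.j_grid:
                for t0 in model.tpu_grid:
                    p0 = FvCBParams(vcmax=v0, j=j0, tpu=t0, rd=P.rd)
                    sse0 = float(np.sum((y - demand_a(x, p0)) ** 2))
                    assert model.sse_ <= sse0 + 1e-9

    def test_fit_rd_recovers_respiration(self):
        res = fit_aci(synth_curve(P, CC_GRID), rd=0.0, fit_rd=True)
        assert res.params.rd == pytest.approx(P.rd, abs=1e-3)

    def test_sklearn_clone_and_params_roundtrip(self):
        from sklearn.base import clone
        m = FvCBModel(rd=2.0, cc_source="cc", gm=0.5)
        m2 = clone(m)
        assert m2.get_params() == m.get_params()


class TestSupplyDemand:
    def test_infinite_conductances_reach_demand_at_ca(self):
        a, ci, cc = aci_with_supply(P, gs=1e7, ca=400.0, gm=1e7)
        assert ci == pytest.approx(400.0, abs=1e-3)
        assert cc == pytest.approx(400.0, abs=1e-3)
        assert a == pytest.approx(float(demand_a(400.0, P)), abs=1e-4)

    def test_supply_identity_holds_at_fixed_point(self):
        a, ci, cc = aci_with_supply(P, gs=0.4, ca=400.0, gm=0.4)
        assert a == pytest.approx((0.4 / 1.6) * (400.0 - ci), rel=1e-8)
        residual = a - float(demand_a(cc, P))
        assert abs(residual) < 1e-8 * max(1.0, a)

    def test_halving_gs_lowers_ci_and_a(self):
        a1, ci1, _ = aci_with_supply(P, gs=0.4, ca=400.0, gm=0.4)
        a2, ci2, _ = aci_with_supply(P, gs=0.2, ca=400.0, gm=0.4)
        assert a2 < a1 and ci2 < ci1

    def test_matches_brute_force_grid_solve(self):
        """Cross-check the root-finder against a dense grid scan of the
        supply-demand residual."""
        gs, ca, gm = 0.3, 400.0, 0.35
        ci_grid = np.linspace(P.gamma_star + 1e-3, ca, 200001)
        supply = (gs / 1.6) * (ca - ci_grid)
        cc_grid = np.maximum(ci_grid - supply / gm, 1e-9)
        resid = supply - demand_a(cc_grid, P)
        k = int(np.argmin(np.abs(resid)))
        a, ci, _ = aci_with_supply(P, gs=gs, ca=ca, gm=gm)
        assert ci == pytest.approx(ci_grid[k], abs=(ca - P.gamma_star) / 100000)

    def test_negative_assimilation_in_darkness(self):
        p = FvCBParams(vcmax=100.0, j=0.5, tpu=10.0, rd=1.0)
        a, ci, _ = aci_with_supply(p, gs=0.2, ca=400.0, gm=0.4)
        assert a < 0
        assert ci > 400.0  # respiring leaf: Ci exceeds Ca
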