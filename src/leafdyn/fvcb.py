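"""Steady-state FvCB demand model: evaluation, least-squares A/Ci fitting,
and the supply-demand intersection.

The demand side is the classic three-limitation biochemical model of C3
photosynthesis. Gross carboxylation at chloroplastic CO2 partial pressure
Cc (ubar) is the minimum of

    Ac = Vcmax (Cc - G*) / (Cc + Kc (1 + O/Ko))      Rubisco-limited
    Aj = J (Cc - G*) / (4 Cc + 8 G*)                 RuBP-regeneration-limited
    Ap = 3 TPU                                       export-limited

and net assimilation is A = min(Ac, Aj, Ap) - Rd. ``J`` here is the linear
electron transport rate at the single measuring irradiance (J1500 when the
curve is logged at 1500 umol m-2 s-1); no light- or temperature-response
functions are attached because all target measurements are at 25 C and one
irradiance.

Kinetic constants default to the widely used 25 C set (Kc = 404.9 ubar,
Ko = 278.4 mbar, Gamma* = 42.75 ubar) and are overridable.

The fit is a deterministic multi-start local least squares (3x3x3 start
grid); regime membership at each point is the plain minimum of the three
hypotheses (no smooth minimum), with ties broken toward Rubisco limitation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .core import ResponseCurve
from .errors import DomainError, NumericError, UnderDeterminedError

KC_25 = 404.9          # ubar
KO_25 = 278.4          # mbar
GAMMA_STAR_25 = 42.75  # ubar
O2_AMBIENT = 210.0     # mbar (21 %)

REGIMES = ("Rubisco", "RuBP", "TPU")


@dataclass(frozen=True)
class FvCBParams:
    """Demand-side model state. Rd is the magnitude of day respiration (>= 0)."""

    vcmax: float
    j: float
    tpu: float
    rd: float
    gamma_star: float = GAMMA_STAR_25
    kc: float = KC_25
    ko: float = KO_25
    o: float = O2_AMBIENT

    def __post_init__(self) -> None:
        for name in ("vcmax", "j", "tpu", "gamma_star", "kc", "ko", "o"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.rd < 0:
            raise DomainError(f"rd must be >= 0, got {self.rd}")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko), ubar."""
        return self.kc * (1.0 + self.o / self.ko)


def _gross_terms(cc, p: FvCBParams):
    cc = np.asarray(cc, dtype=float)
    ac = p.vcmax * (cc - p.gamma_star) / (cc + p.km)
    aj = p.j * (cc - p.gamma_star) / (4.0 * cc + 8.0 * p.gamma_star)
    ap = np.full_like(ac, 3.0 * p.tpu)
    return ac, aj, ap


def demand_a(cc, p: FvCBParams):
    """Net assimilation from the demand side at chloroplastic CO2 ``cc``."""
    if np.any(np.asarray(cc, float) <= 0):
        raise DomainError(f"Cc must be > 0, got {cc}")
    ac, aj, ap = _gross_terms(cc, p)
    return np.minimum(np.minimum(ac, aj), ap) - p.rd


def _demand_scalar(cc: float, p: FvCBParams) -> float:
    """Scalar fast path for root-finding loops (no array overhead)."""
    ac = p.vcmax * (cc - p.gamma_star) / (cc + p.km)
    aj = p.j * (cc - p.gamma_star) / (4.0 * cc + 8.0 * p.gamma_star)
    ap = 3.0 * p.tpu
    m = ac if ac <= aj else aj
    if ap < m:
        m = ap
    return m - p.rd


def regimes(cc, p: FvCBParams) -> np.ndarray:
    """Limitation label per point; ties resolve toward Rubisco, then RuBP."""
    ac, aj, ap = _gross_terms(np.atleast_1d(cc), p)
    stacked = np.stack([ac, aj, ap])
    idx = np.argmin(stacked, axis=0)  # argmin returns first minimum: Rubisco wins ties
    return np.array([REGIMES[i] for i in idx])


@dataclass
class FitResult:
    """Outcome of an A/Ci fit."""

    params: FvCBParams
    regimes: np.ndarray
    sse: float
    converged: bool
    identifiable: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


class FvCBModel(RegressorMixin, BaseEstimator):
    """Least-squares FvCB A/Ci estimator (sklearn interface).

    Parameters
    ----------
    rd : float
        Day respiration, fixed unless ``fit_rd``. Typically supplied by the
        fluorescence/gas-exchange calibration stage.
    fit_rd : bool
        Estimate Rd as a fourth free parameter.
    cc_source : {'ci', 'cc'}
        'ci' fits the curve against substomatal CO2 as the instrument
        reports it (apparent parameters); 'cc' first converts Ci to
        chloroplastic CO2 via ``Cc = Ci - A/gm`` using ``gm``.
    gm : float, optional
        Mesophyll conductance (mol m-2 s-1) used when ``cc_source='cc'``.
    gamma_star, kc, ko, o : float
        Kinetic constants, defaulting to the 25 C set.
    grids : three tuples
        Deterministic multi-start grid (Vcmax x J x TPU).

    Fitted attributes: ``vcmax_``, ``j_``, ``tpu_``, ``rd_``, ``sse_``,
    ``regimes_``, ``converged_``, ``identifiable_``, ``params_``.
    """

    def __init__(self, rd: float = 1.0, fit_rd: bool = False,
                 cc_source: str = "ci", gm: Optional[float] = None,
                 gamma_star: float = GAMMA_STAR_25, kc: float = KC_25,
                 ko: float = KO_25, o: float = O2_AMBIENT,
                 vcmax_grid: tuple = (50.0, 100.0, 150.0),
                 j_grid: tuple = (100.0, 175.0, 250.0),
                 tpu_grid: tuple = (5.0, 10.0, 15.0)):
        self.rd = rd
        self.fit_rd = fit_rd
        self.cc_source = cc_source
        self.gm = gm
        self.gamma_star = gamma_star
        self.kc = kc
        self.ko = ko
        self.o = o
        self.vcmax_grid = vcmax_grid
        self.j_grid = j_grid
        self.tpu_grid = tpu_grid

    # -- helpers ----------------------------------------------------------
    def _to_cc(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.cc_source == "cc":
            if self.gm is None:
                raise DomainError("cc_source='cc' requires gm")
            return x - y / self.gm
        if self.cc_source != "ci":
            raise DomainError(f"cc_source must be 'ci' or 'cc', got {self.cc_source!r}")
        return x

    def _params(self, theta: np.ndarray) -> FvCBParams:
        rd = theta[3] if self.fit_rd else self.rd
        return FvCBParams(vcmax=theta[0], j=theta[1], tpu=theta[2], rd=rd,
                          gamma_star=self.gamma_star, kc=self.kc, ko=self.ko,
                          o=self.o)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise DomainError("X and y must have the same length")
        n_free = 4 if self.fit_rd else 3
        if len(x) < n_free:
            raise UnderDeterminedError(
                f"{len(x)} points cannot constrain {n_free} free parameters"
            )
        cc = self._to_cc(x, y)
        if np.any(cc <= 0):
            raise DomainError("all Cc values must be > 0 after gm conversion")

        def residuals(theta):
            return y - demand_a(cc, self._params(theta))

        lb = [1e-2, 1e-2, 1e-2] + ([0.0] if self.fit_rd else [])
        ub = [np.inf] * n_free
        best = None
        for v0 in self.vcmax_grid:
            for j0 in self.j_grid:
                for t0 in self.tpu_grid:
                    theta0 = [v0, j0, t0] + ([max(self.rd, 0.1)] if self.fit_rd else [])
                    res = least_squares(residuals, theta0, bounds=(lb, ub),
                                        method="trf", xtol=1e-12, ftol=1e-12,
                                        gtol=1e-12)
                    if best is None or res.cost < best.cost:
                        best = res
        theta = best.x
        p = self._params(theta)
        self.vcmax_, self.j_, self.tpu_ = float(theta[0]), float(theta[1]), float(theta[2])
        self.rd_ = float(theta[3]) if self.fit_rd else float(self.rd)
        self.params_ = p
        self.cc_ = cc
        self.sse_ = float(2.0 * best.cost)
        self.regimes_ = regimes(cc, p)
        self.converged_ = bool(best.status > 0 and best.optimality < 1e-3 * (1.0 + self.sse_))
        self.identifiable_ = {
            "vcmax": "Rubisco" in self.regimes_,
            "j": "RuBP" in self.regimes_,
            "tpu": "TPU" in self.regimes_,
        }
        self.fit_warnings_ = []
        for name, ok in self.identifiable_.items():
            if not ok:
                msg = (f"parameter {name} is unidentifiable: no point falls in its "
                       f"limitation regime; returned value is not constrained by the data")
                self.fit_warnings_.append(msg)
                warnings.warn(msg, stacklevel=2)
        return self

    def predict(self, X):
        """Demand-model A at the fitted parameters.

        ``X`` is interpreted on the axis the model was fitted on: Ci when
        ``cc_source='ci'`` (Cc == Ci assumption), chloroplastic Cc when
        ``cc_source='cc'``.
        """
        x = np.asarray(X, dtype=float).reshape(-1)
        return demand_a(x, self.params_)

    def result(self) -> FitResult:
        return FitResult(params=self.params_, regimes=self.regimes_,
                         sse=self.sse_, converged=self.converged_,
                         identifiable=dict(self.identifiable_),
                         warnings=list(self.fit_warnings_))


def fit_aci(curve: ResponseCurve, rd: float = 1.0, fit_rd: bool = False,
            cc_source: str = "ci", gm: Optional[float] = None,
            **constants) -> FitResult:
    """Fit Vcmax, J1500, TPU (and optionally Rd) to an A/Ci response curve."""
    if curve.mode != "ACI":
        raise DomainError("fit_aci requires an ACI-mode curve")
    if len(curve) < 5:
        raise UnderDeterminedError("A/Ci fit requires at least 5 points")
    model = FvCBModel(rd=rd, fit_rd=fit_rd, cc_source=cc_source, gm=gm, **constants)
    model.fit(curve.data["Ci"].to_numpy(), curve.data["A"].to_numpy())
    return model.result()


def aci_with_supply(p: FvCBParams, gs: float, ca: float, gm: float,
                    gb: Optional[float] = None) -> tuple[float, float, float]:
    """Intersect the CO2 supply and demand functions; return (A, Ci, Cc).

    Solves simultaneously::

        A  = (Ca - Ci) / (1.6/gs [+ 1.37/gb])     stomatal (+ boundary-layer)
        Cc = Ci - A/gm                            mesophyll drawdown
        A  = demand_a(Cc)

    by bracketed root-finding on Ci. ``gb`` (boundary-layer conductance to
    water vapour) defaults to None, i.e. an infinitely stirred chamber, in
    which case the supply law is exactly A = (gs/1.6)(Ca - Ci).
    """
    if gs <= 0 or gm <= 0:
        raise DomainError(f"gs and gm must be > 0, got gs={gs}, gm={gm}")
    if ca <= p.gamma_star:
        raise DomainError(f"Ca ({ca}) must exceed gamma_star ({p.gamma_star})")
    r_tot = 1.6 / gs + (1.37 / gb if gb else 0.0)

    def resid(ci: float) -> float:
        a = (ca - ci) / r_tot
        cc = ci - a / gm
        if cc < 1e-9:
            cc = 1e-9
        return a - _demand_scalar(cc, p)

    lo, hi = p.gamma_star + 1e-9, ca
    f_hi = resid(hi)
    if f_hi > 0.0:
        # demand at Ca is negative (A < 0): the leaf releases CO2, Ci > Ca
        hi = ca + 2.0 * r_tot * (p.rd + 1.0)
        f_hi = resid(hi)
    f_lo = resid(lo)
    if f_lo * f_hi > 0.0:
        raise NumericError(
            f"no supply/demand sign change in bracket: gs={gs}, ca={ca}, gm={gm}, "
            f"gb={gb}, params={p}"
        )
    ci = brentq(resid, lo, hi, xtol=1e-10, rtol=1e-14)
    a = (ca - ci) / r_tot
    cc = ci - a / gm
    return float(a), float(ci), float(cc)
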