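"""Combined gas-exchange / fluorescence calibration of Rd, Gamma* and s.

Two-step regression scheme:

1. Under non-photorespiratory conditions (2 % O2, Ca ~ 2000 ubar) and
   strictly light-limited irradiances, J = 4 (A + Rd) and J = s PAR PhiPSII,
   hence A is affine in x = PAR * PhiPSII / 4 with slope s and intercept
   -Rd. Ordinary least squares on the low-irradiance points of the A/PAR
   curve yields s and Rd.
2. Gamma* is then found by least squares over the low-Ci points of the 21 %
   O2 A/Ci curve, inverting the RuBP-limited demand expression with the
   per-point J obtained from fluorescence:

       A_model(Ci; G*) = J (Ci - G*) / (4 Ci + 8 G*) - Rd .

   The result is the *apparent*, Ci-based compensation point: because the
   regression runs on Ci rather than chloroplastic Cc, a finite mesophyll
   conductance shifts the estimate upward by roughly half the Ci - Cc
   drawdown of the calibration points. The bias is systematic and
   documented (see the sensitivity test and docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .core import ResponseCurve
from .errors import DomainError, IllConditionedError, UnderDeterminedError
from .fluorescence import phi_psii


@dataclass(frozen=True)
class CalibrationParams:
    """Fluorescence/gas-exchange calibration output."""

    rd: float           # umol m-2 s-1
    gamma_star: float   # ubar (apparent, Ci-based)
    s: float            # dimensionless PAR*PhiPSII -> J factor
    r2: float           # R^2 of the Rd/s regression
    n_points: int


class RdSCalibrator(BaseEstimator):
    """OLS estimator of Rd and s from a non-photorespiratory A/PAR curve.

    ``fit(X, y)`` expects ``X`` with columns (PAR, PhiPSII) and ``y`` = A.
    Points with PAR above ``low_par_max`` are excluded (the linear J = 4(A+Rd)
    reading only holds while strictly light-limited).

    Fitted attributes: ``s_``, ``rd_``, ``r2_``, ``n_points_``.
    """

    def __init__(self, low_par_max: float = 200.0):
        self.low_par_max = low_par_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 2:
            raise DomainError("X must have two columns: (PAR, PhiPSII)")
        par, phi = X[:, 0], X[:, 1]
        keep = par <= self.low_par_max
        par, phi, y = par[keep], phi[keep], y[keep]
        if len(y) < 4:
            raise UnderDeterminedError(
                f"need >= 4 low-irradiance points, got {len(y)}"
            )
        x = par * phi / 4.0
        if x.min() <= 0 or x.max() / x.min() < 2.0:
            raise IllConditionedError(
                f"regressor range too narrow: x in [{x.min():.3g}, {x.max():.3g}]"
            )
        res = linregress(x, y)
        self.s_ = float(res.slope)
        self.rd_ = float(-res.intercept)
        self.r2_ = float(res.rvalue ** 2)
        self.n_points_ = int(len(y))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.s_ * X[:, 0] * X[:, 1] / 4.0 - self.rd_


class GammaStarEstimator(BaseEstimator):
    """Bounded 1-D least squares for the apparent CO2 compensation point.

    ``fit(X, y)`` expects ``X`` with columns (Ci, PAR, PhiPSII) and
    ``y`` = A; ``rd`` and ``s`` come from :class:`RdSCalibrator`. Only
    points with Ci <= ``ci_max`` enter the objective (stay below the
    Aj/Ap transitions). A boundary optimum raises a warning and sets
    ``boundary_``.
    """

    def __init__(self, rd: float = 1.0, s: float = 0.45,
                 ci_max: float = 200.0, bounds: tuple = (10.0, 100.0)):
        self.rd = rd
        self.s = s
        self.ci_max = ci_max
        self.bounds = bounds

    @staticmethod
    def _model(ci, j, gamma_star, rd):
        return j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star) - rd

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 3:
            raise DomainError("X must have three columns: (Ci, PAR, PhiPSII)")
        ci, par, phi = X[:, 0], X[:, 1], X[:, 2]
        keep = ci <= self.ci_max
        ci, par, phi, y = ci[keep], par[keep], phi[keep], y[keep]
        if len(y) < 3:
            raise UnderDeterminedError(
                f"need >= 3 points with Ci <= {self.ci_max}, got {len(y)}"
            )
        j = self.s * par * phi

        def sse(g):
            return float(np.sum((y - self._model(ci, j, g, self.rd)) ** 2))

        res = minimize_scalar(sse, bounds=self.bounds, method="bounded",
                              options={"xatol": 1e-10})
        self.gamma_star_ = float(res.x)
        self.sse_ = float(res.fun)
        lo, hi = self.bounds
        self.boundary_ = bool(self.gamma_star_ - lo < 1e-3 * (hi - lo)
                              or hi - self.gamma_star_ < 1e-3 * (hi - lo))
        if self.boundary_:
            warnings.warn(
                f"gamma_star optimum at search bound ({self.gamma_star_:.2f} ubar); "
                f"estimate unreliable", stacklevel=2)
        self.n_points_ = int(len(y))
        return self


def _phi_from_curve(curve: ResponseCurve) -> np.ndarray:
    df = curve.data
    if df[["F", "Fm_prime"]].isna().any().any():
        raise DomainError("curve lacks paired fluorescence (F, Fm') on some rows")
    return np.asarray(phi_psii(df["F"], df["Fm_prime"]), dtype=float)


def fit_rd_s(apar_2pct: ResponseCurve, low_par_max: float = 200.0):
    """Rd, s and regression R^2 from a 2 % O2 A/PAR curve with fluorescence."""
    if apar_2pct.mode != "APAR":
        raise DomainError("fit_rd_s requires an APAR-mode curve")
    df = apar_2pct.data
    X = np.column_stack([df["PAR"].to_numpy(), _phi_from_curve(apar_2pct)])
    cal = RdSCalibrator(low_par_max=low_par_max).fit(X, df["A"].to_numpy())
    return cal.rd_, cal.s_, cal.r2_


def fit_gamma_star(aci_21pct: ResponseCurve, rd: float, s: float,
                   ci_max: float = 200.0, bounds: tuple = (10.0, 100.0)) -> float:
    """Apparent Gamma* from the low-Ci points of a 21 % O2 A/Ci curve."""
    if aci_21pct.mode != "ACI":
        raise DomainError("fit_gamma_star requires an ACI-mode curve")
    df = aci_21pct.data
    X = np.column_stack([
        df["Ci"].to_numpy(), df["PAR"].to_numpy(), _phi_from_curve(aci_21pct),
    ])
    est = GammaStarEstimator(rd=rd, s=s, ci_max=ci_max, bounds=bounds)
    est.fit(X, df["A"].to_numpy())
    return est.gamma_star_


def calibrate(apar_2pct: ResponseCurve, aci_21pct: ResponseCurve,
              low_par_max: float = 200.0, ci_max: float = 200.0) -> CalibrationParams:
    """Full two-step calibration: (Rd, s) then apparent Gamma*."""
    rd, s, r2 = fit_rd_s(apar_2pct, low_par_max=low_par_max)
    gamma_star = fit_gamma_star(aci_21pct, rd=rd, s=s, ci_max=ci_max)
    n = int((apar_2pct.data["PAR"] <= low_par_max).sum()
            + (aci_21pct.data["Ci"] <= ci_max).sum())
    return CalibrationParams(rd=rd, gamma_star=gamma_star, s=s, r2=r2, n_points=n)
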