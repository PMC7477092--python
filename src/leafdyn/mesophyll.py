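"""Variable-J mesophyll conductance and chloroplastic CO2.

The variable-J (Harley) method inverts the RuBP-limited demand expression:
given net assimilation A, substomatal Ci, electron transport J from
fluorescence, day respiration Rd and the compensation point Gamma*, the
chloroplastic CO2 implied by J is

    Cc = Gamma* (J + 8 (A + Rd)) / (J - 4 (A + Rd))

and mesophyll conductance follows from Fick's law, gm = A / (Ci - Cc).
The expression amplifies errors violently as J approaches 4 (A + Rd), so
points within a configurable margin of that singularity are flagged
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .calibration import CalibrationParams
from .errors import DomainError, PhotorespirationInconsistencyError
from .fluorescence import phi_psii


@dataclass(frozen=True)
class MesophyllResult:
    """Per-measurement variable-J outcome with echoed inputs."""

    gm: float
    cc: float
    a: float
    ci: float
    j: float
    rd: float
    gamma_star: float
    valid: bool
    reliable: bool = True
    reason: str = ""


def gm_variable_j(a: float, ci: float, j: float, rd: float, gamma_star: float,
                  singularity_margin: float = 0.05) -> MesophyllResult:
    """Variable-J estimate of gm and Cc for a single measurement.

    Raises :class:`PhotorespirationInconsistencyError` when
    J <= 4 (A + Rd) (no physical solution). A computed Cc outside
    (Gamma*, Ci) sets ``valid=False`` instead of raising; J within
    ``singularity_margin`` (relative) of 4 (A + Rd) sets ``reliable=False``.
    """
    if a <= 0:
        raise DomainError(f"variable-J requires A > 0, got {a}")
    if ci <= gamma_star:
        raise DomainError(f"requires Ci > gamma_star, got Ci={ci}, gamma_star={gamma_star}")
    ag = a + rd
    denom = j - 4.0 * ag
    if denom <= 0:
        raise PhotorespirationInconsistencyError(
            f"J={j} <= 4(A+Rd)={4 * ag}: fluorescence and gas exchange inconsistent"
        )
    cc = gamma_star * (j + 8.0 * ag) / denom
    drawdown = ci - cc
    valid = gamma_star < cc < ci
    gm = a / drawdown if drawdown != 0 else float("inf")
    if not valid:
        reason = f"computed Cc={cc:.1f} outside (gamma_star, Ci)=({gamma_star}, {ci})"
    else:
        reason = ""
    reliable = j >= (1.0 + singularity_margin) * 4.0 * ag
    if not reliable and not reason:
        reason = f"J within {singularity_margin:.0%} of the 4(A+Rd) singularity"
    return MesophyllResult(gm=float(gm), cc=float(cc), a=a, ci=ci, j=j, rd=rd,
                           gamma_star=gamma_star, valid=bool(valid and gm > 0),
                           reliable=bool(reliable), reason=reason)


def batch_gm(df: pd.DataFrame, calib: CalibrationParams,
             singularity_margin: float = 0.05) -> list[MesophyllResult]:
    """Variable-J gm for every row of a table with gas exchange + fluorescence.

    J is computed per row as s * PAR * PhiPSII with the calibrated s.
    Rows with missing or inconsistent fluorescence, or that violate the
    method's preconditions, yield flagged (invalid) results rather than
    being dropped: the output list always matches the input length.
    """
    out: list[MesophyllResult] = []
    for _, r in df.iterrows():
        a, ci, par = float(r["A"]), float(r["Ci"]), float(r["PAR"])
        f, fmp = float(r.get("F", np.nan)), float(r.get("Fm_prime", np.nan))
        if not (np.isfinite(f) and np.isfinite(fmp)):
            out.append(MesophyllResult(gm=np.nan, cc=np.nan, a=a, ci=ci, j=np.nan,
                                       rd=calib.rd, gamma_star=calib.gamma_star,
                                       valid=False, reliable=False,
                                       reason="missing fluorescence"))
            continue
        try:
            phi = float(phi_psii(f, fmp))
            j = calib.s * par * phi
            out.append(gm_variable_j(a, ci, j, calib.rd, calib.gamma_star,
                                     singularity_margin=singularity_margin))
        except Exception as exc:  # flagged, never silently dropped
            out.append(MesophyllResult(gm=np.nan, cc=np.nan, a=a, ci=ci,
                                       j=np.nan, rd=calib.rd,
                                       gamma_star=calib.gamma_star, valid=False,
                                       reliable=False, reason=str(exc)))
    return out


def results_frame(results: list[MesophyllResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


class VariableJMesophyll(TransformerMixin, BaseEstimator):
    """Transformer wrapper: rows of (A, Ci, PAR, F, Fm') -> (gm, Cc, flags).

    Stateless apart from the calibration constants passed at construction;
    ``fit`` is a no-op kept for pipeline compatibility.
    """

    def __init__(self, rd: float = 1.0, gamma_star: float = 42.75,
                 s: float = 0.45, singularity_margin: float = 0.05):
        self.rd = rd
        self.gamma_star = gamma_star
        self.s = s
        self.singularity_margin = singularity_margin

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        calib = CalibrationParams(rd=self.rd, gamma_star=self.gamma_star,
                                  s=self.s, r2=float("nan"), n_points=0)
        res = batch_gm(X, calib, singularity_margin=self.singularity_margin)
        frame = results_frame(res)
        frame.index = X.index
        return frame[["gm", "cc", "j", "valid", "reliable", "reason"]]
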