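"""Chlorophyll-fluorescence quenching quantities and the PhiPSII -> J conversion.

All functions accept scalars or numpy arrays and are invariant under a
common rescaling of the raw fluorescence counts. The light-adapted minimal
fluorescence Fo' is never measured here; it is always estimated with the
Oxborough-Baker closed form

    Fo' = Fo / (Fv/Fm + Fo/Fm')

which reduces to Fo in the dark limit (Fm' -> Fm). By construction the
definitional identity PhiPSII = qP * Fv'/Fm' is algebraically exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import FluorescenceSample
from .errors import InvalidFluorescenceError


def _check(cond, msg: str) -> None:
    if not np.all(cond):
        raise InvalidFluorescenceError(msg)


def fvfm(fo, fm):
    """Dark-adapted maximum PSII quantum efficiency, (Fm - Fo)/Fm."""
    fo, fm = np.asarray(fo, float), np.asarray(fm, float)
    _check(fo > 0, "Fo must be > 0")
    _check(fm > fo, f"requires Fm > Fo, got Fm={fm}, Fo={fo}")
    return (fm - fo) / fm


def phi_psii(f, fm_prime):
    """PSII operating efficiency in the light, (Fm' - F)/Fm'."""
    f, fm_prime = np.asarray(f, float), np.asarray(fm_prime, float)
    _check(f > 0, "F must be > 0")
    _check(fm_prime >= f, f"requires Fm' >= F, got F={f}, Fm'={fm_prime}")
    return (fm_prime - f) / fm_prime


def npq(fm, fm_prime):
    """Non-photochemical quenching, (Fm - Fm')/Fm'."""
    fm, fm_prime = np.asarray(fm, float), np.asarray(fm_prime, float)
    _check(fm_prime > 0, "Fm' must be > 0")
    _check(fm >= fm_prime, f"requires Fm >= Fm', got Fm={fm}, Fm'={fm_prime}")
    return (fm - fm_prime) / fm_prime


def fo_prime(fo, fm, fm_prime):
    """Estimated light-adapted minimal fluorescence (Oxborough-Baker)."""
    fo, fm = np.asarray(fo, float), np.asarray(fm, float)
    fm_prime = np.asarray(fm_prime, float)
    _check(fo > 0, "Fo must be > 0")
    _check(fm > fo, "requires Fm > Fo")
    _check(fm_prime > 0, "Fm' must be > 0")
    denom = fvfm(fo, fm) + fo / fm_prime
    _check(denom > 0, "Fo' denominator must be > 0")
    return fo / denom


def qp(f, fm_prime, fo_prime_):
    """Photochemical quenching coefficient, (Fm' - F)/(Fm' - Fo')."""
    f, fm_prime = np.asarray(f, float), np.asarray(fm_prime, float)
    fo_prime_ = np.asarray(fo_prime_, float)
    _check(fm_prime > fo_prime_,
           f"requires Fm' > Fo', got Fm'={fm_prime}, Fo'={fo_prime_}")
    return (fm_prime - f) / (fm_prime - fo_prime_)


def fvfm_prime(fm_prime, fo_prime_):
    """Efficiency of open PSII traps, (Fm' - Fo')/Fm'."""
    fm_prime = np.asarray(fm_prime, float)
    fo_prime_ = np.asarray(fo_prime_, float)
    _check(fo_prime_ > 0, "Fo' must be > 0")
    _check(fm_prime > fo_prime_, "requires Fm' > Fo'")
    return (fm_prime - fo_prime_) / fm_prime


def electron_transport(par, phi, s):
    """Linear electron transport J = s * PAR * PhiPSII (umol e- m-2 s-1).

    ``s`` is the lumped per-leaf calibration factor (absorptance times PSII
    fraction and any alternative-sink correction it absorbs).
    """
    if np.any(np.asarray(s, float) <= 0):
        raise InvalidFluorescenceError("s must be > 0")
    par = np.asarray(par, float)
    if np.any(par < 0):
        raise InvalidFluorescenceError("PAR must be >= 0")
    return s * par * np.asarray(phi, float)


@dataclass(frozen=True)
class QuenchingRecord:
    """Derived quenching quantities for one fluorescence measurement."""

    phi_psii: float
    npq: float
    qp: float
    fvfm_prime: float
    fo_prime: float
    j: float


def quench(sample: FluorescenceSample, par: float, s: float) -> QuenchingRecord:
    """Full quenching partitioning for one sample (needs dark Fo and Fm)."""
    if sample.fo is None or sample.fm is None:
        raise InvalidFluorescenceError("dark Fo and Fm required for quenching analysis")
    fop = float(fo_prime(sample.fo, sample.fm, sample.fm_prime))
    phi = float(phi_psii(sample.f, sample.fm_prime))
    return QuenchingRecord(
        phi_psii=phi,
        npq=float(npq(sample.fm, sample.fm_prime)),
        qp=float(qp(sample.f, sample.fm_prime, fop)),
        fvfm_prime=float(fvfm_prime(sample.fm_prime, fop)),
        fo_prime=fop,
        j=float(electron_transport(par, phi, s)),
    )


def quenching_frame(df: pd.DataFrame, s: float) -> pd.DataFrame:
    """Quenching columns for every row of a trace/curve table with fluorescence.

    Rows without an F / Fm' pair are skipped; the result is indexed by the
    original row index so it can be joined back onto the source table.
    """
    cols = ["F", "Fm_prime", "Fo", "Fm", "PAR"]
    sub = df[cols].dropna(subset=["F", "Fm_prime", "Fo", "Fm"])
    fop = fo_prime(sub["Fo"], sub["Fm"], sub["Fm_prime"])
    phi = phi_psii(sub["F"], sub["Fm_prime"])
    out = pd.DataFrame({
        "phi_psii": phi,
        "npq": npq(sub["Fm"], sub["Fm_prime"]),
        "qp": qp(sub["F"], sub["Fm_prime"], fop),
        "fvfm_prime": fvfm_prime(sub["Fm_prime"], fop),
        "fo_prime": fop,
        "J": electron_transport(sub["PAR"], phi, s),
    }, index=sub.index)
    return out
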