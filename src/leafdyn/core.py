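"""Domain containers and raw-signal corrections for leaf gas-exchange data.

Unit conventions used throughout the package
--------------------------------------------
* CO2 partial pressures (Ca, Ci, Cc, Gamma*) in ubar, numerically
  interchangeable with umol mol-1 at 1 bar total pressure.
* Net assimilation A in umol CO2 m-2 s-1.
* Stomatal conductance gs is conductance to *water vapour* in mol m-2 s-1;
  every supply-function computation divides by 1.6 to obtain the CO2
  conductance.
* Irradiance (PAR) in umol photons m-2 s-1, VPD in mbar, O2 in percent.
* time_s counts seconds since the step change to high irradiance; pre-step
  baseline samples carry negative time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError

#: canonical column order of a trace / curve table
TRACE_COLUMNS = [
    "time_s", "PAR", "A", "gs", "Ci", "Ca", "VPD", "O2",
    "F", "Fm_prime", "Fo", "Fm",
]

FLUOR_COLUMNS = ["F", "Fm_prime", "Fo", "Fm"]


@dataclass(frozen=True)
class FluorescenceSample:
    """One saturating-flash fluorescence record (arbitrary counts).

    ``f`` and ``fm_prime`` are the light-adapted operating and maximal
    fluorescence; ``fo``/``fm`` are the dark-adapted minimal and maximal
    levels when available.
    """

    f: float
    fm_prime: float
    fo: Optional[float] = None
    fm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.fm_prime >= self.f > 0):
            raise DomainError(
                f"fluorescence requires Fm' >= F > 0, got F={self.f}, Fm'={self.fm_prime}"
            )
        if self.fo is not None and self.fm is not None:
            if not (self.fm > self.fo > 0):
                raise DomainError(
                    f"dark fluorescence requires Fm > Fo > 0, got Fo={self.fo}, Fm={self.fm}"
                )


@dataclass(frozen=True)
class GasExchangeSample:
    """One logged instant of leaf gas exchange."""

    time_s: float
    a: float
    gs: float
    ci: float
    ca: float
    par: float
    vpd: float = float("nan")
    o2: float = 21.0
    fluor: Optional[FluorescenceSample] = None

    def __post_init__(self) -> None:
        if not self.gs > 0:
            raise DomainError(f"gs must be > 0, got {self.gs}")
        if not self.ca > 0:
            raise DomainError(f"Ca must be > 0, got {self.ca}")
        if not (0.0 <= self.o2 <= 100.0):
            raise DomainError(f"O2 must be in [0, 100] %, got {self.o2}")
        if self.ci > self.ca and self.a >= 0:
            raise DomainError(
                f"Ci ({self.ci}) may exceed Ca ({self.ca}) only when A < 0 (A={self.a})"
            )


def _row_valid(row: pd.Series) -> bool:
    """Row-level invariant check used when ingesting tabular data."""
    needed = ["time_s", "A", "gs", "Ci", "Ca", "PAR"]
    if not np.isfinite([row[c] for c in needed]).all():
        return False
    if row["gs"] <= 0 or row["Ca"] <= 0:
        return False
    o2 = row.get("O2", 21.0)
    if np.isfinite(o2) and not (0.0 <= o2 <= 100.0):
        return False
    if row["Ci"] > row["Ca"] and row["A"] >= 0:
        return False
    f, fmp = row.get("F", np.nan), row.get("Fm_prime", np.nan)
    if np.isfinite(f) and np.isfinite(fmp) and not (fmp >= f > 0):
        return False
    return True


def _samples_to_frame(samples: Iterable[GasExchangeSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        fl = s.fluor
        rows.append({
            "time_s": s.time_s, "PAR": s.par, "A": s.a, "gs": s.gs,
            "Ci": s.ci, "Ca": s.ca, "VPD": s.vpd, "O2": s.o2,
            "F": fl.f if fl else np.nan,
            "Fm_prime": fl.fm_prime if fl else np.nan,
            "Fo": (fl.fo if fl and fl.fo is not None else np.nan) if fl else np.nan,
            "Fm": (fl.fm if fl and fl.fm is not None else np.nan) if fl else np.nan,
        })
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


class _TableContainer:
    """Shared behaviour for DataFrame-backed sample collections."""

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def to_dataframe(self) -> pd.DataFrame:
        return self.data.copy()

    @property
    def samples(self) -> list[GasExchangeSample]:
        out = []
        for _, r in self.data.iterrows():
            fluor = None
            if np.isfinite(r["F"]) and np.isfinite(r["Fm_prime"]):
                fluor = FluorescenceSample(
                    f=float(r["F"]), fm_prime=float(r["Fm_prime"]),
                    fo=float(r["Fo"]) if np.isfinite(r["Fo"]) else None,
                    fm=float(r["Fm"]) if np.isfinite(r["Fm"]) else None,
                )
            out.append(GasExchangeSample(
                time_s=float(r["time_s"]), a=float(r["A"]), gs=float(r["gs"]),
                ci=float(r["Ci"]), ca=float(r["Ca"]), par=float(r["PAR"]),
                vpd=float(r["VPD"]), o2=float(r["O2"]), fluor=fluor,
            ))
        return out

    @staticmethod
    def _normalise(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for c in TRACE_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        return df[TRACE_COLUMNS].astype(float).reset_index(drop=True)


class ResponseCurve(_TableContainer):
    """An ordered steady-state response curve varying Ca (ACI) or PAR (APAR).

    Invariants: in ACI mode PAR is constant across samples, in APAR mode Ca
    is constant; fits additionally require >= 4 samples (enforced at fit
    time).
    """

    def __init__(self, data: pd.DataFrame, mode: Literal["ACI", "APAR"],
                 o2: float = 21.0) -> None:
        if mode not in ("ACI", "APAR"):
            raise FormatError(f"mode must be 'ACI' or 'APAR', got {mode!r}")
        df = self._normalise(data)
        if df.empty:
            raise EmptyInputError("response curve has no samples")
        if mode == "ACI" and not np.allclose(df["PAR"], df["PAR"].iloc[0], rtol=1e-6):
            raise FormatError("ACI curve requires constant PAR across samples")
        if mode == "APAR" and not np.allclose(df["Ca"], df["Ca"].iloc[0], rtol=1e-6):
            raise FormatError("APAR curve requires constant Ca across samples")
        self.data = df
        self.mode = mode
        self.o2 = float(o2)

    @classmethod
    def from_samples(cls, samples: Sequence[GasExchangeSample],
                     mode: Literal["ACI", "APAR"], o2: float = 21.0) -> "ResponseCurve":
        return cls(_samples_to_frame(samples), mode=mode, o2=o2)


class InductionTrace(_TableContainer):
    """A time-ordered low -> high irradiance transient at fixed cadence.

    Invariants: strictly increasing ``time_s``; at least one pre-step
    (negative-time) sample; PAR takes exactly two values, low before the
    step and high after it.
    """

    def __init__(self, data: pd.DataFrame, genotype: str = "",
                 treatment: str = "") -> None:
        df = self._normalise(data)
        if df.empty:
            raise EmptyInputError("induction trace has no samples")
        t = df["time_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise FormatError("time_s must be strictly increasing")
        if not (t < 0).any():
            raise FormatError("trace needs at least one pre-step (time_s < 0) sample")
        par_vals = np.unique(df["PAR"].round(6))
        if len(par_vals) != 2:
            raise FormatError(
                f"PAR must take exactly two values (low then high), got {par_vals}"
            )
        lo, hi = par_vals
        if not (df.loc[df["time_s"] < 0, "PAR"] == lo).all():
            raise FormatError("pre-step samples must all be at the low PAR level")
        self.data = df
        self.genotype = genotype
        self.treatment = treatment
        #: populated by io.read_trace with row-drop accounting
        self.report: dict = {}

    @classmethod
    def from_samples(cls, samples: Sequence[GasExchangeSample], genotype: str = "",
                     treatment: str = "") -> "InductionTrace":
        return cls(_samples_to_frame(samples), genotype=genotype, treatment=treatment)

    @property
    def par_low(self) -> float:
        return float(self.data["PAR"].min())

    @property
    def par_high(self) -> float:
        return float(self.data["PAR"].max())


# ---------------------------------------------------------------------------
# raw-signal corrections


def leak_correct(a_raw, ca, c_ambient, k_leak: float = 0.0,
                 leaf_area: float = 1.0):
    """Correct apparent assimilation for diffusive CO2 chamber leakage.

    A CO2 gradient between chamber (``ca``) and surrounding air
    (``c_ambient``) drives a diffusion leak with conductance ``k_leak``
    (mol s-1 bar-1); a positive outward gradient lowers apparent A, so the
    correction adds the leak flux back per unit ``leaf_area`` (m2):

        A = A_raw + k_leak * (Ca - C_ambient) / leaf_area

    ``k_leak = 0`` (the default) is the identity.
    """
    if leaf_area <= 0:
        raise DomainError(f"leaf_area must be > 0, got {leaf_area}")
    if k_leak < 0:
        raise DomainError(f"k_leak must be >= 0, got {k_leak}")
    return np.asarray(a_raw, dtype=float) + k_leak * (
        np.asarray(ca, dtype=float) - np.asarray(c_ambient, dtype=float)
    ) / leaf_area


def steady_window_mean(trace: InductionTrace, window: tuple[float, float],
                       fieldname: str) -> float:
    """Arithmetic mean of one field over a [t0, t1] window (seconds).

    Mirrors the instrument practice of logging for a short interval after
    reaching steady state and averaging to reduce noise.
    """
    t0, t1 = window
    df = trace.data
    mask = (df["time_s"] >= t0) & (df["time_s"] <= t1)
    if not mask.any():
        raise EmptyInputError(f"no samples in window [{t0}, {t1}] s")
    if fieldname not in df.columns:
        raise FormatError(f"unknown field {fieldname!r}")
    return float(df.loc[mask, fieldname].mean())
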