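"""Dynamic metrics of the low -> high irradiance transient.

Photosynthetic induction is expressed as percentage progress between the
initial (pre-step, shade-adapted) and final (fully induced) steady states,

    PI(t) = (A(t) - Ai) / (Af - Ai) * 100 ,

with Ai and Af taken as window means (defaults: the 5 min before the step
and minutes 55-60, both configurable; long transients need 40-60 min to
settle). t50 and t90 are the times of the *first* upward crossing of 50 %
and 90 % on a rolling-median-smoothed PI, linearly interpolated between the
bracketing samples; first-crossing semantics keep a post-dip re-crossing
from inflating the metrics, and the transient dip is reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .core import InductionTrace, steady_window_mean
from .errors import (DomainError, EmptyInputError, NoInductionError,
                     UndefinedMetricError)

#: default Ai / Af windows, seconds relative to the step (the pre window
#: ends just before t = 0 so the first high-irradiance sample is excluded)
PRE_WINDOW = (-300.0, -1.0)
FINAL_WINDOW = (3300.0, 3600.0)


@dataclass
class DipResult:
    """Descriptor of the transient assimilation dip (absence is valid)."""

    present: bool
    time_min: float = float("nan")
    depth: float = float("nan")


@dataclass
class CurvatureReport:
    """Quadratic fit of gross photosynthesis against electron transport."""

    c: float               # quadratic coefficient
    c_conf_int: tuple      # 95 % CI on c
    r2_linear: float       # R^2 of the purely linear fit
    curved: bool           # significantly positive c ("upwards curvature")


@dataclass
class InductionMetrics:
    """Per-transient summary of induction kinetics."""

    ai: float
    af: float
    t50_min: float
    t90_min: float
    gs_initial: float
    gs_final: float
    delta_gs: float
    wuei_initial: float
    wuei_final: float
    int_a_5min: float      # umol m-2 s-1 * min
    int_ci_5min: float     # ubar * min
    dip_present: bool
    dip_time_min: float
    dip_depth: float


def _smooth(values: pd.Series, width: int) -> pd.Series:
    if width <= 1:
        return values
    return values.rolling(width, center=True, min_periods=1).median()


def induction_fraction(trace: InductionTrace,
                       pre_window: tuple = PRE_WINDOW,
                       final_window: tuple = FINAL_WINDOW,
                       ai: Optional[float] = None,
                       af: Optional[float] = None) -> pd.Series:
    """PI(t) in percent for t >= 0, indexed by time_s.

    ``ai``/``af`` override the window means when the steady values are
    known externally (e.g. from ground truth). Raises
    :class:`NoInductionError` when Af <= Ai.
    """
    if ai is None:
        ai = steady_window_mean(trace, pre_window, "A")
    if af is None:
        af = steady_window_mean(trace, final_window, "A")
    if af <= ai:
        raise NoInductionError(f"Af ({af}) must exceed Ai ({ai})")
    df = trace.data[trace.data["time_s"] >= 0]
    pi = (df["A"] - ai) / (af - ai) * 100.0
    pi.index = df["time_s"].to_numpy()
    return pi


def time_to_fraction(pi: pd.Series, target: float,
                     smooth_width: int = 5) -> float:
    """Time (minutes) of the first upward crossing of ``target`` percent.

    A rolling median (default width 5 samples ~ 10 s at 2-s cadence) is
    applied before crossing detection so a single noise spike cannot
    trigger an early crossing; the same smoothing is applied identically
    for every target so t50 and t90 are comparable. The crossing time is
    linearly interpolated between the bracketing samples.
    """
    s = _smooth(pi, smooth_width)
    vals = s.to_numpy()
    t = np.asarray(s.index, dtype=float)
    above = vals >= target
    if not above.any():
        raise UndefinedMetricError(f"PI never reaches {target} %")
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0] / 60.0)
    t_cross = t[k - 1] + (target - vals[k - 1]) / (vals[k] - vals[k - 1]) * (t[k] - t[k - 1])
    return float(t_cross / 60.0)


def wue_i(a, gs):
    """Intrinsic water-use efficiency A/gs (umol CO2 mol-1 H2O)."""
    a = np.asarray(a, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if np.any(gs <= 0):
        raise DomainError("gs must be > 0")
    return a / gs


def wue_series(trace: InductionTrace) -> pd.Series:
    """WUEi over the whole trace, indexed by time_s."""
    df = trace.data
    s = pd.Series(wue_i(df["A"].to_numpy(), df["gs"].to_numpy()),
                  index=df["time_s"].to_numpy())
    return s


def integrate_window(trace: InductionTrace, fieldname: str,
                     t_start: float = 0.0, t_end: float = 300.0,
                     max_gap_s: float = 10.0) -> float:
    """Trapezoidal integral of a field over [t_start, t_end] seconds.

    Reported in field-units * min (e.g. umol m-2 s-1 * min for A). A
    coverage gap larger than ``max_gap_s`` raises a warning but the
    integral is still returned.
    """
    df = trace.data
    t = df["time_s"].to_numpy()
    if t.min() > t_start or t.max() < t_end:
        raise EmptyInputError(
            f"trace [{t.min()}, {t.max()}] s does not cover [{t_start}, {t_end}] s"
        )
    mask = (t >= t_start) & (t <= t_end)
    tt, yy = t[mask], df.loc[mask, fieldname].to_numpy()
    gaps = np.diff(np.concatenate([[t_start], tt, [t_end]]))
    if gaps.max() > max_gap_s:
        warnings.warn(f"coverage gap of {gaps.max():.1f} s in [{t_start}, {t_end}] s",
                      stacklevel=2)
    return float(np.trapezoid(yy, tt) / 60.0)


def stomatal_opening(trace: InductionTrace,
                     pre_window: tuple = PRE_WINDOW,
                     final_window: tuple = FINAL_WINDOW) -> tuple[float, float, float]:
    """(gs_initial, gs_final, delta_gs) from window means."""
    gsi = steady_window_mean(trace, pre_window, "gs")
    gsf = steady_window_mean(trace, final_window, "gs")
    return gsi, gsf, gsf - gsi


def gross_vs_j(ag, j, alpha: float = 0.05) -> CurvatureReport:
    """Quadratic regression Ag = a + b J + c J^2 and curvature assessment.

    A significantly positive ``c`` flags upwards curvature (carboxylation
    rising faster than electron transport, the signature of Ci recovery
    during stomatal opening). Requires >= 10 paired points.
    """
    ag = np.asarray(ag, dtype=float)
    j = np.asarray(j, dtype=float)
    if len(ag) < 10:
        raise DomainError(f"need >= 10 (Ag, J) pairs, got {len(ag)}")
    X2 = sm.add_constant(np.column_stack([j, j ** 2]))
    if np.linalg.matrix_rank(X2) < 3:
        raise DomainError("rank-deficient design (J values too few/collinear)")
    quad = sm.OLS(ag, X2).fit()
    lin = sm.OLS(ag, sm.add_constant(j)).fit()
    c = float(quad.params[2])
    ci_lo, ci_hi = (float(v) for v in quad.conf_int(alpha)[2])
    return CurvatureReport(c=c, c_conf_int=(ci_lo, ci_hi),
                           r2_linear=float(lin.rsquared),
                           curved=bool(c > 0 and ci_lo > 0))


def detect_dip(trace: InductionTrace, threshold: float = 0.5,
               window_min: tuple = (0.5, 4.0),
               smooth_width: int = 5) -> DipResult:
    """Detect the transient post-step assimilation dip.

    Works on the rolling-median-smoothed A restricted to ``window_min``
    (minutes after the step): the dip is the maximum peak-to-trough
    drawdown (a local maximum followed by a local minimum); it is reported
    present when the drawdown depth reaches ``threshold``
    (umol m-2 s-1). Absence is a valid result, never an error.
    """
    df = trace.data
    t = df["time_s"].to_numpy()
    lo, hi = window_min[0] * 60.0, window_min[1] * 60.0
    if t.max() < hi or t.min() > lo:
        raise EmptyInputError(f"trace does not cover [{window_min[0]}, {window_min[1]}] min")
    a = _smooth(df["A"], smooth_width).to_numpy()
    mask = (t >= lo) & (t <= hi)
    tt, aa = t[mask], a[mask]
    peak = aa[0]
    t_peak = tt[0]
    best_depth, best_time = 0.0, float("nan")
    for ti, ai in zip(tt, aa):
        if ai > peak:
            peak, t_peak = ai, ti
        drawdown = peak - ai
        if drawdown > best_depth:
            best_depth, best_time = drawdown, ti
    if best_depth >= threshold:
        return DipResult(present=True, time_min=best_time / 60.0, depth=best_depth)
    return DipResult(present=False)


class InductionAnalyzer(TransformerMixin, BaseEstimator):
    """Compute :class:`InductionMetrics` for one or many traces.

    Stateless transformer (``fit`` is a no-op): windows, smoothing and the
    dip threshold are constructor parameters, so the analyzer slots into
    sklearn pipelines and grid searches.
    """

    def __init__(self, pre_window: tuple = PRE_WINDOW,
                 final_window: tuple = FINAL_WINDOW,
                 smooth_width: int = 5, dip_threshold: float = 0.5,
                 dip_window_min: tuple = (0.5, 4.0)):
        self.pre_window = pre_window
        self.final_window = final_window
        self.smooth_width = smooth_width
        self.dip_threshold = dip_threshold
        self.dip_window_min = dip_window_min

    def fit(self, X=None, y=None):
        return self

    def analyze(self, trace: InductionTrace) -> InductionMetrics:
        ai = steady_window_mean(trace, self.pre_window, "A")
        af = steady_window_mean(trace, self.final_window, "A")
        pi = induction_fraction(trace, ai=ai, af=af)
        t50 = time_to_fraction(pi, 50.0, smooth_width=self.smooth_width)
        t90 = time_to_fraction(pi, 90.0, smooth_width=self.smooth_width)
        gsi, gsf, dgs = stomatal_opening(trace, self.pre_window, self.final_window)
        dip = detect_dip(trace, threshold=self.dip_threshold,
                         window_min=self.dip_window_min,
                         smooth_width=self.smooth_width)
        return InductionMetrics(
            ai=ai, af=af, t50_min=t50, t90_min=t90,
            gs_initial=gsi, gs_final=gsf, delta_gs=dgs,
            wuei_initial=float(wue_i(ai, gsi)), wuei_final=float(wue_i(af, gsf)),
            int_a_5min=integrate_window(trace, "A"),
            int_ci_5min=integrate_window(trace, "Ci"),
            dip_present=dip.present, dip_time_min=dip.time_min,
            dip_depth=dip.depth,
        )

    def transform(self, X: Sequence[InductionTrace]) -> pd.DataFrame:
        rows = []
        for trace in X:
            m = asdict(self.analyze(trace))
            m["genotype"] = trace.genotype
            m["treatment"] = trace.treatment
            rows.append(m)
        return pd.DataFrame(rows)
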