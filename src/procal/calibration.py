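"""Calibration-line fitting, zero-forcing, lack-of-fit testing and LOQ.

The detector response of a fluorescence HPLC system is linear in analyte
concentration over the working range, so each analyte/day/lab series is
summarised by an ordinary least-squares line.  When the intercept is not
statistically distinguishable from zero the calibration is forced through
the origin, which reduces the relative error at the low end of the range.
Linearity is verified with a lack-of-fit F-test that partitions the
residual sum of squares into pure (replicate) error and model lack-of-fit.

The limit of quantification follows the calibration-based estimate
LOQ = 10·σ/S, with σ the residual standard deviation of the fit and S its
slope; a separate reporting policy clamps the LOQ to the lowest
calibration level actually used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSeries:
    """Replicated (concentration, response) points for one analyte.

    Parameters
    ----------
    analyte : analyte id (``epicatechin`` or ``dp2`` .. ``dp10``)
    concentrations, responses : paired arrays, μg/mL and fluorescence units
    day, lab : series labels
    """

    analyte: str
    concentrations: np.ndarray
    responses: np.ndarray
    day: str = "day1"
    lab: str = "lab1"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be matching 1-d arrays")
        if c.size < 2:
            raise ValueError("calibration series needs at least 2 points")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.concentrations)

    @property
    def n_levels(self) -> int:
        return self.levels.size


@dataclass(frozen=True)
class CalibrationFit:
    """OLS summary of one calibration series.

    ``residual_sd`` is the root mean squared residual with the proper
    degrees of freedom (n−2 free fit, n−1 when forced through zero); it is
    the σ of the LOQ formula and the regression standard error s(y/x).
    """

    analyte: str
    slope: float
    intercept: float
    residual_sd: float
    r: float
    n_points: int
    zero_forced: bool
    intercept_se: float = math.nan
    day: str = "day1"
    lab: str = "lab1"

    @property
    def se_y(self) -> float:
        """Alias: standard error of the regression."""
        return self.residual_sd

    @property
    def df(self) -> int:
        return self.n_points - (1 if self.zero_forced else 2)


@dataclass(frozen=True)
class ZeroForcingDecision:
    """Outcome of the intercept t-test, with the auxiliary |b| vs s(y/x)
    comparison logged for traceability."""

    force: bool
    t_stat: float
    p_value: float
    intercept: float
    intercept_se: float
    residual_sd: float
    alpha: float = 0.05

    def __bool__(self) -> bool:  # allows `if decide_zero_forcing(fit): ...`
        return self.force


@dataclass(frozen=True)
class LackOfFitResult:
    F: float
    F_critical: float
    df_lof: int
    df_pe: int
    alpha: float
    linear_ok: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "linear_ok", bool(self.F < self.F_critical))


def fit_calibration(series: CalibrationSeries, force_zero: bool = False) -> CalibrationFit:
    """Fit a calibration line by ordinary least squares.

    With ``force_zero`` the no-intercept estimator slope = Σxy/Σx² is used
    and the residual variance carries n−1 degrees of freedom.
    """
    x = series.concentrations
    y = series.responses
    if series.n_levels < 2:
        raise ValueError("cannot fit: fewer than 2 distinct concentration levels")
    if np.ptp(y) == 0 and np.ptp(x) > 0 and np.all(y == 0):
        raise ValueError("degenerate fit: all responses are zero")

    n = x.size
    if force_zero:
        sxx = float(np.dot(x, x))
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        df = n - 1
        residual_sd = float(np.sqrt(np.sum(resid**2) / df)) if df > 0 else 0.0
        r = _pearson(x, y)
        return CalibrationFit(
            analyte=series.analyte,
            slope=slope,
            intercept=0.0,
            residual_sd=residual_sd,
            r=r,
            n_points=n,
            zero_forced=True,
            intercept_se=math.nan,
            day=series.day,
            lab=series.lab,
        )

    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    df = n - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / df)) if df > 0 else 0.0
    return CalibrationFit(
        analyte=series.analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        r=float(res.rvalue),
        n_points=n,
        zero_forced=False,
        intercept_se=float(res.intercept_stderr),
        day=series.day,
        lab=series.lab,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0 if np.ptp(y) == 0 else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def decide_zero_forcing(free_fit: CalibrationFit, alpha: float = 0.05) -> ZeroForcingDecision:
    """Decide whether the calibration may be forced through the origin.

    The rule is a two-sided t-test of the fitted intercept against its
    standard error: forcing is allowed when the intercept is not
    statistically distinguishable from zero at level *alpha*.  The cruder
    |b| < s(y/x) screen is evaluated and logged alongside.
    """
    if free_fit.zero_forced:
        raise ValueError("decide_zero_forcing needs a fit with a free intercept")
    b, se = free_fit.intercept, free_fit.intercept_se
    if se == 0 or math.isnan(se):
        # exact line: intercept determined up to floating-point round-off
        negligible = abs(b) <= 1e-8 * max(1.0, abs(free_fit.slope))
        force = negligible
        t = 0.0 if negligible else math.inf
        p = 1.0 if negligible else 0.0
    else:
        t = b / se
        p = 2 * stats.t.sf(abs(t), free_fit.df)
        force = p >= alpha
    log.info(
        "zero-forcing decision for %s/%s/%s: b=%.4g, se(b)=%.4g, t=%.3g, p=%.3g -> "
        "force=%s (auxiliary screen |b|<s(y/x): %s)",
        free_fit.analyte,
        free_fit.day,
        free_fit.lab,
        b,
        se,
        t,
        p,
        force,
        abs(b) < free_fit.residual_sd,
    )
    return ZeroForcingDecision(
        force=force,
        t_stat=t,
        p_value=p,
        intercept=b,
        intercept_se=se,
        residual_sd=free_fit.residual_sd,
        alpha=alpha,
    )


def lack_of_fit_test(
    series: CalibrationSeries, fit: CalibrationFit, alpha: float = 0.05
) -> LackOfFitResult:
    """Lack-of-fit F-test for the linear calibration model.

    The residual sum of squares about the fitted line is partitioned into
    pure error (replicate scatter within levels) and lack of fit (level
    means about the line); F = MS_lof / MS_pe is referred to
    F(df_lof, df_pe).
    """
    x = series.concentrations
    y = series.responses
    fitted = fit.slope * x + fit.intercept

    levels = series.levels
    m = levels.size
    n = x.size
    n_params = 1 if fit.zero_forced else 2
    df_lof = m - n_params
    df_pe = n - m
    if df_pe < 1:
        raise ValueError("lack-of-fit test inapplicable: no replicated levels (df_pe = 0)")
    if df_lof < 1:
        raise ValueError(
            f"lack-of-fit test inapplicable: only {m} levels for a "
            f"{n_params}-parameter model (df_lof = {df_lof})"
        )

    ss_pe = 0.0
    for lv in levels:
        yy = y[x == lv]
        ss_pe += float(np.sum((yy - yy.mean()) ** 2))
    ss_resid = float(np.sum((y - fitted) ** 2))
    ss_lof = max(ss_resid - ss_pe, 0.0)

    ms_lof = ss_lof / df_lof
    ms_pe = ss_pe / df_pe
    if ms_pe == 0:
        raise ValueError("pure-error mean square is zero; replicate responses are identical")
    F = ms_lof / ms_pe
    F_crit = float(stats.f.ppf(1 - alpha, df_lof, df_pe))
    return LackOfFitResult(F=F, F_critical=F_crit, df_lof=df_lof, df_pe=df_pe, alpha=alpha)


def loq(fit: CalibrationFit) -> float:
    """Theoretical limit of quantification, 10·σ/S (μg/mL)."""
    if fit.slope <= 0:
        raise ValueError("LOQ undefined for non-positive slope")
    return 10.0 * fit.residual_sd / fit.slope


def reported_loq(theoretical: float, lowest_level: float) -> float:
    """Reporting policy: clamp the LOQ up to the lowest calibration level.

    The theoretical 10σ/S estimate may fall far below the lowest standard
    actually run; the reported LOQ is then set at that lowest level.
    """
    if theoretical < 0 or lowest_level <= 0:
        raise ValueError("LOQ inputs must be positive")
    clamped = max(theoretical, lowest_level)
    if clamped != theoretical:
        log.info("LOQ clamped from theoretical %.3g to lowest level %.3g μg/mL",
                 theoretical, lowest_level)
    return clamped


def working_range(series: CalibrationSeries) -> tuple[float, float]:
    """Working range: (lowest, highest) calibration level in μg/mL."""
    levels = series.levels
    if levels.size < 2:
        raise ValueError("working range needs at least 2 distinct levels")
    return float(levels.min()), float(levels.max())
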