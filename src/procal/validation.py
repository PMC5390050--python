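"""Validation statistics: precision ANOVA, recovery, bias, stability and
the combined expanded uncertainty.

Precision is estimated from a one-way (day) ANOVA: the within-day mean
square gives the repeatability variance s_r², the between-day mean square
the day component s_d² = max(0, (MS_between − MS_within)/n̄), and the
intermediate precision s_ip² = s_r² + s_d².  Negative day components are
truncated to zero (the standard restricted estimator), which is why an
intermediate RSD can print below the repeatability RSD.

The expanded uncertainty combines the relative standard uncertainties in
quadrature, GUM-style:

    U = k · sqrt( u_rep(RRF)² + u_il(RRF)² + u_r²/n₁ + u_ip²/n₂
                  + u_bias² + u_rec² )

with k = 2 for ≈95 % coverage, n₁ the total number of analyses and n₂ the
number of days measured.  All components enter as percent relative
standard uncertainties, so U is a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PrecisionEstimate:
    analyte: str
    repeatability_rsd: float  # u_r, %
    intermediate_rsd: float  # u_ip, %
    grand_mean: float
    n_days: int
    n_reps: int  # total observations


@dataclass(frozen=True)
class RecoveryEstimate:
    analyte: str
    recovery: float  # %
    u_rec: float  # SD of individual recoveries, %
    n: int


@dataclass(frozen=True)
class UncertaintyBudget:
    """The six components of the combined budget, all as % relative
    standard uncertainties, plus the coverage factor and effective counts."""

    u_rep_rrf: float
    u_il_rrf: float
    u_r: float
    u_ip: float
    n1: int
    n2: int
    u_bias: float
    u_rec: float
    k: float = 2.0

    def __post_init__(self):
        for name in ("u_rep_rrf", "u_il_rrf", "u_r", "u_ip", "u_bias", "u_rec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if self.k <= 0:
            raise ValueError("coverage factor k must be positive")


@dataclass(frozen=True)
class StabilityVerdict:
    analyte: str
    values: dict[float, float]  # timepoint (h) -> content (mg/g)
    delta: float  # last − first, mg/g
    acceptable_halfwidth: float  # mg/g
    stable: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "stable", abs(self.delta) <= self.acceptable_halfwidth)


def precision_anova(measurements: pd.DataFrame, analyte: str = "") -> PrecisionEstimate:
    """Repeatability and intermediate precision from a one-way day ANOVA.

    *measurements* needs columns ``day`` and ``value``; the layout may be
    unbalanced, in which case the day component is extracted with the
    harmonic-mean number of replicates per day.
    """
    if not {"day", "value"}.issubset(measurements.columns):
        raise ValueError("measurements must have 'day' and 'value' columns")
    df = measurements.dropna(subset=["value"])
    groups = [g["value"].to_numpy(float) for _, g in df.groupby("day")]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    if n_total < 2:
        raise ValueError("degenerate precision input: fewer than 2 measurements")
    if k < 2:
        raise ValueError("intermediate precision undefined with a single day")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("need at least 2 replicates on at least one day")

    grand = float(np.concatenate(groups).mean())
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ss_between = sum(len(g) * (float(g.mean()) - grand) ** 2 for g in groups)
    ms_within = ss_within / (n_total - k)
    ms_between = ss_between / (k - 1)

    n_harm = k / sum(1.0 / len(g) for g in groups)
    s_r2 = ms_within
    s_d2 = max(0.0, (ms_between - ms_within) / n_harm)
    s_ip2 = s_r2 + s_d2

    if grand == 0:
        raise ValueError("grand mean is zero; relative precision undefined")
    return PrecisionEstimate(
        analyte=analyte,
        repeatability_rsd=100.0 * math.sqrt(s_r2) / abs(grand),
        intermediate_rsd=100.0 * math.sqrt(s_ip2) / abs(grand),
        grand_mean=grand,
        n_days=k,
        n_reps=n_total,
    )


def recovery(
    unspiked: Sequence[float],
    spiked: Mapping[float, Sequence[float]],
    added: Mapping[float, float],
    analyte: str = "",
) -> RecoveryEstimate:
    """Spike recovery averaged over fortification levels.

    Per-replicate recovery is 100·(found − mean(unspiked))/added for the
    level's added amount; the estimate is the mean over all levels and
    replicates and u_rec is the SD of those individual recoveries (the
    conservative, level-agnostic dispersion).
    """
    base = float(np.mean(np.asarray(unspiked, dtype=float)))
    recs: list[float] = []
    for level, values in spiked.items():
        amt = float(added[level])
        if amt <= 0:
            raise ValueError(f"added amount must be positive (level {level})")
        for v in np.asarray(values, dtype=float):
            recs.append(100.0 * (float(v) - base) / amt)
    if not recs:
        raise ValueError("no spiked measurements supplied")
    arr = np.asarray(recs)
    u = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RecoveryEstimate(analyte=analyte, recovery=float(arr.mean()), u_rec=u, n=arr.size)


def to_defatted_basis(reference_value: float, fat_mass_fraction: float) -> float:
    """Convert a whole-matrix reference value to the defatted-mass basis.

    Removing the fat concentrates the analyte in the remaining mass, so
    the reference divides by the defatted mass fraction (1 − fat).
    """
    if not 0 <= fat_mass_fraction < 1:
        raise ValueError("fat mass fraction must be in [0, 1)")
    return reference_value / (1.0 - fat_mass_fraction)


def bias_from_control(
    measured: Sequence[float],
    reference_value: float,
    reference_uncertainty: float = 0.0,
) -> float:
    """u_bias (%) from repeated control-material measurements.

    Combines, in quadrature, the relative deviation of the measured mean
    from the certified value and the certificate's own relative standard
    uncertainty.
    """
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    mean = float(np.mean(np.asarray(measured, dtype=float)))
    rel_dev = 100.0 * abs(mean - reference_value) / reference_value
    rel_ref = 100.0 * reference_uncertainty / reference_value
    return math.hypot(rel_dev, rel_ref)


def expanded_uncertainty(budget: UncertaintyBudget) -> float:
    """Expanded relative uncertainty U (%) from the combined budget."""
    u2 = (
        budget.u_rep_rrf**2
        + budget.u_il_rrf**2
        + budget.u_r**2 / budget.n1
        + budget.u_ip**2 / budget.n2
        + budget.u_bias**2
        + budget.u_rec**2
    )
    return budget.k * math.sqrt(u2)


def stability_assess(
    series: Mapping[float, float],
    ip_fraction: float,
    analyte: str = "",
) -> StabilityVerdict:
    """Assess analyte stability over a storage time series.

    *series* maps timepoint (h) to content (mg/g) and must include 0 h.
    delta is content(last) − content(0 h); the acceptance half-width is
    the mean over all timepoints multiplied by the analyte's intermediate
    precision fraction.  The ``stable`` flag (|delta| within the
    half-width) is advisory — both quantities are always reported.
    """
    if len(series) < 2:
        raise ValueError("stability needs at least 2 timepoints")
    times = sorted(series)
    if times[0] != 0:
        raise ValueError("stability series must include the 0 h timepoint")
    if ip_fraction < 0:
        raise ValueError("ip fraction must be non-negative")
    values = [float(series[t]) for t in times]
    delta = values[-1] - values[0]
    halfwidth = float(np.mean(values)) * ip_fraction
    return StabilityVerdict(
        analyte=analyte,
        values={float(t): float(series[t]) for t in times},
        delta=delta,
        acceptable_halfwidth=halfwidth,
    )


def stability_table(
    verdicts: Sequence[StabilityVerdict],
) -> pd.DataFrame:
    """Tabulate stability verdicts (one row per analyte)."""
    rows = []
    for v in verdicts:
        row = {"analyte": v.analyte}
        for t, val in v.values.items():
            row[f"t{t:g}h_mg_per_g"] = val
        row["delta_mg_per_g"] = v.delta
        row["acceptable_halfwidth_mg_per_g"] = v.acceptable_halfwidth
        row["stable"] = v.stable
        rows.append(row)
    return pd.DataFrame(rows)
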