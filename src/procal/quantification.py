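"""RRF determination and conversion of peak responses to contents (mg/g).

Authentic standards exist only for the monomer (epicatechin); oligomers
dp2-10 are quantified indirectly through relative response factors
RRF_dp = slope_dp / slope_epicatechin determined from calibration curves
of oligomers isolated in-house.  A sample peak response is converted to
concentration with the epicatechin slope scaled by the analyte's RRF, and
to content via the gravimetric factors:

    conc (μg/mL)   = response / (S_epi · RRF_dp)
    content (mg/g) = conc · volume_mL · dilution / mass_mg

Each dp class must have its own RRF — fluorescence response per unit mass
drops steeply with the degree of polymerisation, so a generic response
factor would bias high-dp analytes severely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytes import MONOMERS, check_analyte, is_oligomer
from .calibration import CalibrationFit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RRFTable:
    """Per-dp relative response factors with their dispersion.

    ``rrfs`` maps analyte id (``dp2`` .. ``dp10``) to the mean-of-means
    RRF; ``rsd_percent`` holds the between-day RSD of the daily values.
    """

    rrfs: dict[str, float]
    rsd_percent: dict[str, float] = field(default_factory=dict)
    n_days: int = 3
    lab: str = "lab1"

    def __post_init__(self):
        for analyte, v in self.rrfs.items():
            check_analyte(analyte)
            if not 0 < v <= 1:
                raise ValueError(f"RRF for {analyte} must be in (0, 1], got {v}")

    def rrf(self, analyte: str) -> float:
        """RRF for *analyte*; the monomer class quantifies at RRF = 1."""
        if analyte in (MONOMERS, "epicatechin"):
            return 1.0
        if analyte not in self.rrfs:
            raise KeyError(f"no RRF available for {analyte!r}")
        return self.rrfs[analyte]


@dataclass(frozen=True)
class AnalyteResult:
    """Quantified content for one analyte in one sample."""

    analyte: str
    conc_ug_per_ml: float
    content_mg_per_g: float
    below_loq: bool
    loq_used: float


def daily_rrf(dp_fit: CalibrationFit, epi_fit: CalibrationFit) -> float:
    """RRF from one day's paired calibration fits: slope_dp / slope_epi."""
    if (dp_fit.day, dp_fit.lab) != (epi_fit.day, epi_fit.lab):
        raise ValueError(
            f"mismatched day/lab: {dp_fit.day}/{dp_fit.lab} vs {epi_fit.day}/{epi_fit.lab}"
        )
    if epi_fit.slope <= 0:
        raise ValueError("epicatechin slope must be positive")
    return dp_fit.slope / epi_fit.slope


def mean_of_means_rrf(daily: list[float]) -> tuple[float, float]:
    """Mean of the daily RRFs and their RSD (%).

    RSD uses the n−1 sample standard deviation; with a single daily value
    the mean is returned with RSD = nan.
    """
    vals = np.asarray(daily, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one daily RRF")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, math.nan
    rsd = 100.0 * float(vals.std(ddof=1)) / mean
    return mean, rsd


def rrf_dispersion_across_labs(
    lab_tables: list[RRFTable],
) -> pd.DataFrame:
    """Within-lab and between-lab RRF dispersion per analyte.

    Returns a frame indexed by analyte with columns ``u_rep_rrf`` (pooled
    within-lab RSD, %) and ``u_il_rrf`` (RSD of the lab means, %) — the
    two RRF terms of the combined uncertainty budget.
    """
    if len(lab_tables) < 2:
        raise ValueError("between-lab dispersion needs at least 2 labs")
    analytes = sorted(
        set.intersection(*(set(t.rrfs) for t in lab_tables)),
        key=lambda a: int(a[2:]),
    )
    rows = {}
    for analyte in analytes:
        means = np.array([t.rrfs[analyte] for t in lab_tables])
        within = np.array(
            [t.rsd_percent.get(analyte, np.nan) for t in lab_tables], dtype=float
        )
        # pooled within-lab RSD: root mean square of the per-lab RSDs
        u_rep = float(np.sqrt(np.nanmean(within**2))) if np.any(~np.isnan(within)) else math.nan
        u_il = 100.0 * float(means.std(ddof=1)) / float(means.mean())
        rows[analyte] = {"u_rep_rrf": u_rep, "u_il_rrf": u_il}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "analyte"
    return out


def quantify_sample(
    peak_table: pd.DataFrame,
    epi_fit: CalibrationFit,
    rrfs: RRFTable,
    mass_mg: float,
    volume_ml: float,
    dilution: float = 1.0,
    loqs: dict[str, float] | None = None,
) -> list[AnalyteResult]:
    """Convert summed dp-class peak responses to contents.

    *peak_table* needs columns ``analyte`` and ``response`` (responses
    already summed per dp class).  Results below the applicable LOQ are
    flagged and retained; downstream totals exclude them by policy.
    """
    if mass_mg <= 0 or volume_ml <= 0:
        raise ValueError("sample mass and volume must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if epi_fit.slope <= 0:
        raise ValueError("epicatechin slope must be positive")
    loqs = loqs or {}

    results: list[AnalyteResult] = []
    for row in peak_table.itertuples(index=False):
        analyte = check_analyte(row.analyte)
        rrf = rrfs.rrf(analyte)  # raises KeyError for a missing oligomer RRF
        conc = float(row.response) / (epi_fit.slope * rrf)
        content = conc * volume_ml * dilution / mass_mg
        loq_used = float(loqs.get(analyte, 0.0))
        below = conc < loq_used
        if below:
            log.info("%s below LOQ (%.3g < %.3g μg/mL)", analyte, conc, loq_used)
        results.append(
            AnalyteResult(
                analyte=analyte,
                conc_ug_per_ml=conc,
                content_mg_per_g=content,
                below_loq=below,
                loq_used=loq_used,
            )
        )
    return results


def total_oligomers(results: list[AnalyteResult]) -> float:
    """Total oligomeric procyanidin content (mg/g): sum over dp2-10.

    The monomer class is excluded, as are analytes flagged below LOQ.
    """
    total = 0.0
    for r in results:
        if not is_oligomer(r.analyte):
            continue
        if r.below_loq:
            log.info("excluding %s from oligomer total (below LOQ)", r.analyte)
            continue
        total += r.content_mg_per_g
    return total


def results_frame(results: list[AnalyteResult]) -> pd.DataFrame:
    """Tabulate AnalyteResults (one row per analyte)."""
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in results],
            "conc_ug_per_ml": [r.conc_ug_per_ml for r in results],
            "content_mg_per_g": [r.content_mg_per_g for r in results],
            "below_loq": [r.below_loq for r in results],
            "loq_used": [r.loq_used for r in results],
        }
    )
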