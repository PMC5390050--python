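"""Inter-laboratory evaluation: consensus statistics, QC gating and
proficiency z-scores.

The consensus value for an analyte is the arithmetic mean of the
participating laboratories' results and its dispersion the n−1 sample
standard deviation.  Laboratory performance is scored as

    z = (x − μ) / σ

with x the laboratory result and μ, σ the consensus mean and SD of the
same value set.  Classification follows proficiency-testing convention:
|z| ≤ 2 satisfactory, 2 < |z| < 3 doubtful, |z| ≥ 3 unsatisfactory.

A quality-control gate on the shared control material removes
laboratories whose control result is far outside the consensus before
the extracts are evaluated; exclusion is a single round (consensus is
recomputed once after removal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SATISFACTORY = "satisfactory"
DOUBTFUL = "doubtful"
UNSATISFACTORY = "unsatisfactory"


def classify_z(z: float) -> str:
    az = abs(z)
    if az <= 2:
        return SATISFACTORY
    if az < 3:
        return DOUBTFUL
    return UNSATISFACTORY


def consensus_stats(values) -> tuple[float, float, float]:
    """Consensus (mean, SD, %RSD) of a set of laboratory means.

    SD is the n−1 sample standard deviation; RSD = 100·SD/mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("consensus statistics need at least 2 laboratory values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("inf")
    return mean, sd, rsd


def robust_consensus_stats(values) -> tuple[float, float, float]:
    """Median/MAD variant of the consensus (off by default in reports).

    The MAD is scaled by 1.4826 to estimate σ under normality.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("consensus statistics need at least 2 laboratory values")
    med = float(np.median(arr))
    mad = 1.4826 * float(np.median(np.abs(arr - med)))
    rsd = 100.0 * mad / med if med != 0 else float("inf")
    return med, mad, rsd


@dataclass(frozen=True)
class ZScoreReport:
    """z-scores per lab × analyte with per-lab summary statistics."""

    z: pd.DataFrame  # index lab, columns analyte
    classification: pd.DataFrame  # same shape, strings
    per_lab_summary: pd.DataFrame  # index lab, columns avg/med/min/max


def z_scores(values, labs=None) -> pd.Series:
    """z-scores of one value set against its own consensus mean/SD."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("z-scores need at least 2 laboratory values")
    if arr.size == 2:
        log.warning("z-scores from only 2 labs: σ is uninformative")
    mean, sd, _ = consensus_stats(arr)
    if sd == 0:
        raise ValueError("z-scores undefined: zero dispersion across laboratories")
    idx = list(labs) if labs is not None else list(range(1, arr.size + 1))
    return pd.Series((arr - mean) / sd, index=idx, name="z")


def z_score_report(results: pd.DataFrame) -> ZScoreReport:
    """Score a lab × analyte table of results.

    *results* has laboratories as the index and analytes as columns; each
    column is scored against its own consensus.  The per-lab summary
    (avg/med/min/max across analytes) mirrors the standard proficiency
    report layout.
    """
    if results.shape[0] < 3:
        log.warning("fewer than 3 labs: z-score dispersion is uninformative")
    z = results.apply(lambda col: z_scores(col.to_numpy(), labs=results.index), axis=0)
    classification = z.map(classify_z)
    summary = pd.DataFrame(
        {
            "avg": z.mean(axis=1),
            "med": z.median(axis=1),
            "min": z.min(axis=1),
            "max": z.max(axis=1),
        }
    )
    return ZScoreReport(z=z, classification=classification, per_lab_summary=summary)


def qc_gate(
    control_results: dict,
    max_abs_z: float = 3.0,
) -> tuple[list, list]:
    """Screen laboratories on the control material.

    Returns (included_labs, excluded_labs).  A laboratory is excluded
    when its control result lies more than *max_abs_z* standard
    deviations from the leave-one-out consensus of the remaining labs
    (a Grubbs-style jackknife z).  Leaving the scored lab out is
    essential: a gross outlier inflates the all-lab SD enough to mask
    itself — with n labs the classical |z| cannot exceed (n−1)/√n,
    below 3 for any n ≤ 10.  Exclusion is a single round (the consensus
    is recomputed once after removal), so the gate cannot cascade.
    """
    labs = list(control_results)
    vals = np.asarray([control_results[lab] for lab in labs], dtype=float)
    if vals.size < 3:
        raise ValueError("QC gate needs at least 3 laboratories")
    n = vals.size
    total, total_sq = vals.sum(), (vals**2).sum()
    z = np.zeros(n)
    for i in range(n):
        mean_rest = (total - vals[i]) / (n - 1)
        var_rest = (total_sq - vals[i] ** 2 - (n - 1) * mean_rest**2) / (n - 2)
        sd_rest = np.sqrt(max(var_rest, 0.0))
        if sd_rest == 0:
            z[i] = np.inf if vals[i] != mean_rest else 0.0
            continue
        z[i] = (vals[i] - mean_rest) / sd_rest
    excluded = [lab for lab, zi in zip(labs, z) if abs(zi) > max_abs_z]
    included = [lab for lab in labs if lab not in excluded]
    if not included:
        raise ValueError("QC gate excluded every laboratory")
    if excluded:
        log.info("QC gate excluded labs %s (leave-one-out |z| > %g on control sample)",
                 excluded, max_abs_z)
        mean, sd, rsd = consensus_stats([control_results[lab] for lab in included])
        log.info("control consensus after exclusion: mean=%.4g sd=%.4g rsd=%.3g%%",
                 mean, sd, rsd)
    return included, excluded


def within_lab_precision_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """%RSD per lab × material (× analyte) from replicate-level data.

    *dataset* needs columns lab, material, analyte, value (day/replicate
    columns may be present but are pooled: the RSD is taken across all
    independent measurements of a material in a lab).
    """
    req = {"lab", "material", "analyte", "value"}
    if not req.issubset(dataset.columns):
        raise ValueError(f"dataset must have columns {sorted(req)}")

    def rsd(x: pd.Series) -> float:
        m = x.mean()
        return 100.0 * x.std(ddof=1) / m if m != 0 else float("inf")

    out = (
        dataset.groupby(["lab", "material", "analyte"])["value"]
        .agg(mean="mean", rsd_percent=rsd, n="count")
        .reset_index()
    )
    return out
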