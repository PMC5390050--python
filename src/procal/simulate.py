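"""Synthetic detector-data generator for the procyanidin pipeline.

Emulates the statistical structure the analysis assumes: a fluorescence
response linear in concentration, per-dp slopes proportional to the
shipped reference RRFs, multiplicative log-normal day and laboratory
effects on the slopes, and proportional (multiplicative Gaussian)
measurement noise — %RSDs are scale-relative, so proportional noise is
the faithful model.  Optional glass-wall adsorption loss reduces the true
concentration before response generation.

Every generator is a pure function of its configuration and seed: a fixed
seed reproduces the output tables exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .analytes import EPICATECHIN, check_analyte

log = logging.getLogger(__name__)


def _default_rrfs() -> dict[str, float]:
    return dict(reference.RRF_MEAN_OF_MEANS)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design of the simulated calibration experiment.

    Defaults mirror the method's validation design: calibration levels
    spanning 5–100 μg/mL with 3 replicates per level on 3 days, reference
    RRFs as the per-dp slope truths, 2 % proportional response noise and
    a 2 % between-day slope dispersion.
    """

    true_epicatechin_slope: float = 20.0  # response units per (μg/mL)
    true_rrfs: dict[str, float] = field(default_factory=_default_rrfs)
    noise_cv: float = 0.02
    day_effect_cv: float = 0.02
    lab_effect_cv: float = 0.05
    levels: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0)
    replicates_per_level: int = 3
    n_days: int = 3
    n_labs: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_cv", "day_effect_cv", "lab_effect_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.true_epicatechin_slope <= 0:
            raise ValueError("true_epicatechin_slope must be > 0")
        for analyte, v in self.true_rrfs.items():
            check_analyte(analyte)
            if not 0 < v <= 1:
                raise ValueError(f"true_rrfs[{analyte!r}] must be in (0, 1]")
        lv = tuple(float(x) for x in self.levels)
        if len(lv) < 1 or any(x <= 0 for x in lv):
            raise ValueError("levels must be strictly positive")
        if list(lv) != sorted(lv):
            raise ValueError("levels must be sorted ascending")
        object.__setattr__(self, "levels", lv)
        for name in ("replicates_per_level", "n_days", "n_labs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def analytes(self) -> tuple[str, ...]:
        return (EPICATECHIN,) + tuple(self.true_rrfs)

    def true_slope(self, analyte: str) -> float:
        if analyte == EPICATECHIN:
            return self.true_epicatechin_slope
        return self.true_epicatechin_slope * self.true_rrfs[analyte]


@dataclass(frozen=True)
class SampleDesign:
    """Ground truth for a simulated sample preparation.

    ``adsorption_loss_coeff`` is the fraction of analyte lost per cm² of
    contacted glass surface; it may be a single number or a per-analyte
    mapping.  The default of 0 disables the loss scenario.
    """

    true_contents: dict[str, float]  # analyte -> mg/g
    sample_mass_mg: float = 100.0
    volume_ml: float = 50.0
    dilution_factor: float = 1.0
    adsorption_loss_coeff: float | Mapping[str, float] = 0.0
    contacted_surface_cm2: float = 0.0

    def __post_init__(self):
        if not self.true_contents:
            raise ValueError("true_contents must be non-empty")
        for analyte, v in self.true_contents.items():
            check_analyte(analyte)
            if v < 0:
                raise ValueError(f"true_contents[{analyte!r}] must be >= 0")
        if self.sample_mass_mg <= 0:
            raise ValueError("sample_mass_mg must be > 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.contacted_surface_cm2 < 0:
            raise ValueError("contacted_surface_cm2 must be >= 0")
        for analyte in self.true_contents:
            frac = self.loss_fraction(analyte)
            if not 0 <= frac < 1:
                raise ValueError(
                    f"adsorption loss for {analyte!r} must be in [0, 1), got {frac}"
                )

    def loss_fraction(self, analyte: str) -> float:
        """Fraction of *analyte* lost to the contacted glass surface."""
        coeff = self.adsorption_loss_coeff
        if isinstance(coeff, Mapping):
            coeff = coeff.get(analyte, 0.0)
        return float(coeff) * self.contacted_surface_cm2

    def nominal_conc(self, analyte: str) -> float:
        """Concentration (μg/mL) in the measured dissolution, before loss."""
        return (
            self.true_contents[analyte]
            * self.sample_mass_mg
            / (self.volume_ml * self.dilution_factor)
        )


def _lognormal_multipliers(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 log-normal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _noisy(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    out = values * (1.0 + rng.normal(0.0, cv, size=values.shape)) if cv > 0 else values.copy()
    neg = out < 0
    if np.any(neg):
        log.warning("truncated %d negative simulated responses to zero", int(neg.sum()))
        out[neg] = 0.0
    return out


def simulate_calibration(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full calibration experiment.

    Returns a long-format table (analyte, level_ug_per_ml, response, day,
    lab, replicate); one series per (analyte, day, lab).  The response
    model is concentration × true slope × RRF × day multiplier × lab
    multiplier × (1 + noise).
    """
    rng = np.random.default_rng(config.seed)
    analytes = config.analytes
    rows = []
    for li in range(config.n_labs):
        lab = f"lab{li + 1}"
        # lab effect is common-mode (detector gain, injection, path length):
        # one multiplier per lab, shared by all analytes, so RRF ratios stay
        # the stable quantity across labs.  Day effects act per analyte
        # (mobile-phase-dependent fluorescence), giving daily RRFs their
        # few-percent spread.
        lab_mult = _lognormal_multipliers(rng, config.lab_effect_cv, 1)[0]
        for di in range(config.n_days):
            day = f"day{di + 1}"
            day_mults = _lognormal_multipliers(rng, config.day_effect_cv, len(analytes))
            for ai, analyte in enumerate(analytes):
                slope = config.true_slope(analyte) * lab_mult * day_mults[ai]
                for level in config.levels:
                    clean = np.full(config.replicates_per_level, level * slope)
                    resp = _noisy(rng, clean, config.noise_cv)
                    for rep, r in enumerate(resp, start=1):
                        rows.append(
                            {
                                "analyte": analyte,
                                "level_ug_per_ml": level,
                                "response": r,
                                "day": day,
                                "lab": lab,
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows)


def simulate_sample_batch(
    design: SampleDesign,
    config: SimulationConfig,
    n_reps: int = 3,
    n_days: int = 3,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Simulate replicate sample measurements over several days.

    Returns a peak table (sample_id, analyte, response, mass_mg,
    volume_ml, dilution, day, replicate).  Adsorption loss, if enabled,
    reduces the true concentration before the response is generated.
    """
    if n_reps < 1 or n_days < 1:
        raise ValueError("n_reps and n_days must be >= 1")
    rng = np.random.default_rng(config.seed)
    analytes = list(design.true_contents)
    rows = []
    for di in range(n_days):
        day = f"day{di + 1}"
        day_mults = _lognormal_multipliers(rng, config.day_effect_cv, len(analytes))
        for rep in range(1, n_reps + 1):
            for ai, analyte in enumerate(analytes):
                conc = design.nominal_conc(analyte) * (1.0 - design.loss_fraction(analyte))
                rrf = 1.0 if analyte in (EPICATECHIN, "monomers") else config.true_rrfs[analyte]
                clean = conc * config.true_epicatechin_slope * rrf * day_mults[ai]
                resp = _noisy(rng, np.array([clean]), config.noise_cv)[0]
                rows.append(
                    {
                        "sample_id": f"{sample_id}_{day}_r{rep}",
                        "analyte": analyte,
                        "response": resp,
                        "mass_mg": design.sample_mass_mg,
                        "volume_ml": design.volume_ml,
                        "dilution": design.dilution_factor,
                        "day": day,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_spiking(
    base: SampleDesign,
    spike_levels: Sequence[float],
    n_reps: int,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate a fortification (spike-recovery) experiment.

    ``spike_levels`` are fractions of the expected content (1.0 ≈ 100 %
    fortification).  The output holds unfortified and fortified replicate
    sets with the added amount (mg/g) recorded per analyte, as detector
    responses ready for quantification.
    """
    if not spike_levels or any(s <= 0 for s in spike_levels):
        raise ValueError("spike_levels must be non-empty and positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(config.seed)
    analytes = list(base.true_contents)
    rows = []
    for frac in [0.0] + list(spike_levels):
        condition = f"{frac:.0%}"
        for rep in range(1, n_reps + 1):
            for analyte in analytes:
                added = frac * base.true_contents[analyte]
                total_content = base.true_contents[analyte] + added
                conc = (
                    total_content
                    * base.sample_mass_mg
                    / (base.volume_ml * base.dilution_factor)
                ) * (1.0 - base.loss_fraction(analyte))
                rrf = 1.0 if analyte in (EPICATECHIN, "monomers") else config.true_rrfs[analyte]
                clean = conc * config.true_epicatechin_slope * rrf
                resp = _noisy(rng, np.array([clean]), config.noise_cv)[0]
                rows.append(
                    {
                        "condition": condition,
                        "spike_fraction": frac,
                        "replicate": rep,
                        "analyte": analyte,
                        "response": resp,
                        "added_mg_per_g": added,
                        "mass_mg": base.sample_mass_mg,
                        "volume_ml": base.volume_ml,
                        "dilution": base.dilution_factor,
                    }
                )
    return pd.DataFrame(rows)


def simulate_stability(
    design: SampleDesign,
    timepoints_h: Sequence[float],
    drift_per_h: Mapping[str, float],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate a storage-stability time series.

    Content at time t is content(0) × (1 + drift·t), with proportional
    noise on each measured value.  Returns (analyte, timepoint_h,
    value_mg_per_g).
    """
    tps = sorted(float(t) for t in timepoints_h)
    if not tps or tps[0] != 0.0:
        raise ValueError("timepoints_h must include 0")
    rng = np.random.default_rng(config.seed)
    rows = []
    for analyte, content0 in design.true_contents.items():
        drift = float(drift_per_h.get(analyte, 0.0))
        for t in tps:
            clean = content0 * (1.0 + drift * t)
            value = _noisy(rng, np.array([clean]), config.noise_cv)[0]
            rows.append({"analyte": analyte, "timepoint_h": t, "value_mg_per_g": value})
    return pd.DataFrame(rows)
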