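"""End-to-end pipeline: simulate → calibrate → RRF → quantify → validate.

`run_pipeline` wires the stages together on a simulated scenario and
writes one CSV per stage plus a machine-readable JSON summary.  Every
stochastic step derives its seed from the run seed, so a config + seed
pair reproduces the report bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .analytes import EPICATECHIN, MONOMERS, OLIGOMER_IDS
from .calibration import (
    CalibrationSeries,
    decide_zero_forcing,
    fit_calibration,
    lack_of_fit_test,
    loq,
    reported_loq,
    working_range,
)
from .interlab import consensus_stats, qc_gate, z_score_report
from .io import write_table
from .quantification import (
    RRFTable,
    daily_rrf,
    mean_of_means_rrf,
    quantify_sample,
    results_frame,
    total_oligomers,
)
from .simulate import SampleDesign, SimulationConfig, simulate_calibration, simulate_sample_batch, simulate_spiking, simulate_stability
from .validation import (
    UncertaintyBudget,
    expanded_uncertainty,
    precision_anova,
    recovery,
    stability_assess,
    stability_table,
)

log = logging.getLogger(__name__)


def _default_contents() -> dict[str, float]:
    # realistic procyanidin-rich apple-extract profile (mg analyte / g extract)
    contents = {MONOMERS: 12.9}
    t0 = {a: v[0][0] for a, v in reference.STABILITY_SERIES.items() if a != EPICATECHIN}
    contents.update(t0)
    return contents


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    outdir: str = "procal_out"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    true_contents: dict[str, float] = field(default_factory=_default_contents)
    sample_mass_mg: float = 100.0
    volume_ml: float = 50.0
    dilution_factor: float = 1.0
    loq_policy: str = "lowest-level"  # or "theoretical"
    spike_levels: tuple[float, ...] = (1.0, 2.0)
    stability_timepoints_h: tuple[float, ...] = (0.0, 48.0, 96.0, 168.0)
    k: float = 2.0
    n1: int = 9  # total analyses feeding the precision terms
    n2: int = 3  # days measured
    qc_max_abs_z: float = 3.0
    run_interlab: bool = True

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("coverage factor k must be > 0")
        if not self.true_contents:
            raise ValueError("analyte roster (true_contents) must be non-empty")
        if self.loq_policy not in ("lowest-level", "theoretical"):
            raise ValueError("loq_policy must be 'lowest-level' or 'theoretical'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def calibrate_all(cal_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit every (analyte, day, lab) calibration series.

    Applies the zero-forcing decision per series and runs the lack-of-fit
    test on the free fit.  Returns a fit-report frame.
    """
    rows = []
    for (analyte, day, lab), g in cal_table.groupby(["analyte", "day", "lab"]):
        series = CalibrationSeries(
            analyte=analyte,
            concentrations=g["level_ug_per_ml"].to_numpy(float),
            responses=g["response"].to_numpy(float),
            day=str(day),
            lab=str(lab),
        )
        free = fit_calibration(series, force_zero=False)
        decision = decide_zero_forcing(free, alpha=alpha)
        fit = fit_calibration(series, force_zero=True) if decision.force else free
        try:
            lof = lack_of_fit_test(series, fit, alpha=alpha)
            lof_f, lof_ok = lof.F, lof.linear_ok
        except ValueError:
            lof_f, lof_ok = np.nan, np.nan
        lo, hi = working_range(series)
        rows.append(
            {
                "analyte": analyte,
                "day": str(day),
                "lab": str(lab),
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.r,
                "residual_sd": fit.residual_sd,
                "zero_forced": fit.zero_forced,
                "loq_theoretical_ug_per_ml": loq(fit),
                "lof_F": lof_f,
                "lof_linear_ok": lof_ok,
                "range_low_ug_per_ml": lo,
                "range_high_ug_per_ml": hi,
            }
        )
    return pd.DataFrame(rows)


def rrfs_from_fit_report(fit_report: pd.DataFrame, lab: str = "lab1") -> RRFTable:
    """Mean-of-means RRFs from per-day fitted slopes of one lab."""
    rep = fit_report[fit_report["lab"] == lab]
    epi = rep[rep["analyte"] == EPICATECHIN].set_index("day")["slope"]
    rrfs: dict[str, float] = {}
    rsds: dict[str, float] = {}
    n_days = 0
    for analyte in OLIGOMER_IDS:
        sub = rep[rep["analyte"] == analyte].set_index("day")["slope"]
        if sub.empty:
            continue
        daily = [s / epi[day] for day, s in sub.items() if day in epi.index]
        mean, rsd = mean_of_means_rrf(daily)
        rrfs[analyte] = mean
        rsds[analyte] = rsd
        n_days = max(n_days, len(daily))
    return RRFTable(rrfs=rrfs, rsd_percent=rsds, n_days=n_days, lab=lab)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    log.info("pipeline seed: %d", config.seed)

    # --- calibration -------------------------------------------------------
    cal_table = simulate_calibration(sim)
    write_table(cal_table, outdir / "calibration_data.csv")
    fit_report = calibrate_all(cal_table)
    write_table(fit_report, outdir / "calibration_fits.csv")

    rrf_table = rrfs_from_fit_report(fit_report)
    missing = [a for a in OLIGOMER_IDS if a in config.true_contents and a not in rrf_table.rrfs]
    if missing:
        raise RuntimeError(f"quantify stage: missing RRF for {', '.join(missing)}")
    rrf_frame = pd.DataFrame(
        {
            "analyte": list(rrf_table.rrfs),
            "rrf": list(rrf_table.rrfs.values()),
            "rsd_percent": [rrf_table.rsd_percent.get(a, np.nan) for a in rrf_table.rrfs],
        }
    )
    write_table(rrf_frame, outdir / "rrfs.csv")

    # reported LOQ ladder
    if config.loq_policy == "lowest-level":
        loqs = dict(reference.LOQ_UG_PER_ML)
        loqs[MONOMERS] = loqs[EPICATECHIN]
    else:
        epi_fits = fit_report[fit_report["analyte"] == EPICATECHIN]
        theo = float(epi_fits["loq_theoretical_ug_per_ml"].mean())
        loqs = {a: theo for a in list(config.true_contents) + [EPICATECHIN]}

    # --- quantification ----------------------------------------------------
    design = SampleDesign(
        true_contents=config.true_contents,
        sample_mass_mg=config.sample_mass_mg,
        volume_ml=config.volume_ml,
        dilution_factor=config.dilution_factor,
    )
    batch_sim = dataclasses.replace(sim, seed=sim.seed + 1)
    batch = simulate_sample_batch(design, batch_sim, n_reps=3, n_days=3)
    write_table(batch, outdir / "sample_peaks.csv")

    # mean epicatechin fit across days of lab1 for quantification
    epi_rows = fit_report[(fit_report["analyte"] == EPICATECHIN) & (fit_report["lab"] == "lab1")]
    from .calibration import CalibrationFit

    epi_fit = CalibrationFit(
        analyte=EPICATECHIN,
        slope=float(epi_rows["slope"].mean()),
        intercept=0.0,
        residual_sd=float(epi_rows["residual_sd"].mean()),
        r=float(epi_rows["r"].mean()),
        n_points=int(len(epi_rows)),
        zero_forced=True,
    )

    per_measurement = []
    for sample_id, g in batch.groupby("sample_id"):
        results = quantify_sample(
            g[["analyte", "response"]],
            epi_fit,
            rrf_table,
            mass_mg=float(g["mass_mg"].iloc[0]),
            volume_ml=float(g["volume_ml"].iloc[0]),
            dilution=float(g["dilution"].iloc[0]),
            loqs=loqs,
        )
        frame = results_frame(results)
        frame.insert(0, "sample_id", sample_id)
        frame["day"] = g["day"].iloc[0]
        frame["total_oligomers_mg_per_g"] = total_oligomers(results)
        per_measurement.append(frame)
    quant = pd.concat(per_measurement, ignore_index=True)
    write_table(quant, outdir / "quantified.csv")

    # --- precision ---------------------------------------------------------
    precision_rows = []
    for analyte, g in quant.groupby("analyte"):
        est = precision_anova(
            g.rename(columns={"content_mg_per_g": "value"})[["day", "value"]], analyte=analyte
        )
        precision_rows.append(
            {
                "analyte": analyte,
                "repeatability_rsd": est.repeatability_rsd,
                "intermediate_rsd": est.intermediate_rsd,
                "grand_mean_mg_per_g": est.grand_mean,
            }
        )
    precision = pd.DataFrame(precision_rows)
    write_table(precision, outdir / "precision.csv")

    # --- recovery ----------------------------------------------------------
    spike_sim = dataclasses.replace(sim, seed=sim.seed + 2)
    spiking = simulate_spiking(design, list(config.spike_levels), n_reps=3, config=spike_sim)
    write_table(spiking, outdir / "spiking_data.csv")
    recovery_rows = []
    for analyte, g in spiking.groupby("analyte"):
        found = {}
        for frac, gg in g.groupby("spike_fraction"):
            conc = gg["response"] / (epi_fit.slope * rrf_table.rrf(analyte))
            content = conc * gg["volume_ml"] * gg["dilution"] / gg["mass_mg"]
            found[float(frac)] = content.to_numpy()
        added = {
            float(frac): float(gg["added_mg_per_g"].iloc[0])
            for frac, gg in g.groupby("spike_fraction")
            if float(frac) > 0
        }
        est = recovery(
            unspiked=found[0.0],
            spiked={f: found[f] for f in added},
            added=added,
            analyte=analyte,
        )
        recovery_rows.append(
            {"analyte": analyte, "recovery_percent": est.recovery, "u_rec_percent": est.u_rec}
        )
    recovery_report = pd.DataFrame(recovery_rows)
    write_table(recovery_report, outdir / "recovery.csv")

    # --- stability ---------------------------------------------------------
    stab_sim = dataclasses.replace(sim, seed=sim.seed + 3, noise_cv=min(sim.noise_cv, 0.01))
    stab = simulate_stability(
        design, config.stability_timepoints_h, drift_per_h={}, config=stab_sim
    )
    verdicts = []
    for analyte, g in stab.groupby("analyte"):
        series = dict(zip(g["timepoint_h"], g["value_mg_per_g"]))
        ip = reference.STABILITY_SERIES.get(analyte, ((0,) * 4, 0.05))[1]
        verdicts.append(stability_assess(series, ip_fraction=ip, analyte=analyte))
    stability_report = stability_table(verdicts)
    write_table(stability_report, outdir / "stability.csv")

    # --- combined uncertainty ---------------------------------------------
    budget_rows = []
    rec_by_analyte = recovery_report.set_index("analyte")
    prec_by_analyte = precision.set_index("analyte")
    for analyte in config.true_contents:
        rrf_rsd = rrf_table.rsd_percent.get(analyte, 0.0)
        budget = UncertaintyBudget(
            u_rep_rrf=0.0 if analyte == MONOMERS else float(np.nan_to_num(rrf_rsd)),
            u_il_rrf=0.0,  # single simulated lab by default
            u_r=float(prec_by_analyte.loc[analyte, "repeatability_rsd"]),
            u_ip=float(prec_by_analyte.loc[analyte, "intermediate_rsd"]),
            n1=config.n1,
            n2=config.n2,
            u_bias=0.0,
            u_rec=float(rec_by_analyte.loc[analyte, "u_rec_percent"]),
            k=config.k,
        )
        budget_rows.append(
            {
                "analyte": analyte,
                "u_rep_rrf": budget.u_rep_rrf,
                "u_il_rrf": budget.u_il_rrf,
                "u_r": budget.u_r,
                "u_ip": budget.u_ip,
                "u_bias": budget.u_bias,
                "u_rec": budget.u_rec,
                "k": budget.k,
                "U_percent": expanded_uncertainty(budget),
            }
        )
    budgets = pd.DataFrame(budget_rows)
    write_table(budgets, outdir / "uncertainty.csv")

    summary: dict = {
        "seed": config.seed,
        "analytes": sorted(config.true_contents),
        "rrfs": rrf_table.rrfs,
        "mean_total_oligomers_mg_per_g": float(
            quant.groupby("sample_id")["total_oligomers_mg_per_g"].first().mean()
        ),
        "precision": precision.set_index("analyte").to_dict(orient="index"),
        "recovery": recovery_report.set_index("analyte").to_dict(orient="index"),
        "expanded_uncertainty_percent": budgets.set_index("analyte")["U_percent"].to_dict(),
        "stability_all_stable": bool(stability_report["stable"].all()),
    }

    # --- interlab (reference dataset) --------------------------------------
    if config.run_interlab:
        inter = reference.interlab_results()
        control = inter[
            (inter["material"] == "control") & (inter["analyte_class"] == "monomers")
        ].set_index("lab")["mean_mg_per_g"]
        included, excluded = qc_gate(control.to_dict(), max_abs_z=config.qc_max_abs_z)
        kept = inter[inter["lab"].isin(included)]
        consensus_rows = []
        z_inputs = {}
        for (material, cls), g in kept.groupby(["material", "analyte_class"]):
            mean, sd, rsd = consensus_stats(g["mean_mg_per_g"])
            consensus_rows.append(
                {
                    "material": material,
                    "analyte_class": cls,
                    "mean_mg_per_g": mean,
                    "sd_mg_per_g": sd,
                    "rsd_percent": rsd,
                }
            )
            z_inputs[f"{material}:{cls}"] = pd.Series(
                g["mean_mg_per_g"].to_numpy(), index=g["lab"].to_numpy()
            )
        consensus = pd.DataFrame(consensus_rows)
        write_table(consensus, outdir / "interlab_consensus.csv")
        zrep = z_score_report(pd.DataFrame(z_inputs))
        write_table(zrep.z.reset_index(names="lab"), outdir / "interlab_zscores.csv")
        summary["interlab"] = {
            "included_labs": list(included),
            "excluded_labs": list(excluded),
            "max_abs_z": float(zrep.z.abs().max().max()),
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
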