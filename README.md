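# procal

Quantification and method-validation toolkit for monomeric and oligomeric
**procyanidins** (degree of polymerisation dp1–dp10) in apple extracts, as
measured by HILIC-HPLC with fluorescence detection.

## The problem

Flavan-3-ol monomers (epicatechin, catechin) have commercial analytical
standards; procyanidin oligomers dp2–dp10 do not. The established route to
quantifying them is *indirect calibration*: isolate each oligomer once,
determine its **relative response factor**

&nbsp;&nbsp;&nbsp;&nbsp;RRF<sub>dp</sub> = S<sub>dp</sub> / S<sub>epi</sub>

(the ratio of calibration slopes, response per μg/mL), then quantify every
future sample against the epicatechin curve alone:

&nbsp;&nbsp;&nbsp;&nbsp;c = R / (S<sub>epi</sub> · RRF<sub>dp</sub>),&nbsp;&nbsp;
content (mg/g) = c · V · D / m

with R the summed dp-class peak response, V the dissolution volume (mL),
D the extra dilution factor and m the sample mass (mg). Because
fluorescence response per unit mass falls steeply with dp (RRF drops from
≈0.59 at dp2 to ≈0.06 at dp10), a generic response factor would bias
high-dp analytes severely — each dp needs its own.

`procal` implements that quantification scheme together with the
validation statistics that qualify it:

- **calibration** — OLS line fits, an intercept *t*-test deciding whether
  the curve may be forced through the origin, a lack-of-fit *F*-test for
  linearity, working range, and LOQ = 10σ/S with a lowest-level reporting
  clamp;
- **quantification** — daily RRFs, mean-of-means RRF tables with
  between-day and between-lab dispersion, response→content conversion,
  below-LOQ flagging and oligomer totals;
- **validation** — repeatability/intermediate precision from one-way
  (day) ANOVA with the restricted (truncated-at-zero) day component,
  spike recovery averaged over fortification levels, control-material
  bias, storage-stability assessment, and the combined expanded
  uncertainty
  U = k·√(u²<sub>rep(RRF)</sub> + u²<sub>il(RRF)</sub> + u²<sub>r</sub>/n₁ +
  u²<sub>ip</sub>/n₂ + u²<sub>bias</sub> + u²<sub>rec</sub>), k = 2;
- **interlab** — consensus mean/SD/%RSD across laboratories, a
  leave-one-out QC gate on a shared control material, and proficiency
  z-scores z = (x − μ)/σ with the |z| ≤ 2 / < 3 / ≥ 3 classification;
- **simulate** — a synthetic detector-data generator (linear response,
  per-dp slopes, log-normal day/lab effects, proportional noise, optional
  glass-adsorption loss) so the whole pipeline is testable end to end
  without instrument data.

The package ships the reference figures established for the method (RRF
table, LOQ ladder, precision, recoveries, stability series, seven-lab
results) in `procal.reference` for use as fixtures and defaults.

## Worked example

Determine RRFs from a simulated three-day calibration study (8 levels
over 5–100 μg/mL, 3 replicates per level, 2 % proportional noise):

```python
from procal import SimulationConfig, simulate_calibration, consensus_stats
from procal.pipeline import calibrate_all, rrfs_from_fit_report

cal = simulate_calibration(SimulationConfig(seed=42))
rrfs = rrfs_from_fit_report(calibrate_all(cal))
for a in ("dp2", "dp5", "dp10"):
    print(f"{a}: RRF = {rrfs.rrfs[a]:.3f} (between-day RSD {rrfs.rsd_percent[a]:.1f}%)")

mean, sd, rsd = consensus_stats([337.3, 344.2, 323.8, 332.0, 323.2, 306.2, 312.0])
print(f"consensus: {mean:.1f} mg/g, SD {sd:.1f}, RSD {rsd:.1f}%")
```

prints

```
dp2: RRF = 0.592 (between-day RSD 3.8%)
dp5: RRF = 0.236 (between-day RSD 2.3%)
dp10: RRF = 0.061 (between-day RSD 4.3%)
consensus: 325.5 mg/g, SD 13.5, RSD 4.1%
```

The recovered RRFs sit within the simulated between-day spread of the
generator's truths (0.587, 0.238, 0.062); the consensus line is the
seven-laboratory summary of extract-A monomer contents, reproduced from
the per-laboratory means.

The same stages are available from the shell:

```bash
procal simulate --seed 42 --out cal.csv
procal calibrate cal.csv --out fits.csv
procal quantify peaks.csv --fits fits.csv --out contents.csv
procal interlab                       # consensus report from shipped results
procal run --seed 42 --out bundle/    # full pipeline, CSVs + summary.json
```

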