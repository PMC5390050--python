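"""Synthetic-data generator: determinism, response model, recovery oracles."""

import numpy as np
import pandas as pd
import pytest

from procal import (
    RRFTable,
    SampleDesign,
    SimulationConfig,
    quantify_sample,
    simulate_calibration,
    simulate_sample_batch,
    simulate_spiking,
    simulate_stability,
)
from procal.reference import RRF_MEAN_OF_MEANS

from conftest import noise_free_epi_fit


class TestSimulateCalibration:
    def test_noise_free_linear_model(self):
        config = SimulationConfig(
            true_epicatechin_slope=10.0,
            true_rrfs={"dp2": 0.5},
            noise_cv=0.0,
            day_effect_cv=0.0,
            lab_effect_cv=0.0,
            levels=(20.0,),
            replicates_per_level=1,
            n_days=1,
            n_labs=1,
            seed=0,
        )
        table = simulate_calibration(config)
        dp2 = table[table.analyte == "dp2"]
        assert dp2["response"].iloc[0] == pytest.approx(100.0)

    def test_determinism(self, default_config):
        a = simulate_calibration(default_config)
        b = simulate_calibration(default_config)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self, default_config):
        import dataclasses

        other = dataclasses.replace(default_config, seed=default_config.seed + 1)
        assert not simulate_calibration(default_config)["response"].equals(
            simulate_calibration(other)["response"]
        )

    def test_rrf_recovery_via_independent_least_squares(self, default_config):
        """Mean-of-means RRFs from per-day Σxy/Σx² slopes recover the
        planted truths within 3 Monte-Carlo standard errors."""
        table = simulate_calibration(default_config)
        # independent oracle: closed-form forced-zero slope per series
        daily_rrfs: dict[str, list[float]] = {}
        for day, g in table.groupby("day"):
            slopes = {}
            for analyte, gg in g.groupby("analyte"):
                x = gg["level_ug_per_ml"].to_numpy()
                y = gg["response"].to_numpy()
                slopes[analyte] = float(x @ y / (x @ x))
            for analyte in RRF_MEAN_OF_MEANS:
                daily_rrfs.setdefault(analyte, []).append(
                    slopes[analyte] / slopes["epicatechin"]
                )
        # simulated-CV standard error of the 3-day mean: the slope ratio
        # carries per-analyte day effects (×2, numerator and denominator)
        # plus the replicate-noise contribution to each fitted slope
        cv = np.sqrt(2 * (default_config.day_effect_cv**2 + default_config.noise_cv**2))
        for analyte, truth in RRF_MEAN_OF_MEANS.items():
            daily = np.array(daily_rrfs[analyte])
            se = truth * cv / np.sqrt(default_config.n_days)
            assert abs(daily.mean() - truth) < 3 * se, analyte

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="noise_cv"):
            SimulationConfig(noise_cv=-0.1)
        with pytest.raises(ValueError, match="levels"):
            SimulationConfig(levels=(10.0, 5.0))
        with pytest.raises(ValueError, match="true_rrfs"):
            SimulationConfig(true_rrfs={"dp2": 1.5})

    def test_empirical_cv_converges_to_noise_cv(self):
        """Response CV at one level approaches noise_cv for many replicates."""
        config = SimulationConfig(
            true_rrfs={"dp2": 0.5},
            noise_cv=0.05,
            day_effect_cv=0.0,
            lab_effect_cv=0.0,
            levels=(50.0,),
            replicates_per_level=10_000,
            n_days=1,
            seed=11,
        )
        table = simulate_calibration(config)
        resp = table[table.analyte == "dp2"]["response"]
        cv = resp.std(ddof=1) / resp.mean()
        assert cv == pytest.approx(0.05, rel=0.05)


class TestSampleBatch:
    def test_round_trip_identity(self, apple_design):
        config = SimulationConfig(seed=1, noise_cv=0.0, day_effect_cv=0.0, lab_effect_cv=0.0)
        batch = simulate_sample_batch(apple_design, config, n_reps=2, n_days=2)
        fit = noise_free_epi_fit(config.true_epicatechin_slope)
        for _, g in batch.groupby("sample_id"):
            results = quantify_sample(
                g[["analyte", "response"]], fit, RRFTable(rrfs=dict(RRF_MEAN_OF_MEANS)),
                mass_mg=apple_design.sample_mass_mg,
                volume_ml=apple_design.volume_ml,
                dilution=apple_design.dilution_factor,
            )
            for r in results:
                assert r.content_mg_per_g == pytest.approx(
                    apple_design.true_contents[r.analyte], rel=1e-12
                )

    def test_adsorption_loss_monotone_in_surface(self):
        """Recovered oligomer content decreases as contacted glass grows."""
        config = SimulationConfig(seed=1, noise_cv=0.0, day_effect_cv=0.0, lab_effect_cv=0.0)
        fit = noise_free_epi_fit(config.true_epicatechin_slope)
        recovered = []
        for surface in (0.0, 50.0, 100.0, 150.0):
            design = SampleDesign(
                true_contents={"dp4": 80.0},
                adsorption_loss_coeff=0.002,
                contacted_surface_cm2=surface,
            )
            batch = simulate_sample_batch(design, config, n_reps=1, n_days=1)
            results = quantify_sample(
                batch[["analyte", "response"]], fit, RRFTable(rrfs=dict(RRF_MEAN_OF_MEANS)),
                100.0, 50.0,
            )
            recovered.append(results[0].content_mg_per_g)
        assert all(a > b for a, b in zip(recovered, recovered[1:]))
        # oracle: the loss model itself
        assert recovered[2] == pytest.approx(80.0 * (1 - 0.002 * 100.0), rel=1e-12)

    def test_loss_fraction_validation(self):
        with pytest.raises(ValueError, match="adsorption loss"):
            SampleDesign(
                true_contents={"dp2": 1.0},
                adsorption_loss_coeff=0.02,
                contacted_surface_cm2=60.0,
            )


class TestSpiking:
    def test_noise_free_full_recovery(self):
        from procal import recovery

        design = SampleDesign(true_contents={"dp2": 40.0, "dp5": 77.0})
        config = SimulationConfig(seed=2, noise_cv=0.0, day_effect_cv=0.0, lab_effect_cv=0.0)
        table = simulate_spiking(design, [1.0, 2.0], n_reps=3, config=config)
        fit = noise_free_epi_fit(config.true_epicatechin_slope)
        for analyte, g in table.groupby("analyte"):
            found = {}
            for frac, gg in g.groupby("spike_fraction"):
                conc = gg["response"] / (fit.slope * RRF_MEAN_OF_MEANS.get(analyte, 1.0))
                found[frac] = (conc * 50.0 / 100.0).to_numpy()
            added = {
                frac: float(gg["added_mg_per_g"].iloc[0])
                for frac, gg in g.groupby("spike_fraction") if frac > 0
            }
            est = recovery(found[0.0], {f: found[f] for f in added}, added)
            assert est.recovery == pytest.approx(100.0, rel=1e-9)

    def test_condition_labels(self):
        design = SampleDesign(true_contents={"dp2": 40.0})
        config = SimulationConfig(seed=2)
        table = simulate_spiking(design, [1.0, 2.0], n_reps=2, config=config)
        assert set(table["condition"]) == {"0%", "100%", "200%"}

    def test_loss_only_on_higher_oligomers(self):
        """Loss applied to dp≥4 depresses only those recoveries."""
        from procal import recovery

        coeffs = {f"dp{d}": 0.002 for d in range(4, 11)}
        design = SampleDesign(
            true_contents={"dp2": 40.0, "dp4": 80.0, "dp7": 78.0},
            adsorption_loss_coeff=coeffs,
            contacted_surface_cm2=100.0,
        )
        config = SimulationConfig(seed=3, noise_cv=0.0, day_effect_cv=0.0, lab_effect_cv=0.0)
        table = simulate_spiking(design, [1.0], n_reps=2, config=config)
        fit = noise_free_epi_fit(config.true_epicatechin_slope)
        recs = {}
        for analyte, g in table.groupby("analyte"):
            found = {}
            for frac, gg in g.groupby("spike_fraction"):
                conc = gg["response"] / (fit.slope * RRF_MEAN_OF_MEANS[analyte])
                found[frac] = (conc * 50.0 / 100.0).to_numpy()
            added = float(g[g.spike_fraction == 1.0]["added_mg_per_g"].iloc[0])
            recs[analyte] = recovery(found[0.0], {1.0: found[1.0]}, {1.0: added}).recovery
        assert recs["dp2"] == pytest.approx(100.0, rel=1e-9)
        assert recs["dp4"] == pytest.approx(80.0, rel=1e-9)  # 1 − 0.002·100
        assert recs["dp7"] == pytest.approx(80.0, rel=1e-9)


class TestStabilitySim:
    def test_zero_drift_zero_noise(self):
        design = SampleDesign(true_contents={"dp2": 40.0})
        config = SimulationConfig(seed=4, noise_cv=0.0)
        table = simulate_stability(design, [0, 48, 96, 168], {}, config)
        assert table["value_mg_per_g"].nunique() == 1

    def test_drift_substitution(self):
        """content 12.9, drift −0.0004/h: the 168 h value is 12.03."""
        design = SampleDesign(true_contents={"monomers": 12.9})
        config = SimulationConfig(seed=4, noise_cv=0.0)
        table = simulate_stability(design, [0, 168], {"monomers": -0.0004}, config)
        v168 = table[table.timepoint_h == 168]["value_mg_per_g"].iloc[0]
        assert v168 == pytest.approx(12.9 * (1 - 0.0004 * 168), rel=1e-12)
        assert v168 == pytest.approx(12.03, abs=0.005)

    def test_small_drift_within_acceptance_band(self, apple_design):
        """With default noise and |drift|·168 below the band, the stability
        stage flags no failures."""
        from procal import stability_assess

        config = SimulationConfig(seed=5)  # default 2% noise
        drift = {a: 0.00005 for a in apple_design.true_contents}  # 0.84% over 168 h
        table = simulate_stability(apple_design, [0, 48, 96, 168], drift, config)
        for analyte, g in table.groupby("analyte"):
            series = dict(zip(g["timepoint_h"], g["value_mg_per_g"]))
            v = stability_assess(series, ip_fraction=0.10, analyte=analyte)
            assert v.stable, analyte

    def test_requires_time_zero(self):
        design = SampleDesign(true_contents={"dp2": 40.0})
        with pytest.raises(ValueError, match="include 0"):
            simulate_stability(design, [48, 168], {}, SimulationConfig(seed=0))
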