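"""Generator determinism, closed-form recovery, and injected-truth consistency."""

import numpy as np
import pandas as pd
import pytest

from phytosize import trends as tr
from phytosize.simulate import (
    ScenarioConfig,
    generate_dataset,
    generate_environment,
    generate_observations,
    generate_species_pool,
    truth_summary,
)


def _quiet_cfg(**kw):
    base = dict(
        n_stations=1, months=60, n_diatom=4, n_dinoflagellate=3, n_other=2,
        seed=11, temp_noise_sd=0.0, po4_noise_logsd=0.0, din_noise_logsd=0.0,
        size_noise_sd=0.0, abund_noise_sd=0.0, bloom_prob=0.0,
        seasonal_amp_mean=0.0, seasonal_amp_sd=0.0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestEnvironment:
    def test_zero_noise_zero_amplitude_is_exactly_linear(self):
        cfg = _quiet_cfg()
        env = generate_environment(cfg)
        t = np.arange(cfg.months)
        temp = env["temperature"].to_numpy()
        # second differences of a linear series vanish
        assert np.allclose(np.diff(temp, 2), 0.0, atol=1e-12)
        fit = tr.linear_trend(t.astype(float), temp)
        from phytosize.simulate import station_parameters

        w = station_parameters(cfg)["warming"].iloc[0]
        assert fit.slope_per_month == pytest.approx(w / 12.0, abs=1e-12)

    def test_same_seed_identical_tables(self):
        cfg = ScenarioConfig(n_stations=2, months=30, n_diatom=4, n_dinoflagellate=3, n_other=2, seed=3)
        a = generate_dataset(cfg, seed=3)
        b = generate_dataset(cfg, seed=3)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.environment, b.environment)

    def test_po4_floored_positive(self):
        cfg = ScenarioConfig(
            n_stations=2, months=240, n_diatom=4, n_dinoflagellate=3, n_other=2,
            po4_base_mean=5.0, po4_slope_mean=-2.0, seed=1,
        )
        env = generate_environment(cfg)
        assert (env["PO4"] >= cfg.po4_floor).all()


class TestPool:
    def test_group_counts_match_config(self):
        cfg = ScenarioConfig(n_diatom=10, n_dinoflagellate=10, n_other=5, seed=0)
        pool = generate_species_pool(cfg)
        counts = pool["group"].value_counts()
        assert counts["diatom"] == 10 and counts["dinoflagellate"] == 10 and counts["other"] == 5

    def test_small_flag_is_bottom_quartile_floor(self):
        cfg = ScenarioConfig(n_diatom=10, n_dinoflagellate=10, n_other=5, seed=0)
        pool = generate_species_pool(cfg)
        assert pool["small"].sum() == int(np.floor(25 * 0.25))
        assert pool.loc[pool["small"], "v0"].max() <= pool.loc[~pool["small"], "v0"].min()

    def test_baseline_biovolumes_span_orders_of_magnitude(self):
        pool = generate_species_pool(ScenarioConfig(seed=2))
        assert pool["v0"].min() > 1.0
        assert np.log10(pool["v0"].max() / pool["v0"].min()) > 2.5


class TestObservations:
    def test_constant_biovolume_without_size_effects(self):
        cfg = _quiet_cfg(beta_mean=0.0, beta_sd=0.0, gamma_mean=0.0, gamma_sd=0.0)
        env = generate_environment(cfg)
        pool = generate_species_pool(cfg)
        obs = generate_observations(pool, env, cfg, presence_threshold=0.0)
        spread = obs.groupby("species_id")["cell_biovolume"].agg(lambda v: v.max() - v.min())
        assert (spread < 1e-9).all()

    def test_intrinsic_trend_recovered_exactly_by_ols(self):
        cfg = _quiet_cfg(beta_mean=0.0, beta_sd=0.0, gamma_mean=-0.002, gamma_sd=0.0)
        env = generate_environment(cfg)
        pool = generate_species_pool(cfg)
        obs = generate_observations(pool, env, cfg, presence_threshold=0.0)
        for sp, g in obs.groupby("species_id"):
            t = np.arange(len(g), dtype=float)
            fit = tr.linear_trend(t, np.log(g.sort_values("date")["cell_biovolume"].to_numpy()))
            assert fit.slope_per_month == pytest.approx(-0.002, abs=1e-10)

    def test_warming_chain_rule_recovered_exactly(self):
        # zero seasonal amplitude, zero noise: log-size slope = gamma + beta*w/12
        cfg = _quiet_cfg(beta_mean=-0.02, beta_sd=0.01, gamma_mean=-3e-4, gamma_sd=1e-4)
        ds = generate_dataset(cfg)
        truth = ds.truth.species.query("station_id == 'S01'").set_index("species_id")["log_size_slope"]
        for sp, g in ds.observations.groupby("species_id"):
            g = g.sort_values("date")
            t = np.arange(len(g), dtype=float)
            fit = tr.linear_trend(t, np.log(g["cell_biovolume"].to_numpy()))
            assert fit.slope_per_month == pytest.approx(truth[sp], abs=1e-8)

    def test_negative_drift_gives_declining_small_fraction(self):
        from phytosize import size_metrics as sm

        cfg = ScenarioConfig(n_stations=1, months=240, delta=-0.002, seed=5)
        ds = generate_dataset(cfg)
        small = sm.classify_small_species(ds.observations)
        sf = sm.small_fraction_table(ds.observations, small)
        fit = tr.linear_trend(sf["lagged_month"].to_numpy(float), sf["small_fraction"].to_numpy(float))
        assert fit.slope_per_month < 0
        assert fit.p < 0.05


class TestTruth:
    def test_all_zero_effects_give_zero_truth(self):
        cfg = _quiet_cfg(
            beta_mean=0.0, beta_sd=0.0, gamma_mean=0.0, gamma_sd=0.0,
            delta=0.0, po4_small_coupling=0.0,
        )
        truth = truth_summary(cfg)
        assert np.allclose(truth.species["log_size_slope"], 0.0)
        assert np.allclose(truth.stations["small_drift_per_month"], 0.0)

    def test_pure_warming_truth_is_beta_times_monthly_warming(self):
        cfg = _quiet_cfg(beta_mean=-0.03, beta_sd=0.0, gamma_mean=0.0, gamma_sd=0.0)
        truth = truth_summary(cfg)
        from phytosize.simulate import station_parameters

        w = station_parameters(cfg)["warming"].iloc[0]
        st = truth.species.query("station_id == 'S01'")
        assert np.allclose(st["log_size_slope"], -0.03 * w / 12.0)

    def test_truth_matches_regeneration_under_same_seed(self):
        cfg = ScenarioConfig(n_stations=2, months=48, n_diatom=4, n_dinoflagellate=3, n_other=2, seed=9)
        a, b = truth_summary(cfg), truth_summary(cfg)
        pd.testing.assert_frame_equal(a.species, b.species)
        assert a.partition == b.partition
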