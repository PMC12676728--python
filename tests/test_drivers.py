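"""Correlation screening, response-group clustering, partial effects, tournament."""

import numpy as np
import pandas as pd
import pytest

from phytosize import drivers as dr
from phytosize.simulate import (
    ScenarioConfig,
    generate_environment,
    generate_observations,
    generate_species_pool,
)
from phytosize.validation import partial_effect_oracle_gap


def _env_obs_pair(factor_values, size_values):
    """Minimal single-species observation/environment pair over months."""
    months = pd.period_range("2000-01", periods=len(factor_values), freq="M")
    obs = pd.DataFrame(
        {
            "station_id": "A", "wcz": "Z", "date": months, "species_id": "sp1",
            "group": "diatom", "abundance": 10.0, "cell_biovolume": size_values,
        }
    )
    env = pd.DataFrame({"station_id": "A", "date": months, "temperature": factor_values})
    return obs, env


class TestCorrelations:
    def test_perfect_positive_and_negative(self):
        vals = np.linspace(10, 30, 24)
        obs, env = _env_obs_pair(vals, vals)
        r, support = dr.species_env_correlations(obs, env, ["sp1"], ["temperature"])
        assert r.loc["sp1", "temperature"] == pytest.approx(1.0)
        assert support.loc["sp1", "temperature"] == 24
        obs2, env2 = _env_obs_pair(vals, -vals + 100)
        r2, _ = dr.species_env_correlations(obs2, env2, ["sp1"], ["temperature"])
        assert r2.loc["sp1", "temperature"] == pytest.approx(-1.0)

    def test_constant_factor_missing(self):
        obs, env = _env_obs_pair(np.full(10, 20.0), np.linspace(1, 2, 10))
        r, _ = dr.species_env_correlations(obs, env, ["sp1"], ["temperature"])
        assert np.isnan(r.loc["sp1", "temperature"])

    def test_empty_factor_list_errors(self):
        obs, env = _env_obs_pair(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            dr.species_env_correlations(obs, env, ["sp1"], [])


class TestClustering:
    def test_archetypes_separate_with_sign_labels(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(6):
            rows[f"warm{i}"] = [0.8 + rng.normal(0, 0.03), 0.0]
            rows[f"cold{i}"] = [-0.8 + rng.normal(0, 0.03), 0.0]
        corr = pd.DataFrame.from_dict(rows, orient="index", columns=["temperature", "PO4"])
        out = dr.cluster_response_groups(corr, k=2)
        by_cluster = out.groupby("cluster")["species_id"].apply(list)
        assert len(by_cluster) == 2
        for members in by_cluster:
            prefixes = {m[:4] for m in members}
            assert len(prefixes) == 1
        assert set(out["label"]) == {"T+", "T-"}

    def test_nutrient_suffix_labels(self):
        corr = pd.DataFrame(
            {"temperature": [-0.5, -0.5, 0.6], "PO4": [0.6, -0.6, 0.0], "DIN": [0.4, -0.4, 0.0]},
            index=["a", "b", "c"],
        )
        out = dr.cluster_response_groups(corr, k=3)
        labels = dict(zip(out["species_id"], out["label"]))
        assert labels["a"] == "T- & N+"
        assert labels["b"] == "T- & N-"
        assert labels["c"] == "T+"

    def test_k_equals_species_count_gives_singletons(self):
        corr = pd.DataFrame(np.eye(4) * 0.5, columns=list("wxyz"), index=list("abcd"))
        out = dr.cluster_response_groups(corr, k=4, temp_col="w", nutrient_cols=[])
        assert out["cluster"].nunique() == 4

    def test_duplicate_rows_co_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(3, 4))
        corr = pd.DataFrame(
            np.vstack([base, base[0]]), index=["a", "b", "c", "a_copy"],
            columns=["temperature", "PO4", "DIN", "salinity"],
        )
        out = dr.cluster_response_groups(corr, k=3).set_index("species_id")
        assert out.loc["a", "cluster"] == out.loc["a_copy", "cluster"]

    def test_k_exceeding_species_errors(self):
        corr = pd.DataFrame(np.zeros((2, 2)), columns=["temperature", "PO4"], index=["a", "b"])
        with pytest.raises(ValueError):
            dr.cluster_response_groups(corr, k=5)


class TestPartialEffect:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(2)
        n = 120
        t = rng.normal(22, 3, n)
        po4 = rng.normal(30, 5, n)
        station = rng.choice(["A", "B", "C"], n)
        offsets = {"A": 0.0, "B": 1.0, "C": -2.0}
        y = 2.0 - 0.5 * t + 1.0 * po4 + np.array([offsets[s] for s in station])
        df = pd.DataFrame({"y": y, "T": t, "PO4": po4, "station": station})
        res = dr.partial_effect(df, "y", "T", ["PO4"], "station")
        assert res.coefficient == pytest.approx(-0.5, abs=1e-10)
        assert res.p == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_focal_equals_simple_regression(self):
        rng = np.random.default_rng(3)
        n = 200
        focal = np.repeat([-1.0, 1.0], n // 2)
        cov = np.tile([-1.0, 1.0], n // 2)  # exactly orthogonal to focal
        y = 0.7 * focal + 0.2 * cov + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"y": y, "f": focal, "c": cov})
        full = dr.partial_effect(df, "y", "f", ["c"])
        simple = dr.partial_effect(df, "y", "f", [])
        assert full.coefficient == pytest.approx(simple.coefficient, abs=1e-10)

    def test_duplicated_covariate_raises_naming_columns(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.normal(size=30), "a": rng.normal(size=30)})
        df["b"] = df["a"]
        with pytest.raises(ValueError, match="collinear"):
            dr.partial_effect(df, "y", "a", ["b"])

    def test_matches_normal_equations_oracle(self):
        assert partial_effect_oracle_gap(n_designs=50, seed=0) < 1e-8


class TestTSR:
    def _scenario(self, beta):
        cfg = ScenarioConfig(
            n_stations=3, months=120, n_diatom=2, n_dinoflagellate=2, n_other=1,
            beta_mean=beta, beta_sd=0.0, gamma_mean=0.0, gamma_sd=0.0,
            delta=0.0, po4_small_coupling=0.0, bloom_prob=0.0,
            size_noise_sd=0.1, seed=42,
        )
        env = generate_environment(cfg)
        pool = generate_species_pool(cfg)
        obs = generate_observations(pool, env, cfg, presence_threshold=0.0)
        return dr.species_table(obs, env), pool

    def test_injected_negative_beta_follows_tsr(self):
        table, pool = self._scenario(-0.05)
        res = dr.tsr_test(table, pool["species_id"])
        assert (res["class"] == "follows_tsr").all()
        assert res["coefficient"].median() == pytest.approx(-0.05, rel=0.2)

    def test_injected_positive_beta_is_anti_tsr(self):
        table, pool = self._scenario(+0.05)
        res = dr.tsr_test(table, pool["species_id"])
        assert (res["class"] == "anti_tsr").all()


class TestTournament:
    class _Mean:
        name = "mean_only"

        def fit(self, x, y):
            self._m = y.mean()
            return self

        def predict(self, x):
            return np.full(len(x), self._m)

    class _TrueLinear:
        name = "true_linear"

        def fit(self, x, y):
            self._b = np.linalg.lstsq(np.column_stack([x, np.ones(len(x))]), y, rcond=None)[0]
            return self

        def predict(self, x):
            return np.column_stack([x, np.ones(len(x))]) @ self._b

    def _linear_data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, n)
        return x, y

    def test_generating_model_beats_mean_predictor(self):
        x, y = self._linear_data()
        res = dr.model_tournament(x, y, [self._TrueLinear(), self._Mean()], seed=1)
        assert res.winner == "true_linear"

    def test_same_seed_reproduces_scores(self):
        x, y = self._linear_data()
        learners = lambda: [self._TrueLinear(), self._Mean()]  # noqa: E731
        a = dr.model_tournament(x, y, learners(), seed=5)
        b = dr.model_tournament(x, y, learners(), seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_single_learner_wins(self):
        x, y = self._linear_data()
        res = dr.model_tournament(x, y, [self._Mean()], seed=0)
        assert res.winner == "mean_only"

    def test_invalid_test_fraction_errors(self):
        x, y = self._linear_data()
        with pytest.raises(ValueError):
            dr.model_tournament(x, y, [self._Mean()], test_frac=1.5)

    def test_five_default_learner_families(self):
        names = [lr.name for lr in dr.default_learners(fast=True)]
        assert names == ["ridge", "random_forest", "xgboost", "neural_net", "svm"]

    def test_default_learners_run_on_linear_data(self):
        x, y = self._linear_data(n=150)
        res = dr.model_tournament(x, y, dr.default_learners(seed=0, fast=True), seed=2)
        assert res.scores.loc[res.scores["learner"] == "ridge", "r2"].iloc[0] > 0.9
        assert res.winner == "ridge"
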