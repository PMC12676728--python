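"""Community mean size, the small-species quartile rule, Small% and ESD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytosize import size_metrics as sm


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["station_id", "wcz", "date", "species_id", "group", "abundance", "cell_biovolume"]
    ).assign(date=lambda d: pd.PeriodIndex(d["date"], freq="M"))


class TestCommunityMeanSize:
    def test_single_species_equals_its_biovolume(self):
        obs = _obs([("A", "Z", "2000-01", "s1", "diatom", 40.0, 750.0)])
        assert sm.community_mean_size(obs) == pytest.approx(750.0)

    def test_weighted_mean_arithmetic(self):
        obs = _obs([
            ("A", "Z", "2000-01", "s1", "diatom", 9.0, 100.0),
            ("A", "Z", "2000-01", "s2", "diatom", 1.0, 10000.0),
        ])
        assert sm.community_mean_size(obs) == pytest.approx(1090.0)

    def test_abundance_scale_invariance(self):
        obs = _obs([
            ("A", "Z", "2000-01", "s1", "diatom", 9.0, 100.0),
            ("A", "Z", "2000-01", "s2", "diatom", 1.0, 10000.0),
        ])
        doubled = obs.assign(abundance=obs["abundance"] * 2)
        assert sm.community_mean_size(doubled) == pytest.approx(sm.community_mean_size(obs))

    def test_zero_total_abundance_is_missing(self):
        obs = _obs([("A", "Z", "2000-01", "s1", "diatom", 0.0, 100.0)])
        assert np.isnan(sm.community_mean_size(obs))

    @given(st.integers(1, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_convex_combination_of_species_sizes(self, n_sp, seed):
        rng = np.random.default_rng(seed)
        n = rng.lognormal(2, 1, n_sp)
        v = rng.lognormal(5, 2, n_sp)
        obs = _obs([("A", "Z", "2000-01", f"s{i}", "diatom", n[i], v[i]) for i in range(n_sp)])
        c = sm.community_mean_size(obs)
        assert v.min() - 1e-9 <= c <= v.max() + 1e-9
        assert c == pytest.approx(np.average(v, weights=n))


class TestSmallSpecies:
    def test_four_species_flags_only_smallest(self):
        obs = _obs([("A", "Z", "2000-01", f"s{i}", "diatom", 1.0, 10.0 ** (i + 1)) for i in range(4)])
        res = sm.classify_small_species(obs)
        assert res.members == frozenset({"s0"})
        assert res.threshold == pytest.approx(10.0)

    def test_eight_species_flags_two_smallest(self):
        obs = _obs([("A", "Z", "2000-01", f"s{i}", "diatom", 1.0, float(2 ** i)) for i in range(8)])
        res = sm.classify_small_species(obs)
        assert res.members == frozenset({"s0", "s1"})

    def test_tie_at_cut_prefers_lexicographically_smaller_id(self):
        obs = _obs([
            ("A", "Z", "2000-01", "aa", "diatom", 1.0, 5.0),
            ("A", "Z", "2000-01", "ab", "diatom", 1.0, 5.0),
            ("A", "Z", "2000-01", "s3", "diatom", 1.0, 50.0),
            ("A", "Z", "2000-01", "s4", "diatom", 1.0, 500.0),
        ])
        assert sm.classify_small_species(obs).members == frozenset({"aa"})

    def test_q_one_returns_all_and_floor_is_at_least_one(self):
        obs = _obs([("A", "Z", "2000-01", f"s{i}", "diatom", 1.0, float(10 * (i + 1))) for i in range(5)])
        assert len(sm.classify_small_species(obs, q=1.0).members) == 5
        assert len(sm.classify_small_species(obs, q=0.01).members) == 1

    def test_fewer_than_four_species_errors(self):
        obs = _obs([("A", "Z", "2000-01", f"s{i}", "diatom", 1.0, 10.0) for i in range(3)])
        with pytest.raises(ValueError):
            sm.classify_small_species(obs)

    def test_average_biovolume_is_unweighted_over_presences(self):
        obs = _obs([
            ("A", "Z", "2000-01", "s1", "diatom", 1e6, 100.0),
            ("A", "Z", "2000-02", "s1", "diatom", 1.0, 300.0),
        ])
        assert sm.average_species_biovolume(obs)["s1"] == pytest.approx(200.0)


class TestSmallFraction:
    def _small(self):
        return sm.SmallSpeciesSet(frozenset({"small1"}), 0.25, 10.0, "region")

    def test_no_small_species_present_is_zero(self, simple_obs):
        sub = simple_obs[simple_obs["species_id"] != "small1"]
        assert sm.small_fraction(sub[sub["station_id"] == "A"].iloc[:3], self._small()) == 0.0

    def test_all_cells_small_is_one(self, simple_obs):
        sub = simple_obs[simple_obs["species_id"] == "small1"].iloc[:1]
        assert sm.small_fraction(sub, self._small()) == 1.0

    def test_share_arithmetic(self):
        obs = _obs([
            ("A", "Z", "2000-01", "small1", "diatom", 25.0, 10.0),
            ("A", "Z", "2000-01", "big", "diatom", 75.0, 1e4),
        ])
        assert sm.small_fraction(obs, self._small()) == pytest.approx(0.25)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_uniform_scaling_invariance(self, c):
        obs = _obs([
            ("A", "Z", "2000-01", "small1", "diatom", 30.0, 10.0),
            ("A", "Z", "2000-01", "big", "diatom", 70.0, 1e4),
        ])
        scaled = obs.assign(abundance=obs["abundance"] * c)
        assert sm.small_fraction(scaled, self._small()) == pytest.approx(
            sm.small_fraction(obs, self._small())
        )

    def test_richness_variant(self, simple_obs):
        one = simple_obs[simple_obs["station_id"] == "A"]
        one = one[one["date"] == pd.Period("2000-01", "M")]
        assert sm.small_fraction(one, self._small(), mode="richness") == pytest.approx(0.25)

    def test_table_values_in_unit_interval(self, tiny_dataset):
        obs = tiny_dataset.observations
        small = sm.classify_small_species(obs)
        tab = sm.small_fraction_table(obs, small)
        assert tab["small_fraction"].between(0, 1).all()


class TestESD:
    @pytest.mark.parametrize("v,expected", [(np.pi / 6, 1.0), (125 * np.pi / 6, 5.0)])
    def test_sphere_inversion(self, v, expected):
        assert sm.esd_from_biovolume(v) == pytest.approx(expected)

    def test_strictly_increasing(self):
        v = np.logspace(0, 6, 50)
        d = sm.esd_from_biovolume(v)
        assert (np.diff(d) > 0).all()

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            sm.esd_from_biovolume(0.0)


class TestTopSpecies:
    def test_ranking_by_total_abundance(self):
        obs = _obs([
            ("A", "Z", "2000-01", "d1", "diatom", 10.0, 1.0),
            ("A", "Z", "2000-02", "d1", "diatom", 10.0, 1.0),
            ("A", "Z", "2000-01", "d2", "diatom", 5.0, 1.0),
            ("A", "Z", "2000-01", "d3", "diatom", 1.0, 1.0),
        ])
        top = sm.select_top_species(obs, {"diatom": 2})
        assert top["species_id"].tolist() == ["d1", "d2"]

    def test_request_exceeding_group_errors_naming_group(self):
        obs = _obs([("A", "Z", "2000-01", "d1", "diatom", 1.0, 1.0)])
        with pytest.raises(ValueError, match="diatom"):
            sm.select_top_species(obs, {"diatom": 2})

    def test_row_order_invariance(self, tiny_dataset):
        obs = tiny_dataset.observations
        counts = {"diatom": 3, "dinoflagellate": 2}
        a = sm.select_top_species(obs, counts)
        b = sm.select_top_species(obs.sample(frac=1.0, random_state=1), counts)
        pd.testing.assert_frame_equal(a, b)


class TestSpeciesSeries:
    def test_single_sample_series(self, simple_obs):
        one = simple_obs.iloc[:1]
        s = sm.species_size_series(one, "small1", scope="station", scope_id="A")
        assert s.data["value"].tolist() == [10.0]

    def test_region_scope_unweighted_station_mean(self):
        obs = _obs([
            ("A", "Z1", "2000-01", "s1", "diatom", 1.0, 100.0),
            ("B", "Z2", "2000-01", "s1", "diatom", 99.0, 300.0),
        ])
        s = sm.species_size_series(obs, "s1", scope="region")
        assert s.data["value"].tolist() == [200.0]

    def test_unknown_species_errors(self, simple_obs):
        with pytest.raises(ValueError, match="no observations"):
            sm.species_size_series(simple_obs, "ghost")

    def test_absent_months_are_missing_not_zero(self, simple_obs):
        partial = simple_obs[
            ~((simple_obs["species_id"] == "mid1") & (simple_obs["date"] == pd.Period("2000-02", "M")))
        ]
        s = sm.species_size_series(partial, "mid1")
        assert s.data["lagged_month"].tolist() == [0]
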