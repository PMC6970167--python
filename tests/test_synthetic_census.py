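"""Generator contracts: household composition, death draws, censoring, I/O."""

import numpy as np
import pandas as pd
import pytest

import censusmort as cm
from censusmort.errors import ConfigurationError

from conftest import make_deaths, make_persons


def single_stratum_config(
    n_households,
    race_mix,
    homogeneity,
    rate=0.0,
    seed=0,
    size_probs=(0.0, 1.0),
    **kwargs,
):
    """One male/rural/North stratum with a flat true schedule for every race."""
    schedules = {
        ("male", "rural", "North", race): np.full(20, rate) for race in cm.RACES
    }
    return cm.SimulationConfig(
        strata=[
            cm.StratumSpec(
                sex="male",
                residence="rural",
                region="North",
                race_mix=race_mix,
                n_households=n_households,
            )
        ],
        household_size_probs=size_probs,
        homogeneity=homogeneity,
        true_schedules=schedules,
        seed=seed,
        **kwargs,
    )


class TestGeneratePopulation:
    def test_full_homogeneity_gives_race_uniform_households(self):
        config = single_stratum_config(
            200, {"indigenous": 0.5, "white": 0.5}, homogeneity=1.0,
            size_probs=(0, 0, 0, 1.0),
        )
        persons = cm.generate_population(config)
        races_per_hh = persons.groupby("household_id")["race"].nunique()
        assert (races_per_hh == 1).all()
        assert (persons.groupby("household_id").size() == 4).all()

    def test_exactly_one_head_per_household_and_head_age_range(self):
        config = single_stratum_config(
            300, {"brown": 1.0}, homogeneity=0.5, size_probs=(0.3, 0.4, 0.3)
        )
        persons = cm.generate_population(config)
        heads = persons[persons["is_head"]]
        assert (heads.groupby("household_id").size() == 1).all()
        assert heads["age"].between(20, 80).all()
        assert persons[~persons["is_head"]]["age"].between(0, 19).all()

    def test_zero_households_gives_empty_table(self):
        config = single_stratum_config(0, {"white": 1.0}, homogeneity=1.0)
        persons = cm.generate_population(config)
        assert persons.empty
        assert list(persons.columns) == list(cm.schema.PERSON_COLUMNS)

    def test_member_race_share_matches_closed_form(self):
        # homogeneity h with mix p: P(member Indigenous | head Indigenous)
        # = h + (1-h) p = 0.5 + 0.5*0.5 = 0.75
        n = 10_000
        config = single_stratum_config(
            n, {"indigenous": 0.5, "white": 0.5}, homogeneity=0.5, seed=11
        )
        persons = cm.generate_population(config)
        heads = persons[persons["is_head"]].set_index("household_id")["race"]
        members = persons[~persons["is_head"]]
        members = members[heads.reindex(members["household_id"]).to_numpy() == "indigenous"]
        share = (members["race"] == "indigenous").mean()
        sd = np.sqrt(0.75 * 0.25 / len(members))
        assert abs(share - 0.75) < 3 * sd

    def test_invalid_race_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.generate_population(
                single_stratum_config(10, {"white": 0.6, "black": 0.6}, 1.0)
            )

    def test_age_sampler_hook(self):
        config = single_stratum_config(
            50,
            {"white": 1.0},
            homogeneity=1.0,
            age_sampler=lambda rng, n: np.full(n, 7),
        )
        persons = cm.generate_population(config)
        assert (persons.loc[~persons["is_head"], "age"] == 7).all()


class TestGenerateDeaths:
    def test_zero_rates_give_zero_deaths(self):
        config = single_stratum_config(500, {"brown": 1.0}, 1.0, rate=0.0)
        persons = cm.generate_population(config)
        deaths = cm.generate_deaths(persons, config)
        assert deaths.empty

    def test_death_count_matches_binomial_expectation(self):
        # 100k persons at one age, m = 0.02: mean n(1-e^-m) ~ 1980
        config = single_stratum_config(
            100_000,
            {"brown": 1.0},
            1.0,
            rate=0.02,
            seed=3,
            age_sampler=lambda rng, n: np.full(n, 10),
        )
        persons = cm.generate_population(config)
        deaths = cm.generate_deaths(persons, config)
        n = (~persons["is_head"]).sum()
        p = 1 - np.exp(-0.02)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(deaths) - n * p) < 3 * sd

    def test_deaths_have_no_race_and_persons_retained(self):
        config = single_stratum_config(2000, {"indigenous": 1.0}, 1.0, rate=0.1, seed=5)
        persons = cm.generate_population(config)
        deaths = cm.generate_deaths(persons, config)
        assert list(deaths.columns) == ["household_id", "age_at_death", "sex"]
        assert len(deaths) > 0
        # census enumerates the household after the death: persons unchanged
        assert len(persons) == len(cm.generate_population(config))

    def test_missing_schedule_raises(self):
        config = single_stratum_config(100, {"white": 1.0}, 1.0, rate=0.01)
        object.__setattr__(config, "true_schedules", {})
        persons = make_persons([(0, True, 30, "male", "white", "rural", "North"),
                                (0, False, 2, "male", "white", "rural", "North")])
        with pytest.raises(ConfigurationError, match="schedule"):
            cm.generate_deaths(persons, config)

    def test_same_seed_identical_output(self):
        config = single_stratum_config(3000, {"brown": 0.7, "black": 0.3}, 0.8,
                                       rate=0.05, seed=9)
        p1, d1 = cm.simulate(config)
        p2, d2 = cm.simulate(config)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_expected_counts_over_seeds(self):
        # aggregate death counts across seeds track sum of 1-exp(-m)
        total, expected, var = 0, 0.0, 0.0
        for seed in range(20):
            config = single_stratum_config(
                500, {"brown": 1.0}, 1.0, rate=0.03, seed=seed
            )
            persons = cm.generate_population(config)
            deaths = cm.generate_deaths(persons, config)
            n = int((persons["age"] < 20).sum())
            p = 1 - np.exp(-0.03)
            total += len(deaths)
            expected += n * p
            var += n * p * (1 - p)
        assert abs(total - expected) < 4 * np.sqrt(var)


class TestCensoring:
    def test_death_in_single_person_household_erased(self):
        persons = make_persons(
            [
                (0, True, 70, "male", "white", "urban", "North"),
                (1, True, 30, "male", "white", "urban", "North"),
                (1, False, 4, "male", "white", "urban", "North"),
                (1, False, 8, "male", "white", "urban", "North"),
            ]
        )
        deaths = make_deaths([(0, 70, "male"), (1, 4, "male")])
        p_out, d_out = cm.apply_single_person_censoring(persons, deaths)
        assert 0 not in set(p_out["household_id"])
        assert set(d_out["household_id"]) == {1}
        # the size-3 household and its death are untouched
        assert len(p_out[p_out["household_id"] == 1]) == 3

    def test_no_single_person_households_is_identity(self, toy_microdata):
        persons, deaths = toy_microdata
        p_out, d_out = cm.apply_single_person_censoring(persons, deaths)
        pd.testing.assert_frame_equal(p_out, persons)
        pd.testing.assert_frame_equal(d_out, deaths)

    @pytest.mark.parametrize("seed", range(5))
    def test_censoring_never_increases_deaths(self, seed):
        config = single_stratum_config(
            800, {"brown": 1.0}, 1.0, rate=0.05, seed=seed,
            size_probs=(0.4, 0.3, 0.3),
        )
        persons = cm.generate_population(config)
        deaths = cm.generate_deaths(persons, config)
        p_out, d_out = cm.apply_single_person_censoring(persons, deaths)
        assert len(d_out) <= len(deaths)
        sizes = persons.groupby("household_id").size()
        multi = set(sizes[sizes >= 2].index)
        kept = deaths[deaths["household_id"].isin(multi)]
        pd.testing.assert_frame_equal(
            d_out[d_out["household_id"].isin(multi)].reset_index(drop=True),
            kept.reset_index(drop=True),
        )


class TestMicrodataIO:
    def test_round_trip_is_lossless(self, tmp_path):
        config = single_stratum_config(200, {"white": 0.5, "brown": 0.5}, 0.7,
                                       rate=0.05, seed=2)
        persons, deaths = cm.simulate(config)
        cm.write_microdata(persons, deaths, tmp_path / "run")
        p2, d2 = cm.read_microdata(tmp_path / "run")
        pd.testing.assert_frame_equal(persons.reset_index(drop=True), p2)
        pd.testing.assert_frame_equal(deaths.reset_index(drop=True), d2)

    def test_deaths_file_has_no_race_column(self, tmp_path, toy_microdata):
        persons, deaths = toy_microdata
        _, deaths_path = cm.write_microdata(persons, deaths, tmp_path / "t")
        header = deaths_path.read_text().splitlines()[0]
        assert header == "household_id,age_at_death,sex"

    def test_empty_deaths_written_as_header_only(self, tmp_path, toy_microdata):
        persons, _ = toy_microdata
        _, deaths_path = cm.write_microdata(persons, make_deaths([]), tmp_path / "e")
        lines = deaths_path.read_text().splitlines()
        assert lines == ["household_id,age_at_death,sex"]
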