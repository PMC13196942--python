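import numpy as np
import pytest
from scipy import stats

from dinnersim import (
    MealSelection,
    ProteinSource,
    SimConfig,
    choose_meal,
    confer_status,
    evaluate_meal,
    form_party,
    init_state,
    select_cook,
    update_preferences,
)
from dinnersim.dinner import step_day

from conftest import make_small_config


class TestSelectCook:
    def test_single_present_member_is_the_cook(self):
        committed = np.zeros(3, dtype=bool)
        assert select_cook([2], committed, np.random.default_rng(0)) == 2

    def test_no_present_member_means_no_dinner(self):
        committed = np.ones(3, dtype=bool)
        assert select_cook([0, 1, 2], committed, np.random.default_rng(0)) is None

    def test_selection_is_uniform_among_present_members(self):
        committed = np.zeros(3, dtype=bool)
        rng = np.random.default_rng(42)
        picks = np.array([select_cook([0, 1, 2], committed, rng) for _ in range(3000)])
        freqs = np.bincount(picks, minlength=3) / 3000
        assert np.abs(freqs - 1 / 3).max() < 0.04


class TestFormParty:
    def _net(self, friends_of_0):
        fr_ptr = np.array([0, len(friends_of_0), len(friends_of_0)], dtype=np.int64)
        return fr_ptr, np.asarray(friends_of_0, dtype=np.int64)

    def test_zero_invite_probability_keeps_dinner_in_the_family(self):
        fr_ptr, fr_idx = self._net([1])
        committed = np.zeros(2, dtype=bool)
        guests = form_party(0, [0], committed, fr_ptr, fr_idx, 0.0, np.random.default_rng(0))
        assert guests == [0]

    def test_certain_invitation_brings_the_uncommitted_friend(self):
        fr_ptr, fr_idx = self._net([1])
        committed = np.zeros(2, dtype=bool)
        guests = form_party(0, [0], committed, fr_ptr, fr_idx, 1.0, np.random.default_rng(0))
        assert guests == [0, 1]

    def test_a_friend_already_dining_elsewhere_declines(self):
        fr_ptr, fr_idx = self._net([1])
        committed = np.array([False, True])
        guests = form_party(0, [0], committed, fr_ptr, fr_idx, 1.0, np.random.default_rng(0))
        assert guests == [0]


class TestChooseMeal:
    def test_status_rule_follows_the_highest_status_guest(self):
        identity = np.array([ProteinSource.MEAT, ProteinSource.VEGAN])
        status = np.array([0.9, 0.2])
        meal = choose_meal([0, 1], identity, status, MealSelection.STATUS, np.random.default_rng(0))
        assert meal == ProteinSource.MEAT

    def test_majority_rule_picks_the_strict_mode(self):
        identity = np.array([ProteinSource.VEGAN, ProteinSource.VEGAN, ProteinSource.MEAT])
        status = np.zeros(3)
        meal = choose_meal([0, 1, 2], identity, status, MealSelection.MAJORITY, np.random.default_rng(0))
        assert meal == ProteinSource.VEGAN

    def test_majority_tie_is_a_coin_flip(self):
        identity = np.array([ProteinSource.MEAT, ProteinSource.VEGAN])
        status = np.zeros(2)
        rng = np.random.default_rng(1)
        picks = [
            choose_meal([0, 1], identity, status, MealSelection.MAJORITY, rng)
            for _ in range(2000)
        ]
        frac_meat = np.mean([p == ProteinSource.MEAT for p in picks])
        assert abs(frac_meat - 0.5) < 0.04
        assert set(picks) == {ProteinSource.MEAT, ProteinSource.VEGAN}

    def test_random_rule_is_uniform_over_the_four_sources(self):
        identity = np.array([ProteinSource.MEAT])
        rng = np.random.default_rng(2)
        picks = np.array(
            [choose_meal([0], identity, np.zeros(1), MealSelection.RANDOM, rng) for _ in range(4000)]
        )
        freqs = np.bincount(picks, minlength=4) / 4000
        assert np.abs(freqs - 0.25).max() < 0.03

    def test_unknown_strategy_is_an_error(self):
        with pytest.raises(ValueError):
            choose_meal([0], np.zeros(1, int), np.zeros(1), 99, np.random.default_rng(0))


class TestEvaluateMeal:
    def test_median_cook_serves_a_preferred_meal_enjoyed_half_the_time(self):
        rng = np.random.default_rng(3)
        hits = sum(
            evaluate_meal(0, 0.7, 0, cook_skill=0.5, meal_variety=0.3, rng=rng)
            for _ in range(40000)
        )
        assert hits / 40000 == pytest.approx(0.5, abs=0.01)

    def test_total_neophobia_blocks_any_non_preferred_meal(self):
        rng = np.random.default_rng(4)
        assert not any(
            evaluate_meal(0, 1.0, 3, cook_skill=1.0, meal_variety=0.3, rng=rng)
            for _ in range(2000)
        )

    def test_enjoyment_rises_as_an_s_curve_in_cooking_skill(self):
        rng = np.random.default_rng(5)
        skills = np.linspace(0, 1, 6)
        rates = []
        for s in skills:
            rates.append(
                np.mean(
                    [evaluate_meal(0, 0.0, 0, s, 0.3, rng) for _ in range(20000)]
                )
            )
        rates = np.array(rates)
        assert (np.diff(rates) > 0).all()
        # steepest in the middle, flattening toward both ends
        increments = np.diff(rates)
        assert increments.argmax() in (1, 2, 3)
        assert rates[0] == pytest.approx(stats.norm.cdf(-0.5 / 0.3), abs=0.01)
        assert rates[-1] == pytest.approx(stats.norm.cdf(0.5 / 0.3), abs=0.01)

    def test_population_average_enjoyment_is_insensitive_to_meal_variety(self):
        rng = np.random.default_rng(6)
        means = {}
        for variety in (0.1, 0.5):
            skills = rng.uniform(0, 1, 30000)
            means[variety] = np.mean(
                [evaluate_meal(0, 0.0, 0, s, variety, rng) for s in skills]
            )
        assert abs(means[0.1] - means[0.5]) < 0.02


class TestUpdatePreferences:
    def test_enjoyed_meal_shifts_one_increment_toward_the_served_source(self):
        prefs = np.array([0.7, 0.1, 0.1, 0.1])
        identity = update_preferences(prefs, 0, 0, enjoyed=True)
        assert identity == 0
        assert prefs[0] == pytest.approx(0.71)
        assert prefs[1:] == pytest.approx(0.1 - 0.01 / 3)

    def test_saturated_preference_stays_clipped_at_one(self):
        prefs = np.array([1.0, 0.0, 0.0, 0.0])
        update_preferences(prefs, 0, 0, enjoyed=True)
        assert prefs[0] == 1.0 and (prefs[1:] == 0.0).all()

    def test_disliked_meal_leaves_preferences_unchanged(self):
        prefs = np.array([0.7, 0.1, 0.1, 0.1])
        identity = update_preferences(prefs, 0, 3, enjoyed=False)
        assert identity == 0
        assert np.array_equal(prefs, [0.7, 0.1, 0.1, 0.1])

    def test_identity_flip_point_matches_the_iterated_rule(self):
        """Brute-force oracle: iterate the arithmetic rule independently."""
        # oracle: after k enjoyed vegan meals, vegan = .1+.01k, meat = .7-k*.01/3
        flip_oracle = next(
            k for k in range(1, 200) if 0.1 + 0.01 * k > 0.7 - k * 0.01 / 3 + 1e-12
        )
        prefs = np.array([0.7, 0.1, 0.1, 0.1])
        identity = 0
        flipped_at = None
        for k in range(1, 60):
            identity = update_preferences(prefs, identity, 3, enjoyed=True)
            if identity == 3 and flipped_at is None:
                flipped_at = k
        assert flipped_at is not None
        assert abs(flipped_at - flip_oracle) <= 1  # float ties at the crossing


class TestConferStatus:
    def test_nobody_enjoyed_means_no_status_moves(self):
        status = np.array([0.5, 0.5])
        confer_status(status, 0, [0, 1], {0: False, 1: False})
        assert np.array_equal(status, [0.5, 0.5])

    def test_single_enjoying_guest_transfers_one_delta(self):
        status = np.array([0.5, 0.5])
        confer_status(status, 0, [0, 1], {0: True, 1: True})
        assert status[1] == pytest.approx(0.495)
        assert status[0] == pytest.approx(0.505)

    def test_transfers_are_truncated_at_the_bounds_and_conserve_total(self):
        status = np.array([0.999, 0.002])
        confer_status(status, 0, [0, 1], {1: True})
        assert status[0] == pytest.approx(1.0)
        assert status[1] == pytest.approx(0.001)
        status2 = np.array([0.5, 0.001])
        confer_status(status2, 0, [0, 1], {1: True})
        assert status2[1] == 0.0
        assert status2.sum() == pytest.approx(0.501)


class TestStepDay:
    def test_everyone_dines_at_most_once_per_day(self):
        cfg = make_small_config(friend_invite_prob=0.5)
        state = init_state(cfg)
        rng = np.random.default_rng(cfg.seed)
        for day in range(10):
            events = step_day(state, day, rng)
            guests = [g for ev in events for g in ev.guests]
            assert len(guests) == len(set(guests))
            for ev in events:
                assert ev.cook in ev.guests

    def test_event_ledger_matches_households_when_no_one_dines_out(self):
        cfg = make_small_config(n_households=10, friend_invite_prob=0.0)
        state = init_state(cfg)
        rng = np.random.default_rng(1)
        total = sum(len(step_day(state, day, rng)) for day in range(30))
        assert total == 10 * 30

    def test_status_rule_with_frozen_preferences_follows_top_status_identities(self):
        """With no drift and no guests from outside, each household's meal is
        exactly its top-status member's identity, every night."""
        cfg = make_small_config(
            n_households=5,
            friend_invite_prob=0.0,
            preference_increment=0.0,
            supply_mode="INFINITE",
            meal_selection="STATUS",
        )
        state = init_state(cfg)
        expected = {}
        for h in range(state.n_households):
            members = state.members_of(h)
            top = members[np.argmax(state.pop.status[members])]
            expected[h] = state.pop.identity[top]
        rng = np.random.default_rng(2)
        for day in range(50):
            for ev in step_day(state, day, rng):
                assert ev.chosen == expected[ev.household]
                assert ev.obtained == ev.chosen
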