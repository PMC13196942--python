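import numpy as np
import pytest

from dinnersim import (
    InterventionSpec,
    ProteinSource,
    SimConfig,
    SupplyMode,
    init_state,
    run,
    update_preferences,
)
from dinnersim.interventions import (
    end_dietary_change,
    end_inventory_change,
    start_dietary_change,
    start_inventory_change,
)

from conftest import make_small_config


def _dietary(p=0.5, status="random", diet="vegan", duration=10, start_day=5):
    return InterventionSpec(
        kind="dietary_change",
        status_filter=status,
        target_diet=diet,
        fraction_p=p,
        duration=duration,
        start_day=start_day,
    )


class TestDietaryChange:
    def test_zero_fraction_locks_no_one(self):
        state = init_state(make_small_config())
        start_dietary_change(state, _dietary(p=0.0), np.random.default_rng(0))
        assert not state.locked.any()

    def test_full_random_fraction_converts_everyone(self):
        state = init_state(make_small_config())
        start_dietary_change(state, _dietary(p=1.0), np.random.default_rng(0))
        assert (state.pop.identity == ProteinSource.VEGAN).all()
        assert state.locked.all()
        assert (state.pop.prefs[:, ProteinSource.VEGAN] == 0.7).all()

    def test_high_status_filter_selects_only_high_status_persons(self):
        for seed in range(10):
            state = init_state(SimConfig(seed=seed))
            start_dietary_change(state, _dietary(p=0.8, status="high"), np.random.default_rng(seed))
            assert (state.pop.status[state.locked] > 0.75).all()

    def test_empty_eligible_set_warns_and_is_a_no_op(self):
        state = init_state(make_small_config())
        state.pop.status[:] = 0.5  # nobody above the high threshold
        with pytest.warns(UserWarning, match="empty"):
            start_dietary_change(state, _dietary(status="high"), np.random.default_rng(0))
        assert not state.locked.any()

    def test_locked_preferences_do_not_drift_until_release(self):
        cfg = make_small_config(
            intervention=_dietary(p=1.0, duration=10, start_day=5), years=1, days_per_year=30
        )
        res = run(cfg, engine="python")
        # by day 15 the lock is released; during days 5..14 the vector must
        # have stayed at the one-hot-ish intervention profile
        state = res.state
        assert not state.locked.any()
        # after release the drift resumes: one enjoyed vegan dinner moves 0.70 -> 0.71
        prefs = np.array([0.1, 0.1, 0.1, 0.7])
        ident = update_preferences(prefs, 3, 3, enjoyed=True)
        assert ident == 3 and prefs[3] == pytest.approx(0.71)

    def test_identity_equals_target_throughout_the_active_window(self):
        cfg = make_small_config(
            intervention=_dietary(p=1.0, duration=10, start_day=5), years=1, days_per_year=30
        )
        from dinnersim.dinner import step_day
        from dinnersim.interventions import apply_intervention_hooks

        state = init_state(cfg)
        rng = np.random.default_rng(0)
        snapshots = {}
        for day in range(30):
            apply_intervention_hooks(state, day, rng)
            if 5 <= day < 15:
                assert (state.pop.identity == ProteinSource.VEGAN).all()
                snapshots[day] = state.pop.prefs.copy()
            step_day(state, day, rng)
        assert all(np.array_equal(snapshots[5], s) for s in snapshots.values())


class TestInventoryChange:
    def test_fifty_fifty_rewrite_is_exact_and_conserves_units(self):
        state = init_state(make_small_config())
        before = state.stores.init_inv.sum(axis=1).copy()
        start_inventory_change(state, InterventionSpec(kind="inventory_change", plant_fraction=0.5, duration=10, start_day=0))
        after = state.stores.init_inv
        assert np.array_equal(after.sum(axis=1), before)
        for s in range(state.n_stores):
            assert after[s, ProteinSource.VEGAN] == round(before[s] * 0.5)
        assert state.supply_mode == SupplyMode.STATIC
        assert np.array_equal(state.stores.inv, after)

    def test_ninety_percent_plant_splits_the_animal_rest_pro_rata(self):
        state = init_state(make_small_config())
        orig = state.stores.init_inv.copy()
        start_inventory_change(state, InterventionSpec(kind="inventory_change", plant_fraction=0.9, duration=10, start_day=0))
        new = state.stores.init_inv
        for s in range(state.n_stores):
            animal_total = new[s, :3].sum()
            expect = animal_total * orig[s, :3] / orig[s, :3].sum()
            assert np.abs(new[s, :3] - expect).max() <= 1  # largest-remainder rounding
            assert new[s, ProteinSource.VEGAN] == round(orig[s].sum() * 0.9)

    def test_release_restores_the_range_and_responsive_supply(self):
        state = init_state(make_small_config())
        orig = state.stores.init_inv.copy()
        spec = InterventionSpec(kind="inventory_change", plant_fraction=0.7, duration=10, start_day=0)
        start_inventory_change(state, spec)
        state.stores.wk_sales[:] = 3.14  # demand learned during the window
        end_inventory_change(state, spec)
        assert state.supply_mode == SupplyMode.DYNAMIC
        assert np.array_equal(state.stores.init_inv, orig)
        assert (state.stores.wk_sales == 3.14).all()  # ledgers retained

    def test_one_day_intervention_starts_and_ends_without_error(self):
        spec = InterventionSpec(kind="inventory_change", plant_fraction=0.6, duration=1, start_day=3)
        cfg = make_small_config(intervention=spec, years=1, days_per_year=10)
        res = run(cfg)
        assert res.state.supply_mode == SupplyMode.DYNAMIC

    def test_static_semantics_hold_during_the_window(self):
        spec = InterventionSpec(kind="inventory_change", plant_fraction=0.6, duration=20, start_day=2)
        cfg = make_small_config(intervention=spec, years=1, days_per_year=30, seed=3)
        res = run(cfg, engine="python")
        rec = res.record
        # inventory totals snap back to the rewritten range after each restock;
        # during the window total vegan stock never falls below 50% of range
        assert rec.inventory[10, ProteinSource.VEGAN] > rec.inventory[1, ProteinSource.VEGAN]


def test_longer_interventions_cook_more_plant_meals():
    """Cumulative plant meals are nondecreasing in intervention duration."""
    medians = []
    for duration in (30, 360, 1825):
        spec = InterventionSpec(kind="dietary_change", status_filter="random",
                                target_diet="vegan", fraction_p=0.4,
                                duration=duration, start_day=730)
        totals = []
        for r in range(5):
            cfg = SimConfig(intervention=spec, seed=1000 + r)
            totals.append(run(cfg).record.meals[:, ProteinSource.VEGAN].sum())
        medians.append(np.median(totals))
    assert medians[0] <= medians[1] <= medians[2]
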