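"""Shared fixtures.

The heavy replicated experiments (baseline protocol, supply-mode sweep,
intervention experiments, OFAT signatures) are session-scoped so the
qualitative and quantitative checks that share them run them only once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dinnersim import InterventionSpec, SimConfig
from dinnersim.experiments import run_many, run_ofat


def make_small_config(**kw) -> SimConfig:
    """A fast toy neighbourhood used by unit and parity tests."""
    defaults = dict(
        n_households=15,
        n_supermarkets=3,
        grid_size=20,
        service_radius=20.0,
        years=1,
        days_per_year=40,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def baseline_runs():
    """20 replicate default runs (status selection, dynamic supply, 3650 days)."""
    return run_many(SimConfig(), 20, base_seed=100)


@pytest.fixture(scope="session")
def supply_mode_runs():
    """20 replicates per supply regime, status-based selection."""
    return {
        mode: run_many(SimConfig(supply_mode=mode), 20, base_seed=400)
        for mode in ("INFINITE", "STATIC", "DYNAMIC")
    }


@pytest.fixture(scope="session")
def plant_supply_intervention_runs():
    """10 replicates: product range forced to 90% plant for 360 days from day 730."""
    spec = InterventionSpec(
        kind="inventory_change", plant_fraction=0.9, duration=360, start_day=730
    )
    return run_many(SimConfig(intervention=spec), 10, base_seed=300)


@pytest.fixture(scope="session")
def short_intervention_runs():
    """10 replicates each of the two 30-day interventions (relapse check)."""
    dietary = InterventionSpec(
        kind="dietary_change",
        status_filter="random",
        target_diet="vegan",
        fraction_p=0.4,
        duration=30,
        start_day=730,
    )
    inventory = InterventionSpec(
        kind="inventory_change", plant_fraction=0.9, duration=30, start_day=730
    )
    return {
        "dietary": run_many(SimConfig(intervention=dietary), 10, base_seed=900),
        "inventory": run_many(SimConfig(intervention=inventory), 10, base_seed=900),
    }


@pytest.fixture(scope="session")
def ofat_signature_frame():
    """OFAT sweep of the four signature factors, 10 replicates per level."""
    from dinnersim.experiments import DEFAULT_OFAT_GRID

    factors = {
        k: DEFAULT_OFAT_GRID[k]
        for k in ("neophobia", "vegan_status", "cooking_skill", "meal_variety")
    }
    return run_ofat(SimConfig(), factors=factors, replicates=10, base_seed=20)
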