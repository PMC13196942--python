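"""Policy interventions: dietary change and inventory change.

A dietary-change intervention samples a fraction of a status stratum (low,
high, or the whole population) and locks those persons onto a target diet:
identity and preference vector are overwritten and preference drift is
suspended until release, after which drift resumes from wherever the
preferences then stand.  Locked persons still dine, enjoy and confer status.

An inventory-change intervention rewrites every supermarket's product range
to a prescribed plant share (total units preserved; the animal remainder
keeps its current proportions) and freezes supply in STATIC mode so the
range stays fixed for the window.  At release, supply returns to DYNAMIC
with the sales averages accumulated during the window intact, and the
original product range is restored as the static reference.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import (
    N_SOURCES,
    InterventionKind,
    InterventionSpec,
    ProteinSource,
    StatusFilter,
    SupplyMode,
)
from .population import IDENTITY_PREF, OTHER_PREF, SimState, _apportion

__all__ = [
    "start_dietary_change",
    "end_dietary_change",
    "start_inventory_change",
    "end_inventory_change",
    "apply_intervention_hooks",
]


def start_dietary_change(
    state: SimState, spec: InterventionSpec, rng: np.random.Generator
) -> None:
    """Lock a sampled fraction of the eligible stratum onto the target diet."""
    cfg = state.cfg
    status = state.pop.status
    if spec.status_filter == StatusFilter.LOW:
        eligible = np.flatnonzero(status < cfg.status_low_threshold)
    elif spec.status_filter == StatusFilter.HIGH:
        eligible = np.flatnonzero(status > cfg.status_high_threshold)
    else:
        eligible = np.arange(state.n_persons)
    if len(eligible) == 0:
        warnings.warn("dietary-change intervention: eligible set is empty; no-op")
        state.participants = np.zeros(0, dtype=np.int64)
        return
    k = int(np.floor(spec.fraction_p * len(eligible)))
    chosen = rng.choice(eligible, size=k, replace=False).astype(np.int64)
    target = int(spec.target_diet)
    state.pop.identity[chosen] = target
    state.pop.prefs[chosen] = OTHER_PREF
    state.pop.prefs[chosen, target] = IDENTITY_PREF
    state.locked[chosen] = True
    state.participants = chosen


def end_dietary_change(state: SimState, spec: InterventionSpec) -> None:
    """Release participants; preferences resume drifting from their current values."""
    if state.participants is not None and len(state.participants):
        state.locked[state.participants] = False
    state.participants = None


def start_inventory_change(state: SimState, spec: InterventionSpec) -> None:
    """Rewrite every store's product range to the target plant share, freeze supply."""
    st = state.stores
    state.saved_init_inv = st.init_inv.copy()
    for s in range(state.n_stores):
        total = int(st.init_inv[s].sum())
        vegan = int(round(total * spec.plant_fraction))
        animal = _apportion(total - vegan, st.init_inv[s, : N_SOURCES - 1].astype(np.float64))
        new_range = np.concatenate([animal, [vegan]]).astype(np.int64)
        # the rewrite itself is a stocking action, kept on the ledger
        st.restocked[s] += new_range - st.inv[s]
        st.init_inv[s] = new_range
        st.inv[s] = new_range
    state.supply_mode = int(SupplyMode.STATIC)


def end_inventory_change(state: SimState, spec: InterventionSpec) -> None:
    """Return to responsive supply; restore the pre-intervention product range."""
    state.supply_mode = int(SupplyMode.DYNAMIC)
    if state.saved_init_inv is not None:
        state.stores.init_inv[:] = state.saved_init_inv
        state.saved_init_inv = None


def apply_intervention_hooks(
    state: SimState, day: int, rng: np.random.Generator
) -> None:
    """Fire the start/end mutation for ``day`` if the config schedules one."""
    spec = state.cfg.intervention
    if spec is None:
        return
    if day == spec.start_day:
        if spec.kind == InterventionKind.DIETARY_CHANGE:
            start_dietary_change(state, spec, rng)
        else:
            start_inventory_change(state, spec)
    if day == spec.end_day:
        if spec.kind == InterventionKind.DIETARY_CHANGE:
            end_dietary_change(state, spec)
        else:
            end_inventory_change(state, spec)
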