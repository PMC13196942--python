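"""Shopping, stock-out substitution and inventory replenishment.

The cook visits supermarkets nearest-first (up to ``max_supermarket_visits``).
A stock-out is logged as an unmet request; with probability ``1 - neophobia``
the cook then accepts the in-stock substitute they like best, otherwise they
travel on.  If every visit fails, dinner still happens: the cook takes the
best-stocked source at the last store, decrementing stock no further than
zero (availability never cancels a meal).

Supermarkets track sales per weekday as an exponential moving average with a
memory of roughly four same-weekdays (alpha = 0.25).  Restocks fire every
``replenishment_cycle`` days, phase-offset per store.  STATIC supply resets
the initial product range; DYNAMIC supply is order-up-to: the coming cycle's
expected weekday sales times ``1 + safety_margin`` plus unmet requests (the
vegan target scaled by the store's business orientation, a [0, 2] inclination
mapped linearly onto a 0.5-1.5x multiplier), floored at the store's initial
assortment — a responsive retailer overstocks what sells but keeps carrying
its range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import N_SOURCES, ProteinSource, SupplyMode
from .population import SimState

__all__ = ["PurchaseOutcome", "obtain_groceries", "record_sale", "restock", "end_of_day"]

#: EMA weight of the latest same-weekday observation (memory ~4 weeks)
SALES_EMA_ALPHA = 0.25
#: DYNAMIC restock never drops a source below this many units
MIN_STOCK = 1


@dataclass(frozen=True)
class PurchaseOutcome:
    obtained: int                  # ProteinSource actually bought
    supermarket_id: int | None
    visits_made: int
    substituted: bool              # bought something other than the chosen source
    fallback: bool                 # exhausted all visits; forced best-stocked buy
    units: int                     # units actually decremented (ledger basis)


def record_sale(state: SimState, store: int, source: int, qty: int) -> None:
    """Decrement inventory and accumulate the day's sales ledger."""
    st = state.stores
    st.inv[store, source] -= qty
    st.today_sales[store, source] += qty
    st.sold_total[store, source] += qty


def obtain_groceries(
    state: SimState,
    household: int,
    cook: int,
    chosen: int,
    qty: int,
    rng: np.random.Generator,
) -> PurchaseOutcome:
    """Buy ``qty`` units for tonight's party; always yields some source."""
    st = state.stores
    order = state.store_order[household]
    if state.supply_mode == SupplyMode.INFINITE:
        s = int(order[0])
        st.today_sales[s, chosen] += qty
        st.sold_total[s, chosen] += qty
        return PurchaseOutcome(chosen, s, 1, False, False, qty)

    visits = min(state.cfg.max_supermarket_visits, state.n_stores)
    last = -1
    for v in range(visits):
        s = int(order[v])
        last = s
        if st.inv[s, chosen] >= qty:
            record_sale(state, s, chosen, qty)
            return PurchaseOutcome(int(chosen), s, v + 1, False, False, qty)
        st.unmet[s, chosen] += qty
        u = rng.random()
        if u < 1.0 - state.pop.neophobia[cook]:
            sub = _best_substitute(state, s, cook, chosen, qty, rng)
            if sub >= 0:
                record_sale(state, s, sub, qty)
                return PurchaseOutcome(sub, s, v + 1, True, False, qty)
    # all visits failed: best-stocked source at the last store, floored at zero
    src = int(np.argmax(st.inv[last]))
    units = int(min(st.inv[last, src], qty))
    st.inv[last, src] -= units
    st.today_sales[last, src] += units
    st.sold_total[last, src] += units
    return PurchaseOutcome(src, last, visits, src != chosen, True, units)


def _best_substitute(
    state: SimState, store: int, cook: int, chosen: int, qty: int, rng: np.random.Generator
) -> int:
    """In-stock source (excluding ``chosen``) the cook prefers most.

    Exact preference ties are broken uniformly at random; returns -1 when
    nothing else is sufficiently stocked.
    """
    prefs = state.pop.prefs[cook]
    inv = state.stores.inv[store]
    best = -1.0
    tied: list[int] = []
    for src in range(N_SOURCES):
        if src == chosen or inv[src] < qty:
            continue
        if prefs[src] > best:
            best = prefs[src]
            tied = [src]
        elif prefs[src] == best:
            tied.append(src)
    if not tied:
        return -1
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(0, len(tied)))]


def restock(state: SimState, store: int, day: int) -> None:
    """Replenish one store according to the active supply mode."""
    st = state.stores
    cfg = state.cfg
    if state.supply_mode == SupplyMode.INFINITE:
        raise ValueError("restock is undefined under INFINITE supply")
    if state.supply_mode == SupplyMode.STATIC:
        for src in range(N_SOURCES):
            st.restocked[store, src] += st.init_inv[store, src] - st.inv[store, src]
            st.inv[store, src] = st.init_inv[store, src]
    else:  # DYNAMIC
        for src in range(N_SOURCES):
            expected = 0.0
            for d in range(1, cfg.replenishment_cycle + 1):
                expected += st.wk_sales[store, (day + d) % 7, src]
            target = (1.0 + cfg.safety_margin) * expected + st.unmet[store, src]
            if src == ProteinSource.VEGAN:
                target *= st.borient[store] / 2.0 + 0.5
            # order-up-to: demand-responsive, never below the assortment base
            new_inv = max(int(math.ceil(target)), int(st.init_inv[store, src]), MIN_STOCK)
            st.restocked[store, src] += new_inv - st.inv[store, src]
            st.inv[store, src] = new_inv
    st.unmet[store] = 0


def end_of_day(state: SimState, day: int) -> None:
    """Fold today's sales into the weekday averages, then restock due stores."""
    st = state.stores
    weekday = day % 7
    cycle = state.cfg.replenishment_cycle
    for s in range(state.n_stores):
        for src in range(N_SOURCES):
            st.wk_sales[s, weekday, src] = (
                (1.0 - SALES_EMA_ALPHA) * st.wk_sales[s, weekday, src]
                + SALES_EMA_ALPHA * st.today_sales[s, src]
            )
        if state.supply_mode != SupplyMode.INFINITE and day % cycle == s % cycle:
            restock(state, s, day)
        for src in range(N_SOURCES):
            st.today_sales[s, src] = 0
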