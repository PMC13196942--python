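"""Run loop and daily-output recording.

Two interchangeable engines execute the daily cycle:

* ``engine="python"`` composes the documented operation functions in
  :mod:`dinnersim.dinner` and :mod:`dinnersim.retail` — readable, slow.
* ``engine="numba"`` (default) is a jitted kernel that consumes the same
  ``numpy.random.Generator`` in exactly the same draw order, so both engines
  produce bit-identical trajectories for the same seed (enforced by a test).

Intervention scheduling, initialization and metric post-processing are shared
Python code; only the per-day inner loop is duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import N_SOURCES, ProteinSource, SimConfig, SupplyMode
from .dinner import STATUS_TRANSFER, step_day
from .interventions import apply_intervention_hooks
from .population import SimState, init_state

__all__ = ["RunRecord", "RunResult", "run", "apply_overrides"]

_VEGAN = int(ProteinSource.VEGAN)


@dataclass
class RunRecord:
    """Daily model outputs of one run (arrays indexed by day)."""

    meals: np.ndarray            # int64[T, 4] dinners served, by obtained source
    chosen: np.ndarray           # int64[T, 4] dinners by negotiated source
    sold: np.ndarray             # int64[T, 4] units sold across stores
    inventory: np.ndarray        # int64[T, 4] end-of-day stock across stores
    identity_counts: np.ndarray  # int64[T, 4] persons per dietary identity
    n_events: np.ndarray         # int64[T] dinner parties held
    n_guests: np.ndarray         # int64[T] dinner attendances
    n_enjoyed: np.ndarray        # int64[T] guests who enjoyed dinner
    n_at_friends: np.ndarray     # int64[T] guests dining outside the household
    n_substituted: np.ndarray    # int64[T] parties served a substitute source
    n_fallback: np.ndarray       # int64[T] parties served via the always-eat fallback
    diversity: np.ndarray        # float64[T] mean distinct identities per ego network
    days_per_year: int

    @classmethod
    def empty(cls, T: int, days_per_year: int) -> "RunRecord":
        i = lambda *shape: np.zeros(shape, dtype=np.int64)
        return cls(
            meals=i(T, N_SOURCES),
            chosen=i(T, N_SOURCES),
            sold=i(T, N_SOURCES),
            inventory=i(T, N_SOURCES),
            identity_counts=i(T, N_SOURCES),
            n_events=i(T),
            n_guests=i(T),
            n_enjoyed=i(T),
            n_at_friends=i(T),
            n_substituted=i(T),
            n_fallback=i(T),
            diversity=np.zeros(T, dtype=np.float64),
            days_per_year=days_per_year,
        )

    # -- derived outputs --------------------------------------------------
    @property
    def n_days(self) -> int:
        return len(self.n_events)

    @property
    def n_years(self) -> int:
        return self.n_days // self.days_per_year

    def pct_enjoying(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_guests > 0, self.n_enjoyed / self.n_guests, np.nan)

    def plant_share_over(self, start: int, stop: int) -> float:
        """Vegan share of meals served over days [start, stop)."""
        meals = self.meals[start:stop].sum(axis=0)
        total = meals.sum()
        return float(meals[_VEGAN] / total) if total else float("nan")

    def yearly_plant_share(self) -> np.ndarray:
        d = self.days_per_year
        return np.array(
            [self.plant_share_over(y * d, (y + 1) * d) for y in range(self.n_years)]
        )

    def yearly_meals(self) -> np.ndarray:
        """Meals served per year and source, shape (years, 4)."""
        d = self.days_per_year
        return np.array(
            [self.meals[y * d : (y + 1) * d].sum(axis=0) for y in range(self.n_years)]
        )

    def to_frame(self, run_id: int = 0):
        """Tidy long DataFrame: run_id, day, metric, source, value."""
        import pandas as pd

        T = self.n_days
        days = np.arange(T)
        frames = []
        per_source = {
            "meals": self.meals,
            "chosen": self.chosen,
            "sold": self.sold,
            "inventory": self.inventory,
            "identity_counts": self.identity_counts,
        }
        for metric, arr in per_source.items():
            for src in ProteinSource:
                frames.append(
                    pd.DataFrame(
                        {
                            "run_id": run_id,
                            "day": days,
                            "metric": metric,
                            "source": src.name,
                            "value": arr[:, int(src)],
                        }
                    )
                )
        scalar = {
            "n_events": self.n_events,
            "n_guests": self.n_guests,
            "n_enjoyed": self.n_enjoyed,
            "n_at_friends": self.n_at_friends,
            "n_substituted": self.n_substituted,
            "n_fallback": self.n_fallback,
            "diversity": self.diversity,
        }
        for metric, arr in scalar.items():
            frames.append(
                pd.DataFrame(
                    {"run_id": run_id, "day": days, "metric": metric, "source": "", "value": arr}
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class RunResult:
    record: RunRecord
    state: SimState


def apply_overrides(state: SimState, overrides: dict | None) -> None:
    """Agent-level sensitivity overrides applied right after initialization.

    ``neophobia`` / ``cooking_skill`` fix that trait for the whole population;
    ``vegan_status`` forces the status of every vegan-identity person.
    """
    if not overrides:
        return
    for key, value in overrides.items():
        if key == "neophobia":
            state.pop.neophobia[:] = float(value)
        elif key == "cooking_skill":
            state.pop.cooking[:] = float(value)
        elif key == "vegan_status":
            state.pop.status[state.pop.identity == _VEGAN] = float(value)
        else:
            raise ValueError(f"unknown agent override: {key!r}")


def run(
    config: SimConfig,
    overrides: dict | None = None,
    engine: str = "numba",
    collect_events: bool = False,
) -> RunResult:
    """Execute one seeded run of ``config.total_steps`` days.

    ``collect_events`` (python engine only) attaches the full list of
    :class:`~dinnersim.dinner.DinnerEvent` to the result as ``.events``.
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(config, rng)
    apply_overrides(state, overrides)
    T = config.total_steps
    rec = RunRecord.empty(T, config.days_per_year)

    if engine == "python":
        all_events = [] if collect_events else None
        for day in range(T):
            apply_intervention_hooks(state, day, rng)
            events = step_day(state, day, rng)
            _record_day_python(state, day, events, rec)
            if all_events is not None:
                all_events.extend(events)
        result = RunResult(rec, state)
        if all_events is not None:
            result.events = all_events  # type: ignore[attr-defined]
        return result
    if engine != "numba":
        raise ValueError(f"unknown engine: {engine!r}")
    if collect_events:
        raise ValueError("collect_events requires engine='python'")

    pop, st = state.pop, state.stores
    P, H = state.n_persons, state.n_households
    committed = np.zeros(P, dtype=np.bool_)
    guest_buf = np.zeros(P, dtype=np.int64)
    tied_buf = np.zeros(max(P, N_SOURCES), dtype=np.int64)
    enjoy_buf = np.zeros(P, dtype=np.uint8)
    order_buf = np.zeros(H, dtype=np.int64)
    cnt4 = np.zeros(N_SOURCES, dtype=np.int64)
    for day in range(T):
        apply_intervention_hooks(state, day, rng)
        _step_day_kernel(
            rng,
            day,
            state.supply_mode,
            state.meal_selection,
            pop.hh_ptr,
            pop.hh_members,
            pop.p_hh,
            pop.status,
            pop.prefs,
            pop.identity,
            pop.neophobia,
            pop.cooking,
            state.locked,
            state.fr_ptr,
            state.fr_idx,
            st.inv,
            st.init_inv,
            st.wk_sales,
            st.today_sales,
            st.unmet,
            st.borient,
            state.store_order,
            st.restocked,
            st.sold_total,
            config.friend_invite_prob,
            config.meal_variety,
            config.preference_increment,
            STATUS_TRANSFER,
            config.safety_margin,
            config.max_supermarket_visits,
            config.replenishment_cycle,
            committed,
            guest_buf,
            tied_buf,
            enjoy_buf,
            order_buf,
            cnt4,
            rec.meals,
            rec.chosen,
            rec.sold,
            rec.inventory,
            rec.identity_counts,
            rec.n_events,
            rec.n_guests,
            rec.n_enjoyed,
            rec.n_at_friends,
            rec.n_substituted,
            rec.n_fallback,
            rec.diversity,
        )
    return RunResult(rec, state)


def _record_day_python(state: SimState, day: int, events, rec: RunRecord) -> None:
    pop = state.pop
    for ev in events:
        rec.meals[day, ev.obtained] += 1
        rec.chosen[day, ev.chosen] += 1
        rec.sold[day, ev.obtained] += ev.units
        rec.n_events[day] += 1
        rec.n_guests[day] += len(ev.guests)
        rec.n_enjoyed[day] += sum(ev.enjoyed.values())
        rec.n_at_friends[day] += sum(1 for g in ev.guests if pop.p_hh[g] != ev.household)
        rec.n_substituted[day] += ev.substituted
        rec.n_fallback[day] += ev.fallback
    rec.inventory[day] = state.stores.inv.sum(axis=0)
    rec.identity_counts[day] = np.bincount(pop.identity, minlength=N_SOURCES)
    total = 0.0
    for p in range(pop.n_persons):
        seen = [False] * N_SOURCES
        for m in state.members_of(pop.p_hh[p]):
            seen[pop.identity[m]] = True
        for f in state.friends_of(p):
            seen[pop.identity[f]] = True
        total += sum(seen)
    rec.diversity[day] = total / pop.n_persons


@njit(cache=True)
def _step_day_kernel(
    g,
    day,
    supply_mode,
    meal_selection,
    hh_ptr,
    hh_members,
    p_hh,
    status,
    prefs,
    identity,
    neophobia,
    cooking,
    locked,
    fr_ptr,
    fr_idx,
    inv,
    init_inv,
    wk_sales,
    today_sales,
    unmet,
    borient,
    store_order,
    restocked,
    sold_total,
    invite_prob,
    meal_variety,
    increment,
    status_transfer,
    safety_margin,
    max_visits,
    cycle,
    committed,
    guest_buf,
    tied_buf,
    enjoy_buf,
    order_buf,
    cnt4,
    m_meals,
    m_chosen,
    m_sold,
    m_inv,
    m_ident,
    m_events,
    m_guests,
    m_enjoyed,
    m_at_friends,
    m_subst,
    m_fallback,
    m_diversity,
):
    P = status.shape[0]
    H = hh_ptr.shape[0] - 1
    S = borient.shape[0]
    for i in range(P):
        committed[i] = False
    # Fisher-Yates household order (mirrors dinner.shuffled_range)
    for i in range(H):
        order_buf[i] = i
    for i in range(H - 1, 0, -1):
        j = g.integers(0, i + 1)
        tmp = order_buf[i]
        order_buf[i] = order_buf[j]
        order_buf[j] = tmp

    for oi in range(H):
        h = order_buf[oi]
        n_present = 0
        for k in range(hh_ptr[h], hh_ptr[h + 1]):
            m = hh_members[k]
            if not committed[m]:
                guest_buf[n_present] = m
                n_present += 1
        if n_present == 0:
            continue
        cook = guest_buf[g.integers(0, n_present)]
        n_guests = n_present
        for k in range(fr_ptr[cook], fr_ptr[cook + 1]):
            f = fr_idx[k]
            u = g.random()
            if u < invite_prob and not committed[f]:
                guest_buf[n_guests] = f
                n_guests += 1
        for i in range(n_guests):
            committed[guest_buf[i]] = True

        # --- meal negotiation ---
        if meal_selection == 0:  # RANDOM
            chosen = g.integers(0, 4)
        elif meal_selection == 1:  # STATUS
            best_s = -1.0
            ntied = 0
            for i in range(n_guests):
                sv = status[guest_buf[i]]
                if sv > best_s:
                    best_s = sv
                    tied_buf[0] = guest_buf[i]
                    ntied = 1
                elif sv == best_s:
                    tied_buf[ntied] = guest_buf[i]
                    ntied += 1
            if ntied == 1:
                top = tied_buf[0]
            else:
                top = tied_buf[g.integers(0, ntied)]
            chosen = identity[top]
        else:  # MAJORITY
            for s4 in range(4):
                cnt4[s4] = 0
            for i in range(n_guests):
                cnt4[identity[guest_buf[i]]] += 1
            best_c = cnt4[0]
            for s4 in range(1, 4):
                if cnt4[s4] > best_c:
                    best_c = cnt4[s4]
            nmodes = 0
            for s4 in range(4):
                if cnt4[s4] == best_c:
                    tied_buf[nmodes] = s4
                    nmodes += 1
            if nmodes == 1:
                chosen = tied_buf[0]
            else:
                chosen = tied_buf[g.integers(0, nmodes)]

        # --- groceries ---
        qty = n_guests
        obtained = -1
        substituted = False
        fallback = False
        if supply_mode == 0:  # INFINITE
            s0 = store_order[h, 0]
            today_sales[s0, chosen] += qty
            sold_total[s0, chosen] += qty
            obtained = chosen
        else:
            visits = max_visits if max_visits < S else S
            last = -1
            for v in range(visits):
                sv_ = store_order[h, v]
                last = sv_
                if inv[sv_, chosen] >= qty:
                    inv[sv_, chosen] -= qty
                    today_sales[sv_, chosen] += qty
                    sold_total[sv_, chosen] += qty
                    obtained = chosen
                    break
                unmet[sv_, chosen] += qty
                u = g.random()
                if u < 1.0 - neophobia[cook]:
                    bestp = -1.0
                    nsub = 0
                    for src in range(4):
                        if src == chosen or inv[sv_, src] < qty:
                            continue
                        pv = prefs[cook, src]
                        if pv > bestp:
                            bestp = pv
                            tied_buf[0] = src
                            nsub = 1
                        elif pv == bestp:
                            tied_buf[nsub] = src
                            nsub += 1
                    if nsub > 0:
                        if nsub == 1:
                            sub = tied_buf[0]
                        else:
                            sub = tied_buf[g.integers(0, nsub)]
                        inv[sv_, sub] -= qty
                        today_sales[sv_, sub] += qty
                        sold_total[sv_, sub] += qty
                        obtained = sub
                        substituted = True
                        break
            if obtained == -1:
                src = 0
                bi = inv[last, 0]
                for k2 in range(1, 4):
                    if inv[last, k2] > bi:
                        bi = inv[last, k2]
                        src = k2
                units = qty if inv[last, src] >= qty else inv[last, src]
                inv[last, src] -= units
                today_sales[last, src] += units
                sold_total[last, src] += units
                obtained = src
                fallback = True
                substituted = src != chosen

        # --- evaluation, preference drift ---
        cs = cooking[cook]
        n_enj = 0
        for i in range(n_guests):
            gid = guest_buf[i]
            q = g.normal(cs, meal_variety)
            u = g.random()
            e = q >= 0.5 and (obtained == identity[gid] or u >= neophobia[gid])
            enjoy_buf[i] = 1 if e else 0
            if e:
                n_enj += 1
            if e and not locked[gid]:
                other = -increment / 3.0
                for k2 in range(4):
                    v = prefs[gid, k2] + (increment if k2 == obtained else other)
                    if v > 1.0:
                        v = 1.0
                    if v < 0.0:
                        v = 0.0
                    prefs[gid, k2] = v
                bestv = prefs[gid, 0]
                arg = 0
                for k2 in range(1, 4):
                    if prefs[gid, k2] > bestv:
                        bestv = prefs[gid, k2]
                        arg = k2
                if prefs[gid, identity[gid]] != bestv:
                    identity[gid] = arg

        # --- status conferral ---
        for i in range(n_guests):
            gid = guest_buf[i]
            if gid == cook or enjoy_buf[i] == 0:
                continue
            t = status_transfer
            if status[gid] < t:
                t = status[gid]
            if 1.0 - status[cook] < t:
                t = 1.0 - status[cook]
            status[gid] -= t
            status[cook] += t

        # --- per-event outputs ---
        m_meals[day, obtained] += 1
        m_chosen[day, chosen] += 1
        m_events[day] += 1
        m_guests[day] += n_guests
        m_enjoyed[day] += n_enj
        for i in range(n_guests):
            if p_hh[guest_buf[i]] != h:
                m_at_friends[day] += 1
        if substituted:
            m_subst[day] += 1
        if fallback:
            m_fallback[day] += 1

    # --- end-of-day outputs read before ledgers reset ---
    for s in range(S):
        for src in range(4):
            m_sold[day, src] += today_sales[s, src]

    # --- retail end of day: EMA, restock, reset ---
    weekday = day % 7
    for s in range(S):
        for src in range(4):
            wk_sales[s, weekday, src] = (
                0.75 * wk_sales[s, weekday, src] + 0.25 * today_sales[s, src]
            )
        if supply_mode != 0 and day % cycle == s % cycle:
            if supply_mode == 1:  # STATIC
                for src in range(4):
                    restocked[s, src] += init_inv[s, src] - inv[s, src]
                    inv[s, src] = init_inv[s, src]
            else:  # DYNAMIC
                for src in range(4):
                    expected = 0.0
                    for d in range(1, cycle + 1):
                        expected += wk_sales[s, (day + d) % 7, src]
                    target = (1.0 + safety_margin) * expected + unmet[s, src]
                    if src == 3:
                        target *= borient[s] / 2.0 + 0.5
                    ni = int(np.ceil(target))
                    if ni < init_inv[s, src]:
                        ni = init_inv[s, src]
                    if ni < 1:
                        ni = 1
                    restocked[s, src] += ni - inv[s, src]
                    inv[s, src] = ni
            for src in range(4):
                unmet[s, src] = 0
        for src in range(4):
            today_sales[s, src] = 0

    # --- population outputs ---
    for src in range(4):
        m_ident[day, src] = 0
        acc = 0
        for s in range(S):
            acc += inv[s, src]
        m_inv[day, src] = acc
    for p in range(P):
        m_ident[day, identity[p]] += 1
    total_div = 0.0
    for p in range(P):
        s0 = False
        s1 = False
        s2 = False
        s3 = False
        hh = p_hh[p]
        for k in range(hh_ptr[hh], hh_ptr[hh + 1]):
            idm = identity[hh_members[k]]
            if idm == 0:
                s0 = True
            elif idm == 1:
                s1 = True
            elif idm == 2:
                s2 = True
            else:
                s3 = True
        for k in range(fr_ptr[p], fr_ptr[p + 1]):
            idm = identity[fr_idx[k]]
            if idm == 0:
                s0 = True
            elif idm == 1:
                s1 = True
            elif idm == 2:
                s2 = True
            else:
                s3 = True
        cnt = 0
        if s0:
            cnt += 1
        if s1:
            cnt += 1
        if s2:
            cnt += 1
        if s3:
            cnt += 1
        total_div += cnt
    m_diversity[day] = total_div / P
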