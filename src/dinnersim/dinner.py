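"""The nightly dinner practice.

Every evening each household (in freshly shuffled order) selects a cook
uniformly among members not already dining elsewhere.  The cook invites the
present household members plus, occasionally, friends; everyone attends at
most one dinner per day.  The party negotiates the meal under one of three
strategies (random / status-based / majority), the cook shops for it, and
each guest evaluates the result: a meal of quality ``Normal(cook_skill,
meal_variety)`` is enjoyed when the quality clears 0.5 and the source either
matches the guest's identity or passes their neophobia gate.  Enjoyment
nudges the guest's preference for that source up by the preference increment
(spread as a compensating -increment/3 over the other sources); a disliked
meal leaves preferences untouched.  Guests who enjoyed the meal confer a small
zero-sum slice of social status on the cook, which is how a right-skewed
status hierarchy emerges over the years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import N_SOURCES, MealSelection
from .population import SimState
from .retail import PurchaseOutcome, end_of_day, obtain_groceries

__all__ = [
    "DinnerEvent",
    "STATUS_TRANSFER",
    "select_cook",
    "form_party",
    "choose_meal",
    "evaluate_meal",
    "update_preferences",
    "confer_status",
    "step_day",
]

#: status conferred by each enjoying guest on the cook (zero-sum transfer)
STATUS_TRANSFER = 0.005


@dataclass
class DinnerEvent:
    """One household dinner party and its outcome."""

    day: int
    household: int
    cook: int
    guests: list[int]            # cook included; pairwise distinct
    chosen: int                  # negotiated ProteinSource
    obtained: int                # source actually served
    supermarket: int | None
    enjoyed: dict[int, bool]     # per guest
    substituted: bool
    fallback: bool
    units: int = 0               # units actually decremented at the store


def shuffled_range(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fisher-Yates shuffle of ``arange(n)`` drawing one integer per swap.

    Used instead of ``rng.permutation`` so the fast kernel can reproduce the
    identical draw sequence.
    """
    order = np.arange(n, dtype=np.int64)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        order[i], order[j] = order[j], order[i]
    return order


def select_cook(members, committed, rng: np.random.Generator) -> int | None:
    """Uniformly random member not already dining elsewhere; None if all are."""
    present = [int(m) for m in members if not committed[m]]
    if not present:
        return None
    return present[int(rng.integers(0, len(present)))]


def form_party(
    cook: int,
    present_members: list[int],
    committed: np.ndarray,
    fr_ptr: np.ndarray,
    fr_idx: np.ndarray,
    invite_prob: float,
    rng: np.random.Generator,
) -> list[int]:
    """Present household members plus independently invited, uncommitted friends."""
    guests = list(present_members)
    for f in fr_idx[fr_ptr[cook]:fr_ptr[cook + 1]]:
        u = rng.random()
        if u < invite_prob and not committed[f]:
            guests.append(int(f))
    return guests


def choose_meal(
    guests,
    identity: np.ndarray,
    status: np.ndarray,
    strategy: MealSelection,
    rng: np.random.Generator,
) -> int:
    """Negotiate tonight's protein source among the guests."""
    strategy = MealSelection(strategy)
    if strategy == MealSelection.RANDOM:
        return int(rng.integers(0, N_SOURCES))
    if strategy == MealSelection.STATUS:
        best = -1.0
        tied: list[int] = []
        for g in guests:
            if status[g] > best:
                best = status[g]
                tied = [g]
            elif status[g] == best:
                tied.append(g)
        top = tied[0] if len(tied) == 1 else tied[int(rng.integers(0, len(tied)))]
        return int(identity[top])
    if strategy == MealSelection.MAJORITY:
        counts = [0] * N_SOURCES
        for g in guests:
            counts[identity[g]] += 1
        best = max(counts)
        modes = [s for s in range(N_SOURCES) if counts[s] == best]
        if len(modes) == 1:
            return modes[0]
        return modes[int(rng.integers(0, len(modes)))]
    raise ValueError(f"unknown meal-selection strategy: {strategy!r}")


def evaluate_meal(
    guest_identity: int,
    guest_neophobia: float,
    meal: int,
    cook_skill: float,
    meal_variety: float,
    rng: np.random.Generator,
) -> bool:
    """Did this guest enjoy the meal?

    Meal quality is ``Normal(cook_skill, meal_variety)``; enjoyment requires
    quality >= 0.5 and, for a non-preferred source, surviving the neophobia
    gate.  For a preferred meal the enjoyment probability is the probit
    S-curve ``Phi((cook_skill - 0.5) / meal_variety)``, whose average over
    uniformly distributed skills is insensitive to the variety parameter.
    """
    q = rng.normal(cook_skill, meal_variety)
    u = rng.random()
    return bool(q >= 0.5 and (meal == guest_identity or u >= guest_neophobia))


def update_preferences(
    prefs_row: np.ndarray, identity: int, meal: int, enjoyed: bool, increment: float = 0.01
) -> int:
    """Drift the guest's preference vector after a meal; return new identity.

    Only an *enjoyed* meal moves preferences: the served source gains
    ``increment`` and the other three sources each lose ``increment / 3``,
    keeping the vector sum invariant before clipping to [0, 1].  A disliked
    meal leaves the vector unchanged — preferences are built by positive
    mealtime experiences, which is what keeps dietary identities slow-moving
    and resilient.  Identity is the argmax; the incumbent is retained on
    exact ties.
    """
    if enjoyed:
        other = -increment / 3.0
        for k in range(N_SOURCES):
            v = prefs_row[k] + (increment if k == meal else other)
            prefs_row[k] = min(1.0, max(0.0, v))
    best = prefs_row[0]
    arg = 0
    for k in range(1, N_SOURCES):
        if prefs_row[k] > best:
            best = prefs_row[k]
            arg = k
    if prefs_row[identity] == best:
        return int(identity)
    return arg


def confer_status(
    status: np.ndarray,
    cook: int,
    guests,
    enjoyed: dict[int, bool],
    delta: float = STATUS_TRANSFER,
) -> None:
    """Each enjoying non-cook guest transfers ``delta`` status to the cook.

    Transfers are truncated so neither party leaves [0, 1]; within that
    truncation total status is conserved exactly.
    """
    for g in guests:
        if g == cook or not enjoyed[g]:
            continue
        t = min(delta, status[g], 1.0 - status[cook])
        status[g] -= t
        status[cook] += t


def step_day(state: SimState, day: int, rng: np.random.Generator) -> list[DinnerEvent]:
    """Run one full day: dinners for every household, then retail end-of-day.

    This is the readable reference implementation; ``engine.run`` provides a
    numba kernel reproducing the identical draw-for-draw behaviour.
    """
    cfg = state.cfg
    committed = np.zeros(state.n_persons, dtype=np.bool_)
    events: list[DinnerEvent] = []
    for h in shuffled_range(state.n_households, rng):
        h = int(h)
        members = state.members_of(h)
        present = [int(m) for m in members if not committed[m]]
        if not present:
            continue
        cook = present[int(rng.integers(0, len(present)))]
        guests = form_party(
            cook, present, committed, state.fr_ptr, state.fr_idx, cfg.friend_invite_prob, rng
        )
        for g in guests:
            committed[g] = True
        chosen = choose_meal(
            guests, state.pop.identity, state.pop.status, state.meal_selection, rng
        )
        outcome = obtain_groceries(state, h, cook, chosen, len(guests), rng)
        enjoyed: dict[int, bool] = {}
        for g in guests:
            e = evaluate_meal(
                state.pop.identity[g],
                state.pop.neophobia[g],
                outcome.obtained,
                state.pop.cooking[cook],
                cfg.meal_variety,
                rng,
            )
            enjoyed[g] = e
            if not state.locked[g]:
                state.pop.identity[g] = update_preferences(
                    state.pop.prefs[g],
                    int(state.pop.identity[g]),
                    outcome.obtained,
                    e,
                    cfg.preference_increment,
                )
        confer_status(state.pop.status, cook, guests, enjoyed)
        events.append(
            DinnerEvent(
                day=day,
                household=h,
                cook=cook,
                guests=guests,
                chosen=chosen,
                obtained=outcome.obtained,
                supermarket=outcome.supermarket_id,
                enjoyed=enjoyed,
                substituted=outcome.substituted,
                fallback=outcome.fallback,
                units=outcome.units,
            )
        )
    end_of_day(state, day)
    return events
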