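"""Stochastic initialization of the synthetic neighbourhood.

Households are scattered uniformly over a square grid of cells; household
sizes are ``1 + Poisson(mean - 1)`` so the printed mean (2.1 persons) and the
"at least one resident" constraint hold simultaneously.  Each person draws a
social status from a normal distribution truncated to [0, 1], a dietary
identity from the population fractions, and a preference vector concentrated
on that identity (0.7 vs 0.1 for the other three sources).  Friendships are
symmetric ties sampled uniformly outside the own household.  Supermarkets
stock enough units to feed the persons inside their service radius for one
replenishment cycle plus a safety margin, with an initial plant (vegan) share
drawn from the configured interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import N_SOURCES, ConfigError, ProteinSource, SimConfig

__all__ = [
    "Population",
    "Supermarkets",
    "SimState",
    "build_population",
    "build_friend_network",
    "build_supermarkets",
    "init_state",
]

IDENTITY_PREF = 0.7
OTHER_PREF = 0.1
#: friend-edge proposals attempted per person before giving up
_MAX_PROPOSALS = 80


@dataclass
class Population:
    """Person and household arrays (CSR household membership)."""

    hh_loc: np.ndarray      # float64[H, 2] grid cell of each household
    hh_ptr: np.ndarray      # int64[H + 1]
    hh_members: np.ndarray  # int64[P] person ids grouped by household
    p_hh: np.ndarray        # int64[P] household of each person
    status: np.ndarray      # float64[P] in [0, 1]
    prefs: np.ndarray       # float64[P, 4] in [0, 1]
    identity: np.ndarray    # int64[P] argmax of prefs
    neophobia: np.ndarray   # float64[P] in [0, 1]
    cooking: np.ndarray     # float64[P] in [0, 1]

    @property
    def n_persons(self) -> int:
        return len(self.p_hh)

    @property
    def n_households(self) -> int:
        return len(self.hh_ptr) - 1

    def household_sizes(self) -> np.ndarray:
        return np.diff(self.hh_ptr)


@dataclass
class Supermarkets:
    """Store arrays: location, inventory, sales ledgers and orientation."""

    sm_loc: np.ndarray               # float64[S, 2]
    borient: np.ndarray              # float64[S] in [0, 2]
    potential_customers: np.ndarray  # int64[S]
    inv: np.ndarray                  # int64[S, 4] current inventory
    init_inv: np.ndarray             # int64[S, 4] frozen at setup
    wk_sales: np.ndarray             # float64[S, 7, 4] weekday sales averages
    today_sales: np.ndarray          # int64[S, 4] accumulator, reset nightly
    unmet: np.ndarray                # int64[S, 4] requests unmet since restock
    restocked: np.ndarray            # int64[S, 4] cumulative restock deltas
    sold_total: np.ndarray           # int64[S, 4] cumulative units sold

    @property
    def n_stores(self) -> int:
        return len(self.borient)


@dataclass
class SimState:
    """Full mutable simulation state for one run."""

    cfg: SimConfig
    pop: Population
    stores: Supermarkets
    fr_ptr: np.ndarray       # int64[P + 1]
    fr_idx: np.ndarray       # int64[n_edges * 2]
    store_order: np.ndarray  # int64[H, S] stores by increasing distance
    locked: np.ndarray       # bool[P] diet frozen by an active intervention
    supply_mode: int         # mutable: inventory interventions flip it
    meal_selection: int
    participants: np.ndarray | None = None   # active dietary-change sample
    saved_init_inv: np.ndarray | None = None  # pre-intervention product range

    @property
    def n_persons(self) -> int:
        return self.pop.n_persons

    @property
    def n_households(self) -> int:
        return self.pop.n_households

    @property
    def n_stores(self) -> int:
        return self.stores.n_stores

    def friends_of(self, person: int) -> np.ndarray:
        return self.fr_idx[self.fr_ptr[person]:self.fr_ptr[person + 1]]

    def members_of(self, household: int) -> np.ndarray:
        return self.pop.hh_members[self.pop.hh_ptr[household]:self.pop.hh_ptr[household + 1]]


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 1] by rejection (mass outside ~0.1%)."""
    out = rng.normal(mean, sd, size)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def build_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Create households and persons with their characteristic variables."""
    H = cfg.n_households
    hh_loc = rng.integers(0, cfg.grid_size, size=(H, 2)).astype(np.float64)
    sizes = 1 + rng.poisson(cfg.household_size_mean - 1.0, size=H)
    P = int(sizes.sum())
    hh_ptr = np.zeros(H + 1, dtype=np.int64)
    np.cumsum(sizes, out=hh_ptr[1:])
    hh_members = np.arange(P, dtype=np.int64)
    p_hh = np.repeat(np.arange(H, dtype=np.int64), sizes)

    status = _truncated_normal(0.5, 0.15, P, rng)
    identity = rng.choice(N_SOURCES, size=P, p=np.asarray(cfg.diet_fractions)).astype(np.int64)
    prefs = np.full((P, N_SOURCES), OTHER_PREF, dtype=np.float64)
    prefs[np.arange(P), identity] = IDENTITY_PREF
    neophobia = rng.uniform(0.0, 1.0, P)
    cooking = rng.uniform(0.0, 1.0, P)
    return Population(hh_loc, hh_ptr, hh_members, p_hh, status, prefs, identity, neophobia, cooking)


def build_friend_network(
    p_hh: np.ndarray, n_friends: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric friend ties outside the own household, ~n_friends per person.

    Edges are grown by repeated uniform proposals until each person reaches
    the target degree or proposals are exhausted, so the realized mean degree
    sits slightly below the target in small populations.  Returns a CSR
    adjacency ``(fr_ptr, fr_idx)``.
    """
    P = len(p_hh)
    empty = (np.zeros(P + 1, dtype=np.int64), np.zeros(0, dtype=np.int64))
    if n_friends == 0 or P == 0:
        return empty
    hh_sizes = np.bincount(p_hh)
    if len(hh_sizes) == 1 or hh_sizes.max() == P:
        warnings.warn("friend network is empty: no partners outside the own household")
        return empty
    if n_friends >= P - hh_sizes.max():
        raise ConfigError(
            f"n_friends: {n_friends} friends are impossible in a population of {P} "
            f"persons whose largest household has {hh_sizes.max()} members"
        )
    adj: list[set[int]] = [set() for _ in range(P)]
    for p in rng.permutation(P):
        p = int(p)
        attempts = 0
        while len(adj[p]) < n_friends and attempts < _MAX_PROPOSALS:
            attempts += 1
            q = int(rng.integers(0, P))
            if q == p or p_hh[q] == p_hh[p] or q in adj[p] or len(adj[q]) >= n_friends:
                continue
            adj[p].add(q)
            adj[q].add(p)
    fr_ptr = np.zeros(P + 1, dtype=np.int64)
    fr_ptr[1:] = np.cumsum([len(a) for a in adj])
    fr_idx = np.fromiter(
        (q for a in adj for q in sorted(a)), dtype=np.int64, count=int(fr_ptr[-1])
    )
    return fr_ptr, fr_idx


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` units proportionally to ``weights`` (largest remainder)."""
    w = np.asarray(weights, dtype=np.float64)
    if total <= 0:
        return np.zeros(len(w), dtype=np.int64)
    if w.sum() <= 0:
        w = np.ones_like(w)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def build_supermarkets(
    cfg: SimConfig, pop: Population, rng: np.random.Generator
) -> Supermarkets:
    """Place supermarkets and size their initial inventories.

    Stock is sized for the customers a store actually serves: every person
    inside the service radius counts, weighted down by how many competing
    stores also cover them.  Total initial stock per store is ``ceil(weighted
    customers * cycle * (1 + safety margin))`` — one unit per person per day
    for one replenishment cycle plus the safety margin.  The vegan share of
    the range is uniform on the configured interval; the animal remainder is
    an assortment split evenly over meat, fish and dairy & eggs (a product
    range is stocked per category, not matched to demand — which is exactly
    why a fixed range under-supplies the meat-heavy demand).  A store with no
    customers in range holds a token ``cycle`` units of each source.
    """
    S = cfg.n_supermarkets
    sm_loc = rng.integers(0, cfg.grid_size, size=(S, 2)).astype(np.float64)
    person_loc = pop.hh_loc[pop.p_hh]
    d2 = ((person_loc[None, :, :] - sm_loc[:, None, :]) ** 2).sum(axis=2)
    in_range = d2 <= cfg.service_radius**2  # (S, P)
    potential = in_range.sum(axis=1).astype(np.int64)
    coverage = in_range.sum(axis=0)  # stores covering each person
    weights = np.where(coverage > 0, 1.0 / np.maximum(coverage, 1), 0.0)
    served = in_range @ weights  # competition-adjusted customer base

    lo, hi = cfg.plant_inventory_fraction_range
    vegan_share = rng.uniform(lo, hi, S)
    borient = rng.uniform(*cfg.business_orientation_range, size=S)

    init_inv = np.zeros((S, N_SOURCES), dtype=np.int64)
    for s in range(S):
        if potential[s] == 0:
            init_inv[s] = cfg.replenishment_cycle
            continue
        total = math.ceil(served[s] * cfg.replenishment_cycle * (1.0 + cfg.safety_margin))
        vegan = int(round(total * vegan_share[s]))
        vegan = min(max(vegan, math.ceil(total * lo)), math.floor(total * hi))
        init_inv[s, : N_SOURCES - 1] = _apportion(total - vegan, np.ones(N_SOURCES - 1))
        init_inv[s, ProteinSource.VEGAN] = vegan

    wk_sales = np.repeat(
        (init_inv.astype(np.float64) / cfg.replenishment_cycle)[:, None, :], 7, axis=1
    )
    zeros = lambda: np.zeros((S, N_SOURCES), dtype=np.int64)
    return Supermarkets(
        sm_loc=sm_loc,
        borient=borient,
        potential_customers=potential,
        inv=init_inv.copy(),
        init_inv=init_inv,
        wk_sales=np.ascontiguousarray(wk_sales),
        today_sales=zeros(),
        unmet=zeros(),
        restocked=zeros(),
        sold_total=zeros(),
    )


def init_state(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Build the full initial simulation state from a validated config."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = build_population(cfg, rng)
    fr_ptr, fr_idx = build_friend_network(pop.p_hh, cfg.n_friends, rng)
    stores = build_supermarkets(cfg, pop, rng)
    dists = np.linalg.norm(pop.hh_loc[:, None, :] - stores.sm_loc[None, :, :], axis=2)
    store_order = np.argsort(dists, axis=1, kind="stable").astype(np.int64)
    return SimState(
        cfg=cfg,
        pop=pop,
        stores=stores,
        fr_ptr=fr_ptr,
        fr_idx=fr_idx,
        store_order=np.ascontiguousarray(store_order),
        locked=np.zeros(pop.n_persons, dtype=np.bool_),
        supply_mode=int(cfg.supply_mode),
        meal_selection=int(cfg.meal_selection),
    )
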