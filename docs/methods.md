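# Methods

`dinnersim` simulates the nightly dinner practice of a synthetic Dutch
neighbourhood and its coupling to supermarket inventory management. This
note records the model and its assumptions, the parameters that matter, the
numerical conventions, the design choices made where the design was
genuinely open, and the known limitations. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Agents and initialization

**Households** (default 250) sit on uniformly random cells of a 61×61 grid.
Sizes are `1 + Poisson(λ = 1.1)`: the distribution keeps the documented mean
of 2.1 persons while honouring the constraint that every household has at
least one resident (a plain Poisson(2.1) would produce ~12% empty
households).

**Persons** carry: status `~ N(0.5, 0.15)` truncated to [0,1] by rejection
(mass outside is ~0.1%, so the truncation bias on the mean is negligible);
dietary identity drawn from the population fractions — the Dutch survey
shares 95.1/1.7/2.6/0.4 % sum to 99.8, so the default divides them by 0.998
to make a distribution while preserving the ratios; a preference vector of
0.7 on the identity source and 0.1 elsewhere, so roughly 45 reinforcing
meals of another source are needed to flip an identity under the 0.01
increment (preferences are slow-moving by construction); cooking skill and
neophobia `~ U(0,1)`.

**Friend network.** Symmetric ties, target degree 3, grown by uniform random
edge proposals excluding self and household members until the degree target
or a proposal budget is exhausted; realized mean degree is slightly below
target in small populations (unit-tested at 3 ± 0.5). No spatial
assortativity. A population without any cross-household pair warns and
yields an empty network; a degree target that is impossible for the largest
household raises a configuration error.

**Supermarkets** (default 6, uniform random cells) count the persons within
their service radius (default 40 cells) as potential customers. Because
service areas overlap almost completely at that radius, stock is sized for
the *competition-adjusted* customer base: each covered person counts `1/k`
where `k` stores cover them. Total initial stock is
`ceil(served × cycle × 1.1)` — one unit per person per day for one
replenishment cycle plus the 10% safety margin. The plant (vegan) share of
the range is uniform on [0.35, 0.53]; the animal remainder is split
**evenly** over meat, fish and dairy & eggs. The even split models an
assortment — a retailer stocks a product range per category rather than
matching the 95%-meat demand — and is what makes a *fixed* range
under-supply meat. A store with no customers in range keeps a token
`cycle` units per source. Business orientation `~ U(0, 2)` captures the
store's inclination toward sustainable products.

## The daily cycle

Household order is reshuffled every day (Fisher–Yates) to avoid systematic
first-mover advantage in friend invitations and stock. Per household: a
cook is drawn uniformly among members not already committed to another
dinner (none → no dinner); present members join, and each of the cook's
friends is invited independently with probability 0.1, joining if
uncommitted — one dinner per person per day is a hard invariant. The party
negotiates one source (random / status / majority; all exact ties uniform
at random), the cook shops, every guest evaluates the meal, preferences
drift, status is conferred, and finally stores close out the day
(sales averaging, scheduled restocks).

**Shopping.** Stores are visited nearest-first, up to 2 visits by default.
At a store with insufficient stock of the chosen source the shortfall is
logged as an unmet request; with probability `1 − neophobia` the cook takes
the in-stock source they personally prefer most (ties uniform; guests'
preferences are deliberately not consulted — cooks do not recall their
dinner party in the shop), otherwise they travel on. If all visits fail,
the cook buys the best-stocked source at the last store with the decrement
floored at zero: availability never cancels dinner, so the preference
dynamics stay well-defined. Fallback sales are logged as what was actually
decremented, keeping the inventory ledger exact.

**Meal evaluation.** Quality `q ~ N(cook_skill, meal_variety)`; enjoyment
requires `q ≥ 0.5` and, for a source different from the guest's identity,
surviving the neophobia gate (`u ≥ neophobia`). For a preferred meal
`P(enjoy) = Φ((skill − 0.5)/variety)`: an S-curve in cooking skill whose
average over uniformly distributed skills is 1/2 regardless of the variety
parameter — so population enjoyment responds to skill but not to variety,
while variety controls how deterministic an individual cook's outcomes are.

**Preference drift.** Only an enjoyed meal moves preferences: the served
source gains 0.01 and the other three lose 0.01/3 each (sum-invariant
before clipping to [0,1]). A disliked meal changes nothing. This
"reinforcement by positive experience" rule was selected over a symmetric
variant (penalising the served source on a disliked meal and crediting the
others) after the symmetric rule proved structurally unstable: households
with below-median cooking enjoy fewer than half their dinners, giving
whatever they eat a persistent negative drift, so identities rotate through
all four sources within months. That rotation floods every output — it
inflates plant-based cooking several-fold, keeps the meal and identity
series drifting for years, erodes meat dominance, and inverts the expected
signs of the neophobia and vegan-status sensitivity sweeps. Under the
adopted rule, low skill simply freezes preferences, identities are
resilient, and change happens through enjoyed exposure to other sources
(substitutes, friends' dinners, imposed majority/status choices) — the
behaviour the rest of the model's design presumes. Identity is recomputed
as the argmax after each update; the incumbent is retained on exact ties
(hysteresis against flapping).

**Status conferral.** Each non-cook guest who enjoyed the meal transfers
0.005 status to the cook. Transfers are truncated so both parties stay in
[0,1]; within that truncation total status is conserved exactly (the
transfer is reduced, never lost). Zero-sum conferral prevents unbounded
status inflation; the magnitude is an arbitrary slow timescale (~hundreds
of dinners to traverse the status range).

## Retail dynamics

Sales are tracked per weekday as an exponential moving average with
α = 0.25 — a memory of roughly four same-weekdays, matching the practice of
averaging "sales of specific Mondays". The averages warm-start at
`initial_inventory / cycle` so early restocks are sane before data
accumulates. Restocks fire every `replenishment_cycle` days (default 4),
phase-offset by store id so city-wide stock-outs do not synchronise.

* **Infinite:** stock is never decremented; restocking is undefined.
* **Static:** inventory resets to the initial range; the retailer ignores
  demand.
* **Dynamic:** order-up-to
  `target(s) = 1.1 × Σ_{next cycle days} weekday_sales(s) + unmet(s)`, with
  the vegan target scaled by `orientation/2 + 0.5 ∈ [0.5, 1.5]`, and the
  result floored at the initial assortment (and at 1 unit). The floor
  encodes that a responsive retailer overstocks what sells but keeps
  carrying its range; without it, slow movers collapse to a single unit and
  dynamic inventories could never dominate static ones, contrary to the
  behaviour the model is meant to exhibit. Unmet requests add one-for-one
  and reset at each restock.

An exact conservation ledger (initial + restock deltas − sales = current,
per store and source, in integer units) is maintained and tested over
1000-day runs.

## Interventions

Both fire at day 730 by default and run under dynamic supply with
status-based selection. **Dietary change** samples
`⌊p × |eligible|⌋` persons from the status stratum (low / high / random),
overwrites identity and preferences (0.7/0.1 profile) and locks drift until
release; locked persons still dine, enjoy and confer status. **Inventory
change** rewrites every range to the requested plant fraction
(total units preserved; animal part split pro-rata to its current
composition, largest-remainder rounding) and holds supply static for the
window; at release supply returns to dynamic, the original range is
restored as the assortment base, and the weekday sales learned during the
window are retained, so post-intervention restocking reflects
intervention-era demand. Durations span 1–2920 days; the plant fraction is
capped at 0.95 so an animal remainder always exists.

## Experiment harness

* **Baseline protocol:** replicated default runs, replicate `r` seeded
  `base_seed + r`; daily across-run median/IQR summaries and yearly
  plant-share matrices. The package's standard experiment size is 20
  replicates (the acceptance script and tests use 20; the CLI default is
  100), with yearly recording for intervention experiments.
* **Burn-in (homeostasis):** on `s(t) = median(t) + IQR(t)` across runs,
  smoothed by a 28-day centered rolling mean (suppressing weekday and
  count noise), the stabilization day is the first day after which *every*
  sliding 180-day window stays within 5% of its own mean — i.e. the series
  is stable from there to the end of the run. A constant series stabilizes
  at day 0; a series whose only stable stretch is shorter than one window
  returns none. The relative 5% band is scale-dependent: for series whose
  daily level is below ~20 counts (fish or vegan meals, minority identity
  counts), the quantization of a median across 20 runs alone exceeds 5%, so
  such series may honestly never register as stable even when visually
  flat. Majority-series (meat meals, meat identity) stabilize within the
  first two simulated months.
* **OFAT:** one factor at a time over its documented value list
  (global parameters by config replacement; population-wide neophobia,
  cooking skill, and the status of vegan-identity persons as agent
  overrides applied after initialization), recording final-year outcomes;
  trends are summarised by Spearman rank correlation over (level, outcome)
  pairs. Default 5 replicates per level (10 in the signature tests).
* **PRCC:** the number of supermarkets, number of friends and replenishment
  cycle are varied over a 3×3×3 full factorial spanning their documented
  ranges, 5 replicates per cell. All variables are rank-transformed, X and
  Y are each residualised on the two controls by least squares, and the
  Pearson correlation of the residuals is returned; an independent
  brute-force implementation (double-argsort ranks, normal-equation
  residuals, explicit sums) agrees to 1e-10 on synthetic systems.

## Engines, determinism and numerics

The daily cycle exists twice: a pure-Python reference that composes the
documented operation functions, and a numba kernel. Both consume a single
`numpy.random.Generator` in an identical draw order (including a hand-rolled
Fisher–Yates so the shuffle draws match), so for any seed the two engines
produce bit-identical trajectories — enforced by a parametrised test across
all supply modes and selection strategies. All inventory quantities are
64-bit integers; preference and status updates clip via `min/max` in the
same operation order in both engines. Identical seeds give bit-identical
run records; replicate seeds are `base_seed + r`.

One 10-year default run (~525 persons) takes ~0.3 s on one core with the
kernel, which sets the package's standard experiment sizes: 20-replicate
baselines, 10-replicate intervention experiments, 10 replicates per OFAT
level.

## What the generator emulates — and what it does not

The synthetic neighbourhood reproduces the documented marginal statistics:
household-size distribution, dietary identity fractions, status location,
friend-degree target, plant-share interval of initial inventories. It does
not model demography (no birth, death, ageing, household recomposition),
gender or parent-child roles, prices or promotions, non-supermarket
channels, eating out, or spatially/socially assorted networks. Passing
tests therefore show internal consistency with those stylised conditions,
not fidelity to any real neighbourhood's microdata.

## Known limitations

* **Status stays near-symmetric.** With uniformly rotated cooks and
  zero-sum fixed transfers, net status flux is an odd function of cooking
  skill: the distribution spreads and compresses at the [0,1] caps instead
  of developing the right-skewed hierarchy real status systems show
  (measured sample skewness ≈ −0.08 after ten years). A concentration
  mechanism (status-weighted cook selection, conferral proportional to
  standing) would be needed.
* **Baseline plant share sits below survey-anchored expectations.** With
  preferences reinforced only by enjoyment and a responsive supply that
  rarely binds, steady-state plant-based cooking equals the small vegan
  household base rate (~0.4%) plus occasional substitutions, below the
  3–5% market-share figure reported for plant-based sources; matching that
  figure would require a persistently tighter meat supply or an additional
  exposure channel.
* **Strong dietary conversions can persist.** A converted person who heads
  their household's status hierarchy keeps being served, enjoying and
  reinforcing the new diet: long or large dietary-change interventions
  produce durable (not relapsing) preference shifts, and even the 360-day
  90%-plant supply intervention leaves an elevated plant share after
  release.
* **Neophobia has two opposing effects** — it suppresses substitution
  purchases (tested, monotone) but also shields minority identities from
  being converted at imposed majority meals; at the model's inventory
  abundance the net effect of population-wide neophobia on plant-based
  cooking is not reliably negative.
* The burn-in detector's relative tolerance is uninformative for
  small-count series (above).
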