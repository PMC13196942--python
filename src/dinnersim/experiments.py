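"""Experiment harness: baseline protocol, OFAT sweeps and PRCC sampling.

The baseline protocol runs the default configuration (status-based meal
selection, dynamic supply, no intervention) for ``n_runs`` independent seeds
— replicate ``r`` uses ``base_seed + r`` — and summarises the daily outputs
as across-run median and IQR.  Intervention experiments reuse the same
machinery with an intervention block in the config and, following the study
protocol, 20 replicates recorded yearly.

OFAT (one factor at a time) sweeps a single global or agent parameter over
its printed value list with everything else at defaults, recording final-year
outcomes.  The PRCC experiment jointly varies the number of supermarkets, the
number of friends, and the replenishment-cycle length over a full-factorial
design and reports the partial rank correlation of each with the meal and
inventory outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import detect_homeostasis, median_iqr, prcc, rolling_mean
from .config import N_SOURCES, ProteinSource, SimConfig
from .engine import RunRecord, RunResult, run

__all__ = [
    "run_many",
    "run_baseline",
    "daily_summary",
    "yearly_plant_share_matrix",
    "stabilization_days",
    "DEFAULT_OFAT_GRID",
    "AGENT_FACTORS",
    "run_ofat",
    "ofat_trends",
    "DEFAULT_PRCC_LEVELS",
    "run_prcc_experiment",
]

#: smoothing window (days) applied to median+IQR series before burn-in detection
STABILIZATION_SMOOTH = 28


def run_many(
    config: SimConfig,
    n_runs: int,
    base_seed: int | None = None,
    overrides: dict | None = None,
    engine: str = "numba",
    keep_states: bool = True,
) -> list[RunResult]:
    """``n_runs`` independent replicates; replicate ``r`` is seeded ``base_seed + r``."""
    if base_seed is None:
        base_seed = config.seed
    results = []
    for r in range(n_runs):
        res = run(replace(config, seed=base_seed + r), overrides=overrides, engine=engine)
        if not keep_states:
            res = RunResult(res.record, None)  # type: ignore[arg-type]
        results.append(res)
    return results


def run_baseline(
    config: SimConfig, n_runs: int = 100, base_seed: int | None = None, **kw
) -> list[RunResult]:
    """The baseline protocol: replicated default runs without intervention."""
    if config.intervention is not None:
        raise ValueError("baseline runs must not carry an intervention")
    return run_many(config, n_runs, base_seed=base_seed, **kw)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_SERIES = ("meals", "inventory", "identity_counts", "sold", "chosen")


def daily_summary(records: list[RunRecord]) -> pd.DataFrame:
    """Tidy across-run summary: day, metric, source, median, q1, q3."""
    frames = []
    days = np.arange(records[0].n_days)
    for metric in _SERIES:
        stacked = np.stack([getattr(r, metric) for r in records])  # (R, T, 4)
        q1, med, q3 = np.percentile(stacked, [25, 50, 75], axis=0)
        for src in ProteinSource:
            frames.append(
                pd.DataFrame(
                    {
                        "day": days,
                        "metric": metric,
                        "source": src.name,
                        "median": med[:, int(src)],
                        "q1": q1[:, int(src)],
                        "q3": q3[:, int(src)],
                    }
                )
            )
    pct = np.stack([r.pct_enjoying() for r in records])
    q1, med, q3 = np.percentile(pct, [25, 50, 75], axis=0)
    frames.append(
        pd.DataFrame(
            {"day": days, "metric": "pct_enjoying", "source": "", "median": med, "q1": q1, "q3": q3}
        )
    )
    return pd.concat(frames, ignore_index=True)


def yearly_plant_share_matrix(records: list[RunRecord]) -> np.ndarray:
    """Plant (vegan) meal share per run and year, shape (runs, years)."""
    return np.stack([r.yearly_plant_share() for r in records])


def stabilization_days(
    records: list[RunRecord],
    series: tuple[str, ...] = ("meals", "identity_counts"),
    window: int = 180,
    tol: float = 0.05,
    smooth: int | None = STABILIZATION_SMOOTH,
) -> dict[str, int | None]:
    """Burn-in day per output series (one entry per series x protein source).

    The across-run median+IQR series is smoothed with a centered rolling mean
    before detection, suppressing day-scale sampling noise so the detector
    responds to the transient rather than to daily count fluctuations.
    """
    out: dict[str, int | None] = {}
    for metric in series:
        stacked = np.stack([getattr(r, metric) for r in records])
        for src in ProteinSource:
            med, iqr = median_iqr(stacked[:, :, int(src)])
            s = med + iqr
            if smooth:
                s = rolling_mean(s, smooth)
            out[f"{metric}_{src.name.lower()}"] = detect_homeostasis(
                s, None, window=window, tol=tol
            )
    return out


# ---------------------------------------------------------------------------
# OFAT sensitivity analysis
# ---------------------------------------------------------------------------

#: factors applied as agent-level overrides rather than config fields
AGENT_FACTORS = ("neophobia", "cooking_skill", "vegan_status")

DEFAULT_OFAT_GRID: dict[str, list] = {
    "n_supermarkets": [1, 5, 10],
    "n_households": [25, 250, 750, 1500],
    "n_friends": [0, 3, 6],
    "replenishment_cycle": [1, 4, 7],
    "service_radius": [20, 40, 60],
    "max_supermarket_visits": [1, 2, 3, 4, 5, 6, 7, 8],
    "meal_variety": [0.1, 0.2, 0.3, 0.4, 0.5],
    "vegan_status": [0, 1],
    "neophobia": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "cooking_skill": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
}


def _final_year_outcomes(rec: RunRecord) -> dict[str, float]:
    T, d = rec.n_days, rec.days_per_year
    start = T - d
    meals = rec.meals[start:].sum(axis=0)
    guests = rec.n_guests[start:].sum()
    enjoyed = rec.n_enjoyed[start:].sum()
    out = {f"meals_{src.name.lower()}": float(meals[int(src)]) for src in ProteinSource}
    out["meals_total"] = float(meals.sum())
    out["plant_meals"] = float(meals[int(ProteinSource.VEGAN)])
    out["plant_share"] = float(meals[int(ProteinSource.VEGAN)] / meals.sum()) if meals.sum() else np.nan
    out["pct_enjoying"] = float(enjoyed / guests) if guests else np.nan
    inv = rec.inventory[start:].mean(axis=0)
    for src in ProteinSource:
        out[f"inventory_{src.name.lower()}"] = float(inv[int(src)])
    return out


def run_ofat(
    config: SimConfig,
    factors: dict[str, list] | list[str] | None = None,
    replicates: int = 5,
    base_seed: int | None = None,
    engine: str = "numba",
) -> pd.DataFrame:
    """One-factor-at-a-time sweep; returns long-format final-year outcomes."""
    if factors is None:
        grid = dict(DEFAULT_OFAT_GRID)
    elif isinstance(factors, dict):
        grid = factors
    else:
        unknown = [f for f in factors if f not in DEFAULT_OFAT_GRID]
        if unknown:
            raise ValueError(f"unknown OFAT factor(s): {unknown}")
        grid = {f: DEFAULT_OFAT_GRID[f] for f in factors}
    if base_seed is None:
        base_seed = config.seed
    cfg_fields = set(SimConfig.__dataclass_fields__)
    rows = []
    for factor, levels in grid.items():
        if factor not in cfg_fields and factor not in AGENT_FACTORS:
            raise ValueError(f"unknown OFAT factor: {factor!r}")
        for level in levels:
            for r in range(replicates):
                seed = base_seed + r
                if factor in AGENT_FACTORS:
                    res = run(replace(config, seed=seed), overrides={factor: level}, engine=engine)
                else:
                    res = run(replace(config, seed=seed, **{factor: level}), engine=engine)
                row = {"factor": factor, "level": level, "replicate": r, "seed": seed}
                row.update(_final_year_outcomes(res.record))
                rows.append(row)
    return pd.DataFrame(rows)


def ofat_trends(df: pd.DataFrame, outcome: str = "plant_meals") -> pd.DataFrame:
    """Spearman trend of an outcome against each swept factor level."""
    rows = []
    for factor, sub in df.groupby("factor", sort=False):
        rho, p = stats.spearmanr(sub["level"], sub[outcome])
        rows.append({"factor": factor, "outcome": outcome, "spearman_rho": rho, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PRCC experiment
# ---------------------------------------------------------------------------

DEFAULT_PRCC_LEVELS: dict[str, list] = {
    "n_supermarkets": [1, 6, 11],
    "n_friends": [0, 7, 15],
    "replenishment_cycle": [1, 6, 12],
}

_PRCC_OUTPUTS = (
    "meals_meat",
    "meals_nonmeat",
    "inventory_meat",
    "inventory_nonmeat",
)


def run_prcc_experiment(
    config: SimConfig,
    levels: dict[str, list] | None = None,
    replicates: int = 5,
    base_seed: int | None = None,
    engine: str = "numba",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-factorial joint sweep and PRCC of each parameter with each output.

    Returns ``(samples, coefficients)``: the per-run samples and a tidy frame
    with one PRCC per (parameter, output), the other two parameters acting as
    controls.
    """
    levels = dict(DEFAULT_PRCC_LEVELS if levels is None else levels)
    names = list(levels)
    if len(names) != 3:
        raise ValueError("the PRCC design varies exactly three parameters")
    if base_seed is None:
        base_seed = config.seed
    rows = []
    seed = base_seed
    for a in levels[names[0]]:
        for b in levels[names[1]]:
            for c in levels[names[2]]:
                for r in range(replicates):
                    cfg = replace(config, seed=seed, **{names[0]: a, names[1]: b, names[2]: c})
                    rec = run(cfg, engine=engine).record
                    out = _final_year_outcomes(rec)
                    nonmeat_meals = out["meals_fish"] + out["meals_vegetarian"] + out["meals_vegan"]
                    nonmeat_inv = (
                        out["inventory_fish"] + out["inventory_vegetarian"] + out["inventory_vegan"]
                    )
                    rows.append(
                        {
                            names[0]: a,
                            names[1]: b,
                            names[2]: c,
                            "replicate": r,
                            "seed": seed,
                            "meals_meat": out["meals_meat"],
                            "meals_nonmeat": nonmeat_meals,
                            "inventory_meat": out["inventory_meat"],
                            "inventory_nonmeat": nonmeat_inv,
                        }
                    )
                    seed += 1
    samples = pd.DataFrame(rows)
    coefs = []
    for x in names:
        controls = [n for n in names if n != x]
        for outname in _PRCC_OUTPUTS:
            coefs.append(
                {
                    "parameter": x,
                    "output": outname,
                    "prcc": prcc(
                        samples[x].to_numpy(),
                        samples[outname].to_numpy(),
                        samples[controls].to_numpy(),
                    ),
                }
            )
    return samples, pd.DataFrame(coefs)
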