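"""Initialization variants, environmental-change schedules, the 24-scenario
catalog, and the replicate runner."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import GenerationSummary, pm_zone, range_front, summarize_generation
from .model import decide_step, disperse_step, reproduce_step, winter_step
from .params import SimParams
from .population import UNDECIDED, Population

__all__ = [
    "Scenario",
    "ReplicateSet",
    "INIT_REGIONS",
    "INIT_DIVERSITIES",
    "CHANGES",
    "init_population",
    "scenario_catalog",
    "apply_change",
    "run_replicates",
]

logger = logging.getLogger("partmig")

INIT_REGIONS = ("complete", "migrants_only", "residents_only")
INIT_DIVERSITIES = ("maximum", "zero", "zero_fitted")
CHANGES = (
    "none",
    "resident_survival_up",
    "resident_survival_down",
    "migrant_reproduction",
)

_REGION_SHORT = {"complete": "compl", "migrants_only": "migr", "residents_only": "res"}
_DIV_SHORT = {"maximum": "full", "zero": "zero", "zero_fitted": "zerofit"}
_CHANGE_SHORT = {
    "resident_survival_up": "survup",
    "resident_survival_down": "survdown",
    "migrant_reproduction": "migrrepro",
}


@dataclass(frozen=True)
class Scenario:
    """One simulation experiment: where and how the species starts, and what
    (if anything) changes abruptly during the run.

    ``init_region`` places the starting populations: across the whole
    landscape, only at the polar edge (columns 1-10, migratory populations),
    or only at the equatorial edge (columns x_max-10 .. x_max, residential
    populations). ``init_diversity`` sets the initial thresholds: ``maximum``
    draws T ~ U(0, 1] per individual, ``zero`` fixes T = 0.5, and
    ``zero_fitted`` fixes T to the value already adapted to the starting
    side (0.1 for residents, 0.9 for migrants) — hence invalid with the
    complete region. ``change`` shifts resident survival by ±0.2 or scales
    migrant reproduction by 0.8 from ``change_generation`` onward.
    """

    name: str
    init_region: str
    init_diversity: str
    change: str = "none"
    change_generation: int = 300
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.init_region not in INIT_REGIONS:
            raise ValueError(f"unknown init_region {self.init_region!r}")
        if self.init_diversity not in INIT_DIVERSITIES:
            raise ValueError(f"unknown init_diversity {self.init_diversity!r}")
        if self.change not in CHANGES:
            raise ValueError(f"unknown change {self.change!r}")
        if self.init_diversity == "zero_fitted" and self.init_region == "complete":
            raise ValueError(
                "zero_fitted initialization requires migrants_only or residents_only"
            )
        if self.change_generation < 0:
            raise ValueError("change_generation must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def front_direction(self) -> str:
        """Side the range front is measured from (see analysis.range_front)."""
        return "from_high_x" if self.init_region == "residents_only" else "from_low_x"


def _region_columns(region: str, x_max: int) -> tuple[int, int]:
    if region == "complete":
        return 1, x_max
    if region == "migrants_only":
        return 1, min(10, x_max)
    return max(1, x_max - 10), x_max


def init_population(scenario: Scenario, params: SimParams, rng) -> Population:
    """Fill every patch of the scenario's region with K individuals.

    Thresholds follow ``init_diversity``; all other patches start empty and
    the generation counter at 0.
    """
    lo, hi = _region_columns(scenario.init_region, params.x_max)
    xs = np.arange(lo, hi + 1)
    ys = np.arange(1, params.y_max + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x = np.repeat(gx.ravel(), params.K).astype(np.int32)
    y = np.repeat(gy.ravel(), params.K).astype(np.int32)
    n = x.size
    if scenario.init_diversity == "maximum":
        T = 1.0 - rng.random(n)  # U(0, 1]
    elif scenario.init_diversity == "zero":
        T = np.full(n, 0.5)
    else:  # zero_fitted
        T = np.full(n, 0.1 if scenario.init_region == "residents_only" else 0.9)
    return Population(
        x=x, y=y, T=T, phenotype=np.full(n, UNDECIDED, dtype=np.int8), generation=0
    )


def scenario_catalog(
    n_replicates: int = 100, change_generation: int = 300
) -> list[Scenario]:
    """The default 24-scenario catalog.

    Built from the scenario options as 6 range-expansion scenarios (edge
    initializations crossed with the three diversity modes, no change), all
    8 valid region x diversity pairs crossed with the two resident-survival
    shifts (16), and the migrant-reproduction change applied to the two
    full-landscape initializations (2). Survival changes in the "compl-zero"
    scenario are applied immediately (generation 0) so that no genetic
    diversity accumulates before the change; every other change happens at
    ``change_generation``, after demographic equilibrium.
    """

    def name(region: str, div: str, change: str) -> str:
        base = f"{_REGION_SHORT[region]}-{_DIV_SHORT[div]}"
        return base if change == "none" else f"{base}-{_CHANGE_SHORT[change]}"

    valid_pairs = [
        (r, dv)
        for r in INIT_REGIONS
        for dv in INIT_DIVERSITIES
        if not (dv == "zero_fitted" and r == "complete")
    ]
    catalog: list[Scenario] = []
    for region in ("migrants_only", "residents_only"):
        for div in INIT_DIVERSITIES:
            catalog.append(
                Scenario(
                    name=name(region, div, "none"),
                    init_region=region,
                    init_diversity=div,
                    change="none",
                    change_generation=0,
                    n_replicates=n_replicates,
                )
            )
    for change in ("resident_survival_up", "resident_survival_down"):
        for region, div in valid_pairs:
            cg = 0 if (region == "complete" and div == "zero") else change_generation
            catalog.append(
                Scenario(
                    name=name(region, div, change),
                    init_region=region,
                    init_diversity=div,
                    change=change,
                    change_generation=cg,
                    n_replicates=n_replicates,
                )
            )
    for region, div in (("complete", "maximum"), ("complete", "zero")):
        catalog.append(
            Scenario(
                name=name(region, div, "migrant_reproduction"),
                init_region=region,
                init_diversity=div,
                change="migrant_reproduction",
                change_generation=change_generation,
                n_replicates=n_replicates,
            )
        )
    assert len(catalog) == 24
    return catalog


def scenario_by_name(name: str, **overrides) -> Scenario:
    """Look up a catalog scenario by its shorthand name."""
    for sc in scenario_catalog():
        if sc.name == name:
            return replace(sc, **overrides) if overrides else sc
    raise KeyError(f"unknown scenario {name!r}; see scenario_catalog()")


def apply_change(params: SimParams, scenario: Scenario, generation: int) -> SimParams:
    """Parameters in force at ``generation``.

    Identity before ``change_generation``; from it onward the change sets
    ``surv_delta`` to ±0.2 or ``migr_repro_factor`` to 0.8 (absolute values,
    so the operation is idempotent).
    """
    if scenario.change == "none" or generation < scenario.change_generation:
        return params
    if scenario.change == "resident_survival_up":
        return params.replace(surv_delta=0.2)
    if scenario.change == "resident_survival_down":
        return params.replace(surv_delta=-0.2)
    return params.replace(migr_repro_factor=0.8)


@dataclass
class ReplicateSet:
    """Per-scenario collection of replicate trajectories.

    ``zone`` holds one table per replicate with columns
    generation, polar_border, equatorial_border, width, midpoint,
    range_front, n_total, n_migrants, n_residents; ``per_x`` (optional) one
    long table per replicate with per-column counts and mean thresholds.
    """

    scenario: Scenario
    params: SimParams
    n_generations: int
    base_seed: int
    seeds: list[int] = field(default_factory=list)
    zone: list[pd.DataFrame] = field(default_factory=list)
    per_x: list[Optional[pd.DataFrame]] = field(default_factory=list)


def _zone_row(summ: GenerationSummary, direction: str, threshold_frac: float) -> dict:
    z = pm_zone(summ, threshold_frac)
    return {
        "generation": summ.generation,
        "polar_border": z.polar_border,
        "equatorial_border": z.equatorial_border,
        "width": z.width,
        "midpoint": z.midpoint,
        "range_front": range_front(summ, direction),
        "n_total": int(summ.n_individuals.sum()),
        "n_migrants": int(summ.n_migrants.sum()),
        "n_residents": int(summ.n_residents.sum()),
    }


def run_replicates(
    scenario: Scenario,
    params: SimParams,
    n_generations: int,
    base_seed: int,
    record_every: int = 1,
    collect_per_x: bool = False,
    threshold_frac: float = 0.01,
) -> ReplicateSet:
    """Run ``scenario.n_replicates`` independent seeded trajectories.

    Replicate i uses ``numpy.random.default_rng(base_seed + i)``; identical
    arguments therefore give bit-identical results. Summaries are recorded
    right after the migration decision of every ``record_every``-th
    generation (and of the last one).
    """
    if n_generations < scenario.change_generation and scenario.change != "none":
        raise ValueError("n_generations must cover change_generation")
    out = ReplicateSet(
        scenario=scenario,
        params=params,
        n_generations=n_generations,
        base_seed=base_seed,
    )
    for i in range(scenario.n_replicates):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        pop = init_population(scenario, params, rng)
        zone_rows: list[dict] = []
        perx_frames: list[pd.DataFrame] = []
        for g in range(n_generations):
            p_t = apply_change(params, scenario, g)
            pop = decide_step(pop, p_t, rng)
            if g % record_every == 0 or g == n_generations - 1:
                summ = summarize_generation(pop, p_t)
                zone_rows.append(_zone_row(summ, scenario.front_direction, threshold_frac))
                if collect_per_x:
                    perx_frames.append(summ.to_frame())
            pop = winter_step(pop, p_t, rng)
            pop = disperse_step(pop, p_t, rng)
            pop = reproduce_step(pop, p_t, rng)
        out.seeds.append(seed)
        out.zone.append(pd.DataFrame(zone_rows))
        out.per_x.append(pd.concat(perx_frames, ignore_index=True) if collect_per_x else None)
        logger.info(
            "scenario %s replicate %d/%d (seed %d): final population %d",
            scenario.name,
            i + 1,
            scenario.n_replicates,
            seed,
            pop.size,
        )
    return out
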