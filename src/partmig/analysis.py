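"""Summary statistics: per-column phenotype counts, the partial-migration
zone, the range front, and replicate aggregation.

The partial-migration (PM) zone is the band of x-columns whose populations
contain at least a small fraction (1% by default) of both phenotypes. Its
polar border is the smallest x-column where residents reach that fraction of
the column's individuals, the equatorial border the largest x-column where
migrants do; width and midpoint follow from the two borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .params import SimParams
from .population import MIGRANT, RESIDENT, UNDECIDED, Population

__all__ = [
    "GenerationSummary",
    "ZoneMetrics",
    "summarize_generation",
    "pm_zone",
    "range_front",
    "aggregate_replicates",
    "colonization_time",
]

#: statistics aggregated across replicates by :func:`aggregate_replicates`
ZONE_STATS = ("polar_border", "equatorial_border", "width", "midpoint", "range_front")


class ZoneMetrics(NamedTuple):
    polar_border: float
    equatorial_border: float
    width: float
    midpoint: float


@dataclass
class GenerationSummary:
    """Per-x-column totals for one generation.

    Arrays are indexed by column ``x - 1`` and have length ``x_max``.
    Individuals whose phenotype is still undecided (newborns at simulation
    end) are excluded from the phenotype counts but included in occupancy
    (``n_individuals``) and the threshold mean.
    """

    generation: int
    n_migrants: np.ndarray
    n_residents: np.ndarray
    n_individuals: np.ndarray
    mean_T: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.n_individuals.size + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "x": self.x,
                "n_migrants": self.n_migrants,
                "n_residents": self.n_residents,
                "mean_T": self.mean_T,
            }
        )


def summarize_generation(pop: Population, params: SimParams) -> GenerationSummary:
    """Sum phenotypes and average thresholds per x-column (over all y)."""
    xm = params.x_max
    col = pop.x - 1
    n_all = np.bincount(col, minlength=xm)
    n_mig = np.bincount(col[pop.phenotype == MIGRANT], minlength=xm)
    n_res = np.bincount(col[pop.phenotype == RESIDENT], minlength=xm)
    sum_T = np.bincount(col, weights=pop.T, minlength=xm)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_T = np.where(n_all > 0, sum_T / np.maximum(n_all, 1), np.nan)
    return GenerationSummary(
        generation=pop.generation,
        n_migrants=n_mig,
        n_residents=n_res,
        n_individuals=n_all,
        mean_T=mean_T,
    )


def pm_zone(summary: GenerationSummary, threshold_frac: float = 0.01) -> ZoneMetrics:
    """Borders, width and midpoint of the partial-migration zone.

    A column qualifies for the polar border when its residents are at least
    ``threshold_frac`` of the column's decided individuals (and at least one
    resident is present, which makes ``threshold_frac = 0`` the "any
    resident" limiting case); the equatorial border is symmetric for
    migrants. Undefined borders propagate as NaN.
    """
    tot = summary.n_migrants + summary.n_residents
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_res = np.where(tot > 0, summary.n_residents / np.maximum(tot, 1), np.nan)
        frac_mig = np.where(tot > 0, summary.n_migrants / np.maximum(tot, 1), np.nan)
    ok_res = (summary.n_residents >= 1) & (frac_res >= threshold_frac)
    ok_mig = (summary.n_migrants >= 1) & (frac_mig >= threshold_frac)
    polar = float(np.argmax(ok_res) + 1) if ok_res.any() else math.nan
    equat = float(ok_mig.size - np.argmax(ok_mig[::-1])) if ok_mig.any() else math.nan
    width = equat - polar
    midpoint = (polar + equat) / 2.0
    return ZoneMetrics(polar, equat, width, midpoint)


def range_front(
    summary: GenerationSummary,
    direction: str = "from_low_x",
    min_count: int = 1,
) -> float:
    """Most advanced occupied x-column relative to the initialization side.

    ``from_low_x`` (expansion starting at the polar edge) reports the largest
    occupied column; ``from_high_x`` the smallest. NaN on an empty landscape.
    """
    occ = summary.n_individuals >= min_count
    if not occ.any():
        return math.nan
    if direction == "from_low_x":
        return float(occ.size - np.argmax(occ[::-1]))
    if direction == "from_high_x":
        return float(np.argmax(occ) + 1)
    raise ValueError(f"unknown direction {direction!r}")


def aggregate_replicates(zone_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean and sample SD across replicates, per generation and statistic.

    Input tables must share the generation grid (one row per recorded
    generation, columns as written by the runner). Missing values (undefined
    borders) are excluded, with the contributing replicate count reported in
    the ``*_n`` columns.
    """
    if len(zone_tables) == 0:
        raise ValueError("no replicate tables to aggregate")
    gens = zone_tables[0]["generation"].to_numpy()
    for t in zone_tables[1:]:
        if not np.array_equal(t["generation"].to_numpy(), gens):
            raise ValueError("replicates do not share a common generation grid")
    out = {"generation": gens}
    for stat in ZONE_STATS:
        vals = np.column_stack([t[stat].to_numpy(dtype=float) for t in zone_tables])
        ok = ~np.isnan(vals)
        n_ok = ok.sum(axis=1)
        mean = np.where(ok, vals, 0.0).sum(axis=1) / np.maximum(n_ok, 1)
        mean = np.where(n_ok > 0, mean, np.nan)
        dev2 = np.where(ok, (vals - mean[:, None]) ** 2, 0.0).sum(axis=1)
        # sample SD; 0 for a singleton so aggregates stay numeric
        sd = np.where(n_ok > 1, np.sqrt(dev2 / np.maximum(n_ok - 1, 1)), 0.0)
        sd = np.where(n_ok == 0, np.nan, sd)
        out[f"{stat}_mean"] = mean
        out[f"{stat}_sd"] = sd
        out[f"{stat}_n"] = n_ok
    return pd.DataFrame(out)


def colonization_time(
    zone_table: pd.DataFrame, target: int, censor_at: int | None = None
) -> float:
    """First recorded generation at which the range front reaches ``target``.

    Returns ``censor_at`` (the run horizon) when the front never reaches the
    target and a censoring value is given, NaN otherwise.
    """
    front = zone_table["range_front"].to_numpy(dtype=float)
    gens = zone_table["generation"].to_numpy()
    hit = np.flatnonzero(front == target)
    if hit.size:
        return float(gens[hit[0]])
    return float(censor_at) if censor_at is not None else math.nan
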