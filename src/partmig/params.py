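"""Simulation parameters.

All demographic and landscape constants of the model live in a single frozen
dataclass so that a parameter set can be hashed, compared, and swapped
atomically when an environmental-change scenario kicks in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class SimParams:
    """Demographic, genetic and landscape parameters of the model.

    Parameters
    ----------
    K : int
        Carrying capacity — individuals per breeding patch entering the
        density terms of winter survival and reproduction.
    s_m : float
        Winter (migration) survival probability of a migrant; density
        independent.
    c_dens_s : float
        Strength of the density dependence of resident winter survival.
        1 means no density dependence; smaller values mean stronger
        suppression at high resident density.
    c_dens_r : float
        Strength of the density dependence of reproduction (same convention).
    c_loc_r : float
        Strength of the location dependence of reproduction: 1 means no
        dependence, 0 maximum dependence on the x position.
    m : float
        Per-offspring mutation probability of the migration threshold.
    d : float
        Per-survivor dispersal probability.
    delta : int
        Maximum dispersal distance in cells (Chebyshev radius).
    x_max, y_max : int
        Landscape extent; columns run pole-ward (x = 1) to equator-ward
        (x = x_max), each column holds ``y_max`` breeding patches.
    max_brood : int
        Upper bound of the discrete-uniform brood-size draw {0, ..., max_brood}.
    surv_delta : float
        Additive shift of the nominal resident winter-survival gradient
        (0.01·x + surv_delta, clamped to [0, 1]); ±0.2 under the
        environmental-change scenarios.
    migr_repro_factor : float
        Multiplicative factor on a migrant parent's offspring number; 0.8
        under the migrant-reproduction change scenario, 1 otherwise.
    """

    K: int = 100
    s_m: float = 0.5
    c_dens_s: float = 0.6
    c_dens_r: float = 0.4
    c_loc_r: float = 0.8
    m: float = 1e-4
    d: float = 0.1
    delta: int = 2
    x_max: int = 100
    y_max: int = 25
    max_brood: int = 6
    surv_delta: float = 0.0
    migr_repro_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_m", "c_dens_s", "c_dens_r", "c_loc_r", "m", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        for name in ("K", "delta", "x_max", "y_max", "max_brood"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 1):
                raise ValueError(f"{name}={v!r} must be an integer >= 1")
        if not -1.0 <= self.surv_delta <= 1.0:
            raise ValueError(f"surv_delta={self.surv_delta!r} must lie in [-1, 1]")
        if not 0.0 < self.migr_repro_factor <= 1.0:
            raise ValueError(
                f"migr_repro_factor={self.migr_repro_factor!r} must lie in (0, 1]"
            )

    @property
    def n_patches(self) -> int:
        return self.x_max * self.y_max

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
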