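"""Population state: flat arrays of individuals on the breeding landscape."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: phenotype codes; offspring are UNDECIDED until the next migration decision
UNDECIDED: int = 0
RESIDENT: int = 1
MIGRANT: int = 2


@dataclass
class Population:
    """All individuals alive at one point of the annual cycle.

    Individuals are stored as parallel arrays (struct-of-arrays) so every
    stage of a generation is a vectorized numpy operation.

    Attributes
    ----------
    x, y : ndarray of int
        1-based patch coordinates, ``1 <= x <= x_max``, ``1 <= y <= y_max``.
    T : ndarray of float
        Heritable migration threshold of each individual, in [0, 1].
    phenotype : ndarray of int8
        UNDECIDED, RESIDENT or MIGRANT; assigned by the decision stage and
        reset to UNDECIDED for newborn offspring.
    generation : int
        Discrete generation counter (0 at initialization).
    """

    x: np.ndarray
    y: np.ndarray
    T: np.ndarray
    phenotype: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int32)
        self.y = np.asarray(self.y, dtype=np.int32)
        self.T = np.asarray(self.T, dtype=np.float64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n = self.x.size
        if not (self.y.size == self.T.size == self.phenotype.size == n):
            raise ValueError("population arrays must have equal length")

    @classmethod
    def empty(cls, generation: int = 0) -> "Population":
        z = np.empty(0)
        return cls(x=z, y=z, T=z, phenotype=z, generation=generation)

    @property
    def size(self) -> int:
        return int(self.x.size)

    def patch_index(self, y_max: int) -> np.ndarray:
        """Flat 0-based patch id, column-major: (x-1)*y_max + (y-1)."""
        return (self.x.astype(np.int64) - 1) * y_max + (self.y.astype(np.int64) - 1)

    def take(self, mask_or_index: np.ndarray, generation: int | None = None) -> "Population":
        """Subset (or reorder) individuals; state otherwise unchanged."""
        g = self.generation if generation is None else generation
        return Population(
            x=self.x[mask_or_index],
            y=self.y[mask_or_index],
            T=self.T[mask_or_index],
            phenotype=self.phenotype[mask_or_index],
            generation=g,
        )

    def copy(self) -> "Population":
        return Population(
            x=self.x.copy(),
            y=self.y.copy(),
            T=self.T.copy(),
            phenotype=self.phenotype.copy(),
            generation=self.generation,
        )
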