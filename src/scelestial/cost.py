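"""Per-locus and per-sequence substitution costs.

The parsimony cost charges 0 for an unchanged genotype and 1 (the mismatch
cost) for any change.  Missing values get cost ``mismatch/2 + epsilon``
against every observed state and 0 against another missing value — the
midpoint placement that keeps the induced cost a triangle-inequality-
respecting function over the extended alphabet (setting the missing-observed
cost to 0 instead would break it: two observed states at distance 1 would
both sit at distance 0 from the missing state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotype import MISSING, N_OBSERVED, CellSequence

__all__ = ["CostModel", "DEFAULT_COST_MODEL"]

N_STATES = N_OBSERVED + 1  # observed states + missing


@dataclass(frozen=True)
class CostModel:
    """Symmetric per-locus cost over the 10 observed states plus missing.

    Parameters
    ----------
    epsilon:
        Small positive tie-break added to the missing-observed cost so that
        imputable placements are never exactly free; default 1e-5.
    mismatch_cost:
        Cost of a genotype change between observed states; default 1.
    match_cost:
        Cost of identical observed states; default 0.
    matrix:
        Optional full (11, 11) symmetric override, indexed by state code
        (missing = 10).  When given, the scalar parameters are ignored.
    """

    epsilon: float = 1e-5
    mismatch_cost: float = 1.0
    match_cost: float = 0.0
    matrix: Optional[np.ndarray] = None
    _table: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.matrix is not None:
            t = np.asarray(self.matrix, dtype=float)
            if t.shape != (N_STATES, N_STATES):
                raise ValueError(f"cost matrix must be {N_STATES}x{N_STATES}")
            if not np.allclose(t, t.T):
                raise ValueError("cost matrix must be symmetric")
            if t.min() < 0:
                raise ValueError("cost matrix must be nonnegative")
        else:
            if self.epsilon <= 0:
                raise ValueError("epsilon must be positive")
            if not self.mismatch_cost > self.match_cost >= 0:
                raise ValueError("need mismatch_cost > match_cost >= 0")
            t = np.full((N_STATES, N_STATES), self.mismatch_cost, dtype=float)
            np.fill_diagonal(t, self.match_cost)
            miss = self.mismatch_cost / 2.0 + self.epsilon
            t[MISSING, :] = miss
            t[:, MISSING] = miss
            t[MISSING, MISSING] = 0.0
        object.__setattr__(self, "_table", t)

    @property
    def table(self) -> np.ndarray:
        """The (11, 11) cost lookup table, indexed by state code."""
        return self._table

    @property
    def observed_table(self) -> np.ndarray:
        """The (11, 10) table restricted to observed second argument —
        leaf-to-internal costs in the small-parsimony DP (internal nodes
        never carry missing states)."""
        return self._table[:, :N_OBSERVED]

    def locus_cost(self, x: int, y: int) -> float:
        """Cost between two single-locus states (total, symmetric)."""
        return float(self._table[x, y])

    def sequence_cost(self, g1: CellSequence, g2: CellSequence) -> float:
        """Summed per-locus cost between two equal-length sequences."""
        if len(g1) != len(g2):
            raise ValueError(
                f"sequence length mismatch: {len(g1)} vs {len(g2)}"
            )
        return float(self._table[g1.states, g2.states].sum())

    def pairwise_costs(self, states: np.ndarray) -> np.ndarray:
        """All-pairs sequence costs for an (m, n) state grid -> (n, n)."""
        m, n = states.shape
        out = np.zeros((n, n))
        for j in range(n):
            out[:, j] = self._table[states.T, states[:, j]].sum(axis=1)
        return out

    def satisfies_triangle_inequality(self) -> bool:
        """Exhaustive check of c(x,z) <= c(x,y) + c(y,z) over all triples."""
        t = self._table
        via = t[:, :, None] + t[None, :, :]  # (x, y, z)
        return bool(np.all(t[:, None, :] <= via.min(axis=1)[:, None, :] + 1e-12))


DEFAULT_COST_MODEL = CostModel()
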