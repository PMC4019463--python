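"""Analytic model of the optimal pseudo-soma fraction.

Pseudo-somatic cells are propagule-eligible cells that nonetheless perform
most of the mutagenic work.  Allocating a fraction ``f`` of the multicell to
pseudo-soma trades off two things:

* resource acquisition — pseudo-soma gather resources at ``r`` times the
  quiescent-germ baseline rate ``b_g``, so the multicell's rate is
  ``b_g * (1 + f (r - 1))``;
* propagule integrity — a pseudo-somatic cell carries a destructive mutation
  with probability ``mu``, and the propagule is drawn uniformly from *all*
  cells (pseudo-soma are eligible by definition), so the probability of an
  undamaged propagule is ``1 - f mu``.

Expected fitness is the product of the two; it is concave in ``f`` for
``r > 1`` and ``mu > 0`` with the interior optimum

    f* = ((r - 1) - mu) / (2 mu (r - 1)),

clipped to [0, 1].  Pseudo-soma are never favoured without a resource
advantage (``r <= 1`` gives ``f* = 0``) and take over completely when work
carries no mutational cost (``mu = 0``, ``r > 1`` gives ``f* = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "expected_fitness", "optimal_fraction", "sweep"]


@dataclass(frozen=True)
class ModelParams:
    """mu: probability of a destructive mutation in a pseudo-somatic cell;
    r: pseudo-soma to quiescent-germ baseline resource-rate ratio;
    b_g: germ baseline rate (normalisation)."""

    mu: float
    r: float
    b_g: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.r < 0.0:
            raise ValueError("r must be non-negative")
        if self.b_g <= 0.0:
            raise ValueError("b_g must be positive")


def expected_fitness(f: float, params: ModelParams) -> float:
    """Multicell resource rate times the probability of an intact propagule."""
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError("pseudo-soma fraction f must lie in [0, 1]")
    return (1.0 + f * (params.r - 1.0)) * (1.0 - f * params.mu) * params.b_g


def optimal_fraction(params: ModelParams) -> float:
    """Closed-form argmax of :func:`expected_fitness` over f in [0, 1]."""
    mu, r = params.mu, params.r
    if r <= 1.0:
        return 0.0
    if mu == 0.0:
        return 1.0
    f = ((r - 1.0) - mu) / (2.0 * mu * (r - 1.0))
    return float(min(1.0, max(0.0, f)))


def sweep(mu_grid, r_grid) -> np.ndarray:
    """Optimal fraction surface over a (mu, r) grid; shape (len(mu), len(r))."""
    mu_grid = np.atleast_1d(np.asarray(mu_grid, dtype=float))
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if mu_grid.size == 0 or r_grid.size == 0:
        raise ValueError("grids must be nonempty")
    out = np.empty((len(mu_grid), len(r_grid)))
    for i, mu in enumerate(mu_grid):
        for j, r in enumerate(r_grid):
            out[i, j] = optimal_fraction(ModelParams(mu=mu, r=r))
    return out
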