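"""Competitive fitness from two-fluorophore co-culture counts.

A YFP-tagged strain grown against a GFP-tagged competitor changes the
ln(YFP/GFP) count ratio linearly in the number of generations of co-growth
when its per-generation fitness is constant; the fitness is the exponential
of the OLS slope of that regression, and strain fitness is reported relative
to the mean fitness of the reference strain's replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError


@dataclass
class CompetitionTimepoint:
    generations: float
    yfp_count: float
    gfp_count: float

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise DataError("generations must be >= 0")
        if self.yfp_count <= 0 or self.gfp_count <= 0:
            raise DataError("counts must be positive")


def estimate_generations(n_initial: float, n_final: float) -> float:
    """Number of population doublings between two cell-density measurements."""
    if n_initial <= 0 or n_final <= 0:
        raise DataError("cell densities must be positive")
    return math.log2(n_final / n_initial)


def competitive_fitness(timepoints: Sequence[CompetitionTimepoint]) -> float:
    """exp(slope) of the OLS regression of ln(YFP/GFP) on generations.

    With exactly two timepoints this reduces to
    exp(delta ln ratio / delta generations).  Only the count ratio enters,
    so rescaling both channels leaves the estimate unchanged.
    """
    if len(timepoints) < 2:
        raise DataError("need at least 2 timepoints")
    g = np.array([t.generations for t in timepoints], dtype=float)
    if np.ptp(g) == 0:
        raise DataError("identical generation values give a singular fit")
    y = np.log([t.yfp_count / t.gfp_count for t in timepoints])
    slope = np.polyfit(g, y, 1)[0]
    return float(np.exp(slope))


def relative_fitness(
    fitness_values: Sequence[float], reference_fitness_values: Sequence[float]
) -> np.ndarray:
    """Each fitness divided by the mean fitness of the reference replicates,
    so the reference's own relative values average to 1."""
    ref_mean = float(np.mean(reference_fitness_values))
    if ref_mean <= 0:
        raise DataError("reference mean fitness must be positive")
    return np.asarray(fitness_values, dtype=float) / ref_mean
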