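"""Library-scalability calculators.

Two back-of-envelope but load-bearing quantities for planning larger
screens: the expected number of unique double-barcoded diploids produced
by pooled mating plates, and the fraction of barcodes expected to be seen
at a given sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MatingPlan:
    """Pooled-mating plan: cells per plate and lower-bound efficiencies."""

    cells_per_plate: float = 1e10
    mating_efficiency: float = 0.081
    recombination_efficiency: float = 0.027
    n_plates: int = 1

    def __post_init__(self) -> None:
        if self.cells_per_plate <= 0 or self.n_plates <= 0:
            raise ValueError("counts must be positive")
        for eff in (self.mating_efficiency, self.recombination_efficiency):
            if not 0.0 < eff <= 1.0:
                raise ValueError("efficiencies must be in (0, 1]")


def predicted_complexity(plan: MatingPlan) -> float:
    """Expected unique double-barcoded diploids across the mating plates.

    cells/plate x mating efficiency x loxP-recombination efficiency x
    number of plates.  Linear in every argument.
    """
    return (
        plan.cells_per_plate
        * plan.mating_efficiency
        * plan.recombination_efficiency
        * plan.n_plates
    )


def detection_fraction(
    frequencies: Sequence[float], depth: float, k: int = 1
) -> float:
    """Expected fraction of barcodes sequenced to at least ``k`` reads.

    Reads per barcode are approximated as Poisson(depth * frequency) —
    exact in the many-barcodes, small-frequency regime of multinomial
    sampling.  Monotone increasing in depth, decreasing in k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValueError("frequencies must be a non-empty 1-d vector")
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("frequencies must be non-negative and sum to 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, depth * f).mean())
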