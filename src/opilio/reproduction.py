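"""Reproductive bookkeeping: yolk consumption, hatch counts, fecundity.

Deterministic arithmetic on embryo images and hatching logs: percent area
yolk (PAY) as an index of yolk consumption, hatch-count estimation from
dry-mass or volumetric subsamples, and per-female clutch summaries
(fecundity, hatching success, and the non-viable / unhatched percentages,
which partition 100% with hatching success by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ClutchOutcome",
    "percent_area_yolk",
    "clutch_summary",
    "pooled_mean_larval_mass",
    "estimate_count_by_mass",
    "estimate_count_by_volume",
]


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ClutchOutcome:
    """Final tally of one female's clutch after hatching completes.

    viable / nonviable: larvae that hatched and did / did not molt from the
    pre-zoeal to the first zoeal stage; unhatched: eggs remaining.
    """

    viable: int
    nonviable: int
    unhatched: int
    female_id: str = ""
    year: int = 0
    treatment: str = ""

    def __post_init__(self):
        if min(self.viable, self.nonviable, self.unhatched) < 0:
            raise ValueError("clutch counts must be non-negative")

    @property
    def total(self) -> int:
        return self.viable + self.nonviable + self.unhatched


def percent_area_yolk(yolk_area: float, egg_area: float) -> float:
    """PAY = 100 * yolk area / egg area, in [0, 100]."""
    if egg_area <= 0:
        raise ValueError("egg_area must be positive")
    if yolk_area < 0 or yolk_area > egg_area:
        raise ValueError("yolk_area must lie in [0, egg_area]")
    return 100.0 * yolk_area / egg_area


def clutch_summary(outcome: ClutchOutcome) -> dict[str, float]:
    """Fecundity (viable larvae hatched) and the three percentages.

    Hatching success, % non-viable and % unhatched all share the total
    estimated embryo count as denominator, so they sum to exactly 100.
    """
    total = outcome.total
    if total <= 0:
        raise ValueError("clutch total must be positive")
    return {
        "fecundity": float(outcome.viable),
        "hatching_success": 100.0 * outcome.viable / total,
        "pct_nonviable": 100.0 * outcome.nonviable / total,
        "pct_unhatched": 100.0 * outcome.unhatched / total,
    }


def pooled_mean_larval_mass(batch_masses, batch_counts) -> float:
    """Mean individual larval mass pooled over calibration batches.

    Each calibration batch is a counted set of larvae (typically 50) dried
    and weighed together; the pooled mean is total mass over total count.
    """
    masses = np.asarray(batch_masses, dtype=float)
    counts = np.asarray(batch_counts, dtype=float)
    if masses.size == 0 or masses.size != counts.size:
        raise ValueError("need matching, non-empty mass and count sequences")
    if (masses <= 0).any() or (counts <= 0).any():
        raise ValueError("masses and counts must be positive")
    return float(masses.sum() / counts.sum())


def estimate_count_by_mass(batch_dry_mass: float, mean_larval_mass: float) -> int:
    """Estimated larvae in a batch from its dry mass and mean individual mass."""
    if mean_larval_mass <= 0:
        raise ValueError("mean_larval_mass must be positive")
    if batch_dry_mass < 0:
        raise ValueError("batch_dry_mass must be non-negative")
    return _round_half_up(batch_dry_mass / mean_larval_mass)


def estimate_count_by_volume(subsample_counts, subsample_volume: float,
                             total_volume: float) -> int:
    """Estimated larvae from the mean concentration of volumetric subsamples."""
    counts = np.asarray(subsample_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one subsample count")
    if (counts < 0).any():
        raise ValueError("subsample counts must be non-negative")
    if subsample_volume <= 0 or total_volume <= 0:
        raise ValueError("volumes must be positive")
    return _round_half_up(counts.mean() / subsample_volume * total_volume)
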