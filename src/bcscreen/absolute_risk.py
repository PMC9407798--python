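"""Absolute risk over a fixed horizon with competing mortality.

Cause-specific cumulative incidence with piecewise-constant hazards: over
sub-intervals j of the age window, with baseline breast-cancer hazard
``h1*_j = incidence_j * (1 - AR)``, relative risk ``rr`` and competing
mortality ``h2_j``,

    risk = sum_j  [h1*_j rr / (h1*_j rr + h2_j)]
                  * (1 - exp(-(h1*_j rr + h2_j) dt_j))
                  * exp(-sum_{k<j} (h1*_k rr + h2_k) dt_k)

The per-band solution is exact for piecewise-constant hazards; no numerical
quadrature is involved. Fractional start ages split the first band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import HazardTable, ValidationError


@dataclass(frozen=True)
class AbsoluteRiskInput:
    """Inputs for one absolute-risk evaluation.

    ``rr`` is applied age-constant across the window; ``ar`` is the
    attributable-risk fraction used to deflate composite incidence to the
    baseline hazard.
    """

    age_start: float
    horizon: float
    rr: float
    hazards: HazardTable
    ar: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValidationError("horizon must be > 0")
        if self.rr <= 0:
            raise ValidationError("relative risk must be > 0")
        if not (0.0 <= self.ar < 1.0):
            raise ValidationError("attributable risk fraction must lie in [0, 1)")


def absolute_risk(inp: AbsoluteRiskInput) -> float:
    """Probability of breast cancer in [age_start, age_start + horizon).

    Deterministic; exact per-band closed form. Raises if the hazard table
    does not cover the window.
    """
    log_surv = 0.0
    risk = 0.0
    for dt, h1, h2 in inp.hazards.segments(inp.age_start, inp.horizon):
        h1_star = h1 * (1.0 - inp.ar) * inp.rr
        total = h1_star + h2
        if total > 0.0:
            risk += (
                (h1_star / total)
                * (1.0 - math.exp(-total * dt))
                * math.exp(log_surv)
            )
        log_surv -= total * dt
    return risk


def population_average_risk(
    age: float, hazards: HazardTable, horizon: float = 5.0
) -> float:
    """Absolute risk of a same-age woman in the general population.

    Evaluates the raw incidence (rr = 1, AR = 0); shown beside the personal
    risk in the comparison pictogram.
    """
    return absolute_risk(
        AbsoluteRiskInput(age_start=age, horizon=horizon, rr=1.0, hazards=hazards, ar=0.0)
    )
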