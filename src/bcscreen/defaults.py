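"""Bundled default tables: hazards, relative risks, and an example SNP panel.

These defaults make the whole pipeline runnable offline and are explicitly
replaceable: any real deployment should inject registry hazard tables and the
published risk-model coefficients through the same CSV interfaces.

The default hazard table is synthetic but anchored to the screening policy's
semantics: its population-average 5-year risks at ages 60 and 65 equal
1.16% and 1.19% — the age-conditional annual-screening thresholds, which are
defined as the average risks of 60- and 65-year-old women. Competing
mortality follows a Gompertz curve typical of adult female all-cause
mortality net of breast cancer.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import HazardTable, RelativeRiskTable, SnpPanel

#: 5-year population risks the default hazard table is calibrated to, at the
#: ages whose average risks define the annual-screening thresholds.
ANNUAL_THRESHOLD_ANCHORS = {60: 0.0116, 65: 0.0119}

_MORT_A = 6.0e-4  # competing mortality at age 40, deaths / person-year
_MORT_B = 0.085   # Gompertz log-slope per year of age


def _competing_mortality(age_band_start: np.ndarray) -> np.ndarray:
    # hazard at band midpoint, constant within the band
    mid = age_band_start + 0.5
    return _MORT_A * np.exp(_MORT_B * (mid - 40.0))


def _five_year_risk_constant_incidence(h1: float, h2: np.ndarray) -> float:
    """5-year cause-specific cumulative incidence with constant h1 and
    year-by-year competing mortality h2 (length 5)."""
    surv = 1.0
    total = 0.0
    for m in h2:
        h = h1 + m
        if h > 0:
            total += surv * (h1 / h) * (1.0 - np.exp(-h))
        surv *= np.exp(-h)
    return total


@lru_cache(maxsize=1)
def default_hazard_table() -> HazardTable:
    """Synthetic Southern-European-style hazard table on ages [40, 90).

    Incidence rises linearly from 0.0012/year at 40, is constant on [60, 65)
    and [65, 70) at levels solved numerically so that the population 5-year
    risks at 60 and 65 are exactly 1.16% and 1.19%, and plateaus thereafter.
    """
    starts = np.arange(40, 90)
    h2 = _competing_mortality(starts)

    def solve(target: float, age: int) -> float:
        m = h2[age - 40 : age - 35]
        return brentq(
            lambda h1: _five_year_risk_constant_incidence(h1, m) - target,
            1e-6,
            0.05,
            xtol=1e-14,
        )

    h1_60 = solve(ANNUAL_THRESHOLD_ANCHORS[60], 60)
    h1_65 = solve(ANNUAL_THRESHOLD_ANCHORS[65], 65)

    h1 = np.empty_like(h2)
    # linear ramp 40 -> 55, then linear join onto the calibrated 60-64 level
    h1[:15] = np.interp(starts[:15] + 0.0, [40, 50, 55], [0.0012, 0.0020, 0.00225])
    h1[15:20] = np.interp(starts[15:20] + 0.0, [55, 60], [0.00225, h1_60])
    h1[20:25] = h1_60
    h1[25:30] = h1_65
    h1[30:] = h1_65  # plateau through old age
    return HazardTable(starts, h1, h2)


# BCSC-v2-style multiplicative relative risks versus the lowest-risk
# category of each factor. Values are implementer-transcribed approximations
# of the published coefficient scale, shipped as an editable default; every
# test requiring exactness uses synthetic tables instead. Prevalences are the
# study-population marginals, so the attributable-risk correction calibrates
# model-average risk to the raw incidence of that population.
_DEFAULT_RR_ROWS = [
    # factor, category, rr, prevalence
    ("density", "a", 1.00, 0.147),
    ("density", "b", 1.70, 0.307),
    ("density", "c", 2.60, 0.446),
    ("density", "d", 3.35, 0.100),
    ("family_history", "no", 1.00, 0.902),
    ("family_history", "yes", 1.75, 0.098),
    ("benign_disease", "none", 1.00, 0.861),
    ("benign_disease", "non-proliferative", 1.25, 0.059),
    ("benign_disease", "unspecified-benign", 1.35, 0.080),
    ("benign_disease", "proliferative", 1.60, 0.000),
    ("benign_disease", "atypia", 3.00, 0.000),
    ("ethnicity", "white/other", 1.00, 1.000),
]


@lru_cache(maxsize=1)
def default_rr_table() -> RelativeRiskTable:
    frame = pd.DataFrame(
        _DEFAULT_RR_ROWS, columns=["factor", "category", "rr", "prevalence"]
    )
    frame["age_group"] = "all"
    return RelativeRiskTable(frame)


def example_panel(n_snps: int = 83, seed: int = 830) -> SnpPanel:
    """A deterministic example SNP panel of common breast-cancer-scale loci.

    Stands in for a published susceptibility panel, whose identities and
    effect sizes must be supplied through the panel CSV for real use.
    """
    from .synthetic import generate_panel

    return generate_panel(n_snps=n_snps, seed=seed)
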