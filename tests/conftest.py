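"""Shared fixtures: small synthetic tables with hand-checkable values."""

import numpy as np
import pandas as pd
import pytest

from bcscreen import HazardTable, RelativeRiskTable, RiskFactorProfile, SnpPanel


@pytest.fixture
def simple_rr_table() -> RelativeRiskTable:
    """Two-level density and family-history factors with easy products."""
    return RelativeRiskTable(
        pd.DataFrame(
            [
                ("density", "a", 1.0, 0.5),
                ("density", "c", 1.5, 0.5),
                ("family_history", "no", 1.0, 0.8),
                ("family_history", "yes", 2.0, 0.2),
                ("benign_disease", "none", 1.0, 1.0),
                ("ethnicity", "white/other", 1.0, 1.0),
            ],
            columns=["factor", "category", "rr", "prevalence"],
        )
    )


@pytest.fixture
def flat_hazards() -> HazardTable:
    """Constant incidence 0.002/y and competing mortality 0.003/y on [40, 90)."""
    starts = np.arange(40, 90)
    return HazardTable(starts, np.full(50, 0.002), np.full(50, 0.003))


@pytest.fixture
def profile_c_famhx() -> RiskFactorProfile:
    return RiskFactorProfile(
        woman_id="w1", age=45.0, family_history=True, benign_disease="none", density="c"
    )


@pytest.fixture
def reference_profile() -> RiskFactorProfile:
    return RiskFactorProfile(
        woman_id="w0", age=45.0, family_history=False, benign_disease="none", density="a"
    )


@pytest.fixture
def tiny_panel() -> SnpPanel:
    """Two SNPs with per-SNP likelihood ratios computable by hand."""
    return SnpPanel(
        pd.DataFrame(
            {
                "snp_id": ["rsA", "rsB"],
                "risk_allele_frequency": [0.3, 0.3],
                "per_allele_odds_ratio": [1.2, 1.2],
            }
        )
    )


def forward_integration_risk(age_start, horizon, rr, hazards, ar, step=1e-4):
    """Independent fine-grid oracle for the cause-specific cumulative
    incidence: trapezoidal quadrature of integral h1*(t) S(t) dt on a grid
    of width <= ``step``, split at the 1-year band boundaries so the
    integrand is smooth on every panel."""
    boundaries = [age_start]
    next_int = np.floor(age_start) + 1
    while next_int < age_start + horizon - 1e-12:
        boundaries.append(next_int)
        next_int += 1
    boundaries.append(age_start + horizon)

    risk = 0.0
    cumhaz = 0.0
    i0 = int(hazards.age_band_start[0])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        band = int(np.floor(lo + 1e-12)) - i0
        h1 = hazards.incidence[band] * (1.0 - ar) * rr
        h2 = hazards.competing_mortality[band]
        n_sub = max(1, int(np.ceil((hi - lo) / step)))
        t = np.linspace(0.0, hi - lo, n_sub + 1)
        integrand = h1 * np.exp(-(cumhaz + (h1 + h2) * t))
        risk += np.trapezoid(integrand, t)
        cumhaz += (h1 + h2) * (hi - lo)
    return risk
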