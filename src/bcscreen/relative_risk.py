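"""Multiplicative relative risk and the attributable-risk correction.

A woman's combined relative risk is the product of her per-factor relative
risks versus the lowest-risk profile. The attributable-risk fraction AR
rescales composite incidence to the baseline (all-reference) hazard via
``h1* = incidence * (1 - AR)``, with ``1 - AR = 1 / E[rr]`` where the
expectation runs over the population category distribution (factors taken
independent, joint = product of marginals).
"""

from __future__ import annotations

from .types import RelativeRiskTable, RiskFactorProfile, ValidationError

#: Maps profile attributes to (factor name, category extractor).
_PROFILE_FACTORS = {
    "density": lambda p: p.density,
    "family_history": lambda p: "yes" if p.family_history else "no",
    "benign_disease": lambda p: p.benign_disease,
    "ethnicity": lambda p: p.ethnicity,
}


def combined_relative_risk(
    profile: RiskFactorProfile,
    table: RelativeRiskTable,
    age_group: str = "all",
) -> float:
    """Product of the per-factor relative risks for the woman's categories.

    Equals 1.0 for the all-reference profile. Requires non-missing density.
    """
    if profile.density_missing:
        raise ValidationError(
            f"woman {profile.woman_id!r}: density missing, "
            "combined relative risk undefined"
        )
    rr = 1.0
    for factor in table.factors:
        if factor not in _PROFILE_FACTORS:
            raise ValidationError(
                f"relative-risk table factor {factor!r} has no profile field"
            )
        category = _PROFILE_FACTORS[factor](profile)
        rr *= table.rr(factor, category, age_group)
    return rr


def expected_relative_risk(table: RelativeRiskTable, age_group: str = "all") -> float:
    """Population mean of the combined rr under independent factor marginals."""
    expectation = 1.0
    for factor in table.factors:
        cats = table.categories(factor, age_group)
        expectation *= float((cats["rr"] * cats["prevalence"]).sum())
    return expectation


def attributable_risk_fraction(
    table: RelativeRiskTable, age_group: str = "all"
) -> float:
    """AR with ``1 - AR = 1 / E[rr]``; 0 when all relative risks are 1."""
    return 1.0 - 1.0 / expected_relative_risk(table, age_group)
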