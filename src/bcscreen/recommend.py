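"""Screening recommendations from final 5-year risk and age, plus the
per-woman risk-communication report and the reclassification table.

Thresholds are percentages with strict inequality ("higher than"). Annual
screening is age-conditional: the cut is 1.16% for women aged 40-44 and
1.19% otherwise — the average 5-year risks of 60- and 65-year-old women.
Watch-and-wait (defer to the population program invitation at 50) is never
issued at age >= 50; it is replaced by triennial screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import RECOMMENDATION_ORDER, RiskResult, ValidationError


@dataclass(frozen=True)
class ThresholdPolicy:
    """Risk thresholds (percent) mapping final 5-year risk to a category.

    The referral and annual cut-offs follow the study policy. The biennial
    and triennial cut-offs are placeholders bracketing the observed risk
    quartiles of those groups; any real deployment must set them from its
    own screening protocol.
    """

    referral_above: float = 6.0
    annual_above_age_40_44: float = 1.16
    annual_above_otherwise: float = 1.19
    biennial_above: float = 0.80
    triennial_above: float = 0.40
    min_age_watch_wait_forbidden: float = 50.0

    def __post_init__(self) -> None:
        annual_min = min(self.annual_above_age_40_44, self.annual_above_otherwise)
        if not (
            self.referral_above
            > max(self.annual_above_age_40_44, self.annual_above_otherwise)
            and annual_min > self.biennial_above > self.triennial_above > 0.0
        ):
            raise ValidationError(
                "thresholds must satisfy referral > annual > biennial > triennial > 0"
            )

    def annual_threshold(self, age: float) -> float:
        # the lower cut applies on the closed-open age band [40, 45)
        if 40.0 <= age < 45.0:
            return self.annual_above_age_40_44
        return self.annual_above_otherwise


def recommend(risk_post: float, age: float, policy: ThresholdPolicy | None = None) -> str:
    """First matching band top-down: referral, annual, biennial, triennial,
    watch_wait — with watch_wait replaced by triennial at age >= 50."""
    if policy is None:
        policy = ThresholdPolicy()
    if not (0.0 <= risk_post <= 1.0):
        raise ValidationError(f"risk {risk_post} outside [0, 1]")
    pct = risk_post * 100.0
    if pct > policy.referral_above:
        return "referral"
    if pct > policy.annual_threshold(age):
        return "annual"
    if pct > policy.biennial_above:
        return "biennial"
    if pct > policy.triennial_above:
        return "triennial"
    if age >= policy.min_age_watch_wait_forbidden:
        return "triennial"
    return "watch_wait"


def reclassification_table(
    results_without_prs: Sequence[RiskResult],
    results_with_prs: Sequence[RiskResult],
):
    """Cross-tabulate recommendation categories before vs after the PRS.

    Returns ``(table, off_diagonal_fraction)`` where ``table`` is a square
    DataFrame (rows = without PRS, columns = with PRS) over all categories.
    """
    before = {r.woman_id: r.recommendation for r in results_without_prs}
    after = {r.woman_id: r.recommendation for r in results_with_prs}
    if set(before) != set(after):
        only_b = sorted(set(before) - set(after))[:5]
        only_a = sorted(set(after) - set(before))[:5]
        raise ValidationError(
            f"woman ids differ between result sets (e.g. only-before={only_b}, "
            f"only-after={only_a})"
        )
    if not before:
        raise ValidationError("empty result lists")
    cats = list(RECOMMENDATION_ORDER)
    table = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    moved = 0
    for wid, b in before.items():
        a = after[wid]
        table.loc[b, a] += 1
        moved += b != a
    return table, moved / len(before)


def risk_report(result: RiskResult, denominator: int = 1000) -> str:
    """Plain-text analog of the two risk-communication pictograms.

    Renders the personal and same-age population risks as counts out of
    ``denominator`` women (rounded to the nearest integer), plus the
    recommendation sentence.
    """
    personal = round(result.risk_post * denominator)
    population = round(result.pop_risk * denominator)
    sentences = {
        "referral": "Referral to the hospital breast unit for intensified follow-up.",
        "annual": "Annual screening mammogram recommended.",
        "biennial": "Biennial screening mammogram recommended.",
        "triennial": "Triennial screening mammogram recommended.",
        "watch_wait": (
            "Watch and wait: screening will start with the population "
            "program invitation at age 50."
        ),
    }
    return (
        f"Woman {result.woman_id}\n"
        f"  Your 5-year breast cancer risk: {result.risk_post * 100:.2f}% "
        f"({personal} of {denominator} women like you)\n"
        f"  Average risk at your age: {result.pop_risk * 100:.2f}% "
        f"({population} of {denominator} women your age)\n"
        f"  Recommendation: {sentences[result.recommendation]}"
    )
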