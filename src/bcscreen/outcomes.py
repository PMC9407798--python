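"""Primary-outcome scoring and trial statistics.

Attitude is a three-item 1-5 scale summed to 3-15, "positive" when the total
is >= 12. Intention to participate is dichotomized as definitely-will or
likely (levels 1-2) versus the rest. Proportions get exact (Clopper-Pearson)
binomial confidence intervals; missing responses are never imputed and
denominators always report the non-missing count.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import SurveyResponse, ValidationError

POSITIVE_ATTITUDE_THRESHOLD = 12
#: Intention levels counted as intending to participate (definitely / likely).
INTENDING_LEVELS = (1, 2)

LIKERT_ITEMS = ("attitude_1", "attitude_2", "attitude_3", "intention", "satisfaction")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as the summary tables do."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def attitude_score(items: Sequence[int]) -> tuple[int, bool]:
    """Sum of the three attitude items and whether it crosses the positive
    threshold (score >= 12). Undefined if any item is missing."""
    if len(items) != 3:
        raise ValidationError("attitude scale has exactly 3 items")
    if any(v is None for v in items):
        raise ValidationError("attitude score undefined with missing items")
    if any(v not in (1, 2, 3, 4, 5) for v in items):
        raise ValidationError("attitude items must lie in 1..5")
    score = int(sum(items))
    return score, score >= POSITIVE_ATTITUDE_THRESHOLD


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson interval for a proportion, in percent (unrounded).

    Obtained by inverting the exact binomial tail probabilities; round to
    one decimal for table display.
    """
    if trials <= 0:
        raise ValidationError("trials must be > 0")
    if not (0 <= successes <= trials):
        raise ValidationError("successes must lie in [0, trials]")
    ci = stats.binomtest(successes, trials).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return ci.low * 100.0, ci.high * 100.0


def sample_size_for_proportion(
    half_width: float, confidence: float = 0.95, p: float = 0.5
) -> int:
    """Smallest n with a normal-approximation CI half-width at most the
    target: ceil(z^2 p (1-p) / half_width^2)."""
    if not (0.0 < half_width < 1.0):
        raise ValidationError("half_width must lie in (0, 1)")
    if not (0.0 < p < 1.0):
        raise ValidationError("p must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.ceil(z * z * p * (1.0 - p) / (half_width * half_width))


def _item_values(responses: Sequence[SurveyResponse], item: str) -> list[int]:
    if item not in LIKERT_ITEMS:
        raise ValidationError(
            f"unknown item {item!r}; known items: {', '.join(LIKERT_ITEMS)}"
        )
    if item.startswith("attitude_"):
        idx = int(item[-1]) - 1
        values = [r.attitude_items[idx] for r in responses]
    else:
        values = [getattr(r, item) for r in responses]
    return [v for v in values if v is not None]


def likert_summary(responses: Sequence[SurveyResponse], item: str) -> dict:
    """Frequency table with percentages (one decimal), n, median and
    quartiles for one Likert item, over non-missing values."""
    values = _item_values(responses, item)
    n = len(values)
    counts = {level: values.count(level) for level in (1, 2, 3, 4, 5)}
    percentages = {
        level: (round_half_up(100.0 * c / n, 1) if n else float("nan"))
        for level, c in counts.items()
    }
    arr = np.array(values, dtype=float)
    quartiles = (
        tuple(np.percentile(arr, [25, 50, 75])) if n else (math.nan,) * 3
    )
    return {
        "item": item,
        "n": n,
        "counts": counts,
        "percentages": percentages,
        "q1": quartiles[0],
        "median": quartiles[1],
        "q3": quartiles[2],
    }


def attitude_positivity(
    responses: Sequence[SurveyResponse], confidence: float = 0.95
) -> dict:
    """Positive-attitude proportion with exact CI over women whose score is
    defined (all three items answered)."""
    scores = [
        attitude_score(r.attitude_items)
        for r in responses
        if r.attitude_complete
    ]
    n = len(scores)
    positives = sum(1 for _, pos in scores if pos)
    out = {"n": n, "positive": positives}
    if n:
        lo, hi = exact_binomial_ci(positives, n, confidence)
        out.update(
            proportion_pct=round_half_up(100.0 * positives / n, 1),
            ci_low_pct=round_half_up(lo, 1),
            ci_high_pct=round_half_up(hi, 1),
        )
    return out


def intention_to_participate(
    responses: Sequence[SurveyResponse], confidence: float = 0.95
) -> dict:
    """Intending-to-participate proportion (levels 1-2) with exact CI."""
    values = _item_values(responses, "intention")
    n = len(values)
    intending = sum(1 for v in values if v in INTENDING_LEVELS)
    out = {"n": n, "intending": intending}
    if n:
        lo, hi = exact_binomial_ci(intending, n, confidence)
        out.update(
            proportion_pct=round_half_up(100.0 * intending / n, 1),
            ci_low_pct=round_half_up(lo, 1),
            ci_high_pct=round_half_up(hi, 1),
        )
    return out


def attitude_score_summary(responses: Sequence[SurveyResponse]) -> dict:
    """Median and quartiles of the 3-15 attitude score over complete scales."""
    scores = [
        attitude_score(r.attitude_items)[0] for r in responses if r.attitude_complete
    ]
    n = len(scores)
    if not n:
        return {"n": 0, "q1": math.nan, "median": math.nan, "q3": math.nan}
    q1, med, q3 = np.percentile(np.array(scores, dtype=float), [25, 50, 75])
    return {"n": n, "q1": q1, "median": med, "q3": q3}


def outcomes_summary(
    responses: Sequence[SurveyResponse], confidence: float = 0.95
) -> dict:
    """Primary-outcome block: attitude score distribution and positivity,
    intention proportion, satisfaction distribution — each with its own
    non-missing denominator."""
    return {
        "attitude_score": attitude_score_summary(responses),
        "positive_attitude": attitude_positivity(responses, confidence),
        "intention": intention_to_participate(responses, confidence),
        "intention_levels": likert_summary(responses, "intention"),
        "satisfaction": likert_summary(responses, "satisfaction"),
    }
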