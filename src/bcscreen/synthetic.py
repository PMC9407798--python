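"""Synthetic cohort generator.

Emulates a 40-50-year-old screening-trial population: risk-factor marginals
(BI-RADS density 14.7/30.7/44.6/10.0%, family history 9.8%, benign lesions
86.1/5.9/8.0% none/non-proliferative/unspecified), Hardy-Weinberg genotypes
for a configurable SNP panel drawn independently of the classical factors,
and Likert survey responses whose marginals echo the trial's primary-outcome
tables. Ages follow a left-skewed Beta(5, 1.3) on [40, 50) so the median
sits near 48.4 years.

One global seed governs every draw: the seed is split into independent
child streams (factors, genotypes, survey) with numpy's SeedSequence
spawning, so each stage is separately reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    BENIGN_CATEGORIES,
    DENSITY_CATEGORIES,
    RiskFactorProfile,
    SnpPanel,
    SurveyResponse,
    ValidationError,
)

_PROB_TOL = 1e-9

#: Survey marginals over Likert levels 1..5, echoing the trial's tables:
#: two favourable attitude items (median 5), one lukewarm item (median 4,
#: Q1 2), intention heavily at "definitely will", satisfaction mass at 5.
DEFAULT_SURVEY_PROBS = {
    "attitude_1": (0.02, 0.04, 0.10, 0.30, 0.54),
    "attitude_2": (0.02, 0.04, 0.10, 0.30, 0.54),
    "attitude_3": (0.12, 0.15, 0.18, 0.35, 0.20),
    "intention": (0.635, 0.282, 0.061, 0.015, 0.007),
    "satisfaction": (0.003, 0.000, 0.026, 0.110, 0.861),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n: int = 387
    seed: int = 0
    age_range: tuple = (40.0, 50.0)
    density_probs: tuple = (0.147, 0.307, 0.446, 0.100)
    family_history_prob: float = 0.098
    benign_probs: tuple = (0.861, 0.059, 0.080)  # none, non-proliferative, unspecified
    density_missing_prob: float = 0.016
    survey_probs: dict = field(default_factory=lambda: dict(DEFAULT_SURVEY_PROBS))
    survey_missing_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("cohort size n must be > 0")
        for name, probs in (
            ("density_probs", self.density_probs),
            ("benign_probs", self.benign_probs),
            *((k, v) for k, v in self.survey_probs.items()),
        ):
            probs = np.asarray(probs, dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise ValidationError(
                    f"probability vector {name!r} must be non-negative and sum to 1"
                )
        for name in ("family_history_prob", "density_missing_prob", "survey_missing_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 89.0):
            raise ValidationError("age_range must be increasing within [18, 89]")


def generate_panel(
    n_snps: int = 83,
    seed: int = 830,
    freq_range: tuple = (0.10, 0.90),
    or_range: tuple = (1.02, 1.20),
) -> SnpPanel:
    """Reproducible SNP panel with common risk alleles of modest effect.

    Frequencies are uniform on ``freq_range`` and per-allele odds ratios
    uniform on ``or_range`` — the effect-size scale typical of genome-wide
    significant breast-cancer susceptibility loci. For an 83-SNP panel the
    defaults give a composite likelihood ratio with log-scale spread close
    to the interquartile range observed in the trial population.
    """
    if n_snps <= 0:
        raise ValidationError("n_snps must be > 0")
    f_lo, f_hi = freq_range
    o_lo, o_hi = or_range
    if not (0.0 < f_lo <= f_hi < 1.0):
        raise ValidationError("freq_range must lie strictly inside (0, 1)")
    if not (0.0 < o_lo <= o_hi):
        raise ValidationError("or_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    return SnpPanel(
        pd.DataFrame(
            {
                "snp_id": [f"snp{i + 1:03d}" for i in range(n_snps)],
                "risk_allele_frequency": rng.uniform(f_lo, f_hi, n_snps),
                "per_allele_odds_ratio": rng.uniform(o_lo, o_hi, n_snps),
            }
        )
    )


def _draw_ages(rng: np.random.Generator, n: int, age_range: tuple) -> np.ndarray:
    lo, hi = age_range
    return lo + (hi - lo) * rng.beta(5.0, 1.3, size=n)


def generate_cohort(
    spec: CohortSpec, panel: Optional[SnpPanel] = None
) -> tuple[list, pd.DataFrame, list]:
    """Generate profiles, a genotype matrix, and survey responses.

    Returns ``(profiles, genotypes, surveys)``: a list of
    :class:`RiskFactorProfile`, a (women x SNPs) DataFrame of allele counts
    indexed by woman id (NaN for missing — none are generated by default),
    and a list of :class:`SurveyResponse`. Genotypes are per-SNP
    Binomial(2, p) draws (HWE), independent across SNPs and of the classical
    factors. Identical spec and seed give identical output.
    """
    if panel is None:
        panel = generate_panel()
    factors_ss, geno_ss, survey_ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng = np.random.default_rng(factors_ss)

    n = spec.n
    ids = [f"w{i + 1:05d}" for i in range(n)]
    ages = _draw_ages(rng, n, spec.age_range)
    densities = rng.choice(np.array(DENSITY_CATEGORIES), size=n, p=spec.density_probs)
    density_missing = rng.random(n) < spec.density_missing_prob
    famhx = rng.random(n) < spec.family_history_prob
    benign_cats = np.array(BENIGN_CATEGORIES[:3])
    benign = rng.choice(benign_cats, size=n, p=spec.benign_probs)

    profiles = [
        RiskFactorProfile(
            woman_id=ids[i],
            age=float(ages[i]),
            family_history=bool(famhx[i]),
            benign_disease=str(benign[i]),
            density=None if density_missing[i] else str(densities[i]),
        )
        for i in range(n)
    ]

    geno_rng = np.random.default_rng(geno_ss)
    counts = geno_rng.binomial(2, panel.frequencies, size=(n, len(panel))).astype(float)
    genotypes = pd.DataFrame(counts, index=pd.Index(ids, name="woman_id"),
                             columns=panel.snp_ids)

    surveys = _generate_surveys(np.random.default_rng(survey_ss), ids, spec)
    return profiles, genotypes, surveys


def _generate_surveys(
    rng: np.random.Generator, ids: Sequence[str], spec: CohortSpec
) -> list:
    levels = np.arange(1, 6)
    draws = {
        item: rng.choice(levels, size=len(ids), p=np.asarray(probs, dtype=float))
        for item, probs in spec.survey_probs.items()
    }
    missing = {
        item: rng.random(len(ids)) < spec.survey_missing_prob
        for item in spec.survey_probs
    }

    def value(item: str, i: int):
        return None if missing[item][i] else int(draws[item][i])

    return [
        SurveyResponse(
            woman_id=wid,
            attitude_items=(
                value("attitude_1", i),
                value("attitude_2", i),
                value("attitude_3", i),
            ),
            intention=value("intention", i),
            satisfaction=value("satisfaction", i),
        )
        for i, wid in enumerate(ids)
    ]
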