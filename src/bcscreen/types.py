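"""Core domain types shared by every pipeline stage.

Risks are stored as fractions everywhere inside the package and rendered as
percentages only at output boundaries (reports, result files).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DENSITY_CATEGORIES = ("a", "b", "c", "d")
BENIGN_CATEGORIES = (
    "none",
    "non-proliferative",
    "unspecified-benign",
    "proliferative",
    "atypia",
)
#: Screening recommendation categories, ordered from most to least intensive.
RECOMMENDATION_ORDER = ("referral", "annual", "biennial", "triennial", "watch_wait")

MODEL_AGE_MIN = 18.0
MODEL_AGE_MAX = 89.0


class ValidationError(ValueError):
    """A domain object or input table failed validation."""


@dataclass(frozen=True)
class RiskFactorProfile:
    """One woman's classical breast-cancer risk factors.

    Parameters
    ----------
    woman_id : str
        Opaque identifier.
    age : float
        Age in decimal years; the model supports 18-89.
    family_history : bool
        At least one first-degree relative with breast cancer.
    benign_disease : str
        One of :data:`BENIGN_CATEGORIES`.
    density : str or None
        BI-RADS density ``a``-``d``. ``None`` marks missing density; such
        women are excluded from risk estimation and reported, not imputed.
    ethnicity : str
        Race/ethnicity category; a single reference category by default.
    """

    woman_id: str
    age: float
    family_history: bool
    benign_disease: str = "none"
    density: Optional[str] = None
    ethnicity: str = "white/other"

    def __post_init__(self) -> None:
        if not (MODEL_AGE_MIN <= self.age <= MODEL_AGE_MAX):
            raise ValidationError(
                f"age {self.age} outside model support "
                f"[{MODEL_AGE_MIN:g}, {MODEL_AGE_MAX:g}]"
            )
        if self.benign_disease not in BENIGN_CATEGORIES:
            raise ValidationError(
                f"unknown benign-disease category {self.benign_disease!r}; "
                f"allowed: {', '.join(BENIGN_CATEGORIES)}"
            )
        if self.density is not None and self.density not in DENSITY_CATEGORIES:
            raise ValidationError(
                f"unknown density category {self.density!r}; "
                f"allowed: {', '.join(DENSITY_CATEGORIES)} or missing"
            )

    @property
    def density_missing(self) -> bool:
        return self.density is None


class HazardTable:
    """Age-banded cause-specific hazards on closed-open 1-year bands [a, a+1).

    Parameters
    ----------
    age_band_start : sequence of int
        Start of each 1-year band; bands must be contiguous and cover at
        least ages [40, 90).
    incidence : sequence of float
        Breast-cancer incidence, events per person-year (h1).
    competing_mortality : sequence of float
        Mortality from causes other than breast cancer, deaths per
        person-year (h2).
    """

    def __init__(
        self,
        age_band_start: Sequence[int],
        incidence: Sequence[float],
        competing_mortality: Sequence[float],
    ) -> None:
        starts = np.asarray(age_band_start, dtype=int)
        h1 = np.asarray(incidence, dtype=float)
        h2 = np.asarray(competing_mortality, dtype=float)
        if not (len(starts) == len(h1) == len(h2)):
            raise ValidationError("hazard table columns have unequal lengths")
        if len(starts) == 0:
            raise ValidationError("hazard table is empty")
        order = np.argsort(starts)
        starts, h1, h2 = starts[order], h1[order], h2[order]
        if np.any(np.diff(starts) != 1):
            raise ValidationError("hazard age bands must be contiguous 1-year bands")
        if np.any(h1 < 0) or np.any(h2 < 0):
            raise ValidationError("hazards must be non-negative")
        if starts[0] > 40 or starts[-1] + 1 < 90:
            raise ValidationError("hazard table must cover at least ages [40, 90)")
        self.age_band_start = starts
        self.incidence = h1
        self.competing_mortality = h2

    @property
    def age_min(self) -> float:
        return float(self.age_band_start[0])

    @property
    def age_max(self) -> float:
        """Exclusive upper end of hazard coverage."""
        return float(self.age_band_start[-1] + 1)

    def band_index(self, age: float) -> int:
        if not (self.age_min <= age < self.age_max):
            raise ValidationError(
                f"age {age} outside hazard coverage "
                f"[{self.age_min:g}, {self.age_max:g})"
            )
        return int(np.floor(age)) - int(self.age_band_start[0])

    def segments(self, age_start: float, horizon: float):
        """Split [age_start, age_start + horizon) at band boundaries.

        Returns a list of ``(duration, h1, h2)`` tuples with hazards constant
        on each segment. Fractional start ages split the first band.
        """
        if horizon <= 0:
            raise ValidationError("horizon must be positive")
        age_end = age_start + horizon
        if age_end > self.age_max or age_start < self.age_min:
            raise ValidationError(
                f"window [{age_start:g}, {age_end:g}) exceeds hazard coverage "
                f"[{self.age_min:g}, {self.age_max:g})"
            )
        out = []
        a = age_start
        while a < age_end - 1e-12:
            i = self.band_index(a)
            band_end = float(self.age_band_start[i] + 1)
            b = min(band_end, age_end)
            out.append((b - a, float(self.incidence[i]), float(self.competing_mortality[i])))
            a = b
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_band_start": self.age_band_start,
                "incidence": self.incidence,
                "competing_mortality": self.competing_mortality,
            }
        )


class RelativeRiskTable:
    """Per-factor multiplicative relative risks plus category prevalences.

    Backed by a long-format table with columns ``factor``, ``category``,
    ``age_group``, ``rr``, ``prevalence``. ``age_group`` is ``"all"`` for an
    age-constant table. Each (factor, age_group) must contain a reference
    category with rr exactly 1.0 and prevalences summing to 1.
    """

    PREVALENCE_TOL = 1e-9

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"factor", "category", "rr", "prevalence"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(
                f"relative-risk table missing columns: {sorted(missing)}"
            )
        frame = frame.copy()
        if "age_group" not in frame.columns:
            frame["age_group"] = "all"
        frame["rr"] = frame["rr"].astype(float)
        frame["prevalence"] = frame["prevalence"].astype(float)
        if (frame["rr"] <= 0).any():
            raise ValidationError("all relative risks must be > 0")
        if (frame["prevalence"] < 0).any():
            raise ValidationError("prevalences must be non-negative")
        for (factor, age_group), grp in frame.groupby(["factor", "age_group"]):
            total = grp["prevalence"].sum()
            if abs(total - 1.0) > self.PREVALENCE_TOL:
                raise ValidationError(
                    f"prevalences for factor {factor!r} (age group {age_group!r}) "
                    f"sum to {total:.12g}, expected 1"
                )
            if grp["rr"].min() != 1.0:
                raise ValidationError(
                    f"factor {factor!r} (age group {age_group!r}) has no reference "
                    "category with rr = 1.0"
                )
        self.frame = frame
        self._lookup = {
            (r.factor, r.category, r.age_group): r.rr for r in frame.itertuples()
        }

    @property
    def factors(self) -> tuple:
        return tuple(dict.fromkeys(self.frame["factor"]))

    def age_groups(self) -> tuple:
        return tuple(dict.fromkeys(self.frame["age_group"]))

    def _resolve_age_group(self, age_group: str) -> str:
        groups = set(self.frame["age_group"])
        if age_group in groups:
            return age_group
        if "all" in groups:
            return "all"
        raise ValidationError(f"age group {age_group!r} not in table")

    def rr(self, factor: str, category: str, age_group: str = "all") -> float:
        ag = self._resolve_age_group(age_group)
        key = (factor, category, ag)
        if key not in self._lookup:
            raise ValidationError(
                f"category {category!r} for factor {factor!r} "
                f"(age group {ag!r}) absent from relative-risk table"
            )
        return self._lookup[key]

    def categories(self, factor: str, age_group: str = "all") -> pd.DataFrame:
        ag = self._resolve_age_group(age_group)
        sel = self.frame[
            (self.frame["factor"] == factor) & (self.frame["age_group"] == ag)
        ]
        if sel.empty:
            raise ValidationError(f"factor {factor!r} absent from table")
        return sel[["category", "rr", "prevalence"]].reset_index(drop=True)


class SnpPanel:
    """SNP panel: per-SNP risk-allele frequency and per-allele odds ratio."""

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"snp_id", "risk_allele_frequency", "per_allele_odds_ratio"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"SNP panel missing columns: {sorted(missing)}")
        frame = frame.copy()
        p = frame["risk_allele_frequency"].astype(float)
        orr = frame["per_allele_odds_ratio"].astype(float)
        if ((p <= 0) | (p >= 1)).any():
            raise ValidationError("risk allele frequencies must lie strictly in (0, 1)")
        if (orr <= 0).any():
            raise ValidationError("per-allele odds ratios must be > 0")
        if frame["snp_id"].duplicated().any():
            raise ValidationError("duplicate SNP ids in panel")
        if len(frame) == 0:
            raise ValidationError("SNP panel is empty")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> list:
        return list(self.frame["snp_id"])

    @property
    def frequencies(self) -> np.ndarray:
        return self.frame["risk_allele_frequency"].to_numpy(dtype=float)

    @property
    def odds_ratios(self) -> np.ndarray:
        return self.frame["per_allele_odds_ratio"].to_numpy(dtype=float)


@dataclass(frozen=True)
class CompositeLikelihoodRatio:
    """A polygenic risk score expressed as a composite likelihood ratio.

    ``value`` multiplies the prior 5-year-risk odds; it has population mean 1
    under Hardy-Weinberg equilibrium. ``n_snps_used`` counts the non-missing
    genotypes that entered the product (missing SNPs contribute factor 1).
    """

    value: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError("composite likelihood ratio must be > 0")
        if self.n_snps_used < 0:
            raise ValidationError("n_snps_used must be >= 0")


@dataclass(frozen=True)
class RiskResult:
    """Per-woman output of the risk-estimation pipeline (risks as fractions)."""

    woman_id: str
    rr_combined: float
    risk_pre: float
    prs: float
    risk_post: float
    pop_risk: float
    recommendation: str

    def __post_init__(self) -> None:
        for name in ("risk_pre", "risk_post", "pop_risk"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.recommendation not in RECOMMENDATION_ORDER:
            raise ValidationError(
                f"unknown recommendation {self.recommendation!r}; "
                f"allowed: {', '.join(RECOMMENDATION_ORDER)}"
            )


@dataclass(frozen=True)
class SurveyResponse:
    """Primary-outcome survey items for one woman.

    ``attitude_items`` are three 1-5 Likert items; their sum (3-15) is the
    attitude score, defined only when all three items are present.
    ``intention`` runs 1 = definitely will ... 5 = definitely will not.
    ``satisfaction`` runs 1 = very unsatisfied ... 5 = very satisfied.
    """

    woman_id: str
    attitude_items: tuple = (None, None, None)
    intention: Optional[int] = None
    satisfaction: Optional[int] = None

    def __post_init__(self) -> None:
        items = tuple(self.attitude_items)
        if len(items) != 3:
            raise ValidationError("attitude_items must have exactly 3 entries")
        object.__setattr__(self, "attitude_items", items)
        for v in items + (self.intention, self.satisfaction):
            if v is not None and v not in (1, 2, 3, 4, 5):
                raise ValidationError(f"Likert item value {v!r} outside 1..5")

    @property
    def attitude_complete(self) -> bool:
        return all(v is not None for v in self.attitude_items)


def results_to_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(RiskResult)]
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=cols)
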