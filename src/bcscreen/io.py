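"""Delimited-text readers and writers for every pipeline table.

All formats are header-first delimited text (comma by default, delimiter
configurable). Risks are written as percentages with two decimals; column
order is fixed and documented per writer. Validation collects row-level
problems with their row numbers instead of silently dropping records.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    HazardTable,
    RelativeRiskTable,
    RiskFactorProfile,
    RiskResult,
    SnpPanel,
    SurveyResponse,
    ValidationError,
    results_to_frame,
)

logger = logging.getLogger("bcscreen")

PathLike = Union[str, Path]

COHORT_COLUMNS = ("woman_id", "age", "family_history", "benign_disease", "density")
#: Fixed column order of the results file; risks are percentages, 2 decimals.
RESULT_COLUMNS = (
    "woman_id",
    "rr_combined",
    "risk_pre_pct",
    "prs",
    "risk_post_pct",
    "pop_risk_pct",
    "recommendation",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _read_table(path: PathLike, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing mandatory column(s) {missing}; found {list(frame.columns)}"
        )
    return frame


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"cannot parse {raw!r} as yes/no")


def read_cohort(
    path: PathLike, delimiter: str = ",", on_invalid: str = "raise"
) -> Union[list, tuple]:
    """Read risk-factor profiles from a delimited file.

    With ``on_invalid="raise"`` (default) any invalid row aborts the read
    with an error listing every failing row number. With
    ``on_invalid="collect"`` returns ``(profiles, rejected)`` where
    ``rejected`` is a list of ``(row_number, message)``; accepted plus
    rejected rows always account for every input row. A blank density is
    not an error: the profile is flagged density-missing and later excluded
    from risk estimation.
    """
    if on_invalid not in ("raise", "collect"):
        raise ValueError("on_invalid must be 'raise' or 'collect'")
    frame = _read_table(path, delimiter, COHORT_COLUMNS)
    profiles, rejected = [], []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header = line 1
        try:
            density = row.density.strip().lower()
            ethnicity = getattr(row, "ethnicity", "white/other") or "white/other"
            profiles.append(
                RiskFactorProfile(
                    woman_id=row.woman_id.strip(),
                    age=float(row.age),
                    family_history=_parse_bool(row.family_history),
                    benign_disease=row.benign_disease.strip().lower(),
                    density=density if density else None,
                    ethnicity=ethnicity,
                )
            )
        except (ValidationError, ValueError) as exc:
            rejected.append((i, str(exc)))
    if rejected and on_invalid == "raise":
        lines = "; ".join(f"row {r}: {m}" for r, m in rejected)
        raise ValidationError(f"{path}: {len(rejected)} invalid row(s): {lines}")
    if on_invalid == "collect":
        return profiles, rejected
    return profiles


def write_cohort(
    profiles: Sequence[RiskFactorProfile], path: PathLike, delimiter: str = ","
) -> None:
    frame = pd.DataFrame(
        {
            "woman_id": [p.woman_id for p in profiles],
            "age": [f"{p.age:.3f}" for p in profiles],
            "family_history": [int(p.family_history) for p in profiles],
            "benign_disease": [p.benign_disease for p in profiles],
            "density": [p.density or "" for p in profiles],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)


def read_genotypes(
    path: PathLike, panel: SnpPanel, delimiter: str = ","
) -> pd.DataFrame:
    """Read a genotype matrix (women x SNPs) of 0/1/2 allele counts.

    Columns must match the panel SNP ids exactly (order-free); blank cells
    are missing. Returns a float DataFrame indexed by woman id, columns in
    panel order, NaN for missing.
    """
    frame = _read_table(path, delimiter, ("woman_id",))
    cols = [c for c in frame.columns if c != "woman_id"]
    unmatched = sorted(set(cols) ^ set(panel.snp_ids))
    if unmatched:
        raise ValidationError(
            f"{path}: genotype columns do not match panel SNP ids; "
            f"unmatched: {unmatched}"
        )
    bad_cells = []
    data = np.full((len(frame), len(panel)), np.nan)
    for j, snp in enumerate(panel.snp_ids):
        for i, raw in enumerate(frame[snp]):
            raw = raw.strip()
            if not raw:
                continue
            if raw not in ("0", "1", "2"):
                bad_cells.append((i + 2, snp, raw))
            else:
                data[i, j] = float(raw)
    if bad_cells:
        coords = "; ".join(f"row {r}, {s}: {v!r}" for r, s, v in bad_cells[:10])
        raise ValidationError(
            f"{path}: {len(bad_cells)} genotype cell(s) outside {{0,1,2}}: {coords}"
        )
    return pd.DataFrame(
        data, index=pd.Index(frame["woman_id"], name="woman_id"), columns=panel.snp_ids
    )


def write_genotypes(genotypes: pd.DataFrame, path: PathLike, delimiter: str = ",") -> None:
    out = genotypes.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep=delimiter, index=True)


def read_hazard_table(path: PathLike, delimiter: str = ",") -> HazardTable:
    frame = _read_table(
        path, delimiter, ("age_band_start", "incidence", "competing_mortality")
    )
    return HazardTable(
        frame["age_band_start"].astype(int),
        frame["incidence"].astype(float),
        frame["competing_mortality"].astype(float),
    )


def write_hazard_table(table: HazardTable, path: PathLike, delimiter: str = ",") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index=False)


def read_rr_table(path: PathLike, delimiter: str = ",") -> RelativeRiskTable:
    frame = pd.read_csv(path, sep=delimiter)
    return RelativeRiskTable(frame)


def write_rr_table(table: RelativeRiskTable, path: PathLike, delimiter: str = ",") -> None:
    table.frame.to_csv(path, sep=delimiter, index=False)


def read_panel(path: PathLike, delimiter: str = ",") -> SnpPanel:
    frame = pd.read_csv(path, sep=delimiter)
    return SnpPanel(frame)


def write_panel(panel: SnpPanel, path: PathLike, delimiter: str = ",") -> None:
    panel.frame.to_csv(path, sep=delimiter, index=False)


def read_survey(path: PathLike, delimiter: str = ",") -> list:
    """Read survey responses; blank cells are missing (never imputed)."""
    frame = _read_table(
        path,
        delimiter,
        ("woman_id", "attitude_1", "attitude_2", "attitude_3", "intention", "satisfaction"),
    )

    def cell(raw: str) -> Optional[int]:
        raw = raw.strip()
        return int(raw) if raw else None

    responses = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            responses.append(
                SurveyResponse(
                    woman_id=row.woman_id.strip(),
                    attitude_items=(
                        cell(row.attitude_1),
                        cell(row.attitude_2),
                        cell(row.attitude_3),
                    ),
                    intention=cell(row.intention),
                    satisfaction=cell(row.satisfaction),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return responses


def write_survey(
    responses: Sequence[SurveyResponse], path: PathLike, delimiter: str = ","
) -> None:
    def fmt(v) -> str:
        return "" if v is None else str(v)

    frame = pd.DataFrame(
        {
            "woman_id": [r.woman_id for r in responses],
            "attitude_1": [fmt(r.attitude_items[0]) for r in responses],
            "attitude_2": [fmt(r.attitude_items[1]) for r in responses],
            "attitude_3": [fmt(r.attitude_items[2]) for r in responses],
            "intention": [fmt(r.intention) for r in responses],
            "satisfaction": [fmt(r.satisfaction) for r in responses],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)


def write_results(
    results: Sequence[RiskResult], path: PathLike, delimiter: str = ","
) -> None:
    """Write risk results with risks rendered as percentages to 2 decimals,
    in the fixed :data:`RESULT_COLUMNS` order. An empty list writes a
    header-only file."""
    frame = results_to_frame(results)
    out = pd.DataFrame(
        {
            "woman_id": frame["woman_id"],
            "rr_combined": frame["rr_combined"].map(lambda v: f"{v:.4f}"),
            "risk_pre_pct": frame["risk_pre"].map(lambda v: f"{v * 100:.2f}"),
            "prs": frame["prs"].map(lambda v: f"{v:.4f}"),
            "risk_post_pct": frame["risk_post"].map(lambda v: f"{v * 100:.2f}"),
            "pop_risk_pct": frame["pop_risk"].map(lambda v: f"{v * 100:.2f}"),
            "recommendation": frame["recommendation"],
        },
        columns=list(RESULT_COLUMNS),
    )
    out.to_csv(path, sep=delimiter, index=False)


def read_results(path: PathLike, delimiter: str = ",") -> list:
    frame = _read_table(path, delimiter, RESULT_COLUMNS)
    return [
        RiskResult(
            woman_id=row.woman_id,
            rr_combined=float(row.rr_combined),
            risk_pre=float(row.risk_pre_pct) / 100.0,
            prs=float(row.prs),
            risk_post=float(row.risk_post_pct) / 100.0,
            pop_risk=float(row.pop_risk_pct) / 100.0,
            recommendation=row.recommendation,
        )
        for row in frame.itertuples(index=False)
    ]


def profiles_to_frame(profiles: Sequence[RiskFactorProfile]) -> pd.DataFrame:
    """Cohort DataFrame in the canonical column layout used by estimators."""
    return pd.DataFrame(
        {
            "woman_id": [p.woman_id for p in profiles],
            "age": [p.age for p in profiles],
            "family_history": [p.family_history for p in profiles],
            "benign_disease": [p.benign_disease for p in profiles],
            "density": [p.density for p in profiles],
            "ethnicity": [p.ethnicity for p in profiles],
        }
    )


def frame_to_profiles(frame: pd.DataFrame) -> list:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort frame missing column(s) {missing}")
    profiles = []
    for row in frame.itertuples(index=False):
        density = row.density
        if isinstance(density, float) and np.isnan(density):
            density = None
        profiles.append(
            RiskFactorProfile(
                woman_id=str(row.woman_id),
                age=float(row.age),
                family_history=bool(row.family_history),
                benign_disease=str(row.benign_disease),
                density=density if density else None,
                ethnicity=str(getattr(row, "ethnicity", "white/other")),
            )
        )
    return profiles


def load_config(path: PathLike) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return config


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
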