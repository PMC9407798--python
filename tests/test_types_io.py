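"""Domain-type validation and delimited-text round trips."""

import numpy as np
import pandas as pd
import pytest

from bcscreen import (
    HazardTable,
    RelativeRiskTable,
    RiskFactorProfile,
    RiskResult,
    SurveyResponse,
    ValidationError,
)
from bcscreen import io
from bcscreen.synthetic import CohortSpec, generate_cohort, generate_panel


class TestProfileValidation:
    def test_age_outside_model_support_rejected(self):
        with pytest.raises(ValidationError, match="age"):
            RiskFactorProfile(woman_id="x", age=17.0, family_history=False)
        with pytest.raises(ValidationError, match="age"):
            RiskFactorProfile(woman_id="x", age=90.0, family_history=False)

    def test_unknown_benign_category_lists_allowed(self):
        with pytest.raises(ValidationError, match="non-proliferative"):
            RiskFactorProfile(
                woman_id="x", age=45, family_history=False, benign_disease="XYZ"
            )

    def test_missing_density_is_flagged_not_rejected(self):
        p = RiskFactorProfile(woman_id="x", age=45, family_history=False, density=None)
        assert p.density_missing

    def test_risk_result_bounds(self):
        with pytest.raises(ValidationError):
            RiskResult("w", 1.0, 1.5, 1.0, 0.5, 0.01, "annual")
        with pytest.raises(ValidationError):
            RiskResult("w", 1.0, 0.01, 1.0, 0.01, 0.01, "monthly")

    def test_survey_item_range(self):
        with pytest.raises(ValidationError):
            SurveyResponse(woman_id="w", attitude_items=(1, 2, 6))


class TestHazardTable:
    def test_must_cover_40_to_90(self):
        starts = np.arange(40, 60)
        with pytest.raises(ValidationError, match=r"\[40, 90\)"):
            HazardTable(starts, np.ones(20) * 1e-3, np.ones(20) * 1e-3)

    def test_non_contiguous_bands_rejected(self):
        starts = np.concatenate([np.arange(40, 60), np.arange(61, 91)])
        with pytest.raises(ValidationError, match="contiguous"):
            HazardTable(starts, np.ones(50) * 1e-3, np.ones(50) * 1e-3)

    def test_segments_split_fractional_start(self, flat_hazards):
        segs = flat_hazards.segments(44.3, 2.0)
        durations = [d for d, _, _ in segs]
        assert durations == pytest.approx([0.7, 1.0, 0.3])
        assert sum(durations) == pytest.approx(2.0)

    def test_window_beyond_coverage_rejected(self, flat_hazards):
        with pytest.raises(ValidationError, match="coverage"):
            flat_hazards.segments(88.0, 5.0)


class TestRelativeRiskTableValidation:
    def test_prevalences_must_sum_to_one(self):
        frame = pd.DataFrame(
            [("density", "a", 1.0, 0.6), ("density", "c", 1.5, 0.6)],
            columns=["factor", "category", "rr", "prevalence"],
        )
        with pytest.raises(ValidationError, match="sum"):
            RelativeRiskTable(frame)

    def test_reference_category_required(self):
        frame = pd.DataFrame(
            [("density", "a", 1.2, 0.5), ("density", "c", 1.5, 0.5)],
            columns=["factor", "category", "rr", "prevalence"],
        )
        with pytest.raises(ValidationError, match="reference"):
            RelativeRiskTable(frame)


class TestCohortIO:
    def test_round_trip_preserves_densities(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            "woman_id,age,family_history,benign_disease,density\n"
            "w1,45.0,0,none,a\n"
            "w2,41.2,1,non-proliferative,c\n"
            "w3,49.9,0,unspecified-benign,d\n"
        )
        profiles = io.read_cohort(path)
        assert [p.density for p in profiles] == ["a", "c", "d"]
        out = tmp_path / "out.csv"
        io.write_cohort(profiles, out)
        again = io.read_cohort(out)
        assert [(p.woman_id, p.density, p.family_history) for p in again] == [
            (p.woman_id, p.density, p.family_history) for p in profiles
        ]

    def test_blank_density_flags_missing(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            "woman_id,age,family_history,benign_disease,density\nw1,45,0,none,\n"
        )
        (profile,) = io.read_cohort(path)
        assert profile.density_missing

    def test_invalid_rows_reported_with_row_numbers(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            "woman_id,age,family_history,benign_disease,density\n"
            "w1,45,0,none,a\n"
            "w2,12,0,none,a\n"
            "w3,45,0,XYZ,a\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            io.read_cohort(path)
        profiles, rejected = io.read_cohort(path, on_invalid="collect")
        assert len(profiles) + len(rejected) == 3
        assert [r for r, _ in rejected] == [3, 4]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("woman_id,age\nw1,45\n")
        with pytest.raises(ValidationError, match="density"):
            io.read_cohort(path)


class TestGenotypeIO:
    def test_zeros_round_trip(self, tmp_path, tiny_panel):
        path = tmp_path / "g.csv"
        path.write_text("woman_id,rsA,rsB\nw1,0,0\nw2,0,0\n")
        g = io.read_genotypes(path, tiny_panel)
        assert g.shape == (2, 2)
        assert (g.to_numpy() == 0).all()

    def test_value_three_rejected_with_coordinates(self, tmp_path, tiny_panel):
        path = tmp_path / "g.csv"
        path.write_text("woman_id,rsA,rsB\nw1,0,3\n")
        with pytest.raises(ValidationError, match="rsB"):
            io.read_genotypes(path, tiny_panel)

    def test_panel_mismatch_lists_unmatched_ids(self, tmp_path, tiny_panel):
        path = tmp_path / "g.csv"
        path.write_text("woman_id,rsA,rsZ\nw1,0,0\n")
        with pytest.raises(ValidationError, match="rsZ"):
            io.read_genotypes(path, tiny_panel)

    def test_missing_cell_becomes_nan(self, tmp_path, tiny_panel):
        path = tmp_path / "g.csv"
        path.write_text("woman_id,rsA,rsB\nw1,1,\n")
        g = io.read_genotypes(path, tiny_panel)
        assert np.isnan(g.loc["w1", "rsB"])
        assert g.loc["w1", "rsA"] == 1


class TestResultsIO:
    def _result(self, risk_post=0.0172):
        return RiskResult(
            woman_id="w1",
            rr_combined=2.5,
            risk_pre=0.0123,
            prs=1.1,
            risk_post=risk_post,
            pop_risk=0.008,
            recommendation="annual",
        )

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "r.csv"
        io.write_results([], path)
        assert path.read_text().strip() == ",".join(io.RESULT_COLUMNS)

    def test_risks_formatted_as_percent_two_decimals(self, tmp_path):
        path = tmp_path / "r.csv"
        io.write_results([self._result(0.0172)], path)
        row = path.read_text().splitlines()[1].split(",")
        assert row[io.RESULT_COLUMNS.index("risk_post_pct")] == "1.72"

    def test_round_trip_within_formatting_precision(self, tmp_path):
        path = tmp_path / "r.csv"
        original = self._result()
        io.write_results([original], path)
        (back,) = io.read_results(path)
        assert back.woman_id == original.woman_id
        assert back.recommendation == original.recommendation
        assert back.risk_post == pytest.approx(original.risk_post, abs=5e-5)
        assert back.risk_pre == pytest.approx(original.risk_pre, abs=5e-5)


def test_survey_round_trip_preserves_missing(tmp_path):
    responses = [
        SurveyResponse("w1", (5, 4, None), intention=1, satisfaction=None),
        SurveyResponse("w2", (1, 2, 3), intention=None, satisfaction=5),
    ]
    path = tmp_path / "s.csv"
    io.write_survey(responses, path)
    back = io.read_survey(path)
    assert back == responses


def test_simulated_files_round_trip(tmp_path):
    """Generator output written to CSV reads back identically."""
    panel = generate_panel(n_snps=5, seed=1)
    profiles, genotypes, surveys = generate_cohort(CohortSpec(n=30, seed=2), panel)
    io.write_cohort(profiles, tmp_path / "c.csv")
    io.write_genotypes(genotypes, tmp_path / "g.csv")
    io.write_panel(panel, tmp_path / "p.csv")
    back_panel = io.read_panel(tmp_path / "p.csv")
    back_prof = io.read_cohort(tmp_path / "c.csv")
    back_geno = io.read_genotypes(tmp_path / "g.csv", back_panel)
    assert [p.woman_id for p in back_prof] == [p.woman_id for p in profiles]
    assert [p.age for p in back_prof] == pytest.approx(
        [p.age for p in profiles], abs=1e-3
    )
    pd.testing.assert_frame_equal(back_geno, genotypes)
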