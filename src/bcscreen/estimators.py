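"""Scikit-learn-style estimators over the risk model.

The prediction task is predict-shaped — covariates in, 5-year absolute risk
(or a recommendation category) out — so the model surface follows the
sklearn estimator protocol: parameters in ``__init__``, validation and
precomputation in ``fit`` (fitted attributes carry a trailing underscore),
``predict``/``transform`` for outputs, and ``get_params``/``set_params``
for composition with pipelines and model selection. The module-level
functions in :mod:`bcscreen.relative_risk`, :mod:`bcscreen.absolute_risk`,
:mod:`bcscreen.prs` and :mod:`bcscreen.recommend` are the scalar primitives
these estimators vectorize.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import defaults
from .absolute_risk import AbsoluteRiskInput, absolute_risk, population_average_risk
from .io import frame_to_profiles, profiles_to_frame
from .prs import bayes_update, composite_prs_matrix
from .recommend import ThresholdPolicy, recommend
from .relative_risk import attributable_risk_fraction, combined_relative_risk
from .types import RiskFactorProfile, RiskResult, ValidationError


def _as_cohort_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    if len(X) and isinstance(X[0], RiskFactorProfile):
        return profiles_to_frame(list(X))
    raise ValidationError(
        "X must be a cohort DataFrame or a sequence of RiskFactorProfile"
    )


class GailRiskEstimator(BaseEstimator):
    """5-year absolute breast-cancer risk from classical risk factors.

    Combines per-factor multiplicative relative risks (versus the
    lowest-risk profile), deflates composite incidence by the
    attributable-risk fraction, and converts to absolute risk with the
    competing-mortality cause-specific-hazard formula.

    Parameters
    ----------
    rr_table : RelativeRiskTable, optional
        Relative risks and population prevalences; bundled default if None.
    hazard_table : HazardTable, optional
        Age-banded incidence and competing mortality; bundled default if None.
    horizon : float, default 5.0
        Risk horizon in years.

    Attributes
    ----------
    rr_table_, hazard_table_ : resolved tables.
    attributable_risk_ : dict
        Attributable-risk fraction per age group of the table.
    """

    def __init__(self, rr_table=None, hazard_table=None, horizon: float = 5.0):
        self.rr_table = rr_table
        self.hazard_table = hazard_table
        self.horizon = horizon

    def fit(self, X=None, y=None):
        if self.horizon <= 0:
            raise ValidationError("horizon must be > 0")
        self.rr_table_ = self.rr_table or defaults.default_rr_table()
        self.hazard_table_ = self.hazard_table or defaults.default_hazard_table()
        self.attributable_risk_ = {
            ag: attributable_risk_fraction(self.rr_table_, ag)
            for ag in self.rr_table_.age_groups()
        }
        if X is not None:
            _as_cohort_frame(X)  # early schema validation
        return self

    def _profiles(self, X) -> list:
        frame = _as_cohort_frame(X)
        return frame_to_profiles(frame) if isinstance(frame, pd.DataFrame) else list(X)

    def relative_risk(self, X) -> np.ndarray:
        """Combined relative risk per woman (requires non-missing density)."""
        check_is_fitted(self, "rr_table_")
        return np.array(
            [combined_relative_risk(p, self.rr_table_) for p in self._profiles(X)]
        )

    def predict(self, X) -> np.ndarray:
        """Preliminary 5-year absolute risk (fraction) per woman."""
        check_is_fitted(self, "rr_table_")
        ar = self.attributable_risk_["all"]
        out = []
        for p in self._profiles(X):
            rr = combined_relative_risk(p, self.rr_table_)
            out.append(
                absolute_risk(
                    AbsoluteRiskInput(
                        age_start=p.age,
                        horizon=self.horizon,
                        rr=rr,
                        hazards=self.hazard_table_,
                        ar=ar,
                    )
                )
            )
        return np.array(out)

    def population_risk(self, ages) -> np.ndarray:
        """Same-age general-population risk, for the comparison pictogram."""
        check_is_fitted(self, "hazard_table_")
        return np.array(
            [
                population_average_risk(float(a), self.hazard_table_, self.horizon)
                for a in np.atleast_1d(np.asarray(ages, dtype=float))
            ]
        )


class PolygenicRiskUpdater(BaseEstimator):
    """Composite-likelihood-ratio PRS and the Bayesian odds update.

    ``transform`` maps a (women x SNPs) allele-count matrix to one composite
    likelihood ratio per woman; ``update`` applies posterior odds =
    prior odds x PRS elementwise.
    """

    def __init__(self, panel=None):
        self.panel = panel

    def fit(self, X=None, y=None):
        self.panel_ = self.panel or defaults.example_panel()
        if X is not None:
            self._check_columns(X)
        return self

    def _check_columns(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            unmatched = sorted(set(X.columns) ^ set(self.panel_.snp_ids))
            if unmatched:
                raise ValidationError(
                    f"genotype columns do not match panel: {unmatched}"
                )
            return X[self.panel_.snp_ids].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def transform(self, X) -> np.ndarray:
        """Composite PRS per woman; missing genotypes contribute factor 1."""
        check_is_fitted(self, "panel_")
        return composite_prs_matrix(self._check_columns(X), self.panel_)

    def update(self, prior_risk, prs) -> np.ndarray:
        """Vectorized Bayesian update on the 5-year-risk odds."""
        prior = np.atleast_1d(np.asarray(prior_risk, dtype=float))
        lr = np.atleast_1d(np.asarray(prs, dtype=float))
        if np.any((prior < 0) | (prior >= 1)):
            raise ValidationError("prior risks must lie in [0, 1)")
        if np.any(lr <= 0):
            raise ValidationError("likelihood ratios must be > 0")
        odds = prior / (1.0 - prior) * lr
        return odds / (1.0 + odds)


class ScreeningRecommender(BaseEstimator):
    """Maps (final risk, age) to a screening recommendation category.

    Threshold parameters are percentages; see :class:`ThresholdPolicy`.
    """

    def __init__(
        self,
        referral_above: float = 6.0,
        annual_above_age_40_44: float = 1.16,
        annual_above_otherwise: float = 1.19,
        biennial_above: float = 0.80,
        triennial_above: float = 0.40,
        min_age_watch_wait_forbidden: float = 50.0,
    ):
        self.referral_above = referral_above
        self.annual_above_age_40_44 = annual_above_age_40_44
        self.annual_above_otherwise = annual_above_otherwise
        self.biennial_above = biennial_above
        self.triennial_above = triennial_above
        self.min_age_watch_wait_forbidden = min_age_watch_wait_forbidden

    def fit(self, X=None, y=None):
        self.policy_ = ThresholdPolicy(
            referral_above=self.referral_above,
            annual_above_age_40_44=self.annual_above_age_40_44,
            annual_above_otherwise=self.annual_above_otherwise,
            biennial_above=self.biennial_above,
            triennial_above=self.triennial_above,
            min_age_watch_wait_forbidden=self.min_age_watch_wait_forbidden,
        )
        return self

    def predict(self, risk_post, age) -> np.ndarray:
        check_is_fitted(self, "policy_")
        risks = np.atleast_1d(np.asarray(risk_post, dtype=float))
        ages = np.broadcast_to(
            np.atleast_1d(np.asarray(age, dtype=float)), risks.shape
        )
        return np.array(
            [recommend(r, a, self.policy_) for r, a in zip(risks, ages)], dtype=object
        )


class RiskPipeline(BaseEstimator):
    """End-to-end personalized-screening pipeline.

    simulate/estimate order: classical-factor absolute risk, PRS from the
    genotype matrix, Bayesian update, recommendation. Women with missing
    density are excluded from estimation and reported in the skip list.
    """

    def __init__(
        self,
        rr_table=None,
        hazard_table=None,
        panel=None,
        recommender: Optional[ScreeningRecommender] = None,
        horizon: float = 5.0,
    ):
        self.rr_table = rr_table
        self.hazard_table = hazard_table
        self.panel = panel
        self.recommender = recommender
        self.horizon = horizon

    def fit(self, X=None, y=None):
        self.gail_ = GailRiskEstimator(
            rr_table=self.rr_table,
            hazard_table=self.hazard_table,
            horizon=self.horizon,
        ).fit()
        self.prs_ = PolygenicRiskUpdater(panel=self.panel).fit()
        self.recommender_ = (self.recommender or ScreeningRecommender()).fit()
        return self

    def estimate(
        self, cohort, genotypes: Optional[pd.DataFrame] = None
    ) -> tuple[list, list]:
        """Run the pipeline; returns ``(results, skipped)``.

        ``skipped`` lists ``(woman_id, reason)`` for women excluded from
        estimation (missing density, or missing genotype row — the latter
        gets PRS = 1, not a skip). Every woman appears in exactly one of
        the two outputs.
        """
        check_is_fitted(self, "gail_")
        profiles = (
            frame_to_profiles(cohort) if isinstance(cohort, pd.DataFrame) else list(cohort)
        )
        skipped = [
            (p.woman_id, "missing breast density") for p in profiles if p.density_missing
        ]
        estimable = [p for p in profiles if not p.density_missing]
        if not estimable:
            return [], skipped

        frame = profiles_to_frame(estimable)
        rrs = self.gail_.relative_risk(frame)
        priors = self.gail_.predict(frame)
        pop = self.gail_.population_risk(frame["age"].to_numpy())

        if genotypes is not None:
            aligned = genotypes.reindex([p.woman_id for p in estimable])
            prs = self.prs_.transform(aligned)
        else:
            prs = np.ones(len(estimable))
        posts = self.prs_.update(priors, prs)
        recs = self.recommender_.predict(posts, frame["age"].to_numpy())

        results = [
            RiskResult(
                woman_id=p.woman_id,
                rr_combined=float(rrs[i]),
                risk_pre=float(priors[i]),
                prs=float(prs[i]),
                risk_post=float(posts[i]),
                pop_risk=float(pop[i]),
                recommendation=str(recs[i]),
            )
            for i, p in enumerate(estimable)
        ]
        return results, skipped
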