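"""Polygenic risk score as a composite likelihood ratio, and the Bayesian
risk update.

Each SNP contributes LR(g) = OR^g / E[OR^G], where G ~ Binomial(2, p) under
Hardy-Weinberg equilibrium, so E[OR^G] = (1-p)^2 + 2p(1-p) OR + p^2 OR^2 and
the population mean of LR is 1 by construction. SNPs are assumed independent
(likelihood ratios multiply) and independent of the classical risk factors;
missing genotypes contribute factor 1 (the population average), keeping
every woman scoreable without bias under HWE.

The update acts on the 5-year-risk odds: posterior odds = prior odds * PRS.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .types import CompositeLikelihoodRatio, SnpPanel, ValidationError


def hwe_mean_or(p: float, or_allele: float) -> float:
    """E[OR^G] with G ~ HWE(p): (1-p)^2 + 2p(1-p) OR + p^2 OR^2."""
    q = 1.0 - p
    return q * q + 2.0 * p * q * or_allele + p * p * or_allele * or_allele


def snp_likelihood_ratio(g: int, p: float, or_allele: float) -> float:
    """Per-SNP likelihood ratio OR^g normalized to population mean 1."""
    if g not in (0, 1, 2):
        raise ValidationError(f"allele count {g!r} must be 0, 1 or 2")
    if not (0.0 < p < 1.0):
        raise ValidationError("risk allele frequency must lie strictly in (0, 1)")
    if or_allele <= 0:
        raise ValidationError("per-allele odds ratio must be > 0")
    return or_allele**g / hwe_mean_or(p, or_allele)


def composite_prs(
    genotypes: Sequence[Optional[float]], panel: SnpPanel
) -> CompositeLikelihoodRatio:
    """Product of per-SNP likelihood ratios over the non-missing genotypes.

    ``genotypes`` is aligned to the panel order; missing values (None or NaN)
    contribute factor 1 and are excluded from ``n_snps_used``.
    """
    g = np.asarray(
        [np.nan if v is None else float(v) for v in genotypes], dtype=float
    )
    if g.shape[0] != len(panel):
        raise ValidationError(
            f"genotype vector length {g.shape[0]} does not match panel size {len(panel)}"
        )
    observed = ~np.isnan(g)
    gv = g[observed]
    if not np.isin(gv, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(gv[~np.isin(gv, (0.0, 1.0, 2.0))]))
        raise ValidationError(f"allele counts must be 0/1/2 or missing; found {bad}")
    log_or = np.log(panel.odds_ratios[observed])
    log_norm = np.log(
        _hwe_mean_or_vec(panel.frequencies[observed], panel.odds_ratios[observed])
    )
    value = math.exp(float(np.sum(gv * log_or - log_norm)))
    return CompositeLikelihoodRatio(value=value, n_snps_used=int(observed.sum()))


def _hwe_mean_or_vec(p: np.ndarray, orr: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    return q * q + 2.0 * p * q * orr + p * p * orr * orr


def composite_prs_matrix(genotypes: np.ndarray, panel: SnpPanel) -> np.ndarray:
    """Vectorized composite likelihood ratio for a (women x SNPs) matrix.

    NaN marks missing genotypes (factor 1). Returns one PRS per row.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] != len(panel):
        raise ValidationError(
            f"genotype matrix shape {g.shape} does not match panel size {len(panel)}"
        )
    observed = ~np.isnan(g)
    vals = g[observed]
    if not np.isin(vals, (0.0, 1.0, 2.0)).all():
        raise ValidationError("allele counts must be 0/1/2 or missing")
    log_or = np.log(panel.odds_ratios)
    log_norm = np.log(_hwe_mean_or_vec(panel.frequencies, panel.odds_ratios))
    terms = np.where(observed, np.nan_to_num(g) * log_or - log_norm, 0.0)
    return np.exp(terms.sum(axis=1))


def bayes_update(prior_risk: float, prs) -> float:
    """Posterior 5-year risk: posterior odds = prior odds * PRS.

    ``prs`` may be a :class:`CompositeLikelihoodRatio` or a positive float.
    ``prior_risk`` must lie in [0, 1); the odds of risk 1 are undefined.
    """
    lr = prs.value if isinstance(prs, CompositeLikelihoodRatio) else float(prs)
    if lr <= 0:
        raise ValidationError("likelihood ratio must be > 0")
    if not (0.0 <= prior_risk < 1.0):
        raise ValidationError("prior risk must lie in [0, 1)")
    odds = prior_risk / (1.0 - prior_risk) * lr
    return odds / (1.0 + odds)
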