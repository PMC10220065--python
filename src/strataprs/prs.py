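"""Polygenic risk scores: construction, subject scoring, quantile odds ratios.

A PRS is the weighted sum of effect-allele counts across a fixed panel of
susceptibility variants, with weights on the log-OR scale taken from an
external meta-analysis.  Risk stratification is summarised by splitting
subjects into K quantile bins of the score and reporting the odds ratio of
each bin against the middle bin, which represents the average risk of the
population.  Two routes are provided:

* :func:`quantile_or_empirical` — cut-points from the control-only score
  distribution, per-bin ORs and Wald CIs from the 2x2 table against the
  reference bin; and
* :func:`quantile_or_analytic` — a closed form under the rare-disease
  approximation, treating the control score as N(mu, sigma2) (HWE,
  independent variants) and the disease log-odds as linear in the score,
  so the per-bin OR is a ratio of truncated-normal exponential moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import HarmonizationError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import IndividualCohort


@dataclass
class PrsWeightSet:
    """Variant -> weight map on the log-OR scale.

    ``provenance`` records which meta-analysis produced the weights.
    """

    snp_ids: list[str]
    effect_alleles: list[str]
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != len(self.effect_alleles) or len(self.snp_ids) != self.weights.size:
            raise ValidationError("snp_ids, effect_alleles and weights must have equal length")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")

    def __len__(self) -> int:
        return len(self.snp_ids)


def read_weights(path, provenance: str = "") -> PrsWeightSet:
    """Read a weights TSV with columns snp_id, effect_allele, weight."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("snp_id", "effect_allele", "weight"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return PrsWeightSet(
        snp_ids=[str(s) for s in df["snp_id"]],
        effect_alleles=[str(a) for a in df["effect_allele"]],
        weights=df["weight"].to_numpy(dtype=float),
        provenance=provenance or str(path),
    )


def write_weights(weights: PrsWeightSet, path) -> None:
    pd.DataFrame(
        {
            "snp_id": weights.snp_ids,
            "effect_allele": weights.effect_alleles,
            "weight": weights.weights,
        }
    ).to_csv(path, sep="\t", index=False)


def align_weights_to_panel(
    weights: PrsWeightSet,
    snp_ids: Sequence[str],
    effect_alleles: Sequence[str],
    other_alleles: Sequence[str] | None = None,
) -> np.ndarray:
    """Aligned weight vector for a genotype panel, in panel order.

    A weight whose effect allele matches the panel's *other* allele is
    negated (counting the opposite allele flips the sign of a log-OR
    weight; the constant offset cancels in every downstream contrast).
    Variants of the panel without a weight get weight 0; weights naming a
    variant absent from the panel raise :class:`HarmonizationError` listing
    the offenders.
    """
    index = {s: i for i, s in enumerate(snp_ids)}
    missing = [s for s in weights.snp_ids if s not in index]
    if missing:
        raise HarmonizationError(f"weight variants absent from panel: {missing}")
    out = np.zeros(len(snp_ids), dtype=float)
    for s, ea_w, w in zip(weights.snp_ids, weights.effect_alleles, weights.weights):
        i = index[s]
        ea_p = str(effect_alleles[i]).upper()
        if ea_w.upper() == ea_p:
            out[i] = w
        elif other_alleles is not None and ea_w.upper() == str(other_alleles[i]).upper():
            out[i] = -w
        else:
            raise HarmonizationError(
                f"{s}: weight effect allele {ea_w!r} matches neither panel allele"
            )
    return out


def score_cohort(cohort: "IndividualCohort", weights: PrsWeightSet) -> np.ndarray:
    """Per-subject PRS: sum over variants of weight times allele count."""
    beta = align_weights_to_panel(
        weights, cohort.snp_ids, cohort.effect_alleles, cohort.other_alleles
    )
    return cohort.genotypes.astype(float) @ beta


def prs_moments(weights: PrsWeightSet, eafs: Sequence[float]) -> tuple[float, float]:
    """Population mean and variance of the PRS under HWE and independence.

    ``mu = sum 2 p_t beta_t``; ``sigma2 = sum 2 p_t (1-p_t) beta_t**2``.
    """
    p = np.asarray(eafs, dtype=float)
    if p.size != len(weights):
        raise ValidationError("eafs length must match the number of weights")
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("frequencies must lie in (0,1)")
    b = weights.weights
    mu = float(np.sum(2.0 * p * b))
    sigma2 = float(np.sum(2.0 * p * (1.0 - p) * b**2))
    return mu, sigma2


@dataclass
class QuantileOrTable:
    """Per-bin odds ratios against a reference (middle) quantile bin."""

    K: int
    reference: int
    odds_ratios: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_cases: np.ndarray | None = None
    n_controls: np.ndarray | None = None
    mode: str = "analytic"
    notes: str = field(default="")

    def __post_init__(self) -> None:
        if self.K % 2 == 0:
            raise ValidationError("K must be odd so the middle bin is well defined")
        if abs(self.odds_ratios[self.reference] - 1.0) > 1e-12:
            raise ValidationError("reference bin OR must equal 1 exactly")


def _truncnorm_exp_moment(a: np.ndarray, b: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """E[exp(S) | a < S < b] for S ~ N(mu, sigma**2)."""
    za, zb = (a - mu) / sigma, (b - mu) / sigma
    mass = sps.norm.cdf(zb) - sps.norm.cdf(za)
    shifted = sps.norm.cdf(zb - sigma) - sps.norm.cdf(za - sigma)
    return math.exp(mu + sigma**2 / 2.0) * shifted / mass


def quantile_or_analytic(
    weights: PrsWeightSet,
    eafs: Sequence[float],
    K: int = 5,
    reference: int | None = None,
) -> QuantileOrTable:
    """Closed-form quantile-bin odds ratios under the rare-disease model.

    The control-group score is approximated by its population normal limit
    S ~ N(mu, sigma2) with moments from :func:`prs_moments`, and the
    disease log-odds is linear in S with unit loading (the weights are
    themselves log-ORs).  The OR of bin (a, b) against the reference bin is
    then the ratio of truncated-normal exponential moments E[e^S | a<S<b].
    Degenerate weights (sigma2 = 0) yield ORs of 1 by convention.
    """
    if K % 2 == 0:
        raise ValidationError("K must be odd so the middle bin is well defined")
    if reference is None:
        reference = K // 2
    mu, sigma2 = prs_moments(weights, eafs)
    if sigma2 == 0.0:
        return QuantileOrTable(K=K, reference=reference,
                               odds_ratios=np.ones(K), mode="analytic",
                               notes="zero-variance score; ORs = 1 by convention")
    sigma = math.sqrt(sigma2)
    edges = sps.norm.ppf(np.arange(1, K) / K, loc=mu, scale=sigma)
    a = np.concatenate([[-np.inf], edges])
    b = np.concatenate([edges, [np.inf]])
    moments = _truncnorm_exp_moment(a, b, mu, sigma)
    ors = moments / moments[reference]
    ors[reference] = 1.0  # exact by construction
    return QuantileOrTable(K=K, reference=reference, odds_ratios=ors, mode="analytic")


def quantile_or_empirical(
    cohort: "IndividualCohort",
    weights: PrsWeightSet,
    K: int = 5,
    reference: int | None = None,
    stratum: str | None = None,
    haldane: bool = False,
) -> QuantileOrTable:
    """Empirical quantile-bin odds ratios from an individual-level cohort.

    Cut-points are the K-quantiles of the *control* score distribution
    (controls approximate the population under the rare-disease
    assumption).  Each non-reference bin's OR and 95% Wald CI come from the
    2x2 case/control table against the reference bin.  A zero cell raises
    an error unless ``haldane=True`` applies the Haldane-Anscombe 0.5
    correction.
    """
    if K % 2 == 0:
        raise ValidationError("K must be odd so the middle bin is well defined")
    if reference is None:
        reference = K // 2
    prs = score_cohort(cohort, weights)
    mask = np.ones(prs.size, dtype=bool)
    if stratum is not None:
        mask = cohort.stratum == stratum
    prs, case = prs[mask], cohort.case_flag[mask]
    controls = prs[~case]
    if controls.size < K or np.count_nonzero(case) == 0:
        raise ValidationError("need cases and at least K controls to form bins")
    edges = np.quantile(controls, np.arange(1, K) / K)
    bins = np.digitize(prs, edges)  # 0..K-1
    n_case = np.array([np.sum(case & (bins == k)) for k in range(K)], dtype=float)
    n_ctrl = np.array([np.sum(~case & (bins == k)) for k in range(K)], dtype=float)
    if np.any(n_case == 0) or np.any(n_ctrl == 0):
        if not haldane:
            raise ValidationError(
                "a quantile bin has a zero case or control cell; "
                "pass haldane=True to apply the Haldane-Anscombe 0.5 correction"
            )
        n_case = n_case + 0.5
        n_ctrl = n_ctrl + 0.5
    a, b = n_case, n_ctrl
    c, d = n_case[reference], n_ctrl[reference]
    log_or = np.log(a) - np.log(b) - math.log(c) + math.log(d)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    zq = sps.norm.ppf(0.975)
    ors = np.exp(log_or)
    lo, hi = np.exp(log_or - zq * se), np.exp(log_or + zq * se)
    ors[reference], lo[reference], hi[reference] = 1.0, 1.0, 1.0
    return QuantileOrTable(
        K=K,
        reference=reference,
        odds_ratios=ors,
        ci_low=lo,
        ci_high=hi,
        n_cases=n_case,
        n_controls=n_ctrl,
        mode="empirical",
        notes="cut-points from control-only quantiles",
    )
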