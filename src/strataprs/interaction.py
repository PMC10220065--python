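"""Summary-statistics test for multiplicative PRS-by-stratum interaction.

The question: is the association between a polygenic risk score and disease
stronger in one exposure stratum (e.g. never-smokers) than in the other
(ever-smokers)?  With individual genotypes the natural statistic contrasts
the case-control difference in mean PRS between the strata,

    Delta_s = mean PRS among cases - mean PRS among controls  (stratum s),
    Z = (Delta_1 - Delta_0) / sqrt(var(Delta_1) + var(Delta_0)),

which is standard normal under the null of no interaction.  When only
per-variant summary statistics are available, the same Z decomposes (for
independent variants) into a weighted contrast of the per-variant
association z-scores of the two strata:

    Z = sum_t (w_t^1 z_t^1 - w_t^0 z_t^0),

where the weight of variant t in stratum s is

    w_t^s = beta_t sqrt(v_t^{s+}/n^{s+} + v_t^{s-}/n^{s-}) / D,

with beta_t the PRS weight, v_t^{s+-} the genotypic variances among cases
and controls, n^{s+-} the (possibly variant-specific) counts, and D the
square root of the sum over variants of beta_t^2 times all four
variance/count terms, which normalises var(Z) to 1.

:func:`interaction_test_summary` implements the summary form and
:func:`interaction_test_individual` the individual-level form; the two are
algebraically identical when the summary z-scores are the two-sample
mean-difference z-scores with matching sample variances, and agree closely
when the z-scores come from single-variant logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import ValidationError
from .prs import PrsWeightSet, align_weights_to_panel, score_cohort
from .sumstats import VariantRecord, harmonize, wald_heterogeneity, zscore_to_p

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import IndividualCohort

#: stratum axis order used throughout: row 0 = never, row 1 = ever
STRATUM_INDEX = {"never": 0, "ever": 1}


@dataclass
class StratifiedSnpStats:
    """Per-variant, per-stratum inputs of the summary-statistics test.

    All per-variant arrays have shape ``(2, M)`` with row 0 the never
    stratum and row 1 the ever stratum (see :data:`STRATUM_INDEX`).
    ``n_case``/``n_control`` may be shape ``(2,)`` (one count per stratum)
    or ``(2, M)`` (variant-specific counts, e.g. when strata mix data
    sources of different depth).  ``z_logistic`` is the single-variant
    logistic-regression Wald z (what GWAS summary files contain);
    ``z_meandiff`` the two-sample genotype mean-difference z, for which the
    summary/individual equivalence is exact.  Variants that are monomorphic
    in a stratum carry NaN columns.
    """

    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    z_meandiff: np.ndarray
    var_case: np.ndarray
    var_control: np.ndarray
    n_case: np.ndarray
    n_control: np.ndarray
    eaf: np.ndarray
    z_logistic: np.ndarray | None = None
    variance_denominator: str = "n-1"

    def __post_init__(self) -> None:
        M = len(self.snp_ids)
        for name in ("z_meandiff", "var_case", "var_control", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (2, M):
                raise ValidationError(f"{name} must have shape (2, {M})")
        if self.z_logistic is not None:
            self.z_logistic = np.asarray(self.z_logistic, dtype=float)
            if self.z_logistic.shape != (2, M):
                raise ValidationError(f"z_logistic must have shape (2, {M})")
        for name in ("n_case", "n_control"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == (2,):
                arr = np.repeat(arr[:, None], M, axis=1)
            if arr.shape != (2, M):
                raise ValidationError(f"{name} must have shape (2,) or (2, {M})")
            setattr(self, name, arr)
        ok = np.isfinite(self.var_case) & np.isfinite(self.var_control)
        if np.any((self.var_case[ok] <= 0) | (self.var_control[ok] <= 0)):
            raise ValidationError("genotypic variances must be > 0")
        if np.any(self.n_case < 2) or np.any(self.n_control < 2):
            raise ValidationError("per-stratum case and control counts must be >= 2")

    @property
    def M(self) -> int:
        return len(self.snp_ids)


@dataclass
class InteractionResult:
    """Outcome of the PRS-by-stratum interaction test."""

    Z: float
    p: float
    contributions: np.ndarray
    log10p: float = 0.0
    method: str = "summary"

    def __post_init__(self) -> None:
        if abs(self.Z - float(np.sum(self.contributions))) > 1e-10 * max(1.0, abs(self.Z)):
            raise ValidationError("Z must equal the sum of per-variant contributions")


def _result(Z: float, contributions: np.ndarray, method: str) -> InteractionResult:
    p, log10p = zscore_to_p(Z)
    return InteractionResult(Z=float(Z), p=float(p), contributions=contributions,
                             log10p=float(log10p), method=method)


def interaction_test_summary(
    stats: StratifiedSnpStats,
    weights: PrsWeightSet,
    z_source: str = "logistic",
    variance_source: str = "observed",
    drop_missing: bool = False,
) -> InteractionResult:
    """PRS-by-stratum interaction test from per-variant summary statistics.

    Parameters
    ----------
    z_source
        ``"logistic"`` (default; what real GWAS summary files provide) or
        ``"meandiff"`` (for which the individual-level equivalence is exact).
    variance_source
        ``"observed"`` uses the genotypic sample variances carried in
        ``stats``; ``"hwe"`` replaces them by ``2 p (1-p)`` from the pooled
        per-stratum effect-allele frequency, the only option when raw
        variances are unavailable from a summary file.
    drop_missing
        Variants with NaN statistics in either stratum (e.g. monomorphic in
        one stratum) are an error by default, to avoid silently biasing the
        score; ``True`` drops them instead.
    """
    if z_source == "logistic":
        if stats.z_logistic is None:
            raise ValidationError("stats carry no logistic z-scores; use z_source='meandiff'")
        z = stats.z_logistic
    elif z_source == "meandiff":
        z = stats.z_meandiff
    else:
        raise ValidationError(f"unknown z_source {z_source!r}")

    beta = align_weights_to_panel(
        weights, stats.snp_ids, stats.effect_alleles, stats.other_alleles
    )
    if not np.any(beta != 0.0):
        raise ValidationError("all PRS weights are zero; the test is undefined")

    if variance_source == "observed":
        v_case, v_ctrl = stats.var_case, stats.var_control
    elif variance_source == "hwe":
        v = 2.0 * stats.eaf * (1.0 - stats.eaf)
        v_case, v_ctrl = v, v
    else:
        raise ValidationError(f"unknown variance_source {variance_source!r}")

    finite = np.all(np.isfinite(z), axis=0) & np.all(np.isfinite(v_case), axis=0) \
        & np.all(np.isfinite(v_ctrl), axis=0)
    if not np.all(finite):
        if not drop_missing:
            bad = [s for s, f in zip(stats.snp_ids, finite) if not f]
            raise ValidationError(
                f"variants with undefined statistics in a stratum: {bad}; "
                "pass drop_missing=True to exclude them"
            )
        z = z[:, finite]
        v_case, v_ctrl = v_case[:, finite], v_ctrl[:, finite]
        n_case, n_ctrl = stats.n_case[:, finite], stats.n_control[:, finite]
        beta = beta[finite]
    else:
        n_case, n_ctrl = stats.n_case, stats.n_control

    # per-variant, per-stratum sampling variance of the genotype mean difference
    var_delta = v_case / n_case + v_ctrl / n_ctrl  # (2, M)
    denom = np.sqrt(np.sum(beta**2 * np.sum(var_delta, axis=0)))
    if denom == 0.0:
        raise ValidationError("weight normalisation is degenerate (zero denominator)")
    w = beta * np.sqrt(var_delta) / denom  # (2, M)
    contributions = w[1] * z[1] - w[0] * z[0]
    return _result(np.sum(contributions), contributions, method=f"summary:{z_source}")


def interaction_test_individual(
    cohort: "IndividualCohort", weights: PrsWeightSet
) -> InteractionResult:
    """Individual-level oracle form of the interaction test.

    Computes the per-stratum case-control difference in mean PRS directly
    from subject-level scores; the variance of each difference is assembled
    per variant as ``sum_t beta_t^2 (var_case_t/n+ + var_control_t/n-)``
    (independent variants), matching the normalisation of the summary form
    exactly.
    """
    prs = score_cohort(cohort, weights)
    beta = align_weights_to_panel(
        weights, cohort.snp_ids, cohort.effect_alleles, cohort.other_alleles
    )
    delta = np.zeros(2)
    var_delta = np.zeros(2)
    mean_diff = np.zeros((2, len(beta)))
    for label, s in STRATUM_INDEX.items():
        in_s = cohort.stratum == label
        case = in_s & cohort.case_flag
        ctrl = in_s & ~cohort.case_flag
        if np.count_nonzero(case) < 2 or np.count_nonzero(ctrl) < 2:
            raise ValidationError(f"stratum {label!r} needs >= 2 cases and >= 2 controls")
        delta[s] = prs[case].mean() - prs[ctrl].mean()
        g_case = cohort.genotypes[case].astype(float)
        g_ctrl = cohort.genotypes[ctrl].astype(float)
        var_delta[s] = np.sum(
            beta**2 * (g_case.var(axis=0, ddof=1) / g_case.shape[0]
                       + g_ctrl.var(axis=0, ddof=1) / g_ctrl.shape[0])
        )
        mean_diff[s] = g_case.mean(axis=0) - g_ctrl.mean(axis=0)
    denom = np.sqrt(var_delta.sum())
    if denom == 0.0:
        raise ValidationError("degenerate cohort: zero PRS sampling variance")
    contributions = beta * (mean_diff[1] - mean_diff[0]) / denom
    return _result((delta[1] - delta[0]) / denom, contributions, method="individual")


def per_snp_interaction(
    record_never: VariantRecord, record_ever: VariantRecord
) -> tuple[float, float]:
    """Wald test of a multiplicative variant-by-stratum interaction.

    The ever-stratum record is harmonised to the never-stratum effect
    allele, then the two log-ORs are contrasted with
    :func:`strataprs.sumstats.wald_heterogeneity`.
    """
    aligned = harmonize(record_never, record_ever)
    return wald_heterogeneity(record_never.beta, record_never.se, aligned.beta, aligned.se)
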