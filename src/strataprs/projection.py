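"""Forward projection of GWAS yield and PRS accuracy under a mixture architecture.

The genetic architecture of a trait is summarised by the number of
candidate variants M, the fraction pi that is truly associated, and a
two-Gaussian mixture for the standardized (frequency-normalized) effect
sizes of the associated variants:

    beta_m ~ pi p1 N(0, sigma1^2) + pi p2 N(0, sigma2^2) + (1 - pi) delta_0.

Effects live on the standardized-genotype scale, so a case-control study
with n_cases / n_controls estimates each beta_m with standard error
``se = sqrt(1/n_cases + 1/n_controls)`` regardless of allele frequency.
Given fitted architecture parameters (fitting itself is the province of
dedicated summary-statistics likelihood tools and is not reimplemented
here), this module projects:

* :func:`expected_discoveries` — the expected number of variants reaching
  a significance threshold, in closed form;
* :func:`expected_auc` — the expected AUC of an additive PRS trained on a
  study of a given size, by Monte Carlo over architecture realisations,
  with either hard-threshold or posterior-mean (Bayes) SNP weighting; the
  per-realisation AUC uses the normal, rare-disease approximation
  ``AUC = Phi(sum w beta / sqrt(2 sum w^2))``;
* :func:`auc_uncertainty` — the AUC uncertainty induced by the sampling
  covariance of the fitted parameters, by resampling parameter sets from a
  multivariate normal with rejection of draws violating the constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError


@dataclass
class GeneticArchitecture:
    """Three-component effect-size mixture, plus optional parameter covariance.

    ``param_cov`` is the 5x5 covariance of Gamma = (pi, p1, p2, sigma1_sq,
    sigma2_sq) from the architecture fit, used only by
    :func:`auc_uncertainty`.
    """

    M: int
    pi: float
    p1: float
    p2: float
    sigma1_sq: float
    sigma2_sq: float
    param_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValidationError("M must be >= 1")
        if not (0.0 < self.pi <= 1.0):
            raise ValidationError("pi must lie in (0, 1]")
        if self.p1 < 0 or self.p2 < 0 or abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValidationError("p1, p2 must be nonnegative and sum to 1")
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValidationError("component variances must be > 0")
        if self.param_cov is not None:
            c = np.asarray(self.param_cov, dtype=float)
            if c.shape != (5, 5) or not np.allclose(c, c.T):
                raise ValidationError("param_cov must be a symmetric 5x5 matrix")
            if np.min(np.linalg.eigvalsh(c)) < -1e-10:
                raise ValidationError("param_cov must be positive semidefinite")
            self.param_cov = c

    @property
    def gamma(self) -> np.ndarray:
        return np.array([self.pi, self.p1, self.p2, self.sigma1_sq, self.sigma2_sq])


@dataclass
class StudyDesign:
    """Training-GWAS sample sizes and significance threshold."""

    n_cases: int
    n_controls: int
    alpha: float = 5e-8

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("counts must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0,1)")

    @property
    def se(self) -> float:
        """SE of a standardized-scale effect estimate."""
        return math.sqrt(1.0 / self.n_cases + 1.0 / self.n_controls)


def sample_true_effects(arch: GeneticArchitecture, seed=None) -> np.ndarray:
    """One realisation of the M true standardized effect sizes."""
    rng = np.random.default_rng(seed)
    return _sample_effects(arch, rng, 1)[0]


def _sample_effects(arch: GeneticArchitecture, rng: np.random.Generator, reps: int) -> np.ndarray:
    """(reps, M) matrix of true effects."""
    u = rng.random((reps, arch.M))
    comp1 = u < arch.pi * arch.p1
    comp2 = (u >= arch.pi * arch.p1) & (u < arch.pi)
    beta = np.zeros((reps, arch.M))
    n1, n2 = int(comp1.sum()), int(comp2.sum())
    if n1:
        beta[comp1] = rng.normal(0.0, math.sqrt(arch.sigma1_sq), size=n1)
    if n2:
        beta[comp2] = rng.normal(0.0, math.sqrt(arch.sigma2_sq), size=n2)
    return beta


def expected_discoveries(arch: GeneticArchitecture, design: StudyDesign) -> float:
    """Expected number of variants reaching the significance threshold.

    Marginally ``beta_hat ~ N(0, sigma_i^2 + se^2)`` within component i, so
    the detection probability has the closed form ``2 Phi(-c se /
    sqrt(sigma_i^2 + se^2))`` with c the two-sided critical value; null
    variants contribute the false-positive rate alpha.
    """
    se = design.se
    c = sps.norm.isf(design.alpha / 2.0)
    pow1 = 2.0 * sps.norm.cdf(-c * se / math.sqrt(arch.sigma1_sq + se**2))
    pow2 = 2.0 * sps.norm.cdf(-c * se / math.sqrt(arch.sigma2_sq + se**2))
    return arch.M * (
        arch.pi * arch.p1 * pow1 + arch.pi * arch.p2 * pow2 + (1.0 - arch.pi) * design.alpha
    )


def monte_carlo_discoveries(
    arch: GeneticArchitecture, design: StudyDesign, reps: int = 30, seed=None
) -> tuple[float, float]:
    """Simulation estimate of the expected discovery count, with MC SE."""
    rng = np.random.default_rng(seed)
    se = design.se
    c = sps.norm.isf(design.alpha / 2.0)
    counts = np.empty(reps)
    for r in range(reps):
        beta = _sample_effects(arch, rng, 1)[0]
        beta_hat = beta + rng.normal(0.0, se, size=arch.M)
        counts[r] = np.count_nonzero(np.abs(beta_hat / se) > c)
    return float(counts.mean()), float(counts.std(ddof=1) / math.sqrt(reps))


def _posterior_mean_weights(beta_hat: np.ndarray, arch: GeneticArchitecture, se: float) -> np.ndarray:
    """E[beta | beta_hat] under the three-component mixture prior."""
    comps = [
        (1.0 - arch.pi, se**2, 0.0),
        (arch.pi * arch.p1, arch.sigma1_sq + se**2, arch.sigma1_sq / (arch.sigma1_sq + se**2)),
        (arch.pi * arch.p2, arch.sigma2_sq + se**2, arch.sigma2_sq / (arch.sigma2_sq + se**2)),
    ]
    log_like = np.stack(
        [np.log(w) - 0.5 * (np.log(2 * np.pi * v) + beta_hat**2 / v) if w > 0
         else np.full_like(beta_hat, -np.inf)
         for w, v, _ in comps]
    )
    log_like -= log_like.max(axis=0, keepdims=True)
    resp = np.exp(log_like)
    resp /= resp.sum(axis=0, keepdims=True)
    shrink = resp[1] * comps[1][2] + resp[2] * comps[2][2]
    return shrink * beta_hat


def _auc_from_weights(w: np.ndarray, beta: np.ndarray) -> float:
    """Normal rare-disease AUC of a PRS with weights w and true effects beta."""
    ssw = float(np.sum(w**2))
    if ssw == 0.0:
        return 0.5
    return float(sps.norm.cdf(np.sum(w * beta) / math.sqrt(2.0 * ssw)))


def expected_auc(
    arch: GeneticArchitecture,
    design: StudyDesign,
    weighting: str = "threshold",
    mc_reps: int = 200,
    seed=None,
    weight_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    return_replicates: bool = False,
):
    """Expected PRS AUC for a training study of the given size.

    Per Monte-Carlo replicate: draw true effects, draw their estimates
    ``beta_hat ~ N(beta, se^2)``, form SNP weights — ``threshold`` keeps
    ``beta_hat`` for variants passing the significance threshold and zeroes
    the rest; ``posterior_mean`` shrinks every ``beta_hat`` by Bayes' rule
    under the mixture prior — and evaluate ``Phi(sum w beta / sqrt(2 sum
    w^2))`` (0.5 when no variant is selected).  Returns the mean AUC and
    its Monte-Carlo standard error.  ``weight_fn(beta, beta_hat)``
    overrides the weighting rule (e.g. the oracle ``w = beta``), for
    validation against the closed-form ceiling ``Phi(sqrt(sum beta^2)/sqrt(2))``.
    With ``return_replicates=True`` a third element is returned carrying the
    per-replicate AUCs and realized ``sum beta^2`` values.
    """
    if mc_reps < 2:
        raise ValidationError("mc_reps must be >= 2")
    if weighting not in ("threshold", "posterior_mean"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    se = design.se
    c = sps.norm.isf(design.alpha / 2.0)
    aucs = np.empty(mc_reps)
    ssb = np.empty(mc_reps)
    for r in range(mc_reps):
        beta = _sample_effects(arch, rng, 1)[0]
        beta_hat = beta + rng.normal(0.0, se, size=arch.M)
        if weight_fn is not None:
            w = weight_fn(beta, beta_hat)
        elif weighting == "threshold":
            w = np.where(np.abs(beta_hat / se) > c, beta_hat, 0.0)
        else:
            w = _posterior_mean_weights(beta_hat, arch, se)
        aucs[r] = _auc_from_weights(w, beta)
        ssb[r] = float(np.sum(beta**2))
    mean, mc_se = float(aucs.mean()), float(aucs.std(ddof=1) / math.sqrt(mc_reps))
    if return_replicates:
        return mean, mc_se, {"aucs": aucs, "sum_beta_sq": ssb}
    return mean, mc_se


@dataclass
class AucUncertainty:
    """AUC with parameter-uncertainty resampling."""

    auc_mean: float
    auc_se: float
    ci: tuple[float, float]
    n_rejected: int
    aucs: np.ndarray


def auc_uncertainty(
    arch: GeneticArchitecture,
    design: StudyDesign,
    reps: int = 1000,
    seed=None,
    mc_reps: int = 20,
    weighting: str = "threshold",
) -> AucUncertainty:
    """Propagate architecture-parameter uncertainty into the projected AUC.

    Parameter sets Gamma_k are drawn from a multivariate normal centred on
    the fitted Gamma with the fitted covariance; draws violating the
    constraints (pi outside (0,1], p1 outside [0,1], non-positive
    variances) are rejected and redrawn rather than clipped, which would
    bias the resampled distribution at the boundary.  If more than 90% of
    draws are invalid the covariance is deemed inconsistent with the
    constraints and an error is raised.  Returns the mean, SD and
    percentile 95% CI over the retained draws.  Deterministic given
    ``seed``.
    """
    if arch.param_cov is None:
        raise ValidationError("auc_uncertainty requires arch.param_cov")
    rng = np.random.default_rng(seed)
    gamma = arch.gamma
    aucs = np.empty(reps)
    n_rejected = 0
    max_tries = 10 * reps
    k = tries = 0
    while k < reps:
        if tries >= max_tries:
            raise ValidationError(
                f"more than 90% of parameter draws violate the constraints "
                f"({n_rejected}/{tries}); param_cov is inconsistent with them"
            )
        draw = rng.multivariate_normal(gamma, arch.param_cov)
        tries += 1
        pi, p1, p2, s1, s2 = draw
        if not (0.0 < pi <= 1.0) or not (0.0 <= p1 <= 1.0) or s1 <= 0 or s2 <= 0:
            n_rejected += 1
            continue
        arch_k = GeneticArchitecture(
            M=arch.M, pi=pi, p1=p1, p2=1.0 - p1, sigma1_sq=s1, sigma2_sq=s2
        )
        aucs[k], _ = expected_auc(
            arch_k, design, weighting=weighting, mc_reps=mc_reps,
            seed=rng.integers(2**31 - 1),
        )
        k += 1
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return AucUncertainty(
        auc_mean=float(aucs.mean()),
        auc_se=float(aucs.std(ddof=1)),
        ci=(float(lo), float(hi)),
        n_rejected=n_rejected,
        aucs=aucs,
    )
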