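"""Synthetic stratified case-control cohorts with known per-allele effects.

The generator inverts the additive logistic association model that a GWAS
fits: genotypes are drawn Binomial(2, p_t) per variant (Hardy-Weinberg
equilibrium, independent variants), disease status follows

    logit P(D=1 | g) = alpha_s + sum_t beta_{t,s} g_t

with a stratum-specific intercept alpha_s calibrated so the population
prevalence matches a target, and cases/controls are then sampled
retrospectively to exact per-stratum quotas — the ascertainment of a
case-control study.  Strata model exposure groups (never- vs ever-smokers)
with their own per-allele log-OR vectors, so an interaction alternative is
simply ``beta_never != beta_ever``.

:func:`summarize_cohort` reduces a cohort to the per-variant, per-stratum
statistics the summary-level machinery consumes: single-variant logistic
Wald z-scores (what real GWAS summary files contain), two-sample genotype
mean-difference z-scores (for which the summary/individual interaction
algebra is exact), genotypic sample variances (n-1 denominator) within
cases and controls, and pooled effect-allele frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from .exceptions import SimulationBudgetError, ValidationError
from .interaction import STRATUM_INDEX, StratifiedSnpStats
from .sumstats import VariantRecord

_CALIBRATION_SEED = 202301  # fixed: intercept calibration is a deterministic map
_CALIBRATION_SAMPLE = 20000
_MAX_CHUNKS = 200

_intercept_cache: dict[tuple, float] = {}


@dataclass
class CohortConfig:
    """Generative parameters of a two-stratum case-control cohort."""

    M: int
    eafs: np.ndarray
    beta_never: np.ndarray
    beta_ever: np.ndarray
    n_cases_never: int
    n_controls_never: int
    n_cases_ever: int
    n_controls_ever: int
    target_prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.eafs = np.asarray(self.eafs, dtype=float)
        self.beta_never = np.asarray(self.beta_never, dtype=float)
        self.beta_ever = np.asarray(self.beta_ever, dtype=float)
        for name in ("eafs", "beta_never", "beta_ever"):
            if getattr(self, name).shape != (self.M,):
                raise ValidationError(f"{name} must be a length-{self.M} vector")
        if np.any((self.eafs <= 0) | (self.eafs >= 1)):
            raise ValidationError("eafs must lie in (0,1)")
        for name in ("n_cases_never", "n_controls_never", "n_cases_ever", "n_controls_ever"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 < self.target_prevalence < 0.5):
            raise ValidationError("target_prevalence must lie in (0, 0.5)")


@dataclass
class IndividualCohort:
    """Genotype matrix plus case flags and stratum labels.

    ``genotypes`` holds allele counts in {0,1,2}, one row per subject and
    one column per variant; panel metadata (ids and alleles) makes the
    cohort self-describing for weight harmonisation.
    """

    genotypes: np.ndarray
    case_flag: np.ndarray
    stratum: np.ndarray
    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]

    def __post_init__(self) -> None:
        self.case_flag = np.asarray(self.case_flag, dtype=bool)
        self.stratum = np.asarray(self.stratum)
        g = self.genotypes
        if g.ndim != 2 or g.shape[0] != self.case_flag.size:
            raise ValidationError("genotypes must be (n_subjects, M)")
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValidationError("genotype entries must lie in {0,1,2}")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def M(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class CohortSummary:
    """Output of :func:`summarize_cohort`.

    ``records`` maps stratum label to per-variant logistic-regression
    results (empty when the logistic pass is skipped); ``stats`` carries
    the mean-difference z-scores and genotypic variances; ``flagged`` lists
    variants that were monomorphic within a stratum, whose statistics are
    NaN and which downstream tests exclude explicitly.
    """

    records: dict[str, list[VariantRecord]]
    stats: StratifiedSnpStats
    flagged: list[str] = field(default_factory=list)


def _calibrate_intercept(
    eafs: np.ndarray, beta: np.ndarray, target: float, tol: float = 1e-3
) -> float:
    """Intercept alpha with simulated population prevalence == target.

    Exact (``logit(target)``) when all effects are zero; otherwise bisection
    on the mean of ``expit(alpha + G beta)`` over a fixed-seed calibration
    sample, to tolerance ``tol``.  Cached: the map depends only on
    (eafs, beta, target).
    """
    if not np.any(beta != 0.0):
        return float(logit(target))
    key = (eafs.tobytes(), beta.tobytes(), float(target))
    if key in _intercept_cache:
        return _intercept_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    g = rng.binomial(2, eafs, size=(_CALIBRATION_SAMPLE, eafs.size))
    score = g @ beta
    half_width = 2.0 * float(np.sum(np.abs(beta))) + 1.0
    lo = float(logit(target)) - half_width
    hi = float(logit(target)) + half_width
    alpha = 0.5 * (lo + hi)
    for _ in range(80):
        alpha = 0.5 * (lo + hi)
        prev = float(np.mean(expit(alpha + score)))
        if abs(prev - target) < tol:
            break
        if prev < target:
            lo = alpha
        else:
            hi = alpha
    _intercept_cache[key] = alpha
    return alpha


def _default_panel(M: int) -> tuple[list[str], list[str], list[str]]:
    ids = [f"snp{t:05d}" for t in range(M)]
    return ids, ["A"] * M, ["G"] * M


def simulate_cohort(config: CohortConfig) -> IndividualCohort:
    """Draw a stratified case-control cohort to exact per-cell quotas.

    Within each stratum a population is simulated in chunks (genotypes
    under HWE, disease by the logistic model) and case/control rows are
    retained until the configured quotas are filled.  Deterministic given
    ``config.seed``.  If the quotas cannot be filled within a bounded
    number of chunks — e.g. an extreme prevalence — a
    :class:`SimulationBudgetError` is raised.
    """
    rng = np.random.default_rng(config.seed)
    blocks: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    plan = [
        ("never", config.beta_never, config.n_cases_never, config.n_controls_never),
        ("ever", config.beta_ever, config.n_cases_ever, config.n_controls_ever),
    ]
    prev = config.target_prevalence
    for label, beta, n_cases, n_controls in plan:
        alpha = _calibrate_intercept(config.eafs, beta, prev)
        need_pop = max(n_cases / prev, n_controls / (1.0 - prev))
        chunk = int(1.3 * need_pop) + 256
        cases: list[np.ndarray] = []
        controls: list[np.ndarray] = []
        got_cases = got_controls = 0
        for _ in range(_MAX_CHUNKS):
            if got_cases >= n_cases and got_controls >= n_controls:
                break
            g = rng.binomial(2, config.eafs, size=(chunk, config.M)).astype(np.int8)
            y = rng.random(chunk) < expit(alpha + g.astype(float) @ beta)
            if got_cases < n_cases:
                take = g[y][: n_cases - got_cases]
                cases.append(take)
                got_cases += take.shape[0]
            if got_controls < n_controls:
                take = g[~y][: n_controls - got_controls]
                controls.append(take)
                got_controls += take.shape[0]
        else:
            raise SimulationBudgetError(
                f"stratum {label!r}: could not fill {n_cases}+{n_controls} "
                f"case/control quota within {_MAX_CHUNKS} chunks of {chunk}"
            )
        g_s = np.vstack(cases + controls)
        blocks.append(g_s)
        flags.append(np.concatenate([np.ones(n_cases, bool), np.zeros(n_controls, bool)]))
        labels.append(np.full(n_cases + n_controls, label))
    ids, ea, oa = _default_panel(config.M)
    return IndividualCohort(
        genotypes=np.vstack(blocks),
        case_flag=np.concatenate(flags),
        stratum=np.concatenate(labels),
        snp_ids=ids,
        effect_alleles=ea,
        other_alleles=oa,
    )


def simulate_population(
    n: int,
    eafs: Sequence[float],
    beta: Sequence[float],
    target_prevalence: float,
    seed: int = 0,
    stratum: str = "never",
) -> IndividualCohort:
    """Prospective population of ``n`` subjects with realized disease status.

    Unlike :func:`simulate_cohort` there is no case/control quota: every
    drawn subject is kept, so case counts are random with expectation
    ``n * target_prevalence``.  Useful for rare-disease settings where the
    full population is the natural substrate (e.g. empirical quantile ORs).
    """
    eafs = np.asarray(eafs, dtype=float)
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    alpha = _calibrate_intercept(eafs, beta, target_prevalence)
    g = rng.binomial(2, eafs, size=(n, eafs.size)).astype(np.int8)
    y = rng.random(n) < expit(alpha + g.astype(float) @ beta)
    ids, ea, oa = _default_panel(eafs.size)
    return IndividualCohort(
        genotypes=g,
        case_flag=y,
        stratum=np.full(n, stratum),
        snp_ids=ids,
        effect_alleles=ea,
        other_alleles=oa,
    )


def _logistic_wald(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Single-variant additive logistic regression; (beta, se) or NaNs."""
    X = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=50)
        if not fit.mle_retvals.get("converged", True):
            return np.nan, np.nan
        return float(fit.params[1]), float(fit.bse[1])
    except Exception:
        return np.nan, np.nan


def summarize_cohort(
    cohort: IndividualCohort, include_logistic: bool = True
) -> CohortSummary:
    """Per-variant, per-stratum summary statistics of a cohort.

    For every variant and stratum this computes the pooled effect-allele
    frequency, genotypic sample variances among cases and among controls
    (n-1 denominator, recorded in the output metadata), the two-sample
    mean-difference z-score, and — unless ``include_logistic=False`` — the
    logistic-regression Wald statistics as :class:`VariantRecord` lists.
    Variants monomorphic within a stratum are flagged with a warning and
    carry NaN statistics.
    """
    strata = list(STRATUM_INDEX)
    M = cohort.M
    shape = (2, M)
    z_md = np.full(shape, np.nan)
    z_lr = np.full(shape, np.nan) if include_logistic else None
    v_case = np.full(shape, np.nan)
    v_ctrl = np.full(shape, np.nan)
    eaf = np.full(shape, np.nan)
    n_case = np.zeros(2)
    n_ctrl = np.zeros(2)
    records: dict[str, list[VariantRecord]] = {s: [] for s in strata} if include_logistic else {}
    flagged: set[str] = set()

    for label in strata:
        s = STRATUM_INDEX[label]
        in_s = cohort.stratum == label
        case = in_s & cohort.case_flag
        ctrl = in_s & ~cohort.case_flag
        nc, nk = int(case.sum()), int(ctrl.sum())
        if nc < 2 or nk < 2:
            raise ValidationError(f"stratum {label!r} needs >= 2 cases and >= 2 controls")
        n_case[s], n_ctrl[s] = nc, nk
        g_case = cohort.genotypes[case].astype(float)
        g_ctrl = cohort.genotypes[ctrl].astype(float)
        g_all = cohort.genotypes[in_s].astype(float)
        eaf[s] = g_all.mean(axis=0) / 2.0
        mono = g_all.var(axis=0) == 0.0
        vc = g_case.var(axis=0, ddof=1)
        vk = g_ctrl.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (g_case.mean(axis=0) - g_ctrl.mean(axis=0)) / np.sqrt(vc / nc + vk / nk)
        vc[mono] = np.nan
        vk[mono] = np.nan
        z[mono] = np.nan
        v_case[s], v_ctrl[s], z_md[s] = vc, vk, z
        flagged.update(np.asarray(cohort.snp_ids)[mono].tolist())
        if include_logistic:
            y = np.concatenate([np.ones(nc), np.zeros(nk)])
            gg = np.vstack([g_case, g_ctrl])
            for t in range(M):
                if mono[t]:
                    continue
                b, se = _logistic_wald(y, gg[:, t])
                if not np.isfinite(b) or not np.isfinite(se) or se <= 0:
                    flagged.add(cohort.snp_ids[t])
                    continue
                z_lr[s, t] = b / se
                records[label].append(
                    VariantRecord(
                        snp_id=cohort.snp_ids[t],
                        chrom="0",
                        pos=t + 1,
                        effect_allele=cohort.effect_alleles[t],
                        other_allele=cohort.other_alleles[t],
                        eaf=float(eaf[s, t]),
                        beta=b,
                        se=se,
                        n_cases=nc,
                        n_controls=nk,
                        stratum=label,
                    )
                )
    if flagged:
        warnings.warn(
            f"{len(flagged)} variant(s) monomorphic or unfit in a stratum, "
            f"statistics set to NaN: {sorted(flagged)[:10]}...",
            stacklevel=2,
        )
    stats = StratifiedSnpStats(
        snp_ids=list(cohort.snp_ids),
        effect_alleles=list(cohort.effect_alleles),
        other_alleles=list(cohort.other_alleles),
        z_meandiff=z_md,
        z_logistic=z_lr,
        var_case=v_case,
        var_control=v_ctrl,
        n_case=n_case,
        n_control=n_ctrl,
        eaf=eaf,
    )
    return CohortSummary(records=records, stats=stats, flagged=sorted(flagged))
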