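"""Per-variant summary statistics: data model, I/O, meta-analysis, heterogeneity, FDR.

The unit of data is one per-variant association result from a case-control
GWAS stratum: effect allele, effect-allele frequency (EAF), per-allele log
odds ratio (natural log), its standard error, z-score, two-sided p-value and
sample counts.  On top of that this module provides

* conversion of published ``OR (95% CI)`` cells into (log-OR, SE),
* inverse-variance-weighted fixed-effect meta-analysis,
* a Wald test for heterogeneity of two effect estimates (also the workhorse
  for per-variant exposure-stratum interaction tests), and
* Benjamini-Hochberg step-up q-values.

p-values are computed from z-scores through the normal survival function in
log space so that extremely significant variants (|z| > 38 or so) do not
underflow to 0; ``log10p`` is carried alongside ``p`` for that reason.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateIntervalError,
    HarmonizationError,
    SumstatsFormatError,
    ValidationError,
)

STRATA = ("never", "ever", "combined")

_LN10 = math.log(10.0)

#: complementary base pairing, used to detect strand flips
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def zscore_to_p(z: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal p-value for a z-score, computed in log space.

    Returns ``(p, log10p)``; ``p`` underflows to 0.0 below ~1e-308 but
    ``log10p`` stays finite.
    """
    z = np.asarray(z, dtype=float)
    logp = math.log(2.0) + sps.norm.logsf(np.abs(z))
    return np.exp(logp), logp / _LN10


@dataclass
class VariantRecord:
    """One per-variant association result in one stratum.

    ``beta`` is the per-effect-allele log odds ratio (natural log); ``eaf``
    the effect-allele frequency.  ``z``, ``p`` and ``log10p`` are derived
    from ``beta``/``se`` when not supplied.  A supplied ``p`` (e.g. one
    transcribed from a published table, where the printed CI is rounded) is
    kept as-is rather than overwritten.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n_cases: int
    n_controls: int
    stratum: str = "combined"
    z: float | None = None
    p: float | None = None
    log10p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(
                f"{self.snp_id}: eaf must lie in (0,1), got {self.eaf}"
            )
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError(f"{self.snp_id}: case/control counts must be >= 1")
        if self.stratum not in STRATA:
            raise ValidationError(
                f"{self.snp_id}: stratum must be one of {STRATA}, got {self.stratum!r}"
            )
        if self.z is None:
            self.z = self.beta / self.se
        if self.p is None:
            p, log10p = zscore_to_p(self.z)
            self.p = float(p)
            self.log10p = float(log10p)
        else:
            if not (0.0 < self.p <= 1.0):
                raise ValidationError(f"{self.snp_id}: p must lie in (0,1]")
            if self.log10p is None:
                self.log10p = math.log10(self.p)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def is_strand_ambiguous(self) -> bool:
        return is_strand_ambiguous(self.effect_allele, self.other_allele)


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect combination of k estimates."""

    beta: float
    se: float
    z: float
    p: float
    k: int
    log10p: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("meta-analysis SE must be > 0")
        if self.k < 1:
            raise ValidationError("meta-analysis needs k >= 1 inputs")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def ci_to_logse(
    or_point: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Recover (log-OR, SE) from a published odds ratio and Wald CI.

    ``se = (ln ci_high - ln ci_low) / (2 z)`` with ``z`` the normal quantile
    at ``(1+level)/2`` (1.959964 for a 95% interval) — the GWAS convention
    for Wald intervals on the log-odds scale.
    """
    if not (0.0 < ci_low <= or_point <= ci_high):
        raise ValidationError(
            f"require 0 < ci_low <= or <= ci_high, got ({or_point}, {ci_low}, {ci_high})"
        )
    if ci_low == ci_high:
        raise DegenerateIntervalError("confidence interval has zero width")
    if not (0.0 < level < 1.0):
        raise ValidationError("confidence level must lie in (0,1)")
    zq = sps.norm.ppf(0.5 + level / 2.0)
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * zq)
    return beta, se


def fixed_effect_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    ``estimates`` is a sequence of ``(beta, se)`` pairs on the log-OR scale.
    Weights are ``1/se**2``; the combined estimate is the weighted mean and
    the combined SE is ``(sum of weights)**-0.5``.
    """
    if len(estimates) == 0:
        raise ValidationError("fixed_effect_meta requires at least one estimate")
    beta = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be > 0")
    w = 1.0 / se**2
    beta_c = float(np.sum(w * beta) / np.sum(w))
    se_c = float(1.0 / math.sqrt(np.sum(w)))
    z = beta_c / se_c
    p, log10p = zscore_to_p(z)
    return MetaResult(beta=beta_c, se=se_c, z=z, p=float(p), k=len(estimates),
                      log10p=float(log10p))


def wald_heterogeneity(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Wald test of equality of two independent effect estimates.

    ``z = (beta1 - beta2) / sqrt(se1**2 + se2**2)``; two-sided normal p.
    Used both for cross-population heterogeneity of effect sizes and for
    per-variant exposure-stratum interaction tests.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValidationError("standard errors must be > 0")
    z = (beta1 - beta2) / math.sqrt(se1**2 + se2**2)
    p, _ = zscore_to_p(z)
    return float(z), float(p)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr requires a non-empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def is_strand_ambiguous(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, which cannot be disambiguated across strands."""
    return _COMPLEMENT.get(effect_allele.upper()) == other_allele.upper()


def harmonize(reference: VariantRecord, other: VariantRecord) -> VariantRecord:
    """Align ``other`` to the effect allele of ``reference``.

    If the two records already agree, ``other`` is returned unchanged.  If
    the alleles are swapped, beta and z are negated and eaf reflected.
    Strand-ambiguous (A/T, C/G) variants are flagged with a warning rather
    than silently flipped.  Unresolvable allele pairs raise
    :class:`HarmonizationError`.
    """
    if reference.snp_id != other.snp_id:
        raise HarmonizationError(
            f"cannot harmonize different variants {reference.snp_id!r} / {other.snp_id!r}"
        )
    ea_r, oa_r = reference.effect_allele.upper(), reference.other_allele.upper()
    ea_o, oa_o = other.effect_allele.upper(), other.other_allele.upper()
    if reference.is_strand_ambiguous() or other.is_strand_ambiguous():
        warnings.warn(
            f"{reference.snp_id}: strand-ambiguous alleles; harmonisation by allele "
            "label only, check strand before trusting the sign",
            stacklevel=2,
        )
    if (ea_o, oa_o) == (ea_r, oa_r):
        return other
    if (ea_o, oa_o) == (oa_r, ea_r):
        flipped = replace(
            other,
            effect_allele=reference.effect_allele,
            other_allele=reference.other_allele,
            eaf=1.0 - other.eaf,
            beta=-other.beta,
            z=-other.z if other.z is not None else None,
        )
        return flipped
    raise HarmonizationError(
        f"{reference.snp_id}: alleles {ea_o}/{oa_o} incompatible with {ea_r}/{oa_r}"
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "n_cases", "n_controls", "stratum")


def read_sumstats(path) -> list[VariantRecord]:
    """Read a tab-delimited summary-statistics file into validated records.

    The header must name the mandatory columns plus either ``beta``+``se``
    or ``or``+``or_l95``+``or_u95`` (the latter converted through
    :func:`ci_to_logse`).  Lines starting with ``#`` are ignored.  Row order
    is preserved; an invalid row raises :class:`ValidationError` naming it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s) {missing}")
    has_beta = "beta" in df.columns and "se" in df.columns
    has_ci = all(c in df.columns for c in ("or", "or_l95", "or_u95"))
    if not (has_beta or has_ci):
        raise SumstatsFormatError(
            f"{path}: need either beta+se or or+or_l95+or_u95 columns"
        )
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        try:
            if has_beta and not (pd.isna(row.get("beta")) or pd.isna(row.get("se"))):
                beta, se = float(row["beta"]), float(row["se"])
            else:
                beta, se = ci_to_logse(
                    float(row["or"]), float(row["or_l95"]), float(row["or_u95"])
                )
            p = float(row["p"]) if "p" in df.columns and not pd.isna(row["p"]) else None
            records.append(
                VariantRecord(
                    snp_id=str(row["snp_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    eaf=float(row["eaf"]),
                    beta=beta,
                    se=se,
                    p=p,
                    n_cases=int(row["n_cases"]),
                    n_controls=int(row["n_controls"]),
                    stratum=str(row["stratum"]),
                )
            )
        except (ValidationError, DegenerateIntervalError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_sumstats(records: Sequence[VariantRecord], path) -> None:
    """Write records as a tab-delimited file readable by :func:`read_sumstats`."""
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "n_cases": [r.n_cases for r in records],
            "n_controls": [r.n_controls for r in records],
            "stratum": [r.stratum for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def meta_analyze_records(records: Sequence[VariantRecord]) -> MetaResult:
    """Fixed-effect meta-analysis of records for one variant.

    Records after the first are harmonised to the first record's effect
    allele before combining.
    """
    if len(records) == 0:
        raise ValidationError("no records to combine")
    ref = records[0]
    aligned = [ref] + [harmonize(ref, r) for r in records[1:]]
    return fixed_effect_meta([(r.beta, r.se) for r in aligned])
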