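"""Familial relative risk attributable to susceptibility variants.

Under a multiplicative per-allele model, a variant with risk-allele
frequency p and per-allele odds ratio OR contributes a familial relative
risk to first-degree relatives of

    lambda = (p OR^2 + (1 - p)) / (p OR + 1 - p)^2,

which is >= 1 with equality iff OR = 1, and is invariant to relabelling the
risk allele (p -> 1-p, OR -> 1/OR).  Assuming independent variants acting
multiplicatively, the fraction of the observed familial risk lambda0
explained by a panel is ``sum_t ln(lambda_t) / ln(lambda0)``.  lambda0 is an
external epidemiological estimate and therefore a parameter, not a
constant; 1.84 is a published first-degree-relative estimate for lung
adenocarcinoma and serves as the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

DEFAULT_LAMBDA0 = 1.84


@dataclass
class FamilialVariant:
    """Risk-allele frequency and per-allele odds ratio for one variant."""

    p: float
    odds_ratio: float
    snp_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValidationError(f"{self.snp_id}: frequency must lie in (0,1)")
        if not self.odds_ratio > 0:
            raise ValidationError(f"{self.snp_id}: odds ratio must be > 0")


@dataclass
class FamilialResult:
    """Per-variant familial relative risks and the fraction explained."""

    lambdas: np.ndarray
    fraction: float
    lambda0: float
    contributions: np.ndarray  # per-variant ln(lambda_t) / ln(lambda0)


def lambda_snp(p: float, or_point: float) -> float:
    """Familial relative risk contributed by one variant."""
    if not (0.0 < p < 1.0):
        raise ValidationError("frequency must lie strictly inside (0,1)")
    if not or_point > 0:
        raise ValidationError("odds ratio must be > 0")
    num = p * or_point**2 + (1.0 - p)
    den = (p * or_point + 1.0 - p) ** 2
    return num / den


def as_risk_allele(p: float, or_point: float) -> tuple[float, float]:
    """Flip to the risk-allele orientation (OR >= 1); lambda is unchanged."""
    if or_point >= 1.0:
        return p, or_point
    return 1.0 - p, 1.0 / or_point


def frr_fraction(
    variants: Sequence[FamilialVariant], lambda0: float = DEFAULT_LAMBDA0
) -> FamilialResult:
    """Fraction of the familial relative risk explained by a variant panel.

    Protective-allele inputs are internally flipped to the risk-allele
    orientation for reporting; the fraction itself is unaffected by the
    flip.  An empty panel explains fraction 0.
    """
    if not lambda0 > 1.0:
        raise ValidationError("lambda0 must be > 1")
    lambdas = np.array(
        [lambda_snp(*as_risk_allele(v.p, v.odds_ratio)) for v in variants], dtype=float
    )
    contributions = np.log(lambdas) / math.log(lambda0) if lambdas.size else np.array([])
    fraction = float(np.sum(contributions)) if lambdas.size else 0.0
    return FamilialResult(
        lambdas=lambdas, fraction=fraction, lambda0=lambda0, contributions=contributions
    )
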