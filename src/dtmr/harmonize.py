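"""Harmonisation of exposure and outcome summary statistics.

Two-sample MR joins per-variant effects from two GWAS; before any
estimation both must be expressed per copy of the same effect allele.
Variants whose outcome record carries the swapped allele pair have their
outcome beta negated; variants whose allele pairs differ are dropped
with a logged reason.  Because palindromic variants are excluded at
selection, no frequency-based strand inference is needed and EAF is
never consulted.

Estimates are computed on the biomarker-increasing scale and reported,
following the convention for anti-inflammatory drug proxies, as odds
ratios per unit *decrease* in the genetically predicted biomarker:
OR = exp(-theta).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .exceptions import AlleleMismatchError, ConfigurationError
from .instruments import PALINDROMIC_PAIRS
from .io import VariantAssociation

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile; 95% CIs throughout


@dataclass
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on one orientation."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    flipped: bool = False
    palindromic: bool = False
    chrom: str = ""
    pos: int = 0

    def __post_init__(self):
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


def harmonize_pair(exposure: VariantAssociation,
                   outcome: VariantAssociation) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's allele orientation."""
    if exposure.rsid != outcome.rsid:
        raise ConfigurationError(
            f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    if (outcome.effect_allele == exposure.effect_allele
            and outcome.other_allele == exposure.other_allele):
        beta_y, flipped = outcome.beta, False
    elif (outcome.effect_allele == exposure.other_allele
            and outcome.other_allele == exposure.effect_allele):
        beta_y, flipped = -outcome.beta, True
    else:
        raise AlleleMismatchError(
            f"{exposure.rsid}: allele mismatch "
            f"({exposure.effect_allele}/{exposure.other_allele} vs "
            f"{outcome.effect_allele}/{outcome.other_allele})")
    return HarmonizedInstrument(
        rsid=exposure.rsid,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_y,
        se_outcome=outcome.se,
        flipped=flipped,
        palindromic=exposure.alleles in PALINDROMIC_PAIRS,
        chrom=exposure.chrom,
        pos=exposure.pos,
    )


def harmonize(exposures: list[VariantAssociation],
              outcomes: list[VariantAssociation]
              ) -> tuple[list[HarmonizedInstrument], list[dict]]:
    """Join two sets of associations on rsid.

    Returns the harmonized instruments plus a drop-log of
    ``{"rsid": ..., "reason": ...}`` records for variants missing from
    the outcome GWAS or with incompatible alleles.
    """
    by_rsid = {o.rsid: o for o in outcomes}
    kept, dropped = [], []
    for exp in exposures:
        out = by_rsid.get(exp.rsid)
        if out is None:
            dropped.append({"rsid": exp.rsid,
                            "reason": "absent from outcome GWAS"})
            continue
        try:
            kept.append(harmonize_pair(exp, out))
        except AlleleMismatchError:
            dropped.append({"rsid": exp.rsid, "reason": "allele mismatch"})
    if dropped:
        logger.info("harmonisation dropped %d variant(s)", len(dropped))
    return kept, dropped


def orient_exposure_increasing(instruments: list[HarmonizedInstrument]
                               ) -> list[HarmonizedInstrument]:
    """Re-express every instrument with beta_exposure ≥ 0.

    Negating both betas (and swapping the allele labels) leaves each
    Wald ratio unchanged; estimation then happens on the
    biomarker-increasing scale.  Instruments with exactly zero exposure
    effect have an undefined ratio and are dropped with a warning.
    """
    out = []
    for ins in instruments:
        if ins.beta_exposure == 0:
            logger.warning("dropping %s: zero exposure effect", ins.rsid)
            continue
        if ins.beta_exposure < 0:
            ins = replace(
                ins,
                effect_allele=ins.other_allele,
                other_allele=ins.effect_allele,
                beta_exposure=-ins.beta_exposure,
                beta_outcome=-ins.beta_outcome,
                flipped=not ins.flipped,
            )
        out.append(ins)
    return out


def to_or_per_unit_decrease(theta: float, se: float,
                            ci_low: float | None = None,
                            ci_high: float | None = None
                            ) -> tuple[float, float, float]:
    """Transform a log-odds slope into an OR per unit biomarker decrease.

    Returns ``(OR, ci_low, ci_high)`` with OR = exp(-theta) and CI
    bounds ordered ascending after the sign flip.
    """
    if ci_low is None:
        ci_low = theta - Z95 * se
    if ci_high is None:
        ci_high = theta + Z95 * se
    lo, hi = math.exp(-ci_high), math.exp(-ci_low)
    return math.exp(-theta), min(lo, hi), max(lo, hi)
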